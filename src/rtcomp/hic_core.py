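"""Cis contact-matrix plumbing and first-order Hi-C statistics.

Everything downstream of binned counts: matrix balancing (iterative
correction to equal marginals), per-distance expected values,
observed/expected maps, contact-probability scaling curves, short/long-range
signal fractions and differential maps against a reference genotype.

Conventions
-----------
* Bins are 0-based half-open; entry ``(i, j)`` covers
  ``[i*bs, (i+1)*bs) x [j*bs, (j+1)*bs)``.
* Invalid bins (mask) carry NaN rows/columns; NaN entries are excluded from
  every mean.
* The diagonal and the first off-diagonal are excluded from O/E (and hence
  saddles) by default — the usual short-range artefact convention; the number
  of excluded diagonals is configurable.
* Analyses are cis-only; trans contacts are never represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ContactMatrix",
    "ScalingCurve",
    "balance",
    "expected_by_distance",
    "observed_over_expected",
    "contact_scaling",
    "range_fractions",
    "differential_map",
]


@dataclass
class ContactMatrix:
    """Symmetric cis contact matrix for one chromosome.

    ``scale`` tracks the processing stage: ``"raw"`` counts, ``"balanced"``
    frequencies (weights present), ``"oe"`` observed/expected, or
    ``"log_ratio"`` for differential maps.
    """

    chrom: str
    bin_size: int
    data: np.ndarray
    valid: np.ndarray
    scale: str = "raw"
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = self.data.shape[0]
        if self.data.shape != (n, n):
            raise ValueError("contact matrix must be square")
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != (n,):
            raise ValueError("valid mask length must match matrix size")
        finite = np.isfinite(self.data)
        if not np.allclose(
            np.where(finite, self.data, 0.0),
            np.where(finite.T, self.data.T, 0.0),
            rtol=1e-8,
            atol=1e-8,
            equal_nan=False,
        ):
            raise ValueError("contact matrix must be symmetric")

    @property
    def n_bins(self) -> int:
        return self.data.shape[0]

    @property
    def balanced(self) -> bool:
        return self.scale in ("balanced", "oe")

    def masked_data(self) -> np.ndarray:
        """Copy of the matrix with invalid rows/columns set to NaN."""
        out = self.data.copy()
        out[~self.valid, :] = np.nan
        out[:, ~self.valid] = np.nan
        return out

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.chrom,
            self.bin_size,
            self.data.copy(),
            self.valid.copy(),
            self.scale,
            None if self.weights is None else self.weights.copy(),
        )


def _as_list(m) -> list[ContactMatrix]:
    return [m] if isinstance(m, ContactMatrix) else list(m)


def balance(
    matrix: ContactMatrix,
    tol: float = 1e-5,
    max_iter: int = 1000,
    mad_max: float = 5.0,
) -> ContactMatrix:
    """Iterative correction to equal marginals.

    Bins whose marginal is zero, or whose log marginal deviates from the
    median by more than `mad_max` median absolute deviations, are masked
    before correction. Iteration divides rows/columns by their normalised
    marginals until every unmasked marginal is within `tol` (relative) of the
    common mean. The returned matrix is rescaled so unmasked marginals
    average 1, and carries per-bin weights such that
    ``balanced = raw * w_i * w_j``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if matrix.scale != "raw":
        raise ValueError("balance expects a raw count matrix")
    data = matrix.masked_data()
    n = matrix.n_bins
    marg = np.nansum(np.where(np.isfinite(data), data, 0.0), axis=1)
    valid = matrix.valid & (marg > 0)
    if valid.sum() == 0:
        raise ValueError("all bins masked; nothing to balance")
    logm = np.log(marg[valid])
    med = np.median(logm)
    mad = np.median(np.abs(logm - med))
    if mad > 0:
        keep = np.abs(np.log(np.where(marg > 0, marg, np.nan)) - med) <= mad_max * mad
        valid &= np.where(np.isfinite(keep), keep, False).astype(bool)
    if valid.sum() == 0:
        raise ValueError("all bins masked after MAD filtering")
    data[~valid, :] = np.nan
    data[:, ~valid] = np.nan
    weights = np.full(n, np.nan)
    weights[valid] = 1.0
    for _ in range(max_iter):
        s = np.nansum(np.where(np.isfinite(data), data, 0.0), axis=1)
        sv = s[valid]
        sv = sv / sv.mean()
        scale = np.ones(n)
        scale[valid] = sv
        data /= np.outer(scale, scale)
        weights[valid] /= sv
        if np.max(np.abs(sv - 1.0)) < tol:
            break
    # final rescale: unmasked marginals average exactly 1
    s = np.nansum(np.where(np.isfinite(data), data, 0.0), axis=1)
    g = s[valid].mean()
    if g > 0:
        data /= g
        weights[valid] /= np.sqrt(g)
    return ContactMatrix(matrix.chrom, matrix.bin_size, data, valid, "balanced", weights)


def _diag_stats(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-offset sums and finite-pair counts over the upper triangle."""
    n = data.shape[0]
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    for d in range(n):
        diag = np.diagonal(data, d)
        fin = np.isfinite(diag)
        sums[d] = diag[fin].sum()
        counts[d] = int(fin.sum())
    return sums, counts


def expected_by_distance(
    matrix: ContactMatrix, min_pairs: int = 10, pool_factor: float = 1.3
) -> np.ndarray:
    """Mean contact frequency per bin-distance, for a balanced matrix.

    Distances with fewer than `min_pairs` unmasked pairs borrow strength from
    a geometrically widening window ``[d/f, d*f]`` (f grows by `pool_factor`
    until the window holds enough pairs). Returns an array of length n_bins
    indexed by bin distance; NaN where no data exists at all.
    """
    if not matrix.balanced:
        raise ValueError("expected_by_distance requires a balanced matrix")
    data = matrix.masked_data()
    sums, counts = _diag_stats(data)
    n = len(sums)
    expected = np.full(n, np.nan)
    ok = counts >= min_pairs
    expected[ok] = sums[ok] / counts[ok]
    for d in np.nonzero(~ok)[0]:
        if counts[d] == 0 and d == 0:
            continue
        f = pool_factor
        while True:
            lo = max(1, int(np.floor(d / f))) if d > 0 else 0
            hi = min(n - 1, int(np.ceil(d * f))) if d > 0 else 0
            c = counts[lo : hi + 1].sum()
            if c >= min_pairs or (lo == 1 and hi == n - 1):
                if c > 0:
                    expected[d] = sums[lo : hi + 1].sum() / c
                break
            f *= pool_factor
    return expected


def observed_over_expected(
    matrix: ContactMatrix, exclude_diags: int = 2, min_pairs: int = 10
) -> ContactMatrix:
    """Divide a balanced matrix by its per-distance expected.

    The first `exclude_diags` diagonals (main diagonal included) are set to
    NaN. For every distance with at least `min_pairs` unmasked pairs the mean
    O/E is exactly 1 by construction.
    """
    if not matrix.balanced:
        raise ValueError("observed_over_expected requires a balanced matrix")
    expected = expected_by_distance(matrix, min_pairs=min_pairs)
    data = matrix.masked_data()
    n = matrix.n_bins
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    occupied = np.zeros(n, dtype=bool)
    for d in range(exclude_diags, n):
        diag = np.diagonal(data, d)
        if np.any(np.isfinite(diag) & (diag != 0)):
            occupied[d] = True
    bad = occupied & (expected == 0)
    if bad.any():
        raise ValueError(
            f"zero expected value at occupied distance(s) {np.nonzero(bad)[0][:5]}"
        )
    exp_d = np.where(expected > 0, expected, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = data / exp_d[dist]
    oe[dist < exclude_diags] = np.nan
    return ContactMatrix(
        matrix.chrom, matrix.bin_size, oe, matrix.valid.copy(), "oe", matrix.weights
    )


@dataclass
class ScalingCurve:
    """Contact frequency vs genomic distance on geometric distance bins.

    ``freq`` is the across-replica median, normalised to unit area in
    log-distance (so samples with different totals are comparable); ``sd`` is
    the across-replica standard deviation on the same normalisation.
    """

    distances: np.ndarray  # bp, geometric bin centres
    freq: np.ndarray
    sd: np.ndarray
    n_pairs: np.ndarray
    per_sample: np.ndarray  # (n_samples, n_distance_bins)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.distances) <= 0):
            raise ValueError("distances must be strictly increasing")

    def loglog_slope(self, d_min: float | None = None, d_max: float | None = None) -> float:
        """Least-squares slope of log(freq) vs log(distance) on a range."""
        sel = np.isfinite(self.freq) & (self.freq > 0)
        if d_min is not None:
            sel &= self.distances >= d_min
        if d_max is not None:
            sel &= self.distances <= d_max
        x = np.log(self.distances[sel])
        y = np.log(self.freq[sel])
        return float(np.polyfit(x, y, 1)[0])


def _sample_scaling(
    mats: list[ContactMatrix], edges: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    sums = np.zeros(len(edges) - 1)
    pairs = np.zeros(len(edges) - 1)
    for m in mats:
        data = m.masked_data()
        dsum, dcnt = _diag_stats(data)
        d_bp = np.arange(len(dsum)) * m.bin_size
        which = np.searchsorted(edges, d_bp, side="right") - 1
        for k in range(len(edges) - 1):
            sel = (which == k) & (np.arange(len(dsum)) > 0)
            sums[k] += dsum[sel].sum()
            pairs[k] += dcnt[sel].sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(pairs > 0, sums / pairs, np.nan)
    return freq, pairs


def contact_scaling(
    samples: list[list[ContactMatrix]] | list[ContactMatrix],
    dist_bins_per_decade: int = 8,
) -> ScalingCurve:
    """Distance-decay curve, median across replicate samples.

    `samples` is a list of replicas, each a list of balanced per-chromosome
    matrices (a single matrix or flat list is treated as one replica). Per
    replica, mean balanced signal per pair is aggregated in geometric distance
    bins pooled over chromosomes, then normalised to unit area in
    log-distance; the reported curve is the per-distance median with an
    across-replica sd band.
    """
    if dist_bins_per_decade <= 0:
        raise ValueError("dist_bins_per_decade must be positive")
    if isinstance(samples, ContactMatrix):
        samples = [[samples]]
    elif samples and isinstance(samples[0], ContactMatrix):
        samples = [list(samples)]  # type: ignore[list-item]
    if not samples:
        raise ValueError("need at least one sample")
    flat = [m for s in samples for m in s]
    bs = {m.bin_size for m in flat}
    if len(bs) != 1:
        raise ValueError("inconsistent bin sizes across matrices")
    bin_size = bs.pop()
    for m in flat:
        if not m.balanced:
            raise ValueError("contact_scaling requires balanced matrices")
    d_max = max(m.n_bins - 1 for m in flat) * bin_size
    lo, hi = np.log10(bin_size), np.log10(d_max)
    n_edges = int(np.ceil((hi - lo) * dist_bins_per_decade)) + 1
    edges = 10 ** np.linspace(lo, hi + 1e-9, n_edges + 1)
    dlog = np.diff(np.log(edges))
    curves, pair_list = [], []
    for s in samples:
        freq, pairs = _sample_scaling(list(s), edges)
        area = np.nansum(freq * dlog)
        curves.append(freq / area)
        pair_list.append(pairs)
    per_sample = np.vstack(curves)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN distance bins
        med = np.nanmedian(per_sample, axis=0)
        sd = (
            np.nanstd(per_sample, axis=0, ddof=1)
            if len(curves) > 1
            else np.zeros_like(med)
        )
    centres = np.sqrt(edges[:-1] * edges[1:])
    keep = np.isfinite(med)
    return ScalingCurve(
        centres[keep],
        med[keep],
        sd[keep],
        np.sum(pair_list, axis=0)[keep],
        per_sample[:, keep],
    )


def range_fractions(
    matrix: ContactMatrix | list[ContactMatrix],
    short_max: float = 0.3e6,
    long_min: float = 10e6,
) -> tuple[float, float]:
    """Fractions of cis signal at short (<= short_max) and long (>= long_min) range.

    Computed over unmasked off-diagonal entries of one or more balanced
    matrices (pooled); the two fractions plus the mid-range remainder sum
    to 1.
    """
    if short_max >= long_min:
        raise ValueError("short_max must be below long_min")
    mats = _as_list(matrix)
    tot = short = long_ = 0.0
    for m in mats:
        if not m.balanced:
            raise ValueError("range_fractions requires balanced matrices")
        dsum, _ = _diag_stats(m.masked_data())
        d_bp = np.arange(len(dsum)) * m.bin_size
        sel = np.arange(len(dsum)) > 0
        tot += dsum[sel].sum()
        short += dsum[sel & (d_bp <= short_max)].sum()
        long_ += dsum[sel & (d_bp >= long_min)].sum()
    if tot <= 0:
        raise ValueError("no unmasked cis signal")
    return short / tot, long_ / tot


def differential_map(
    sample: ContactMatrix, reference: ContactMatrix, pseudo: float = 1e-9
) -> ContactMatrix:
    """Log ratio of two balanced maps, each rescaled to equal total signal.

    ``entry = log((sample + pseudo) / (reference + pseudo))`` after dividing
    each matrix by its total unmasked signal; antisymmetric under swapping the
    arguments. Bins masked in either input are masked in the output.
    """
    if pseudo <= 0:
        raise ValueError("pseudo must be positive")
    if not (sample.balanced and reference.balanced):
        raise ValueError("differential_map requires balanced matrices")
    if sample.chrom != reference.chrom or sample.n_bins != reference.n_bins:
        raise ValueError("sample and reference must share chromosome and binning")
    if sample.bin_size != reference.bin_size:
        raise ValueError("bin size mismatch")
    valid = sample.valid & reference.valid
    a = sample.masked_data()
    b = reference.masked_data()
    a /= np.nansum(np.where(np.isfinite(a), a, 0.0))
    b /= np.nansum(np.where(np.isfinite(b), b, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = np.log((a + pseudo) / (b + pseudo))
    diff[~valid, :] = np.nan
    diff[:, ~valid] = np.nan
    return ContactMatrix(sample.chrom, sample.bin_size, diff, valid, "log_ratio")
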