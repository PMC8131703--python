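"""Track-conditioned saddle statistics.

A saddle plot bins the genome into Q equal-count quantiles of a ranking
track (RT score, RIF1 occupancy, or the compartment eigenvector), then
averages the observed/expected contact frequency over every cis pair of
quantile groups. Same-class corners (top-top = AA, bottom-bottom = BB for an
RT ranking) above 1 and the cross corner (AB) below 1 are the signature of
A/B compartmentalisation; the corner statistic ``(AA*BB)/AB**2`` is the
compartment strength (1 for a structureless map). On the package's
block-model generator with modulation ``exp(delta*c_i*c_j)`` the strength
has the closed form ``exp(4*delta)``, which anchors all numerical checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import BinnedTrack, GenomeSpec
from .hic_core import ContactMatrix

__all__ = [
    "QuantileLabels",
    "SaddleResult",
    "DistanceStrengthCurve",
    "digitize_track",
    "saddle_matrix",
    "compartment_strength",
    "strength_by_distance",
    "differential_saddle",
]


@dataclass
class QuantileLabels:
    """Per-bin quantile group labels: 1 = lowest track values, 0 = masked."""

    genome: GenomeSpec
    labels: np.ndarray
    n_quantiles: int
    track_name: str = ""

    def chrom_labels(self, name: str) -> np.ndarray:
        return self.labels[self.genome.chrom_slices()[name]]


def digitize_track(
    track: BinnedTrack, n_quantiles: int, trim_fraction: float = 0.02
) -> QuantileLabels:
    """Assign bins to Q equal-count quantile groups of the track.

    The lowest and highest `trim_fraction` of values are masked as an outlier
    guard; ties are broken by stable bin order, and group sizes differ by at
    most one. Group 1 holds the lowest values.
    """
    if n_quantiles < 2:
        raise ValueError("need at least 2 quantiles")
    if not 0.0 <= trim_fraction <= 0.1:
        raise ValueError("trim_fraction must lie in [0, 0.1]")
    idx = np.nonzero(~track.mask)[0]
    n = len(idx)
    if n < 10 * n_quantiles:
        raise ValueError(
            f"need at least {10 * n_quantiles} unmasked bins, got {n}"
        )
    order = idx[np.argsort(track.values[idx], kind="stable")]
    n_trim = int(np.floor(trim_fraction * n))
    kept = order[n_trim : n - n_trim] if n_trim else order
    k = len(kept)
    groups = (np.arange(k) * n_quantiles) // k + 1
    labels = np.zeros(track.genome.n_bins, dtype=int)
    labels[kept] = groups
    return QuantileLabels(track.genome, labels, n_quantiles, track.name)


@dataclass
class SaddleResult:
    """Q x Q aggregated O/E matrix over track quantiles.

    ``saddle[p, q]`` is the pair-count-weighted mean O/E between quantile
    groups p+1 and q+1 (both orders pooled, so the matrix is symmetric);
    cells with no pairs are NaN, never zero.
    """

    track_name: str
    n_quantiles: int
    saddle: np.ndarray
    pair_counts: np.ndarray
    strength: float
    corner_fraction: float = 0.2


def saddle_matrix(
    oe_list: list[ContactMatrix] | ContactMatrix,
    labels: QuantileLabels,
    min_dist: float | None = None,
    max_dist: float | None = None,
    corner_fraction: float = 0.2,
) -> SaddleResult:
    """Aggregate O/E maps into a Q x Q saddle over quantile pairs.

    Pools all unmasked cis pairs with ``min_dist <= |i-j|*bin_size <=
    max_dist`` across chromosomes and replicate matrices, weighted by pair
    counts. `min_dist` defaults to 2 bins.
    """
    mats = [oe_list] if isinstance(oe_list, ContactMatrix) else list(oe_list)
    if not mats:
        raise ValueError("need at least one matrix")
    q = labels.n_quantiles
    sums = np.zeros((q, q))
    counts = np.zeros((q, q))
    for m in mats:
        if m.scale != "oe":
            raise ValueError("saddle_matrix expects O/E matrices")
        lab = labels.chrom_labels(m.chrom)
        if len(lab) != m.n_bins:
            raise ValueError(
                f"labels for {m.chrom} do not match matrix size"
            )
        lo = 2 * m.bin_size if min_dist is None else min_dist
        data = m.masked_data()
        n = m.n_bins
        iu, ju = np.triu_indices(n, k=1)
        vals = data[iu, ju]
        d_bp = (ju - iu) * m.bin_size
        sel = np.isfinite(vals) & (d_bp >= lo)
        if max_dist is not None:
            sel &= d_bp <= max_dist
        sel &= (lab[iu] > 0) & (lab[ju] > 0)
        p_, q_, v = lab[iu[sel]] - 1, lab[ju[sel]] - 1, vals[sel]
        np.add.at(sums, (p_, q_), v)
        np.add.at(counts, (p_, q_), 1.0)
    sums = sums + sums.T
    counts = counts + counts.T
    with np.errstate(invalid="ignore", divide="ignore"):
        saddle = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
    result = SaddleResult(labels.track_name, q, saddle, counts, np.nan, corner_fraction)
    try:
        result.strength = compartment_strength(result, corner_fraction)
    except ValueError:
        result.strength = float("nan")
    return result


def _corner_mean(saddle: np.ndarray, counts: np.ndarray, rows: slice, cols: slice) -> float:
    s = saddle[rows, cols]
    c = counts[rows, cols]
    ok = np.isfinite(s) & (c > 0)
    if not ok.any():
        raise ValueError("saddle corner is entirely missing")
    return float((s[ok] * c[ok]).sum() / c[ok].sum())


def compartment_strength(s: SaddleResult, corner_fraction: float = 0.2) -> float:
    """Corner statistic ``(AA * BB) / AB**2`` of a saddle.

    With ``k = max(1, floor(corner_fraction * Q))``: AA is the pair-weighted
    mean over the top-k x top-k cells, BB over the bottom corner, AB across;
    a structureless map scores 1.
    """
    if not 0.0 < corner_fraction <= 0.5:
        raise ValueError("corner_fraction must lie in (0, 0.5]")
    q = s.n_quantiles
    k = max(1, int(np.floor(corner_fraction * q)))
    top, bottom = slice(q - k, q), slice(0, k)
    aa = _corner_mean(s.saddle, s.pair_counts, top, top)
    bb = _corner_mean(s.saddle, s.pair_counts, bottom, bottom)
    ab = _corner_mean(s.saddle, s.pair_counts, top, bottom)
    if ab <= 0:
        raise ValueError("cross-corner mean is non-positive")
    return (aa * bb) / ab**2


@dataclass
class DistanceStrengthCurve:
    """Compartment strength stratified by genomic-distance band."""

    bands: list[tuple[float, float]]  # bp, half-open [lo, hi)
    strength: np.ndarray  # NaN where a corner is empty
    pair_counts: np.ndarray

    def __post_init__(self) -> None:
        prev = -np.inf
        for lo, hi in self.bands:
            if hi <= lo or lo < prev:
                raise ValueError("bands must be disjoint and increasing")
            prev = hi


def strength_by_distance(
    oe_list: list[ContactMatrix] | ContactMatrix,
    labels: QuantileLabels,
    bands: list[tuple[float, float]],
    corner_fraction: float = 0.2,
) -> DistanceStrengthCurve:
    """Saddle strength restricted to each distance band.

    Bands with an entirely empty corner (e.g. beyond the chromosome length)
    are reported as NaN, never imputed.
    """
    prev = -np.inf
    for lo, hi in bands:
        if hi <= lo or lo < prev:
            raise ValueError("bands must be disjoint and increasing")
        prev = hi
    strengths, pairs = [], []
    for lo, hi in bands:
        res = saddle_matrix(
            oe_list, labels, min_dist=lo, max_dist=hi, corner_fraction=corner_fraction
        )
        strengths.append(res.strength)
        pairs.append(res.pair_counts.sum() / 2.0)
    return DistanceStrengthCurve(list(bands), np.asarray(strengths), np.asarray(pairs))


def differential_saddle(s: SaddleResult, reference: SaddleResult) -> np.ndarray:
    """log2 ratio of two saddles; NaN where either cell is missing."""
    if s.n_quantiles != reference.n_quantiles:
        raise ValueError("saddles have different numbers of quantiles")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.log2(s.saddle / reference.saddle)
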