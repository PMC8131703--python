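"""A/B compartment calling and cross-sample compartment PCA.

The compartment eigenvector (E1) of a chromosome is the leading eigenvector
of the Pearson-correlation matrix of its observed/expected contact map — the
classical construction: bins that contact the same partners correlate, and
the dominant mode splits the chromosome into the two interaction classes.
The sign of E1 is arbitrary per chromosome, so it is oriented against a
reference track (replication timing by default: A = early = positive E1,
reflecting the overlap of the A compartment with early-replicating
chromatin). Cross-sample structure is summarised by a PCA in which each
sample's genome-wide E1 profile is one observation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .genome import BinnedTrack, GenomeSpec
from .hic_core import ContactMatrix

__all__ = [
    "CompartmentProfile",
    "compartment_eigenvector",
    "ab_fraction",
    "compartment_pca",
]


@dataclass
class CompartmentProfile:
    """Per-bin eigenvector, A/B labels and leading-eigenvalue variance share."""

    e1: BinnedTrack
    ab_labels: np.ndarray  # "A", "B" or "masked" per bin
    orientation_track_name: str
    explained_variance_share: float
    per_chrom_share: dict[str, float]


def _chrom_eigenvector(
    oe: ContactMatrix, orientation: np.ndarray, orient_mask: np.ndarray
) -> tuple[np.ndarray, float]:
    """Leading eigenvector of the O/E correlation matrix for one chromosome."""
    valid = oe.valid
    sub = oe.masked_data()[np.ix_(valid, valid)]
    ma = np.ma.masked_invalid(sub)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-masked columns raise RuntimeWarnings
        corr = np.ma.corrcoef(ma, rowvar=False)
    corr = np.asarray(corr.filled(0.0))
    np.fill_diagonal(corr, 1.0)
    evals, evecs = np.linalg.eigh(corr)
    lead = evecs[:, -1]
    share = float(evals[-1] / np.trace(corr)) if np.trace(corr) > 0 else 0.0
    e1 = np.full(oe.n_bins, np.nan)
    e1[valid] = lead
    ref_ok = valid & ~orient_mask
    if ref_ok.sum() >= 2 and np.std(orientation[ref_ok]) > 0:
        r = np.corrcoef(e1[ref_ok], orientation[ref_ok])[0, 1]
        if np.isfinite(r) and r < 0:
            e1 = -e1
    return e1, share


def compartment_eigenvector(
    oe_list: list[ContactMatrix] | ContactMatrix,
    orientation: BinnedTrack,
    min_bins: int = 20,
) -> CompartmentProfile:
    """Compute E1 per chromosome from O/E maps, oriented by a genomic track.

    Per chromosome the Pearson-correlation matrix of unmasked O/E columns is
    formed and its leading eigenvector extracted; the sign is flipped so that
    the correlation with the orientation track is non-negative. Chromosomes
    with fewer than `min_bins` unmasked bins are fully masked (with a
    warning). A bins are E1 > 0.
    """
    mats = [oe_list] if isinstance(oe_list, ContactMatrix) else list(oe_list)
    genome = orientation.genome
    slices = genome.chrom_slices()
    e1_vals = np.full(genome.n_bins, np.nan)
    shares: dict[str, float] = {}
    weights: dict[str, int] = {}
    for m in mats:
        if m.scale != "oe":
            raise ValueError("compartment_eigenvector expects O/E matrices")
        if m.chrom not in slices:
            raise ValueError(f"chromosome {m.chrom!r} not in orientation genome")
        sl = slices[m.chrom]
        if sl.stop - sl.start != m.n_bins:
            raise ValueError(f"matrix for {m.chrom} does not match the genome binning")
        if int(m.valid.sum()) < min_bins:
            warnings.warn(
                f"chromosome {m.chrom}: only {int(m.valid.sum())} unmasked bins; masked"
            )
            shares[m.chrom] = float("nan")
            weights[m.chrom] = 0
            continue
        ovals, omask = orientation.chrom_view(m.chrom)
        e1, share = _chrom_eigenvector(m, ovals, omask)
        e1_vals[sl] = e1
        shares[m.chrom] = share
        weights[m.chrom] = int(m.valid.sum())
    track = BinnedTrack(genome, e1_vals, name="E1")
    labels = np.where(
        track.mask, "masked", np.where(track.values > 0, "A", "B")
    ).astype(str)
    wtot = sum(weights.values())
    overall = (
        sum(shares[c] * weights[c] for c in shares if weights[c] > 0) / wtot
        if wtot
        else float("nan")
    )
    return CompartmentProfile(track, labels, orientation.name, overall, shares)


def ab_fraction(profile: CompartmentProfile) -> tuple[float, float]:
    """Fractions of unmasked bins labelled A and B (they sum to 1)."""
    unmasked = profile.ab_labels != "masked"
    n = int(unmasked.sum())
    if n == 0:
        raise ValueError("all bins masked")
    a = float((profile.ab_labels == "A").sum()) / n
    return a, 1.0 - a


def compartment_pca(
    profiles: list[CompartmentProfile], labels: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of samples in E1-profile space.

    Samples are observations, per-bin E1 values (over bins unmasked in every
    sample) are features, centred across samples. Returns ``(coords,
    variance_shares)`` with coords of shape (n_samples, 2).
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 samples")
    if len(labels) != len(profiles):
        raise ValueError("label count must match sample count")
    genome = profiles[0].e1.genome
    for p in profiles[1:]:
        if p.e1.genome != genome:
            raise ValueError("profiles on different genomes")
    joint = ~np.logical_or.reduce([p.e1.mask for p in profiles])
    if joint.sum() < 3:
        raise ValueError("fewer than 3 jointly unmasked bins")
    x = np.vstack([p.e1.values[joint] for p in profiles])
    if np.allclose(x, x.mean(axis=0), atol=1e-12):  # identical samples
        return np.zeros((len(profiles), 2)), np.zeros(2)
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(x)
    return coords, pca.explained_variance_ratio_
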