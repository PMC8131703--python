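"""Synthetic Repli-seq / Hi-C generator with planted, dose-tunable structure.

The generator plants a ground truth that downstream analyses must recover:

* a segmentation of each chromosome into replication domains (geometric
  lengths), each labelled A (early) or B (late) and carrying an RT value drawn
  from a two-component Gaussian mixture — this makes the genome-wide RT
  distribution bimodal by construction;
* early/late Repli-seq counts whose multinomial weights invert the RT
  estimator (logistic weight of ``2**RT``), so log2(E/L) after RPM is an
  unbiased readout of the planted RT up to a genome-wide offset;
* a RIF1-occupancy track anti-correlated with RT (high over late/B domains,
  emulating RIF1-associated domains);
* cis Hi-C contact maps with power-law distance decay multiplicatively
  modulated by compartment identity: the structured observed/expected is
  ``exp(delta * c_i * c_j)`` with ``c in {+1 (A), -1 (B)}``, linearly mixed
  toward a structure-free null by ``lambda_mix`` (the dosage dial:
  0 = wild-type-like, 1 = no compartmentalisation), then Poisson-sampled.

The multiplicative form gives the saddle corner strength the closed form
``exp(4*delta)`` at ``lambda_mix = 0``, which serves as the exact oracle for
the whole compartment-strength pipeline.

Determinism: every operation takes an integer seed and derives its generator
as ``np.random.default_rng([seed, OP_CONSTANT, ...])``; repeated calls with
the same inputs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome import BinnedTrack, GenomeSpec
from .hic_core import ContactMatrix

__all__ = [
    "Domain",
    "DomainSegmentation",
    "GenotypeSpec",
    "RTMixture",
    "SynthConfig",
    "segment_genome",
    "make_rt_track",
    "simulate_repliseq_counts",
    "simulate_rif1_track",
    "simulate_hic",
    "structured_oe",
    "reassign_b_to_a",
]

# seed-derivation constants, one per stochastic operation
_SEED_SEGMENT = 11
_SEED_RT = 23
_SEED_REPLISEQ = 37
_SEED_RIF1 = 41
_SEED_HIC = 53
_SEED_RELABEL = 67


@dataclass(frozen=True)
class Domain:
    """Half-open bin interval [start, end) with a compartment label and RT."""

    start: int
    end: int
    label: str  # "A" or "B"
    rt: float

    def __post_init__(self) -> None:
        if self.label not in ("A", "B"):
            raise ValueError(f"label must be A or B, got {self.label!r}")
        if self.end <= self.start:
            raise ValueError("empty domain interval")


@dataclass
class DomainSegmentation:
    """Per-chromosome tiling into replication domains."""

    genome: GenomeSpec
    domains: dict[str, list[Domain]]

    def __post_init__(self) -> None:
        for name, length in self.genome.chromosomes:
            doms = self.domains.get(name)
            if not doms:
                raise ValueError(f"no domains for chromosome {name}")
            if doms[0].start != 0 or doms[-1].end != length:
                raise ValueError(f"domains do not tile chromosome {name}")
            for a, b in zip(doms, doms[1:]):
                if a.end != b.start:
                    raise ValueError(f"gap/overlap in segmentation of {name}")

    def rt_track(self) -> BinnedTrack:
        """Piecewise-constant track of domain RT values."""
        vals = np.empty(self.genome.n_bins)
        for name, sl in self.genome.chrom_slices().items():
            v = vals[sl]
            for d in self.domains[name]:
                v[d.start : d.end] = d.rt
        return BinnedTrack(self.genome, vals, np.zeros(len(vals), bool), "rt_planted")

    def label_signs(self) -> BinnedTrack:
        """Per-bin compartment identity c_i: +1 for A, -1 for B."""
        vals = np.empty(self.genome.n_bins)
        for name, sl in self.genome.chrom_slices().items():
            v = vals[sl]
            for d in self.domains[name]:
                v[d.start : d.end] = 1.0 if d.label == "A" else -1.0
        return BinnedTrack(self.genome, vals, np.zeros(len(vals), bool), "compartment")

    def refine(self, factor: int) -> "DomainSegmentation":
        """Re-express the segmentation on a `factor`-times finer binning."""
        fine = self.genome.refine(factor)
        doms = {
            name: [
                Domain(d.start * factor, d.end * factor, d.label, d.rt)
                for d in self.domains[name]
            ]
            for name in self.genome.names
        }
        return DomainSegmentation(fine, doms)

    def with_rt_scaled(self, factor: float) -> "DomainSegmentation":
        """Shrink (or expand) every domain RT value toward zero by `factor`."""
        doms = {
            name: [replace(d, rt=d.rt * factor) for d in ds]
            for name, ds in self.domains.items()
        }
        return DomainSegmentation(self.genome, doms)


@dataclass(frozen=True)
class RTMixture:
    """Two-component Gaussian mixture for domain RT values (log2 E/L units)."""

    mu_early: float = 1.5
    mu_late: float = -1.5
    sigma: float = 0.3
    p_early: float = 0.5

    def __post_init__(self) -> None:
        if self.mu_early <= self.mu_late:
            raise ValueError("mu_early must exceed mu_late")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 < self.p_early < 1:
            raise ValueError("p_early must lie in (0, 1)")


@dataclass(frozen=True)
class GenotypeSpec:
    """Synthetic genotype: dosage dial plus sequencing budgets.

    ``lambda_mix`` interpolates the Hi-C observed/expected between the full
    planted compartment structure (0) and a structure-free null (1);
    ``rt_shrink`` flattens the planted RT program toward zero (0 keeps the
    wild-type program, 1 abolishes it).
    """

    name: str
    lambda_mix: float
    coverage: float = 50.0
    repliseq_depth: int = 10_000_000
    seed: int = 0
    rt_shrink: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_mix <= 1.0:
            raise ValueError("lambda_mix must lie in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.repliseq_depth <= 0:
            raise ValueError("repliseq_depth must be positive")
        if not 0.0 <= self.rt_shrink <= 1.0:
            raise ValueError("rt_shrink must lie in [0, 1]")


@dataclass(frozen=True)
class SynthConfig:
    """Full parameterisation of one synthetic experiment."""

    genome: GenomeSpec
    mean_domain_bins: float = 8.0
    rt_mixture: RTMixture = field(default_factory=RTMixture)
    decay_alpha: float = 1.0
    delta_compartment: float = 0.3
    rif1_noise_sd: float = 0.5
    bin_noise_sd: float = 0.2
    genotypes: tuple[GenotypeSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.decay_alpha <= 0:
            raise ValueError("decay_alpha must be positive")
        if self.delta_compartment < 0:
            raise ValueError("delta_compartment must be non-negative")
        if self.rif1_noise_sd < 0 or self.bin_noise_sd < 0:
            raise ValueError("noise sds must be non-negative")


def segment_genome(
    spec: GenomeSpec,
    mean_domain_bins: float,
    seed: int,
    rt_mixture: RTMixture | None = None,
    p_alternate: float = 0.7,
) -> DomainSegmentation:
    """Tile every chromosome into replication domains.

    Domain lengths are geometric with the given mean, truncated to
    ``[2, chromosome length]``. Labels alternate A/B with probability
    `p_alternate`; otherwise the label is an independent fair draw. Each
    domain's RT value comes from the mixture component matching its label
    (A -> early, B -> late).
    """
    if mean_domain_bins < 2:
        raise ValueError("mean_domain_bins must be at least 2")
    mix = rt_mixture or RTMixture()
    rng = np.random.default_rng([seed, _SEED_SEGMENT])
    # geometric on {1,2,...} with mean m has p = 1/m; truncate below at 2
    p = 1.0 / mean_domain_bins
    domains: dict[str, list[Domain]] = {}
    for name, length in spec.chromosomes:
        doms: list[Domain] = []
        pos = 0
        prev: str | None = None
        while pos < length:
            size = int(rng.geometric(p))
            size = max(2, min(size, length - pos))
            if length - (pos + size) == 1:  # avoid a trailing 1-bin domain
                size += 1
            if prev is None:
                label = "A" if rng.random() < mix.p_early else "B"
            elif rng.random() < p_alternate:
                label = "B" if prev == "A" else "A"
            else:
                label = "A" if rng.random() < 0.5 else "B"
            mu = mix.mu_early if label == "A" else mix.mu_late
            rt = float(rng.normal(mu, mix.sigma))
            doms.append(Domain(pos, pos + size, label, rt))
            prev = label
            pos += size
        domains[name] = doms
    return DomainSegmentation(spec, domains)


def reassign_b_to_a(
    seg: DomainSegmentation,
    fraction: float,
    seed: int,
    rt_mixture: RTMixture | None = None,
) -> DomainSegmentation:
    """Relabel a fraction of B domains as A (emulates A-compartment expansion).

    Relabelled domains redraw their RT from the early component so labels and
    RT stay consistent.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    mix = rt_mixture or RTMixture()
    rng = np.random.default_rng([seed, _SEED_RELABEL])
    domains: dict[str, list[Domain]] = {}
    for name, ds in seg.domains.items():
        out = []
        for d in ds:
            if d.label == "B" and rng.random() < fraction:
                d = Domain(d.start, d.end, "A", float(rng.normal(mix.mu_early, mix.sigma)))
            out.append(d)
        domains[name] = out
    return DomainSegmentation(seg.genome, domains)


def make_rt_track(seg: DomainSegmentation, bin_noise_sd: float, seed: int) -> BinnedTrack:
    """Per-bin RT: the domain value plus i.i.d. Gaussian bin noise."""
    if bin_noise_sd < 0:
        raise ValueError("bin_noise_sd must be non-negative")
    base = seg.rt_track()
    rng = np.random.default_rng([seed, _SEED_RT])
    vals = base.values + rng.normal(0.0, bin_noise_sd, base.values.shape)
    return BinnedTrack(seg.genome, vals, base.mask, "rt_true")


def simulate_repliseq_counts(
    rt: BinnedTrack, depth: int, seed: int
) -> tuple[BinnedTrack, BinnedTrack]:
    """Draw early/late read counts whose log2 ratio encodes the RT track.

    The early-fraction weight of bin *i* is the logistic
    ``w_i = 2**rt_i / (1 + 2**rt_i)``; early counts are multinomial over bins
    with probabilities proportional to ``w``, late proportional to ``1 - w``,
    each with `depth` total reads. After RPM normalisation, log2(E/L)
    recovers rt_i up to sampling noise and a genome-wide additive offset.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng([seed, _SEED_REPLISEQ])
    w = np.zeros_like(rt.values)
    ok = ~rt.mask
    z = np.exp2(rt.values[ok])
    w[ok] = z / (1.0 + z)
    lw = np.zeros_like(w)
    lw[ok] = 1.0 - w[ok]
    early = rng.multinomial(depth, w / w.sum()).astype(float)
    late = rng.multinomial(depth, lw / lw.sum()).astype(float)
    return (
        BinnedTrack(rt.genome, early, rt.mask.copy(), "early_counts"),
        BinnedTrack(rt.genome, late, rt.mask.copy(), "late_counts"),
    )


def simulate_rif1_track(rt: BinnedTrack, noise_sd: float, seed: int) -> BinnedTrack:
    """RIF1 occupancy: minus RT plus noise (high over late/B domains)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng([seed, _SEED_RIF1])
    vals = -rt.values + rng.normal(0.0, noise_sd, rt.values.shape)
    return BinnedTrack(rt.genome, vals, rt.mask.copy(), "rif1")


def _mixed_oe_block(signs: np.ndarray, delta: float, lambda_mix: float) -> np.ndarray:
    """Structured O/E exp(delta*c_i*c_j), linearly mixed toward the flat null."""
    struct = np.exp(delta * np.outer(signs, signs))
    return (1.0 - lambda_mix) * struct + lambda_mix


def simulate_hic(
    seg: DomainSegmentation,
    genotype: GenotypeSpec,
    decay_alpha: float,
    delta: float,
    sample: bool = True,
) -> list[ContactMatrix]:
    """Cis contact maps: power-law decay times mixed compartment modulation.

    Expected count for bins i<j on one chromosome is
    ``coverage * |i-j|**(-decay_alpha) * M(i,j)`` with
    ``M = (1-lambda)*exp(delta*c_i*c_j) + lambda``; observed counts are
    Poisson unless ``sample=False`` (then the noiseless expectation matrix is
    returned, the basis of the closed-form oracles). The diagonal is zeroed
    and masked out of validity; matrices are exactly symmetric.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if decay_alpha <= 0:
        raise ValueError("decay_alpha must be positive")
    rng = np.random.default_rng([genotype.seed, _SEED_HIC])
    signs_all = seg.label_signs()
    out: list[ContactMatrix] = []
    for name, length in seg.genome.chromosomes:
        signs, _ = signs_all.chrom_view(name)
        idx = np.arange(length)
        dist = np.abs(idx[:, None] - idx[None, :]).astype(float)
        with np.errstate(divide="ignore"):
            decay = np.where(dist > 0, dist, np.nan) ** (-decay_alpha)
        lam = genotype.coverage * decay * _mixed_oe_block(signs, delta, genotype.lambda_mix)
        lam = np.where(dist > 0, lam, 0.0)
        if sample:
            upper = np.triu(rng.poisson(lam).astype(float), k=1)
            data = upper + upper.T
        else:
            data = lam.copy()
            np.fill_diagonal(data, 0.0)
        out.append(
            ContactMatrix(
                chrom=name,
                bin_size=seg.genome.bin_size,
                data=data,
                valid=np.ones(length, bool),
                scale="raw",
            )
        )
    return out


def structured_oe(
    seg: DomainSegmentation, delta: float, lambda_mix: float = 0.0
) -> list[ContactMatrix]:
    """Noiseless observed/expected maps of the planted block model.

    Entries are exactly ``(1-lambda)*exp(delta*c_i*c_j) + lambda`` for every
    off-diagonal pair, i.e. the generative O/E with the distance decay already
    divided out. On these matrices the saddle corner strength equals
    ``((1-l)e^d + l)^2 / ((1-l)e^-d + l)^2`` — ``exp(4*delta)`` at
    ``lambda_mix = 0`` — to machine precision.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    signs_all = seg.label_signs()
    out = []
    for name, length in seg.genome.chromosomes:
        signs, _ = signs_all.chrom_view(name)
        data = _mixed_oe_block(signs, delta, lambda_mix)
        np.fill_diagonal(data, np.nan)
        out.append(
            ContactMatrix(
                chrom=name,
                bin_size=seg.genome.bin_size,
                data=data,
                valid=np.ones(length, bool),
                scale="oe",
            )
        )
    return out
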