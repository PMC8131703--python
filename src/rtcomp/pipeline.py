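"""End-to-end experiment orchestration.

Generates a synthetic genotype panel (wild-type-like, hemizygous-like,
knockout-like), runs the Repli-seq and Hi-C analyses per genotype and emits
one result bundle: RT profiles/distributions/bimodality, replica
correlation and clustering, contact scaling and range fractions,
differential maps, compartment profiles and A/B fractions, saddles under
three rankings with global and distance-stratified strengths, RT-change
tables and a cross-sample compartment PCA.

The panel encodes the central dissociation the framework is built to
expose: compartment strength responds to the dosage dial ``lambda_mix``
(WT 0 -> hem 0.4 -> KO 0.8) while the replication-timing programme does
not respond to dosage — only the KO-like genotype flattens RT. Replicates
of a genotype share one RT track (a clone's programme is reproducible) and
differ in read sampling and Hi-C Poisson noise.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .compartments import CompartmentProfile, ab_fraction, compartment_eigenvector, compartment_pca
from .genome import BinnedTrack, GenomeSpec
from .hic_core import (
    ContactMatrix,
    balance,
    contact_scaling,
    differential_map,
    observed_over_expected,
    range_fractions,
)
from .repliseq import (
    RTChangeTable,
    bimodality,
    classify_rt_changes,
    cluster_profiles,
    compute_rt_profile,
    correlate_profiles,
    exclude_bins,
    mean_profile,
    median_center,
    rpm_normalize,
    rt_distribution,
)
from .saddle import (
    DistanceStrengthCurve,
    SaddleResult,
    compartment_strength,
    digitize_track,
    saddle_matrix,
    strength_by_distance,
)
from .synthgen import (
    GenotypeSpec,
    RTMixture,
    SynthConfig,
    make_rt_track,
    segment_genome,
    simulate_hic,
    simulate_repliseq_counts,
    simulate_rif1_track,
)

__all__ = ["ExperimentConfig", "GenotypeResult", "ResultBundle", "run_experiment", "summarize", "default_config"]

REFERENCE_GENOTYPE = "WT-like"


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one synthetic panel."""

    synth: SynthConfig
    n_replicates: int = 3
    rt_refine_factor: int = 5  # Hi-C bins per RT bin (250 kb -> 50 kb)
    pseudocount: float = 0.1
    exclude_chromosomes: tuple[str, ...] = ()
    n_hist_bins: int = 50
    n_quantiles: int = 20
    corner_fraction: float = 0.2
    trim_fraction: float = 0.02
    distance_bands: tuple[tuple[float, float], ...] = (
        (1e6, 4e6),
        (4e6, 16e6),
        (16e6, 64e6),
    )
    switch_threshold: float = 0.5
    change_threshold: float = 0.25
    seed: int = 0

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(config_to_dict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def default_config(
    seed: int = 0,
    n_chromosomes: int = 10,
    chrom_bins: int = 400,
    bin_size: int = 250_000,
    coverage: float = 50.0,
    repliseq_depth: int = 10_000_000,
    delta: float = 0.3,
    n_replicates: int = 3,
) -> ExperimentConfig:
    """The default three-genotype panel.

    Genotype presets: WT-like (full structure), hem-like (lambda 0.4, WT RT),
    KO-like (lambda 0.8, RT flattened by shrink 0.95 so its genome-wide RT
    distribution is unimodal around zero).
    """
    genome = GenomeSpec(
        tuple((f"chr{i + 1}", chrom_bins) for i in range(n_chromosomes)), bin_size
    )
    base = 1000 * (seed + 1)
    genotypes = (
        GenotypeSpec(REFERENCE_GENOTYPE, 0.0, coverage, repliseq_depth, base + 0, 0.0),
        GenotypeSpec("hem-like", 0.4, coverage, repliseq_depth, base + 100, 0.0),
        GenotypeSpec("KO-like", 0.8, coverage, repliseq_depth, base + 200, 0.95),
    )
    synth = SynthConfig(
        genome=genome,
        mean_domain_bins=8.0,
        rt_mixture=RTMixture(),
        decay_alpha=1.0,
        delta_compartment=delta,
        rif1_noise_sd=0.5,
        bin_noise_sd=0.2,
        genotypes=genotypes,
    )
    return ExperimentConfig(synth=synth, n_replicates=n_replicates, seed=seed)


@dataclass
class GenotypeResult:
    """All per-genotype artefacts of one pipeline run."""

    spec: GenotypeSpec
    rt_replicates: list[BinnedTrack]
    rt_mean: BinnedTrack
    rt_true: BinnedTrack
    rif1: BinnedTrack
    rt_histogram: tuple[np.ndarray, np.ndarray]
    bimodality_score: float
    is_bimodal: bool
    balanced: dict[int, list[ContactMatrix]]  # replicate -> per-chrom matrices
    oe: dict[int, list[ContactMatrix]]
    pooled_balanced: list[ContactMatrix]
    pooled_oe: list[ContactMatrix]
    scaling: "object"
    short_fraction: float
    long_fraction: float
    profile: CompartmentProfile
    replicate_profiles: list[CompartmentProfile]
    a_fraction: float
    saddles: dict[str, SaddleResult]  # ranking name -> saddle
    strengths: dict[str, float]
    strength_bands: DistanceStrengthCurve
    diff_long_range: float | None = None
    diff_saddles: dict[str, np.ndarray] = field(default_factory=dict)
    rt_changes: RTChangeTable | None = None


@dataclass
class ResultBundle:
    config: ExperimentConfig
    config_hash: str
    genotypes: dict[str, GenotypeResult]
    replica_labels: list[str]
    correlation: np.ndarray
    cluster: "object"
    pca_coords: np.ndarray
    pca_shares: np.ndarray
    pca_labels: list[str]


def _mean_balanced(mats_per_rep: list[list[ContactMatrix]]) -> list[ContactMatrix]:
    """Average replicate balanced matrices chromosome-wise (triplicates combined)."""
    out = []
    for mats in zip(*mats_per_rep):
        valid = np.logical_and.reduce([m.valid for m in mats])
        stack = np.stack([m.masked_data() for m in mats])
        data = stack.mean(axis=0)
        data[~valid, :] = np.nan
        data[:, ~valid] = np.nan
        m0 = mats[0]
        out.append(ContactMatrix(m0.chrom, m0.bin_size, data, valid, "balanced"))
    return out


def _rt_readout(
    rt_true: BinnedTrack, depth: int, seed: int, config: ExperimentConfig
) -> BinnedTrack:
    early, late = simulate_repliseq_counts(rt_true, depth, seed)
    early = exclude_bins(early, config.exclude_chromosomes, strict=False)
    late = exclude_bins(late, config.exclude_chromosomes, strict=False)
    rt = compute_rt_profile(
        rpm_normalize(early), rpm_normalize(late), config.pseudocount
    )
    return median_center(rt)


def run_experiment(config: ExperimentConfig, outdir: str | None = None) -> ResultBundle:
    """Run the full panel; deterministic given the config.

    Differential analyses (maps, saddles, RT changes) use the genotype named
    ``"WT-like"`` as the reference. With `outdir`, tracks are written as
    bedGraph, tables as TSV and a YAML manifest records parameters, seeds and
    the config hash.
    """
    synth = config.synth
    if len({g.name for g in synth.genotypes}) != len(synth.genotypes):
        raise ValueError("genotype names must be unique")
    if REFERENCE_GENOTYPE not in {g.name for g in synth.genotypes}:
        raise ValueError(f"panel must contain the reference genotype {REFERENCE_GENOTYPE!r}")
    seg = segment_genome(
        synth.genome, synth.mean_domain_bins, config.seed, synth.rt_mixture
    )
    seg_fine = seg.refine(config.rt_refine_factor)

    results: dict[str, GenotypeResult] = {}
    for gs in synth.genotypes:
        stage = f"genotype {gs.name}"
        try:
            seg_g = seg_fine.with_rt_scaled(1.0 - gs.rt_shrink)
            rt_true = make_rt_track(seg_g, synth.bin_noise_sd, gs.seed)
            rif1 = simulate_rif1_track(rt_true, synth.rif1_noise_sd, gs.seed)
            rt_reps = [
                _rt_readout(rt_true, gs.repliseq_depth, gs.seed + 1 + r, config)
                for r in range(config.n_replicates)
            ]
            rt_mean = mean_profile(rt_reps)
            hist = rt_distribution(rt_mean, config.n_hist_bins)
            bscore, bflag = bimodality(rt_mean)

            balanced: dict[int, list[ContactMatrix]] = {}
            oe: dict[int, list[ContactMatrix]] = {}
            for r in range(config.n_replicates):
                raw = simulate_hic(
                    seg,
                    replace(gs, seed=gs.seed + 1 + r),
                    synth.decay_alpha,
                    synth.delta_compartment,
                )
                balanced[r] = [balance(m) for m in raw]
                oe[r] = [observed_over_expected(m) for m in balanced[r]]
            pooled_balanced = _mean_balanced(list(balanced.values()))
            pooled_oe = [observed_over_expected(m) for m in pooled_balanced]

            scaling = contact_scaling(list(balanced.values()))
            short_f, long_f = range_fractions(pooled_balanced)

            rt_coarse = rt_mean.coarsen(config.rt_refine_factor)
            rt_coarse.name = "rt"
            rif1_coarse = rif1.coarsen(config.rt_refine_factor)
            rif1_coarse.name = "rif1"
            profile = compartment_eigenvector(pooled_oe, rt_coarse)
            rep_profiles = [
                compartment_eigenvector(oe[r], rt_coarse)
                for r in range(config.n_replicates)
            ]
            a_frac, _ = ab_fraction(profile)

            all_oe = [m for r in oe.values() for m in r]
            rankings = {
                "rt": rt_coarse,
                "rif1": rif1_coarse,
                "e1": profile.e1,
            }
            saddles, strengths = {}, {}
            for rank_name, track in rankings.items():
                labels = digitize_track(track, config.n_quantiles, config.trim_fraction)
                s = saddle_matrix(all_oe, labels, corner_fraction=config.corner_fraction)
                saddles[rank_name] = s
                strengths[rank_name] = s.strength
            rt_labels = digitize_track(rt_coarse, config.n_quantiles, config.trim_fraction)
            bands = strength_by_distance(
                all_oe, rt_labels, list(config.distance_bands), config.corner_fraction
            )

            results[gs.name] = GenotypeResult(
                spec=gs,
                rt_replicates=rt_reps,
                rt_mean=rt_mean,
                rt_true=rt_true,
                rif1=rif1,
                rt_histogram=hist,
                bimodality_score=bscore,
                is_bimodal=bflag,
                balanced=balanced,
                oe=oe,
                pooled_balanced=pooled_balanced,
                pooled_oe=pooled_oe,
                scaling=scaling,
                short_fraction=short_f,
                long_fraction=long_f,
                profile=profile,
                replicate_profiles=rep_profiles,
                a_fraction=a_frac,
                saddles=saddles,
                strengths=strengths,
                strength_bands=bands,
            )
        except Exception as err:  # annotate failures with the stage
            raise RuntimeError(
                f"pipeline stage failed: {stage} (lambda_mix={gs.lambda_mix}, "
                f"seed={gs.seed}): {err}"
            ) from err

    # cross-genotype analyses
    ref = results[REFERENCE_GENOTYPE]
    from .saddle import differential_saddle

    for name, res in results.items():
        if name == REFERENCE_GENOTYPE:
            continue
        diffs = [
            differential_map(s, r)
            for s, r in zip(res.pooled_balanced, ref.pooled_balanced)
        ]
        vals = []
        for dm in diffs:
            n = dm.n_bins
            iu, ju = np.triu_indices(n, k=1)
            d_bp = (ju - iu) * dm.bin_size
            v = dm.masked_data()[iu, ju]
            sel = np.isfinite(v) & (d_bp > 10e6)
            vals.append(v[sel])
        allv = np.concatenate(vals) if vals else np.array([])
        res.diff_long_range = float(allv.mean()) if allv.size else float("nan")
        res.diff_saddles = {
            k: differential_saddle(res.saddles[k], ref.saddles[k]) for k in res.saddles
        }
        res.rt_changes = classify_rt_changes(
            ref.rt_mean, res.rt_mean, config.switch_threshold, config.change_threshold
        )

    labels = [
        f"{gs.name}_r{r + 1}"
        for gs in synth.genotypes
        for r in range(config.n_replicates)
    ]
    all_rt = [
        t for gs in synth.genotypes for t in results[gs.name].rt_replicates
    ]
    corr = correlate_profiles(all_rt)
    clust = cluster_profiles(corr, labels)
    all_profiles = [
        p for gs in synth.genotypes for p in results[gs.name].replicate_profiles
    ]
    coords, shares = compartment_pca(all_profiles, labels)

    bundle = ResultBundle(
        config=config,
        config_hash=config.config_hash(),
        genotypes=results,
        replica_labels=labels,
        correlation=corr,
        cluster=clust,
        pca_coords=coords,
        pca_shares=shares,
        pca_labels=labels,
    )
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def summarize(bundle: ResultBundle) -> pd.DataFrame:
    """One row per genotype with the headline statistics."""
    rows = []
    rep_corr = pd.DataFrame(
        bundle.correlation, index=bundle.replica_labels, columns=bundle.replica_labels
    )
    for name, res in bundle.genotypes.items():
        own = [l for l in bundle.replica_labels if l.rsplit("_r", 1)[0] == name]
        sub = rep_corr.loc[own, own].to_numpy()
        iu = np.triu_indices(len(own), k=1)
        mean_r = float(sub[iu].mean()) if len(own) > 1 else 1.0
        idx = [i for i, l in enumerate(bundle.pca_labels) if l.rsplit("_r", 1)[0] == name]
        row = {
            "genotype": name,
            "lambda_mix": res.spec.lambda_mix,
            "bimodality_score": res.bimodality_score,
            "is_bimodal": res.is_bimodal,
            "mean_replica_correlation": mean_r,
            "short_fraction": res.short_fraction,
            "long_fraction": res.long_fraction,
            "a_fraction": res.a_fraction,
            "strength_rt": res.strengths["rt"],
            "strength_rif1": res.strengths["rif1"],
            "strength_e1": res.strengths["e1"],
            "pc1": float(bundle.pca_coords[idx, 0].mean()),
            "switch_fraction_vs_ref": (
                res.rt_changes.switch_fraction() if res.rt_changes is not None else 0.0
            ),
        }
        for (lo, hi), s in zip(res.strength_bands.bands, res.strength_bands.strength):
            row[f"strength_{lo / 1e6:g}-{hi / 1e6:g}Mb"] = s
        rows.append(row)
    return pd.DataFrame(rows)


def write_bundle(bundle: ResultBundle, outdir: str) -> None:
    """Write tracks (bedGraph), tables (TSV) and the manifest (YAML)."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, res in bundle.genotypes.items():
        rio.write_bedgraph(res.rt_mean, out / f"rt_{name}.bedgraph")
        rio.write_bedgraph(res.profile.e1, out / f"e1_{name}.bedgraph")
        for rank, s in res.saddles.items():
            pd.DataFrame(s.saddle).to_csv(
                out / f"saddle_{rank}_{name}.tsv", sep="\t", index=False
            )
        pd.DataFrame(
            {
                "band_lo": [b[0] for b in res.strength_bands.bands],
                "band_hi": [b[1] for b in res.strength_bands.bands],
                "strength": res.strength_bands.strength,
                "pairs": res.strength_bands.pair_counts,
            }
        ).to_csv(out / f"strength_bands_{name}.tsv", sep="\t", index=False)
        if res.rt_changes is not None:
            fr = res.rt_changes.fractions()
            pd.DataFrame([fr]).to_csv(
                out / f"rt_changes_{name}.tsv", sep="\t", index=False
            )
    pd.DataFrame(
        bundle.correlation, index=bundle.replica_labels, columns=bundle.replica_labels
    ).to_csv(out / "replica_correlation.tsv", sep="\t")
    with open(out / "dendrogram.nwk", "w") as fh:
        fh.write(bundle.cluster.to_newick() + "\n")
    pd.DataFrame(
        {
            "sample": bundle.pca_labels,
            "pc1": bundle.pca_coords[:, 0],
            "pc2": bundle.pca_coords[:, 1],
        }
    ).to_csv(out / "pca_coords.tsv", sep="\t", index=False)
    summarize(bundle).to_csv(out / "summary.tsv", sep="\t", index=False)
    rio.write_manifest(
        {"config": config_to_dict(bundle.config), "config_hash": bundle.config_hash},
        out / "manifest.yaml",
    )


# -- config (de)serialisation -------------------------------------------------

def config_to_dict(config: ExperimentConfig) -> dict:
    s = config.synth
    return {
        "genome": {
            "chromosomes": [[n, l] for n, l in s.genome.chromosomes],
            "bin_size": s.genome.bin_size,
        },
        "mean_domain_bins": s.mean_domain_bins,
        "rt_mixture": {
            "mu_early": s.rt_mixture.mu_early,
            "mu_late": s.rt_mixture.mu_late,
            "sigma": s.rt_mixture.sigma,
            "p_early": s.rt_mixture.p_early,
        },
        "decay_alpha": s.decay_alpha,
        "delta_compartment": s.delta_compartment,
        "rif1_noise_sd": s.rif1_noise_sd,
        "bin_noise_sd": s.bin_noise_sd,
        "genotypes": [
            {
                "name": g.name,
                "lambda_mix": g.lambda_mix,
                "coverage": g.coverage,
                "repliseq_depth": g.repliseq_depth,
                "seed": g.seed,
                "rt_shrink": g.rt_shrink,
            }
            for g in s.genotypes
        ],
        "n_replicates": config.n_replicates,
        "rt_refine_factor": config.rt_refine_factor,
        "pseudocount": config.pseudocount,
        "exclude_chromosomes": list(config.exclude_chromosomes),
        "n_hist_bins": config.n_hist_bins,
        "n_quantiles": config.n_quantiles,
        "corner_fraction": config.corner_fraction,
        "trim_fraction": config.trim_fraction,
        "distance_bands": [[lo, hi] for lo, hi in config.distance_bands],
        "switch_threshold": config.switch_threshold,
        "change_threshold": config.change_threshold,
        "seed": config.seed,
    }


def config_from_dict(d: dict) -> ExperimentConfig:
    genome = GenomeSpec(
        tuple((n, int(l)) for n, l in d["genome"]["chromosomes"]),
        int(d["genome"]["bin_size"]),
    )
    mix = RTMixture(**d["rt_mixture"])
    genotypes = tuple(GenotypeSpec(**g) for g in d["genotypes"])
    synth = SynthConfig(
        genome=genome,
        mean_domain_bins=float(d["mean_domain_bins"]),
        rt_mixture=mix,
        decay_alpha=float(d["decay_alpha"]),
        delta_compartment=float(d["delta_compartment"]),
        rif1_noise_sd=float(d["rif1_noise_sd"]),
        bin_noise_sd=float(d["bin_noise_sd"]),
        genotypes=genotypes,
    )
    return ExperimentConfig(
        synth=synth,
        n_replicates=int(d["n_replicates"]),
        rt_refine_factor=int(d["rt_refine_factor"]),
        pseudocount=float(d["pseudocount"]),
        exclude_chromosomes=tuple(d["exclude_chromosomes"]),
        n_hist_bins=int(d["n_hist_bins"]),
        n_quantiles=int(d["n_quantiles"]),
        corner_fraction=float(d["corner_fraction"]),
        trim_fraction=float(d["trim_fraction"]),
        distance_bands=tuple((float(lo), float(hi)) for lo, hi in d["distance_bands"]),
        switch_threshold=float(d["switch_threshold"]),
        change_threshold=float(d["change_threshold"]),
        seed=int(d["seed"]),
    )


def config_from_yaml(path: str) -> ExperimentConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
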