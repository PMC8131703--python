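#!/usr/bin/env python
"""Generate the default synthetic genotype panel and write its inputs.

Builds the three-genotype series — WT-like (full compartment structure),
hem-like (mixing 0.4, wild-type RT programme) and KO-like (mixing 0.8,
flattened RT) — on a 10-chromosome genome (400 bins of 250 kb each; RT
tracks refined to 50 kb), then writes the planted RT and RIF1 tracks as
bedGraph, one example contact matrix as coordinate-list text, and the
manifest with every parameter and seed.

Run from the repository root:  python analysis/01_simulate.py
"""

from dataclasses import replace
from pathlib import Path

import numpy as np

from rtcomp import io as rio
from rtcomp.pipeline import config_to_dict, default_config
from rtcomp import synthgen as sg

OUT = Path("results/simulate")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = default_config(seed=SEED)
    s = cfg.synth
    seg = sg.segment_genome(s.genome, s.mean_domain_bins, cfg.seed, s.rt_mixture)
    seg_fine = seg.refine(cfg.rt_refine_factor)

    lengths = [
        d.end - d.start for doms in seg.domains.values() for d in doms
    ]
    a_share = float((seg.label_signs().values > 0).mean())
    print(
        f"segmented {len(s.genome.names)} chromosomes into {len(lengths)} domains "
        f"(mean {np.mean(lengths):.1f} bins = "
        f"{np.mean(lengths) * s.genome.bin_size / 1e6:.1f} Mb; A share {a_share:.2f})"
    )

    for gs in s.genotypes:
        seg_g = seg_fine.with_rt_scaled(1.0 - gs.rt_shrink)
        rt = sg.make_rt_track(seg_g, s.bin_noise_sd, gs.seed)
        rif1 = sg.simulate_rif1_track(rt, s.rif1_noise_sd, gs.seed)
        rio.write_bedgraph(rt, OUT / f"rt_true_{gs.name}.bedgraph")
        rio.write_bedgraph(rif1, OUT / f"rif1_{gs.name}.bedgraph")
        r = float(np.corrcoef(rif1.values, rt.values)[0, 1])
        print(
            f"{gs.name}: lambda_mix={gs.lambda_mix}, rt_shrink={gs.rt_shrink}; "
            f"RT sd {rt.values.std():.2f}, corr(RIF1, RT) = {r:.2f}"
        )

    # one example raw contact matrix (WT-like, first chromosome, replicate 1)
    wt = s.genotypes[0]
    mats = sg.simulate_hic(
        seg, replace(wt, seed=wt.seed + 1), s.decay_alpha, s.delta_compartment
    )
    rio.write_matrix_txt(mats[0], OUT / "hic_WT-like_r1_chr1.txt")
    print(
        f"example Hi-C map {mats[0].chrom}: {mats[0].n_bins} bins, "
        f"{mats[0].data.sum() / 2:.0f} cis contacts"
    )

    rio.write_manifest(
        {"config": config_to_dict(cfg), "config_hash": cfg.config_hash()},
        OUT / "manifest.yaml",
    )
    print(f"wrote tracks and manifest to {OUT}/")


if __name__ == "__main__":
    main()
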