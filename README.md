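# rtcomp

Joint analysis of DNA **replication timing (RT)** and Hi-C **A/B
compartmentalisation** across a genotype dose series, with a synthetic-data
generator that plants known structure so every stage of the pipeline is
testable without any download.

The scientific setting: RIF1 recruits PP1 to control the genome-wide
replication-timing programme, and independently confines 3D chromatin
contacts. Reducing RIF1 dosage (wild type → hemizygous → null / PP1-binding
mutant) weakens A/B compartmentalisation *progressively*, while the RT
programme is robust to dosage and collapses only when RIF1 function is lost
outright. This package reproduces that dissociation end to end on synthetic
genomes: the compartment arm responds to a dose dial, the RT arm does not.

## What it computes

**Repli-seq arm** (`rtcomp.repliseq`) — per-bin RT score
`log2(E_RPM / L_RPM)` from early/late fraction read counts at 50 kb;
genome-wide RT distributions and a bimodality verdict
(ΔBIC of 1- vs 2-component Gaussian mixtures plus a mean-separation guard);
Pearson correlation and average-linkage clustering of replica profiles;
per-bin classification of RT changes between conditions
(early↔late switches, moves toward/away from zero).

**Hi-C arm** (`rtcomp.hic_core`) — iterative-correction balancing with
MAD-based bin filtering; per-distance expected and observed/expected (O/E)
maps; contact-probability scaling curves *P(s)* (geometric distance bins,
unit area in log-distance, median over replicas); short-range (≤ 0.3 Mbp)
and long-range (≥ 10 Mbp) signal fractions; log-ratio differential maps
against a reference genotype.

**Compartment arm** (`rtcomp.compartments`, `rtcomp.saddle`) — per-chromosome
compartment eigenvector E1 (leading eigenvector of the Pearson-correlation
matrix of the O/E map, oriented so A = early-replicating = positive);
A/B bin fractions at 250 kb; track-conditioned saddle plots (quantiles of
RT, RIF1 occupancy, or E1) with the corner compartment strength

```
strength = (AA · BB) / AB²      (1 = no compartmentalisation)
```

globally and stratified by distance band; differential saddles; and a
cross-sample PCA of E1 profiles.

**Generator** (`rtcomp.synthgen`) — genomes segmented into replication
domains (geometric lengths, mean 2 Mb), each A (early) or B (late) with an
RT value from a bimodal Gaussian mixture (μ = ±1.5, σ = 0.3); Repli-seq
counts drawn multinomially with logistic weights `2^RT/(1+2^RT)` so the RT
estimator is unbiased on the generator; a RIF1 track anti-correlated with
RT (emulating RIF1-associated domains); and Hi-C maps with expected counts

```
Λ(i,j) = coverage · |i−j|^(−α) · [(1−λ)·exp(δ·c_i·c_j) + λ],   c ∈ {+1 (A), −1 (B)}
```

Poisson-sampled. The mixing dial λ interpolates to a structure-free null
and models RIF1 dosage (presets: WT-like λ=0, hem-like λ=0.4, KO-like
λ=0.8 with the RT programme flattened). The multiplicative form gives the
saddle strength the closed form `exp(4δ)` at λ=0, the exact oracle behind
the test suite.

## Worked example

```bash
python analysis/01_simulate.py
python analysis/02_replication_timing.py
python analysis/03_contact_scaling.py
python analysis/04_compartments_saddles.py
python analysis/05_summary.py
```

(or `rtcomp run --seed 1 --outdir results/panel` for the one-command
version). The final summary printed for the default panel (10 chromosomes ×
100 Mb, 3 replicates per genotype, seed 1):

```
genotype  lambda_mix  is_bimodal  mean_replica_correlation  long_fraction  a_fraction  strength_rt       pc1  switch_fraction_vs_ref
 WT-like         0.0        True                  0.995403       0.233151    0.501796     3.245049 -1.224514                 0.00000
hem-like         0.4        True                  0.995358       0.238009    0.501427     2.024584 -0.961847                 0.00005
 KO-like         0.8       False                  0.846668       0.243995    0.492884     1.163819  2.186360                 0.05435
```

Reading the table: RT is bimodal and replica-consistent for WT-like and
hem-like but unimodal for KO-like (`is_bimodal`, and the 2-cluster cut of
the replica dendrogram groups hem-like with WT-like); compartment strength
falls monotonically with the dose dial (3.25 → 2.02 → 1.16) while the
long-range contact fraction rises (0.233 → 0.238 → 0.244); hem-like PC1
lies between the WT-like and KO-like group means; and only the flattened
programme produces RT switches against WT-like (5.4% vs 0.005%).

## Layout

```
src/rtcomp/        library: genome, synthgen, repliseq, hic_core,
                   compartments, saddle, pipeline, io, cli
analysis/          numbered narrative drivers writing results/
tests/             pytest suite (unit, property and acceptance tests)
scripts/           acceptance.py
docs/methods.md    model, parameters, numerical choices, limitations
```
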