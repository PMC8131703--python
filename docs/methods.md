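# Methods

## The model in brief

The package treats a genome as an ordered set of chromosomes cut into
fixed-size bins (250 kb for Hi-C and compartment analyses; 50 kb for
replication timing, obtained by refining each coarse bin five-fold so domain
boundaries align exactly across resolutions). Two coupled layers of planted
structure drive everything:

1. **Replication domains.** Each chromosome is tiled by domains whose
   lengths (in 250 kb bins) are geometric with mean 8, truncated below at 2
   — memoryless segmentation with a single parameter, mean domain size
   2 Mb. Each domain carries a compartment label, A or B: the first domain
   of a chromosome is a fair draw, and each subsequent domain alternates
   with probability 0.7 (otherwise an independent fair draw), which keeps
   the genome near a 50/50 A/B split while producing realistic runs. The
   domain's replication-timing value is drawn from the mixture component
   matching its label: A → N(+1.5, 0.3), B → N(−1.5, 0.3), in log2
   early/late units. Per-bin RT adds N(0, 0.2) bin noise. The resulting
   genome-wide RT distribution is bimodal by construction.

2. **Compartmentalised contact maps.** For bins *i < j* on one chromosome
   with labels c ∈ {+1 (A), −1 (B)}, the expected cis contact count is

       Λ(i,j) = coverage · |i−j|^(−α) · [(1−λ)·exp(δ·c_i·c_j) + λ]

   with power-law decay exponent α = 1 and compartment preference δ = 0.3
   on the log scale; observed counts are Poisson, symmetrised, diagonal
   zeroed. The multiplicative exponential modulation is chosen so the
   saddle corner strength has the closed form exp(4δ) at λ = 0 — an exact,
   independent oracle for the entire downstream strength pipeline. The
   mixing parameter λ ∈ [0, 1] linearly interpolates the
   observed/expected surface toward a structure-free null and is the
   *dosage dial*: reduced RIF1 dosage is modelled as uniform weakening of
   compartmentalisation, which reproduces an intermediate but reproducible
   degree of change for hemizygous-like genotypes as a simple
   interpolation. A-compartment expansion is available separately as
   relabelling a fraction of B domains to A (`reassign_b_to_a`), since no
   quantitative rule for it is established.

**Genotype presets.** WT-like (λ = 0, intact RT), hem-like (λ = 0.4,
intact RT), KO-like (λ = 0.8, RT flattened). Flattening multiplies every
planted domain RT value by (1 − shrink) with shrink = 0.95. The value is
a deliberate calibration: with the RT mixture above, a component
separation of 3·(1−shrink) must fall below the within-component spread
(~0.21 once bin noise is included) for the genome-wide distribution to be
unimodal — the defining property of the null-like RT phenotype this preset
emulates. Milder shrinkage (e.g. 0.65, separation/sd ≈ 4.6) still yields a
clearly bimodal distribution and would emulate a compressed-but-intact
programme instead.

**Replicate structure.** Each genotype draws one genotype-level RT track
(domain values plus bin noise, seeded by the genotype); replicates differ
only in Repli-seq multinomial sampling and Hi-C Poisson noise. This
encodes that a clone's RT programme — including the residual programme of a
flattened genotype — is biologically reproducible. If bin noise were
redrawn per replicate, the flattened genotype's small shared signal
(sd ≈ 0.075) would be swamped by per-replicate noise (sd 0.2) and its
replicas would not cluster together, contradicting the phenomenon the
panel is built to show.

**Repli-seq inverse model.** Early counts are multinomial over bins with
probabilities ∝ w, late ∝ (1 − w), where w = 2^RT/(1 + 2^RT), each
fraction with its own total depth (default 10⁷ reads). This logistic
weight is the exact inverse of the estimator log2(E/L), so the RT readout
is unbiased on the generator up to a genome-wide additive offset set by
the ratio of effective library sizes.

**Determinism.** Every stochastic operation derives its generator as
`np.random.default_rng([seed, OP_CONSTANT])` with a fixed per-operation
constant; pipelines re-run bit-identically from one integer seed.

## Analysis conventions and numerical choices

* **RPM and RT score.** Each fraction is scaled to reads per million over
  unmasked bins; RT = log2((E + 0.1)/(L + 0.1)) with a 0.1 RPM pseudocount
  to bound scores on empty bins. Bins on excluded chromosomes or under a
  coverage threshold are masked, never dropped, so coordinates stay aligned
  across tracks. Profiles are median-centred before cross-sample
  comparison to remove the library-size offset (harmless for
  correlations). Note the genome-wide median of a *bimodal* profile sits in
  the low-density trough between the modes and is therefore a noisy
  location statistic; where an offset must be removed precisely (estimator
  consistency checks), the median of the recovered-minus-planted difference
  is used instead.
* **Bimodality.** ΔBIC between 1- and 2-component Gaussian mixture fits
  (threshold 10) *and* a separation guard |μ₁−μ₂| > max(σ₁, σ₂). The guard
  matters: with tens of thousands of bins, ΔBIC detects any non-Gaussianity;
  only the guard distinguishes two humps from one heavy hump.
* **Clustering.** Distance 1 − r on Pearson correlations over jointly
  unmasked bins; average linkage; the 2-cluster cut is reported alongside
  the dendrogram (Newick export).
* **RT changes.** With Δ = rt_b − rt_a: a *switch* (EtoL/LtoE) requires
  opposite signs beyond ±0.25 in the two conditions and |Δ| ≥ 0.5;
  otherwise |Δ| ≥ 0.25 is a *change*, split by whether |rt| moves toward or
  away from zero; else stable. Because each genotype carries its own bin
  noise (sd 0.2), unrelated genotypes show ~35–40 % small "changes" purely
  from noise exceeding the 0.25 threshold; switches are the noise-robust
  statistic and stay at ~0 between genotypes sharing a programme.
* **Balancing.** Iterative correction to equal marginals: bins with zero
  marginal or |log marginal − median| > 5 MADs are masked; rows/columns are
  divided by normalised marginals until all unmasked marginals agree
  within 10⁻⁵ (max 1000 sweeps); weights are stored so
  balanced = raw · w_i · w_j. Balancing forces end-of-chromosome bins (with
  fewer cis partners) up to the common marginal, a percent-level edge
  artifact inherent to the method; it cancels in strength ratios but is
  visible in fine null calibrations.
* **Expected and O/E.** Expected(d) is the mean of unmasked entries at bin
  distance d; distances with fewer than 10 pairs borrow from a
  geometrically widening window (factor 1.3). The diagonal and first
  off-diagonal are excluded from O/E (short-range artefact convention;
  configurable). Dividing by an expected estimated from few noisy pairs
  carries a Jensen-type upward bias of order var(ê)/ê²; distance-restricted
  analyses avoid it.
* **Scaling curves.** Geometric distance bins, 8 per decade, pooled over
  chromosomes; each sample normalised to unit area in log-distance so
  genotypes with different totals are comparable; the reported curve is the
  per-distance median across replicas with an sd band.
* **Saddles and strength.** Ranking tracks are digitised into Q = 20
  equal-count quantiles after trimming the extreme 2 % (outlier guard; ties
  broken by stable bin order). The saddle pools all unmasked cis pairs at
  ≥ 2 bins separation across chromosomes and replicate matrices, weighted
  by pair counts (replicate combination = pooling). Strength uses 20 %
  corners: with k = ⌊0.2·Q⌋, AA/BB/AB are pair-weighted corner means and
  strength = (AA·BB)/AB². Empty cells propagate as missing, never zero or
  imputed. Strength is invariant to Q within 10 % on noiseless models.
* **Compartment eigenvector.** Per chromosome, the leading eigenvector of
  the Pearson-correlation matrix of unmasked O/E columns (masked entries
  handled pairwise); sign fixed by non-negative correlation with the
  orientation track (the genotype's own RT profile coarsened to 250 kb;
  A = early = positive); chromosomes with < 20 usable bins are fully
  masked. The variance share of the leading eigenvalue is reported. E1
  estimated from the same maps that enter a saddle is *circular*: shared
  noise inflates E1-conditioned strength by ~20 % at coverage 50 and the
  bias vanishes as coverage grows (≈ 6 % at coverage 1000). RT- or
  RIF1-conditioned strengths are free of this selection effect.
* **Cross-sample PCA.** Samples are observations, per-bin E1 values over
  jointly unmasked bins are features, centred across samples; replicate
  profiles enter individually.

## What the generator emulates — and what it does not

Emulated: domain-scale RT organisation with a bimodal score distribution;
RIF1 occupancy anti-correlated with RT in megabase blocks; distance decay
with compartment modulation; dose-dependent loss of compartmentalisation
with intact RT; Poisson sequencing noise; replicate reproducibility.

Not emulated: TADs, loops and insulation (compartment-level claims only);
trans contacts (all analyses are cis); per-bin visibility biases
(mappability, GC), so balancing is exactly neutral in expectation on
synthetic maps; S-phase substructure of Repli-seq; sub-compartments;
chromosome-specific biology. Passing tests therefore demonstrate the
*pipeline's* correctness and sensitivity under these idealised conditions,
not robustness to the full artefact spectrum of real Hi-C/Repli-seq
libraries.

## Problem sizes

The default panel is 10 chromosomes × 100 Mb (400 × 250 kb bins; 2000 ×
50 kb bins) with 3 genotypes × 3 replicates, coverage 50 expected contacts
at one-bin separation and 10⁷ Repli-seq reads per fraction — small enough
to run the full experiment in about ten seconds while keeping ≥ 10⁵ cis
pairs per genotype for saddle statistics. Seed-replication studies in the
tests and the acceptance script use 2–4 chromosome genomes at the same bin
sizes; the package's statistics are intensive (means, fractions, ratios),
so results transfer directly to larger genomes with smaller error bars.

## Known limitations

* Strength estimates at coverage ≤ 50 are mildly biased by the
  E1-circularity and expected-estimation effects described above (both
  quantified in the test suite); conclusions rest on ratios and orderings,
  which are robust.
* The uniform-mixing dosage model cannot distinguish "all pairs weaken
  equally" from compartment-identity remodelling; the A-expansion knob is a
  separate, deliberately simple mechanism.
* The bimodality verdict is tuned for RT-like mixtures (two components of
  comparable weight); strongly skewed or three-state distributions need a
  different statistic.
* bedGraph reading assumes constant interval width equal to the bin size;
  arbitrary-interval tracks must be binned upstream. The cooler adapter
  reads single-resolution files only.
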