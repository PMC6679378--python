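# Methods

## Cross and meiosis model

The simulator emulates a reciprocal F2 intercross between two inbred
strains (GK and BN by naming convention; the `B` allele is the GK allele
throughout). Each F2 genome is the union of two independent gametes; each
gamete is a Markov walk along a chromosome whose switch probability
between adjacent markers is the Haldane map function

    r(d) = (1 − e^(−2d/100)) / 2,     d in cM,

i.e. crossovers are a Poisson process with no interference. This is
deliberately the same model that underlies the genotype-probability HMM,
so the simulator and the imputation are exactly matched: recovery failures
in tests indicate defects, not model mismatch. Only autosomes are
simulated and scanned; no sex-chromosome model is provided.

Defaults mirror the study design the package targets: 123 individuals,
63 female / 60 male, 55 from a GK grandmother and 68 from a BN
grandmother. An optional missing-at-random genotype rate is exposed
(default 0, since no empirical rate is available).

Random-number streams are split per purpose, per chromosome and per gene
(`SeedSequence([seed, tag, index])`), so simulating a subset of
chromosomes or genes reproduces the same draws, and all outputs are
bit-identical under a fixed seed.

## Expression model

Each transcript is generated from the same regression model the scan fits:

    y_i = m + b_c c_i + b_s s_i + b_g g_i + b_d h_i + gs·s_i g_i + gc·c_i g_i + e_i

with g_i the centred GK-allele dosage (−1, 0, +1) at the transcript's
effect locus, h_i the heterozygote indicator, and e_i iid N(0, σ²).
`b_g` is therefore a *per-allele* effect on the (log2-like) expression
scale; the expression ratio reported by the scan, ER = mean(GK/GK) −
mean(BN/BN), equals 2·b_g in expectation.

When an effect locus falls between markers, the true genotype is drawn by
exact conditional sampling: the F2 genotype process along a chromosome is
itself Markov (the two gametes are exchangeable), so the forward–backward
posterior at an inserted untyped locus, followed by one categorical draw,
samples from the exact joint distribution of (markers, hidden locus).
One consequence worth knowing: hidden genotypes of two genes on the same
chromosome are conditionally independent given the markers, rather than
jointly correlated as they would be on a physical chromosome. This does
not affect any per-transcript statistic, but the between-transcript
correlation of trans signals on shared chromosomes is slightly understated.

Generator defaults for effect sizes are stated in residual-SD units
(σ = 1): cis/trans additive effects 1.5, interaction effects 2.0, sex and
cross-direction main effects 0.3 and 0.2. Hotspot target effects are drawn
N(−1.5, 0.3²) per allele — negative mean, so GK alleles predominantly
downregulate targets, reproducing the direction asymmetry that motivates
the `frac_gk_down` hotspot summary.

### What the generator does *not* emulate

Bead-level array structure, spatial artifacts, probe-sequence effects
other than the SNP-attenuation mechanism below, expression-correlation
networks among transcripts, and non-Gaussian noise. Passing tests
demonstrate the statistical machinery is correct under its stated model;
they do not certify performance on real arrays with correlated probes or
heavy-tailed noise.

### SNP-carrying probes

Probes whose target sequence differs between the strains hybridize
allele-dependently. `inject_probe_artifacts` multiplies the linear
intensity by `attenuation^dosage` at the probe's own locus (equivalently
adds `dosage·log2(attenuation)` on the log2 scale, using the nearest
framework marker's observed genotype). This manufactures a spurious cis
signal on otherwise null transcripts — the reason such probes must be
excluded before scanning, which `exclude_snp_probes` does from a plain
id list.

### Raw intensities and detection scores

`simulate_raw_intensities` produces Normal(μ_b, σ_b) background plus
Exponential(α) signal noise plus the supplied matrix in linear units.
Detection scores are the empirical fraction of a seeded pool of 10,000
pure-background draws below each observed value, so background-only
probes score ~Uniform(0,1) and the default detection filter
(score < 0.5 in > 50% of samples, strict inequality) removes them about
half the time while keeping real signals essentially always.

## Genotype probabilities

A three-state HMM (AA/AB/BB) per individual and chromosome with
stationary distribution (¼, ½, ¼), transition matrices from the Haldane
recombination fraction, and an emission model with a single global
genotyping-error rate (default 0.002; a mis-call lands on either wrong
genotype with equal probability). Missing and pseudomarker loci emit
uniformly. The grid is "typed markers plus pseudomarkers" (default
spacing 2.5 cM) rather than a uniform grid, so typed markers are exactly
representable; pseudomarker physical positions are linearly interpolated
from flanking markers, which is what makes the Mb-based cis windows of
the classifier meaningful for peaks between markers. With error rate 0,
typed non-missing markers get degenerate probabilities; fully missing
individuals fall back to the F2 prior everywhere. The forward–backward
recursion is normalized per locus, and its output is checked against
exhaustive 3^k path enumeration in the tests (agreement < 1e-10).

## Scans and significance

LOD is computed by projecting phenotypes onto precomputed orthonormal
bases of the per-locus design matrices (QR per locus, SVD for the null
model). Near-collinear genotype columns are dropped by a relative
threshold on the R diagonal, so degenerate loci score ~0 rather than
blowing up. Numerical conventions: perfect fits (RSS₁ ≤ 1e−14·‖y‖²) are
capped at LOD 300; constant phenotypes score 0; LOD is clipped to be
non-negative; peak ties resolve to the lowest chromosome, then lowest cM
(the first grid index). Individuals with a missing phenotype are dropped
for that transcript only. The dominance term is included by default
(2 genotype df); the additive-only 1-df model is a trivial restriction of
the same code path.

Permutations shuffle the phenotype within sex × cross-direction cells,
keeping genotypes and covariates fixed, so the null respects the additive
covariate structure. The adjusted p uses the (1 + count)/(n_perm + 1)
estimator; with the default 1000 permutations the smallest attainable p
is 1/1001. The two-stage rule — adjusted p per transcript, then BH across
transcripts, declared = q < 0.05 — reconciles the per-transcript
"adjusted P < 0.05" criterion with an FDR-0.05 criterion across the
transcriptome; both thresholds are configurable.

Interaction (LODf) significance uses a Freedman–Lane scheme: the nuisance
model H_add at the transcript's additive peak locus is fitted, its
residuals are permuted within strata and added back to the fitted values,
and the maximum LODf is rescanned. This keeps the additive genetic signal
in the null draws, so LODf significance is not inflated by a strong main
effect. The additive-peak choice of nuisance locus is a design decision;
the alternative (per-locus nuisance) costs a factor of the grid size and
changes results negligibly at F2 resolution.

Secondary peaks — the basis of the polygeny report — are chromosomes
other than the primary peak's whose maximum LOD exceeds the transcript's
own permutation 95% threshold; polygenic genes are those with declared
eQTLs on ≥ 2 distinct chromosomes. Within-chromosome secondary peaks are
deliberately not counted: F2 linkage disequilibrium cannot separate them.

## Architecture analysis

Class labels partition declared eQTLs: `trans` (different chromosome),
`cis_5Mb` (≤ 5 Mb, inclusive), `cis_10Mb` (5–10 Mb), `same_chrom_distant`
(> 10 Mb), `unassigned` (gene unmapped or multiply mapped). Peak physical
positions are the grid locus's interpolated Mb.

Hotspot detection partitions each chromosome into 5 cM bins, counts
distant-class peaks per bin, and flags bins whose count exceeds the
1 − α/n_bins quantile of Poisson(total/n_bins) — a Bonferroni-corrected
homogeneous null chosen for strict family-wise control (verified ≤ α on
uniform simulations). The member list and the fraction of members with
ER < 0 (GK-allele downregulation) are reported per hotspot.

## Conservation and enrichment

Cross-tissue conservation requires declared eQTLs for the same gene in
both tables, peaks on one chromosome within 15 cM, and matching nonzero
ER signs; cross-mapping-system conservation uses a 10 Mb physical window
(two systems do not share a genetic map) and reports, rather than
requires, direction agreement. With multiple eQTLs per gene any matching
pair qualifies. Overlap significance is a one-sided Fisher's exact test;
the default background universe is the set of transcripts scanned in both
tables (the choice is the caller's — pass whatever universe is
defensible).

Pathway enrichment is the hypergeometric upper tail P(X ≥ k) per set,
against the background of genes with detectable expression (post-filter),
with sets intersected with the background first, K = 0 sets skipped, and
BH adjustment across tested sets. Probes must be collapsed to genes by
the caller before testing.

## Problem sizes used in the shipped experiments

The calibration experiments (tests and `scripts/acceptance.py`) run at
the design size of the target study: 123 individuals, five 100 cM
chromosomes with markers every 10 cM, 1000 stratified permutations per
transcript; 200 null transcripts for type-I calibration and 10 replicate
studies of 500 transcripts (100 cis at 1.5 σ) for FDR calibration. These
sizes give binomial/Monte-Carlo error small enough for the stated bounds
while keeping a full run in the tens of seconds on one CPU. The scan
itself is vectorized so that one transcript's 1000-permutation genome
scan is a handful of matrix products (~7 ms at this grid size).

## Known limitations

- No multiple-QTL or variance-component models; one primary peak (plus
  cross-chromosome secondary peaks) per transcript.
- The X chromosome is out of scope end to end.
- The hotspot null ignores marker-density variation along the genome
  (irrelevant for the uniform simulated maps, approximate for real ones).
- Quantile-normalization idempotence is exact only in the absence of
  ties; tie groups share their mean reference quantile.
- The normexp fit is per array and assumes a single background
  population; negative-control-based variants are not implemented.
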