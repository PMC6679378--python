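# eqtlkit

Expression QTL mapping for F2 intercrosses, built around the design of a
reciprocal GK×BN rat cross: ~123 F2 animals from two grandmother lineages,
both sexes, genotyped at framework markers and profiled on expression
arrays. The package provides every stage of the analysis as a tested,
reusable library — simulation of crosses with a known eQTL architecture,
genotype-probability imputation, Haley–Knott genome scans with permutation
significance, cis/trans/hotspot architecture analysis, cross-tissue and
cross-population conservation, and hypergeometric pathway enrichment —
plus a thin `eqtlkit` command-line wrapper.

Because genotype data for such crosses are typically not publicly
deposited, the package is validated end to end on synthetic data whose
generating model is the same regression model the scan fits, so every
significance statement can be checked against known truth.

## The model

For one transcript, expression *y<sub>i</sub>* of individual *i* is
modelled as

> *y<sub>i</sub>* = *m* + *b<sub>c</sub>c<sub>i</sub>* + *b<sub>s</sub>s<sub>i</sub>* + *b<sub>g</sub>g<sub>i</sub>* + *b<sub>d</sub>h<sub>i</sub>* + *e<sub>i</sub>*

with cross direction *c<sub>i</sub>* and sex *s<sub>i</sub>* as additive
covariates and genotype terms evaluated by Haley–Knott regression on
expected genotype scores from the imputation HMM: the additive score
*a* = P(BB) − P(AA) (GK-allele contrast) and dominance score *h* = P(AB).
Evidence for linkage at a locus is

> LOD = (*n*/2) · log₁₀(RSS₀ / RSS₁),

the least-squares analogue of the likelihood-ratio statistic comparing the
covariate-only null with the genotype model. Sex- and cross-direction-
interaction scans add *s·a, s·h* (or *c·a, c·h*) terms (model *H*<sub>int</sub>)
and report **LODf** = LOD<sub>int</sub> − LOD<sub>add</sub>.

Genome-wide significance per transcript comes from 1000 permutations of the
phenotype within sex × cross-direction strata; a transcript's adjusted
*p* is (1 + #{permutation max-LOD ≥ observed}) / (*n*<sub>perm</sub> + 1).
Across transcripts, Benjamini–Hochberg FDR is applied to the adjusted
*p*-values, and a declared eQTL is *q* < 0.05. Declared eQTLs are
classified by the distance between the peak and the gene: a different
chromosome is *trans*; ≤ 5 Mb (strict) or ≤ 10 Mb on the same chromosome
is a candidate *cis* effect. Hotspots are 5 cM bins carrying more distant
eQTL peaks than a Bonferroni-corrected homogeneous Poisson null allows.

## Worked example

Simulate a 123-animal cross on five 100 cM chromosomes (markers every
10 cM), with 20 null transcripts and 5 cis-regulated transcripts
(per-allele effect 1.5 residual SD), then scan with 1000 stratified
permutations per transcript:

```python
from eqtlkit import simulate_map, simulate_f2_genotypes, simulate_expression
from eqtlkit.simdata import standard_architecture
from eqtlkit.genoprob import genotype_probabilities
from eqtlkit.scan import scan_transcripts

gmap = simulate_map([100.0] * 5, 10.0, 2.0)
arch = standard_architecture(gmap, n_null=20, n_cis=5, cis_effect=1.5, seed=1)
cross = simulate_f2_genotypes(gmap, arch)
expr, truth = simulate_expression(cross, gmap, arch)
gp = genotype_probabilities(cross, gmap, step_cm=2.5)
records, _ = scan_transcripts(expr, gp, cross.covariates(), cross.strata(),
                              n_perm=1000, seed=2)
print(records.loc[records.significant,
                  ["transcript", "peak_chrom", "peak_cm", "lod", "qvalue", "er"]])
```

prints

```text
transcript peak_chrom  peak_cm       lod   qvalue       er
  null0016          1      0.0  3.992215 0.045788 0.231417
   cis0001          2     50.0 24.380807 0.004995 3.483347
   cis0002          4     37.5 14.267251 0.004995 2.958562
   cis0003          2     15.0 16.033267 0.004995 2.605405
   cis0004          3     95.0 20.920160 0.004995 3.429146
   cis0005          1     85.0 23.621166 0.004995 3.620765
```

All five simulated cis eQTLs are declared, each peak lands within one
grid step of its true locus (e.g. `cis0001` truth: chr 2 at 50.5 cM), and
the expression ratio `er` — the fitted GK/GK minus BN/BN homozygote
difference — recovers ≈ 2 × 1.5 = 3, the two-allele-step effect. One null
transcript slips in at *q* ≈ 0.046: exactly the kind of false discovery an
FDR-0.05 rule permits.

The same run is available from a shell via `eqtlkit run --out results/`
with a YAML config; see `eqtlkit --help` for the per-stage subcommands
(`simulate`, `genoprob`, `normalize`, `scan`, `classify`, `compare`,
`enrich`).

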