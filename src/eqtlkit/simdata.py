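"""Synthetic F2 intercross data with a known eQTL architecture.

The generator mirrors the design of a reciprocal GK x BN F2 cross: two
grandmother lineages, both sexes, framework markers on a multi-chromosome
genetic map, and per-transcript expression generated from the scan
regression model

    y_i = m + b_c c_i + b_s s_i + b_g g_i + b_d h_i + gs s_i g_i + gc c_i g_i + e_i

with g_i the centred GK-allele dosage (-1, 0, +1) at the gene's effect
locus, h_i the heterozygote indicator, c_i the cross direction, s_i the sex
and e_i iid Gaussian noise.  Meiosis follows the Haldane model (independent
crossovers, no interference), matching the hidden Markov model used for
genotype-probability imputation, and every draw is reproducible from a
single integer seed with per-chromosome and per-gene substreams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._types import CrossData, GeneticMap
from .genoprob import forward_backward, haldane_r

_CODES = np.array(["AA", "AB", "BB"])


@dataclass
class GeneEffect:
    """True generative parameters for one simulated transcript."""

    gene: str
    chrom: object = None            # eQTL chromosome (None = no eQTL)
    pos_cm: float | None = None     # eQTL position
    additive: float = 0.0           # b_g, per GK-allele effect (log2 units)
    dominance: float = 0.0          # b_d, heterozygote deviation
    sex_interaction: float = 0.0    # gs
    cde_interaction: float = 0.0    # gc
    residual_sd: float = 1.0        # sd of e_i
    baseline: float = 8.0           # m
    sex_main: float = 0.0           # b_s
    cross_main: float = 0.0         # b_c
    gene_chrom: object = None       # physical location of the transcript
    gene_mb: float | None = None

    def validate(self) -> None:
        effects = (
            self.additive,
            self.dominance,
            self.sex_interaction,
            self.cde_interaction,
            self.baseline,
            self.sex_main,
            self.cross_main,
        )
        if not all(math.isfinite(v) for v in effects):
            raise ValueError(f"gene {self.gene}: effects must be finite")
        if not (self.residual_sd > 0 and math.isfinite(self.residual_sd)):
            raise ValueError(f"gene {self.gene}: residual_sd must be positive")
        if (self.chrom is None) != (self.pos_cm is None):
            raise ValueError(f"gene {self.gene}: eQTL chromosome and position must come together")


@dataclass
class HotspotSpec:
    """A trans-regulatory hotspot: one locus controlling many target genes."""

    chrom: object
    pos_cm: float
    n_targets: int
    effect_mean: float = -1.5   # negative = GK alleles downregulate targets
    effect_sd: float = 0.3
    residual_sd: float = 1.0


@dataclass
class SimArchitecture:
    """Complete description of one simulated study."""

    n_individuals: int = 123
    cross_fraction: float = 55 / 123   # fraction with a GK grandmother
    female_fraction: float = 63 / 123
    genes: list = field(default_factory=list)
    hotspots: list = field(default_factory=list)
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self, gmap: GeneticMap | None = None) -> None:
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")
        for name, frac in (
            ("cross_fraction", self.cross_fraction),
            ("female_fraction", self.female_fraction),
            ("missing_rate", self.missing_rate),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for ge in self.genes:
            ge.validate()
            if gmap is not None and ge.chrom is not None:
                length = gmap.chrom_length_cm(ge.chrom)
                if not 0.0 <= ge.pos_cm <= length:
                    raise ValueError(
                        f"gene {ge.gene}: effect locus {ge.pos_cm} cM is off "
                        f"chromosome {ge.chrom} (0-{length} cM)"
                    )


def simulate_map(
    chrom_lengths_cm, marker_spacing_cm: float, mb_per_cm: float = 2.0
) -> GeneticMap:
    """Evenly spaced framework-marker map.

    Markers start at 0 cM on each chromosome with the requested spacing;
    physical positions are a fixed Mb-per-cM scaling so that cis/trans
    geometry is deterministic.
    """
    if marker_spacing_cm <= 0:
        raise ValueError("marker spacing must be positive")
    if mb_per_cm <= 0:
        raise ValueError("mb_per_cm must be positive")
    rows = []
    for ci, length in enumerate(chrom_lengths_cm, start=1):
        if length <= 0:
            raise ValueError("chromosome lengths must be positive")
        n_markers = int(np.floor(length / marker_spacing_cm + 1e-9)) + 1
        for mi in range(n_markers):
            cm = mi * marker_spacing_cm
            rows.append((f"c{ci}m{mi + 1}", str(ci), cm, cm * mb_per_cm))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chrom", "cm", "mb"]))


def _gamete_walk(rng: np.random.Generator, n: int, rec: np.ndarray) -> np.ndarray:
    """One gamete per individual: Markov walk over parental alleles {0,1}."""
    m = len(rec) + 1
    alleles = np.empty((n, m), dtype=np.int8)
    alleles[:, 0] = rng.integers(0, 2, size=n)
    for j in range(1, m):
        switch = rng.random(n) < rec[j - 1]
        alleles[:, j] = alleles[:, j - 1] ^ switch
    return alleles


def _assign_labels(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    labels = np.zeros(n, dtype=int)
    k = int(round(fraction * n))
    labels[rng.permutation(n)[:k]] = 1
    return labels


def simulate_f2_genotypes(
    gmap: GeneticMap, arch: SimArchitecture, return_gametes: bool = False
):
    """Simulate marker genotypes for an F2 intercross.

    Each F2 genome is the union of two independent gametes; each gamete is a
    Markov walk along each chromosome with crossover probability between
    adjacent markers given by the Haldane map function.  Sex and
    cross-direction labels follow the architecture's fractions (assignment
    permuted but deterministic under the seed).

    With ``return_gametes=True`` also returns the per-chromosome phased
    allele matrices ``{chrom: (gamete1, gamete2)}`` for recombination
    accounting in tests.
    """
    arch.validate(gmap)
    n = arch.n_individuals
    label_rng = np.random.default_rng(np.random.SeedSequence([arch.seed, 0]))
    sex = _assign_labels(label_rng, n, arch.female_fraction)
    cross = _assign_labels(label_rng, n, arch.cross_fraction)

    ids = pd.Index([f"F2_{i + 1:04d}" for i in range(n)], name="individual")
    columns = {}
    gametes = {}
    for ci, chrom in enumerate(gmap.chromosomes):
        sub = gmap.chrom_markers(chrom)
        rec = np.atleast_1d(haldane_r(np.diff(sub["cm"].to_numpy(float))))
        rng = np.random.default_rng(np.random.SeedSequence([arch.seed, 1, ci]))
        g1 = _gamete_walk(rng, n, rec)
        g2 = _gamete_walk(rng, n, rec)
        dosage = g1 + g2
        if return_gametes:
            gametes[chrom] = (g1, g2)
        for j, name in enumerate(sub["marker"]):
            columns[name] = _CODES[dosage[:, j]]

    geno = pd.DataFrame(columns, index=ids)
    if arch.missing_rate > 0:
        miss_rng = np.random.default_rng(np.random.SeedSequence([arch.seed, 3]))
        mask = miss_rng.random(geno.shape) < arch.missing_rate
        geno = geno.mask(mask)

    cd = CrossData(geno, pd.Series(sex, index=ids), pd.Series(cross, index=ids))
    return (cd, gametes) if return_gametes else cd


def _conditional_dosage(
    cross: CrossData, gmap: GeneticMap, chrom, pos_cm: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample the true genotype dosage at an arbitrary map position.

    The F2 genotype chain is Markov, so the dosage at ``pos_cm`` given all
    observed markers on the chromosome is obtained exactly from the
    forward-backward posterior at an inserted untyped locus, followed by one
    categorical draw per individual.  At a typed, non-missing marker the
    posterior is degenerate and the draw returns the observed genotype.
    """
    sub = gmap.chrom_markers(chrom)
    length = float(sub["cm"].max())
    if not 0.0 <= pos_cm <= length:
        raise ValueError(f"effect locus {pos_cm} cM is off chromosome {chrom}")
    cm = sub["cm"].to_numpy(float)
    dosage = cross.dosage()[sub["marker"].tolist()].to_numpy()
    obs = np.where(np.isnan(dosage), -1, dosage).astype(int)

    hit = np.nonzero(np.isclose(cm, pos_cm, atol=1e-9))[0]
    if hit.size:
        idx = int(hit[0])
        positions = cm
    else:
        idx = int(np.searchsorted(cm, pos_cm))
        positions = np.insert(cm, idx, pos_cm)
        obs = np.insert(obs, idx, -1, axis=1)

    post = forward_backward(obs, np.atleast_1d(haldane_r(np.diff(positions))), 0.0)
    p = post[:, idx, :]
    u = rng.random(len(p))
    return (u > p[:, 0]).astype(int) + (u > p[:, 0] + p[:, 1]).astype(int)


def _resolve_gene_positions(genes, gmap: GeneticMap):
    """Fill in missing physical positions (cis default; null genes spread evenly)."""
    resolved = []
    chroms = gmap.chromosomes
    null_counter = 0
    n_null = sum(1 for g in genes if g.gene_chrom is None and g.chrom is None)
    for ge in genes:
        if ge.gene_chrom is not None:
            if ge.gene_mb is None:
                raise ValueError(f"gene {ge.gene}: gene_chrom given without gene_mb")
            resolved.append(ge)
        elif ge.chrom is not None:
            resolved.append(
                replace(ge, gene_chrom=ge.chrom, gene_mb=float(gmap.interp_mb(ge.chrom, ge.pos_cm)))
            )
        else:
            chrom = chroms[null_counter % len(chroms)]
            sub = gmap.chrom_markers(chrom)
            frac = (null_counter // len(chroms) + 0.5) / max(1, math.ceil(n_null / len(chroms)))
            mb = float(sub["mb"].min() + frac * (sub["mb"].max() - sub["mb"].min()))
            resolved.append(replace(ge, gene_chrom=chrom, gene_mb=mb))
            null_counter += 1
    return resolved


def simulate_expression(
    cross: CrossData, gmap: GeneticMap, arch: SimArchitecture
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the probe x individual expression matrix and its truth table.

    Returns ``(expression, truth)``: expression is genes x individuals on a
    log2-like scale; the truth table has one row per gene with the
    generative effects, eQTL location and gene position (the acceptance
    surface for recovery tests).
    """
    arch.validate(gmap)
    genes = _resolve_gene_positions(list(arch.genes), gmap)
    if not genes:
        raise ValueError("architecture contains no genes")

    s = cross.sex.to_numpy(float)
    c = cross.cross.to_numpy(float)
    n = cross.n_individuals

    rows, truth_rows = [], []
    for gi, ge in enumerate(genes):
        rng = np.random.default_rng(np.random.SeedSequence([arch.seed, 2, gi]))
        if ge.chrom is not None:
            dos = _conditional_dosage(cross, gmap, ge.chrom, ge.pos_cm, rng)
        else:
            dos = np.ones(n, int)  # no genetic term enters below
        g = dos - 1.0
        h = (dos == 1).astype(float)
        y = (
            ge.baseline
            + ge.cross_main * c
            + ge.sex_main * s
            + ge.residual_sd * rng.standard_normal(n)
        )
        if ge.chrom is not None:
            y = (
                y
                + ge.additive * g
                + ge.dominance * h
                + ge.sex_interaction * s * g
                + ge.cde_interaction * c * g
            )
        rows.append(y)
        truth_rows.append(
            {
                "gene": ge.gene,
                "eqtl_chrom": ge.chrom,
                "eqtl_cm": ge.pos_cm,
                "eqtl_mb": (
                    float(gmap.interp_mb(ge.chrom, ge.pos_cm)) if ge.chrom is not None else None
                ),
                "additive": ge.additive,
                "dominance": ge.dominance,
                "sex_interaction": ge.sex_interaction,
                "cde_interaction": ge.cde_interaction,
                "residual_sd": ge.residual_sd,
                "baseline": ge.baseline,
                "sex_main": ge.sex_main,
                "cross_main": ge.cross_main,
                "gene_chrom": ge.gene_chrom,
                "gene_mb": ge.gene_mb,
                "has_eqtl": ge.chrom is not None
                and (
                    ge.additive != 0
                    or ge.dominance != 0
                    or ge.sex_interaction != 0
                    or ge.cde_interaction != 0
                ),
            }
        )

    expr = pd.DataFrame(np.vstack(rows), index=[g.gene for g in genes], columns=cross.individuals)
    truth = pd.DataFrame(truth_rows).set_index("gene")
    return expr, truth


def annotation_from_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Gene annotation table (gene, chromosome, Mb) from a truth table."""
    ann = truth[["gene_chrom", "gene_mb"]].rename(
        columns={"gene_chrom": "chrom", "gene_mb": "mb"}
    )
    return ann.reset_index()


def inject_probe_artifacts(
    expr: pd.DataFrame,
    snp_probes,
    attenuation: float,
    cross: CrossData,
    gmap: GeneticMap,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Hybridization artifacts for probes overlapping GK/BN sequence variants.

    A mismatching GK allele under the probe attenuates its signal: the linear
    intensity is multiplied by ``attenuation ** (GK-allele dosage)`` at the
    probe's own locus, i.e. ``dosage * log2(attenuation)`` is added on the
    log2 scale.  This manufactures a spurious cis-eQTL at the probe's own
    position even for transcripts with no true genetic regulation.  The
    genotype used is the observed call at the nearest framework marker
    (expected dosage 1 where missing).
    """
    if not 0.0 < attenuation <= 1.0:
        raise ValueError("attenuation must lie in (0, 1]")
    snp_probes = list(snp_probes)
    unknown = [g for g in snp_probes if g not in expr.index]
    if unknown:
        raise KeyError(f"unknown genes in snp_probes: {unknown}")
    if attenuation == 1.0 or not snp_probes:
        return expr.copy()

    ann = annotation.set_index("gene")
    dosage_all = cross.dosage()
    out = expr.copy()
    shift = math.log2(attenuation)
    for gene in snp_probes:
        chrom, mb = ann.loc[gene, "chrom"], float(ann.loc[gene, "mb"])
        sub = gmap.chrom_markers(chrom)
        cm = float(gmap.interp_cm(chrom, mb))
        nearest = sub.iloc[(sub["cm"] - cm).abs().argmin()]["marker"]
        dos = dosage_all[nearest].fillna(1.0).to_numpy()
        out.loc[gene] = out.loc[gene].to_numpy() + shift * dos
    return out


def simulate_raw_intensities(
    expr: pd.DataFrame,
    bg_mean: float,
    bg_sd: float,
    signal_scale: float,
    seed: int,
    n_background_pool: int = 10_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw bead-intensity fixture: additive Normal background plus Exponential signal.

    raw = Normal(bg_mean, bg_sd) + Exponential(mean=signal_scale) + expr,
    with ``expr`` interpreted in linear intensity units (pass zeros for a
    pure background + signal-noise fixture).  Detection scores are the
    empirical fraction of a seeded pool of pure-background draws lying below
    each observed value, so pure-background probes score ~ Uniform(0, 1).
    """
    if bg_sd <= 0 or signal_scale <= 0:
        raise ValueError("bg_sd and signal_scale must be positive")
    rng = np.random.default_rng(seed)
    shape = expr.shape
    raw = (
        rng.normal(bg_mean, bg_sd, size=shape)
        + rng.exponential(signal_scale, size=shape)
        + expr.to_numpy(float)
    )
    pool = np.sort(rng.normal(bg_mean, bg_sd, size=n_background_pool))
    scores = np.searchsorted(pool, raw, side="left") / n_background_pool
    raw_df = pd.DataFrame(raw, index=expr.index, columns=expr.columns)
    det_df = pd.DataFrame(scores, index=expr.index, columns=expr.columns)
    return raw_df, det_df


def standard_architecture(
    gmap: GeneticMap,
    n_null: int = 0,
    n_cis: int = 0,
    n_trans: int = 0,
    n_sex: int = 0,
    n_cde: int = 0,
    cis_effect: float = 1.5,
    trans_effect: float = 1.5,
    interaction_effect: float = 2.0,
    residual_sd: float = 1.0,
    sex_main: float = 0.3,
    cross_main: float = 0.2,
    hotspots=(),
    n_individuals: int = 123,
    cross_fraction: float = 55 / 123,
    female_fraction: float = 63 / 123,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> SimArchitecture:
    """Convenience builder for a study-scale architecture.

    Effect loci are placed uniformly at random on the map (reproducibly from
    ``seed``); cis genes sit at their own eQTL, trans/interaction genes are
    encoded on a different chromosome, and each hotspot contributes
    ``n_targets`` trans-regulated genes with Normal(effect_mean, effect_sd)
    per-allele effects.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9]))
    chroms = gmap.chromosomes

    def random_locus():
        chrom = chroms[rng.integers(len(chroms))]
        return chrom, float(rng.uniform(0.0, gmap.chrom_length_cm(chrom)))

    def other_chrom(chrom):
        pool = [c for c in chroms if c != chrom] or [chrom]
        return pool[rng.integers(len(pool))]

    genes = []
    common = dict(residual_sd=residual_sd, sex_main=sex_main, cross_main=cross_main)
    for i in range(n_null):
        genes.append(GeneEffect(gene=f"null{i + 1:04d}", **common))
    for i in range(n_cis):
        chrom, pos = random_locus()
        genes.append(
            GeneEffect(gene=f"cis{i + 1:04d}", chrom=chrom, pos_cm=pos, additive=cis_effect, **common)
        )
    for i in range(n_trans):
        chrom, pos = random_locus()
        gc = other_chrom(chrom)
        genes.append(
            GeneEffect(
                gene=f"trans{i + 1:04d}",
                chrom=chrom,
                pos_cm=pos,
                additive=trans_effect,
                gene_chrom=gc,
                gene_mb=float(
                    rng.uniform(gmap.chrom_markers(gc)["mb"].min(), gmap.chrom_markers(gc)["mb"].max())
                ),
                **common,
            )
        )
    for i in range(n_sex):
        chrom, pos = random_locus()
        genes.append(
            GeneEffect(
                gene=f"sexint{i + 1:04d}",
                chrom=chrom,
                pos_cm=pos,
                sex_interaction=interaction_effect,
                **common,
            )
        )
    for i in range(n_cde):
        chrom, pos = random_locus()
        genes.append(
            GeneEffect(
                gene=f"cdeint{i + 1:04d}",
                chrom=chrom,
                pos_cm=pos,
                cde_interaction=interaction_effect,
                **common,
            )
        )
    for hi, hs in enumerate(hotspots, start=1):
        for i in range(hs.n_targets):
            effect = float(rng.normal(hs.effect_mean, hs.effect_sd))
            gc = other_chrom(hs.chrom)
            genes.append(
                GeneEffect(
                    gene=f"hs{hi}_{i + 1:04d}",
                    chrom=hs.chrom,
                    pos_cm=hs.pos_cm,
                    additive=effect,
                    residual_sd=hs.residual_sd,
                    sex_main=sex_main,
                    cross_main=cross_main,
                    gene_chrom=gc,
                    gene_mb=float(
                        rng.uniform(
                            gmap.chrom_markers(gc)["mb"].min(), gmap.chrom_markers(gc)["mb"].max()
                        )
                    ),
                )
            )

    return SimArchitecture(
        n_individuals=n_individuals,
        cross_fraction=cross_fraction,
        female_fraction=female_fraction,
        genes=genes,
        hotspots=list(hotspots),
        missing_rate=missing_rate,
        seed=seed,
    )


def simulate_gene_sets(
    genes, n_sets: int = 20, set_size: int = 25, enriched_genes=None, seed: int = 0
) -> dict:
    """Named gene sets drawn from ``genes``, optionally one set enriched in
    ``enriched_genes`` (used to exercise the hypergeometric test end to end)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    genes = list(genes)
    sets = {}
    for i in range(n_sets):
        size = min(set_size, len(genes))
        members = list(rng.choice(genes, size=size, replace=False))
        sets[f"SET{i + 1:03d}"] = members
    if enriched_genes:
        pool = [g for g in enriched_genes if g in set(genes)]
        k = min(set_size, len(pool))
        members = list(rng.choice(pool, size=k, replace=False))
        if k < set_size:
            rest = [g for g in genes if g not in set(members)]
            members += list(rng.choice(rest, size=min(set_size - k, len(rest)), replace=False))
        sets["SET_ENRICHED"] = members
    return sets
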