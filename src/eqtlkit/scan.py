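"""Haley-Knott genome scans with permutation-based significance.

The scan regresses one transcript's expression on expected genotype scores
at each grid locus: the additive score a = P(BB) - P(AA) (GK-allele
contrast) and the dominance score h = P(AB), with sex and cross direction
as additive covariates.  Evidence for linkage is the LOD score

    LOD = (n/2) * log10(RSS_null / RSS_full)

comparing the covariate-only null model with the model adding (a, h) by
ordinary least squares.  Genotype x covariate interaction scans add
(s*a, s*h) (or c*a, c*h) and report LODf, the LOD difference between the
interactive and the additive model.  Genome-wide significance per
transcript comes from permutations of the phenotype within sex x cross
strata; across transcripts, Benjamini-Hochberg FDR is applied to the
permutation-adjusted p-values.

All heavy paths are vectorized: per-locus design matrices are reduced to
orthonormal bases once, so LOD curves for hundreds of permuted phenotypes
are a single matrix product per locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._types import GenoProbs

log = logging.getLogger(__name__)

LOD_CAP = 300.0


# ---------------------------------------------------------------------------
# least-squares plumbing

def _cov_array(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    arr = covariates.to_numpy(float) if hasattr(covariates, "to_numpy") else np.asarray(covariates, float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] != n:
        raise ValueError("covariate rows do not match phenotype length")
    return arr


def _basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (collinear columns dropped)."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    if s[0] <= 0:
        return U[:, :0]
    return U[:, s > max(X.shape) * np.finfo(float).eps * s[0]]


def _interacting_values(covariates, interacting, n: int) -> np.ndarray:
    if isinstance(interacting, str) and hasattr(covariates, "columns"):
        if interacting not in covariates.columns:
            raise KeyError(f"interacting covariate {interacting!r} not among covariates")
        return covariates[interacting].to_numpy(float)
    arr = _cov_array(covariates, n)
    return arr[:, int(interacting)]


def _locus_bases(G: np.ndarray, cov: np.ndarray, icov: np.ndarray | None) -> np.ndarray:
    """Stacked orthonormal bases of the per-locus full-model designs.

    G is (n, L, 3); the design at locus l is [1, covariates, a_l, h_l]
    plus (icov*a_l, icov*h_l) when an interacting covariate is given.
    Near-collinear genotype columns are dropped (their basis vectors
    zeroed), so degenerate loci score LOD ~ 0 instead of blowing up.
    """
    n, L, _ = G.shape
    a = G[:, :, 2] - G[:, :, 0]
    h = G[:, :, 1]
    k = cov.shape[1]
    extra = 2 if icov is None else 4
    p = 1 + k + extra
    designs = np.empty((L, n, p))
    designs[:, :, 0] = 1.0
    for j in range(k):
        designs[:, :, 1 + j] = cov[:, j]
    designs[:, :, 1 + k] = a.T
    designs[:, :, 2 + k] = h.T
    if icov is not None:
        designs[:, :, 3 + k] = (icov[:, None] * a).T
        designs[:, :, 4 + k] = (icov[:, None] * h).T
    Q, R = np.linalg.qr(designs)
    diag = np.abs(np.einsum("lii->li", R))
    keep = diag > 1e-8 * np.maximum(diag.max(axis=1, keepdims=True), 1.0)
    return Q * keep[:, None, :]


def _lod_matrix(Y: np.ndarray, Q0: np.ndarray, QL: np.ndarray, cap: float = LOD_CAP) -> np.ndarray:
    """LOD for every locus (rows) and every phenotype column of Y."""
    n = Y.shape[0]
    yss = np.einsum("ij,ij->j", Y, Y)
    rss0 = yss - np.einsum("ij,ij->j", Q0.T @ Y, Q0.T @ Y)
    rss0 = np.maximum(rss0, 0.0)
    proj = QL.transpose(0, 2, 1) @ Y                      # (L, p, C)
    rss1 = np.maximum(yss[None, :] - np.einsum("lpc,lpc->lc", proj, proj), 0.0)
    scale = np.maximum(yss, 1e-300)
    floor = rss0 * 10.0 ** (-2.0 * cap / n)               # RSS ratio giving exactly cap
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = (n / 2.0) * np.log10(rss0[None, :] / np.maximum(rss1, floor[None, :]))
    # numerically perfect fits hit the cap; constant phenotypes score zero
    lod = np.where(rss1 <= scale[None, :] * 1e-14, cap, lod)
    lod = np.where(rss0[None, :] <= scale[None, :] * 1e-14, 0.0, lod)
    return np.clip(lod, 0.0, cap)


# ---------------------------------------------------------------------------
# single-locus interface

def hk_lod(y, probs, covariates=None, cap: float = LOD_CAP) -> float:
    """Haley-Knott LOD at one locus.

    ``probs`` is the (n, 3) genotype-probability matrix; the full model adds
    the expected genotype scores (a, h) to intercept + covariates.  A
    perfect fit is capped at ``cap``.
    """
    y = np.asarray(y, float)
    probs = np.asarray(probs, float)
    cov = _cov_array(covariates, len(y))
    G = probs[:, None, :]
    Q0 = _basis(np.column_stack([np.ones(len(y)), cov]))
    QL = _locus_bases(G, cov, None)
    return float(_lod_matrix(y[:, None], Q0, QL, cap)[0, 0])


def hk_lod_interactive(y, probs, covariates, interacting, cap: float = LOD_CAP):
    """Interactive-covariate LOD at one locus.

    Returns ``(lod_int, lodf)`` where the interactive model H_int adds
    genotype x covariate products to the additive model H_add and
    LODf = LOD_int - LOD_add (non-negative by model nesting).
    """
    y = np.asarray(y, float)
    probs = np.asarray(probs, float)
    n = len(y)
    cov = _cov_array(covariates, n)
    icov = _interacting_values(covariates, interacting, n)
    G = probs[:, None, :]
    Q0 = _basis(np.column_stack([np.ones(n), cov]))
    lod_add = _lod_matrix(y[:, None], Q0, _locus_bases(G, cov, None), cap)[0, 0]
    lod_int = _lod_matrix(y[:, None], Q0, _locus_bases(G, cov, icov), cap)[0, 0]
    return float(lod_int), float(max(lod_int - lod_add, 0.0))


# ---------------------------------------------------------------------------
# genome scans

@dataclass
class ScanCurve:
    """LOD curve over the grid plus the peak locus (ties resolved to the
    first grid locus, i.e. lowest chromosome then lowest cM)."""

    curve: pd.DataFrame
    peak: dict = field(default_factory=dict)


def _prepare(y, genoprobs: GenoProbs, covariates, interacting):
    y = np.asarray(y, float)
    mask = np.isfinite(y)
    G = genoprobs.probs
    cov = _cov_array(covariates, len(y))
    icov = None
    if interacting is not None:
        icov = _interacting_values(covariates, interacting, len(y))
    if not mask.all():
        y, G, cov = y[mask], G[mask], cov[mask]
        icov = icov[mask] if icov is not None else None
    n = len(y)
    Q0 = _basis(np.column_stack([np.ones(n), cov]))
    return y, G, cov, icov, Q0, mask


def genome_scan(
    y, genoprobs: GenoProbs, covariates=None, mode: str = "additive", cap: float = LOD_CAP
) -> ScanCurve:
    """Scan every grid locus; in interaction modes the peak is on LODf.

    ``mode``: ``additive``, ``sex_int`` or ``cross_int`` (the latter two
    require the corresponding column in ``covariates``).
    """
    if mode not in ("additive", "sex_int", "cross_int"):
        raise ValueError(f"unknown scan mode {mode!r}")
    interacting = {"additive": None, "sex_int": "sex", "cross_int": "cross"}[mode]
    y, G, cov, icov, Q0, _ = _prepare(y, genoprobs, covariates, interacting)

    curve = genoprobs.loci[["locus", "chrom", "cm", "mb"]].copy()
    lod_add = _lod_matrix(y[:, None], Q0, _locus_bases(G, cov, None), cap)[:, 0]
    if mode == "additive":
        curve["lod"] = lod_add
        stat = lod_add
    else:
        lod_int = _lod_matrix(y[:, None], Q0, _locus_bases(G, cov, icov), cap)[:, 0]
        curve["lod_add"] = lod_add
        curve["lod_int"] = lod_int
        curve["lodf"] = np.maximum(lod_int - lod_add, 0.0)
        stat = curve["lodf"].to_numpy()
    i = int(np.argmax(stat))
    peak = curve.iloc[i].to_dict()
    peak["index"] = i
    return ScanCurve(curve, peak)


def stratified_permutations(strata, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """(n_perm, n) index array permuting individuals within each stratum."""
    strata = np.zeros(1, int) if strata is None else np.asarray(strata)
    n = len(strata)
    idx = np.tile(np.arange(n), (n_perm, 1))
    for s in np.unique(strata):
        members = np.nonzero(strata == s)[0]
        if len(members) < 2:
            continue
        order = np.argsort(rng.random((n_perm, len(members))), axis=1)
        idx[:, members] = members[order]
    return idx


def _check_n_perm(n_perm: int) -> None:
    if n_perm < 10:
        raise ValueError("need at least 10 permutations")
    if n_perm < 100:
        log.warning("n_perm=%d is low; adjusted p-values will be coarse", n_perm)


def permutation_adjusted_p(
    y,
    genoprobs: GenoProbs,
    covariates=None,
    n_perm: int = 1000,
    seed: int = 0,
    strata=None,
    cap: float = LOD_CAP,
):
    """Genome-scan adjusted p-value for one transcript.

    Phenotype rows are permuted within sex x cross strata (genotypes and
    covariates fixed) and the adjusted p-value is
    (1 + #{permutation max-LOD >= observed max LOD}) / (n_perm + 1).
    Returns ``(p, null_max)`` with the permutation max-LOD sample.
    """
    _check_n_perm(n_perm)
    y, G, cov, _, Q0, mask = _prepare(y, genoprobs, covariates, None)
    strata_used = None if strata is None else np.asarray(strata)[mask]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5]))
    idx = stratified_permutations(
        strata_used if strata_used is not None else np.zeros(len(y), int), n_perm, rng
    )
    Y = np.empty((len(y), n_perm + 1))
    Y[:, 0] = y
    Y[:, 1:] = y[idx].T
    lods = _lod_matrix(Y, Q0, _locus_bases(G, cov, None), cap)
    maxima = lods.max(axis=0)
    null_max = maxima[1:]
    p = (1.0 + np.sum(null_max >= maxima[0])) / (n_perm + 1.0)
    return float(p), null_max


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values across transcripts."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def allele_effect(y, probs, covariates=None):
    """Fitted genotype-class means and the expression ratio at a locus.

    Fits the full additive+dominance model at the given locus and reports
    the fitted means of the GK/GK, GK/BN and BN/BN classes (covariates at
    their sample means) and the expression ratio
    ER = mean(GK/GK) - mean(BN/BN), a signed log2-scale allelic effect:
    negative ER means GK alleles downregulate the transcript.  Classes with
    no individual assigned (by most probable genotype) are flagged: their
    means are model extrapolations.
    """
    y = np.asarray(y, float)
    probs = np.asarray(probs, float)
    cov = _cov_array(covariates, len(y))
    mask = np.isfinite(y)
    y, probs, cov = y[mask], probs[mask], cov[mask]
    a = probs[:, 2] - probs[:, 0]
    h = probs[:, 1]
    X = np.column_stack([np.ones(len(y)), cov, a, h])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    base = beta[0] + cov.mean(axis=0) @ beta[1 : 1 + cov.shape[1]]
    b_a, b_h = beta[-2], beta[-1]
    means = {"BNBN": base - b_a, "GKBN": base + b_h, "GKGK": base + b_a}
    present = np.bincount(np.argmax(probs, axis=1), minlength=3) > 0
    flags = {cls: bool(ok) for cls, ok in zip(("BNBN", "GKBN", "GKGK"), present)}
    er = float(means["GKGK"] - means["BNBN"])
    return {"means": means, "er": er, "class_observed": flags}


# ---------------------------------------------------------------------------
# multi-transcript drivers

def scan_transcripts(
    expr: pd.DataFrame,
    genoprobs: GenoProbs,
    covariates=None,
    strata=None,
    n_perm: int = 1000,
    seed: int = 0,
    fdr: float = 0.05,
    report_secondary: bool = True,
    cap: float = LOD_CAP,
):
    """Additive genome scan with permutation significance for every transcript.

    Two-stage significance: a genome-scan adjusted p-value per transcript
    (stratified permutations), then Benjamini-Hochberg FDR across
    transcripts; a declared eQTL is q < ``fdr``.  Secondary peaks are
    reported on chromosomes other than the primary peak whose LOD exceeds
    the transcript's permutation 95% threshold.

    Returns ``(records, secondary)`` DataFrames.
    """
    _check_n_perm(n_perm)
    loci = genoprobs.loci
    chrom_codes = loci["chrom"].to_numpy()
    cov_full = _cov_array(covariates, expr.shape[1])
    strata_full = (
        np.zeros(expr.shape[1], int) if strata is None else np.asarray(strata)
    )

    # shared per-locus bases for the common complete-phenotype case
    n_all = expr.shape[1]
    Q0_full = _basis(np.column_stack([np.ones(n_all), cov_full]))
    QL_full = _locus_bases(genoprobs.probs, cov_full, None)

    records, secondary = [], []
    for ti, (transcript, row) in enumerate(expr.iterrows()):
        y_raw = row.to_numpy(float)
        mask = np.isfinite(y_raw)
        if mask.all():
            y, G, cov, Q0, QL = y_raw, genoprobs.probs, cov_full, Q0_full, QL_full
            strata_t = strata_full
        else:
            y = y_raw[mask]
            G = genoprobs.probs[mask]
            cov = cov_full[mask]
            Q0 = _basis(np.column_stack([np.ones(len(y)), cov]))
            QL = _locus_bases(G, cov, None)
            strata_t = strata_full[mask]

        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 6, ti]))
        idx = stratified_permutations(strata_t, n_perm, rng)
        Y = np.empty((len(y), n_perm + 1))
        Y[:, 0] = y
        Y[:, 1:] = y[idx].T
        lods = _lod_matrix(Y, Q0, QL, cap)
        obs = lods[:, 0]
        null_max = lods[:, 1:].max(axis=0)
        peak_i = int(np.argmax(obs))
        p = (1.0 + np.sum(null_max >= obs[peak_i])) / (n_perm + 1.0)
        threshold = float(np.quantile(null_max, 0.95))

        eff = allele_effect(y, G[:, peak_i, :], cov)
        rec = {
            "transcript": transcript,
            "peak_locus": loci.at[peak_i, "locus"],
            "peak_chrom": loci.at[peak_i, "chrom"],
            "peak_cm": float(loci.at[peak_i, "cm"]),
            "peak_mb": float(loci.at[peak_i, "mb"]),
            "lod": float(obs[peak_i]),
            "pvalue": p,
            "threshold_95": threshold,
            "mean_BNBN": eff["means"]["BNBN"],
            "mean_GKBN": eff["means"]["GKBN"],
            "mean_GKGK": eff["means"]["GKGK"],
            "er": eff["er"],
            "n_used": int(len(y)),
        }
        records.append(rec)

        if report_secondary:
            peak_chrom = chrom_codes[peak_i]
            for chrom in pd.unique(chrom_codes):
                if chrom == peak_chrom:
                    continue
                sel = np.nonzero(chrom_codes == chrom)[0]
                j = sel[int(np.argmax(obs[sel]))]
                if obs[j] > threshold:
                    secondary.append(
                        {
                            "transcript": transcript,
                            "peak_chrom": chrom,
                            "peak_cm": float(loci.at[int(j), "cm"]),
                            "peak_mb": float(loci.at[int(j), "mb"]),
                            "lod": float(obs[j]),
                        }
                    )

    records = pd.DataFrame(records)
    records["qvalue"] = fdr_adjust(records["pvalue"].to_numpy())
    records["significant"] = records["qvalue"] < fdr
    secondary = pd.DataFrame(
        secondary, columns=["transcript", "peak_chrom", "peak_cm", "peak_mb", "lod"]
    )
    return records, secondary


def interaction_scan(
    expr: pd.DataFrame,
    genoprobs: GenoProbs,
    covariates,
    interacting: str = "sex",
    strata=None,
    n_perm: int = 1000,
    seed: int = 0,
    cap: float = LOD_CAP,
) -> pd.DataFrame:
    """Genotype x covariate interaction scan (sex-specific or cross-direction
    effects) with a permutation-adjusted p-value per transcript.

    The null distribution of the maximum LODf keeps the additive genetic
    signal intact: residuals from the additive model H_add at the
    transcript's additive peak are permuted within strata and added back to
    the fitted values before rescanning (a Freedman-Lane scheme).
    """
    _check_n_perm(n_perm)
    loci = genoprobs.loci
    n_all = expr.shape[1]
    cov = _cov_array(covariates, n_all)
    icov = _interacting_values(covariates, interacting, n_all)
    strata_full = np.zeros(n_all, int) if strata is None else np.asarray(strata)
    Q0 = _basis(np.column_stack([np.ones(n_all), cov]))
    QL_add = _locus_bases(genoprobs.probs, cov, None)
    QL_int = _locus_bases(genoprobs.probs, cov, icov)
    a = genoprobs.additive_score()
    h = genoprobs.dominance_score()

    out = []
    for ti, (transcript, row) in enumerate(expr.iterrows()):
        y = row.to_numpy(float)
        if not np.isfinite(y).all():
            raise ValueError("interaction_scan requires complete phenotypes")
        lod_add = _lod_matrix(y[:, None], Q0, QL_add, cap)[:, 0]
        lod_int = _lod_matrix(y[:, None], Q0, QL_int, cap)[:, 0]
        lodf = np.maximum(lod_int - lod_add, 0.0)
        peak_i = int(np.argmax(lodf))
        add_peak = int(np.argmax(lod_add))

        # Freedman-Lane null: permute residuals of H_add at the additive peak
        X = np.column_stack([np.ones(n_all), cov, a[:, add_peak], h[:, add_peak]])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        resid = y - fitted
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7, ti]))
        idx = stratified_permutations(strata_full, n_perm, rng)
        Ystar = fitted[:, None] + resid[idx].T
        null_add = _lod_matrix(Ystar, Q0, QL_add, cap)
        null_int = _lod_matrix(Ystar, Q0, QL_int, cap)
        null_max = np.maximum(null_int - null_add, 0.0).max(axis=0)
        p = (1.0 + np.sum(null_max >= lodf[peak_i])) / (n_perm + 1.0)

        out.append(
            {
                "transcript": transcript,
                "peak_locus": loci.at[peak_i, "locus"],
                "peak_chrom": loci.at[peak_i, "chrom"],
                "peak_cm": float(loci.at[peak_i, "cm"]),
                "peak_mb": float(loci.at[peak_i, "mb"]),
                "lodf": float(lodf[peak_i]),
                "lod_add_at_peak": float(lod_add[peak_i]),
                "pvalue": p,
            }
        )
    return pd.DataFrame(out)
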