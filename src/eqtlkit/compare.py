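"""Cross-tissue and cross-population eQTL conservation.

Two eQTL tables (e.g. kidney vs adipose tissue from the same cross, or an
F2 cross vs a recombinant-inbred panel) are intersected at the gene level.
Tissue-level conservation requires peaks on the same chromosome within a
genetic-distance window and a consistent allelic effect direction;
cross-mapping-system conservation uses a physical-distance window (the two
systems have different genetic maps).  Overlap significance is a one-sided
Fisher's exact test over the shared background of scanned genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def _declared(records: pd.DataFrame) -> pd.DataFrame:
    if "significant" in records.columns:
        return records[records["significant"] == True]  # noqa: E712
    return records


def conserved_crosstissue(
    records_a: pd.DataFrame, records_b: pd.DataFrame, window_cm: float = 15.0
) -> pd.DataFrame:
    """Genes with a conserved eQTL in two tissues.

    A gene is conserved iff it has a declared eQTL in both tables whose
    peaks lie on the same chromosome within ``window_cm`` and whose
    expression ratios share the same (nonzero) sign.  When a gene has
    several eQTLs, any matching pair qualifies.  Symmetric in (A, B).
    """
    a, b = _declared(records_a), _declared(records_b)
    rows = []
    by_gene_b = dict(tuple(b.groupby("transcript")))
    for gene, grp_a in a.groupby("transcript"):
        grp_b = by_gene_b.get(gene)
        if grp_b is None:
            continue
        best = None
        for _, ra in grp_a.iterrows():
            for _, rb in grp_b.iterrows():
                if str(ra["peak_chrom"]) != str(rb["peak_chrom"]):
                    continue
                if abs(float(ra["peak_cm"]) - float(rb["peak_cm"])) > window_cm:
                    continue
                if np.sign(ra["er"]) == 0 or np.sign(ra["er"]) != np.sign(rb["er"]):
                    continue
                cand = {
                    "gene": gene,
                    "chrom": ra["peak_chrom"],
                    "peak_cm_a": float(ra["peak_cm"]),
                    "peak_cm_b": float(rb["peak_cm"]),
                    "er_a": float(ra["er"]),
                    "er_b": float(rb["er"]),
                    "lod_a": float(ra["lod"]),
                    "lod_b": float(rb["lod"]),
                }
                if best is None or cand["lod_a"] + cand["lod_b"] > best["lod_a"] + best["lod_b"]:
                    best = cand
        if best is not None:
            rows.append(best)
    return pd.DataFrame(
        rows,
        columns=["gene", "chrom", "peak_cm_a", "peak_cm_b", "er_a", "er_b", "lod_a", "lod_b"],
    )


def overlap_enrichment(n_conserved: int, n_a: int, n_b: int, n_background: int) -> float:
    """One-sided Fisher's exact p for over-representation of the overlap.

    The 2x2 table partitions the ``n_background`` gene universe by eQTL
    status in A and in B; the p-value is the hypergeometric upper tail
    P(X >= n_conserved).
    """
    k, na, nb, nn = int(n_conserved), int(n_a), int(n_b), int(n_background)
    if not (0 <= k <= min(na, nb) and max(na, nb) <= nn):
        raise ValueError("inconsistent counts for the 2x2 overlap table")
    table = [[k, na - k], [nb - k, nn - na - nb + k]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def conserved_crossmodel(
    records_f2: pd.DataFrame, records_ri: pd.DataFrame, window_mb: float = 10.0
) -> pd.DataFrame:
    """Genes with co-localized eQTLs in two mapping systems.

    Conservation requires declared eQTLs for the gene in both systems with
    peaks on the same chromosome within ``window_mb`` (peak positions, not
    gene positions, so trans eQTLs compare meaningfully); the direction
    agreement of the allelic effects is reported per pair rather than
    required.
    """
    a, b = _declared(records_f2), _declared(records_ri)
    rows = []
    by_gene_b = dict(tuple(b.groupby("transcript")))
    for gene, grp_a in a.groupby("transcript"):
        grp_b = by_gene_b.get(gene)
        if grp_b is None:
            continue
        best = None
        for _, ra in grp_a.iterrows():
            for _, rb in grp_b.iterrows():
                if str(ra["peak_chrom"]) != str(rb["peak_chrom"]):
                    continue
                dist = abs(float(ra["peak_mb"]) - float(rb["peak_mb"]))
                if dist > window_mb:
                    continue
                cand = {
                    "gene": gene,
                    "chrom": ra["peak_chrom"],
                    "peak_mb_f2": float(ra["peak_mb"]),
                    "peak_mb_ri": float(rb["peak_mb"]),
                    "er_f2": float(ra["er"]),
                    "er_ri": float(rb["er"]),
                    "direction_consistent": bool(
                        np.sign(ra["er"]) == np.sign(rb["er"]) and np.sign(ra["er"]) != 0
                    ),
                    "distance_mb": dist,
                }
                if best is None or cand["distance_mb"] < best["distance_mb"]:
                    best = cand
        if best is not None:
            rows.append(best)
    return pd.DataFrame(
        rows,
        columns=["gene", "chrom", "peak_mb_f2", "peak_mb_ri", "er_f2", "er_ri",
                 "direction_consistent", "distance_mb"],
    )
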