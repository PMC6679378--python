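"""Post-scan eQTL architecture: cis/trans classes, hotspots, polygeny.

An eQTL is classified by the physical distance between the scan peak
(interpolated Mb at the grid locus) and the regulated gene: a peak on a
different chromosome is unambiguously trans; a peak within 5 Mb (strict) or
10 Mb (loose) of the gene is a candidate cis effect; same-chromosome peaks
beyond the loose window stay in their own class.  Hotspots are genomic bins
linked to more trans peaks than a homogeneous Poisson null allows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

CLASS_LABELS = ("cis_5Mb", "cis_10Mb", "same_chrom_distant", "trans", "unassigned")

#: eQTL classes whose peaks enter hotspot counting (non-local regulation)
DISTANT_CLASSES = ("trans", "same_chrom_distant")


def classify_eqtl(
    gene_chrom,
    gene_mb,
    peak_chrom,
    peak_mb,
    window_strict_mb: float = 5.0,
    window_mb: float = 10.0,
) -> str:
    """Class label for one eQTL; unmappable genes -> ``unassigned``."""
    if gene_chrom is None or (isinstance(gene_mb, float) and np.isnan(gene_mb)) or gene_mb is None:
        return "unassigned"
    if str(gene_chrom) != str(peak_chrom):
        return "trans"
    dist = abs(float(peak_mb) - float(gene_mb))
    if dist <= window_strict_mb:
        return "cis_5Mb"
    if dist <= window_mb:
        return "cis_10Mb"
    return "same_chrom_distant"


def classify_records(
    records: pd.DataFrame,
    annotation: pd.DataFrame,
    window_strict_mb: float = 5.0,
    window_mb: float = 10.0,
) -> pd.DataFrame:
    """Attach gene positions and class labels to a scan-record table.

    ``annotation`` columns: gene, chrom, mb (genes missing from the table,
    or annotated to multiple positions, become ``unassigned``).
    """
    ann = annotation.drop_duplicates()
    multi = ann["gene"][ann["gene"].duplicated()].unique()
    ann = ann[~ann["gene"].isin(multi)].set_index("gene")
    out = records.copy()
    gene_chrom, gene_mb, labels = [], [], []
    for _, rec in out.iterrows():
        g = rec["transcript"]
        if g in ann.index:
            gc, gm = ann.at[g, "chrom"], float(ann.at[g, "mb"])
        else:
            gc, gm = None, np.nan
        gene_chrom.append(gc)
        gene_mb.append(gm)
        labels.append(
            classify_eqtl(gc, gm, rec["peak_chrom"], rec["peak_mb"], window_strict_mb, window_mb)
        )
    out["gene_chrom"] = gene_chrom
    out["gene_mb"] = gene_mb
    out["eqtl_class"] = labels
    return out


def detect_hotspots(
    records: pd.DataFrame,
    chrom_lengths_cm: dict,
    bin_cm: float = 5.0,
    alpha: float = 0.001,
    classes=DISTANT_CLASSES,
) -> pd.DataFrame:
    """Bins with a significant excess of distant eQTL peaks.

    The genome is partitioned into ``bin_cm`` bins; peak counts of trans
    (and same-chromosome-distant) eQTLs are compared against
    Poisson(mean = total peaks / total bins), Bonferroni-corrected over the
    number of bins.  Returns one row per hotspot bin with its member
    transcripts and the fraction of members whose GK allele downregulates
    expression (ER < 0).
    """
    if records.empty:
        return pd.DataFrame(
            columns=["chrom", "bin_start_cm", "bin_end_cm", "count", "threshold",
                     "members", "frac_gk_down"]
        )
    sub = records[records["eqtl_class"].isin(classes)] if "eqtl_class" in records else records
    bins = []
    for chrom, length in chrom_lengths_cm.items():
        edges = np.arange(0.0, float(length) + bin_cm, bin_cm)
        for lo in edges[:-1]:
            bins.append((chrom, lo, lo + bin_cm))
    n_bins = len(bins)
    counts = np.zeros(n_bins, int)
    members: list[list] = [[] for _ in range(n_bins)]
    index = {}
    for i, (chrom, lo, hi) in enumerate(bins):
        index.setdefault(chrom, []).append((lo, hi, i))
    for _, rec in sub.iterrows():
        for lo, hi, i in index.get(rec["peak_chrom"], ()):
            if lo <= rec["peak_cm"] < hi:
                counts[i] += 1
                members[i].append(rec["transcript"])
                break
    total = counts.sum()
    mu = total / n_bins if n_bins else 0.0
    threshold = stats.poisson.ppf(1.0 - alpha / max(n_bins, 1), mu) if total else np.inf

    er_by_transcript = (
        records.set_index("transcript")["er"] if "er" in records else pd.Series(dtype=float)
    )
    rows = []
    for i, (chrom, lo, hi) in enumerate(bins):
        if counts[i] > threshold:
            ers = er_by_transcript.reindex(members[i]).dropna()
            frac_down = float((ers < 0).mean()) if len(ers) else np.nan
            rows.append(
                {
                    "chrom": chrom,
                    "bin_start_cm": lo,
                    "bin_end_cm": hi,
                    "count": int(counts[i]),
                    "threshold": float(threshold),
                    "members": ";".join(map(str, members[i])),
                    "frac_gk_down": frac_down,
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "bin_start_cm", "bin_end_cm", "count", "threshold",
                       "members", "frac_gk_down"]
    )


def polygenic_genes(records: pd.DataFrame, secondary: pd.DataFrame) -> list:
    """Genes with two or more declared eQTLs on distinct chromosomes.

    A gene qualifies when it has a declared (significant) primary eQTL and
    at least one secondary peak on a different chromosome above its
    permutation threshold; within-chromosome secondary peaks are not
    counted (they are not separable at F2 mapping resolution).
    """
    if records.empty or secondary.empty:
        return []
    declared = records[records.get("significant", False) == True]  # noqa: E712
    primary_chrom = declared.set_index("transcript")["peak_chrom"]
    out = []
    for transcript, grp in secondary.groupby("transcript"):
        if transcript not in primary_chrom.index:
            continue
        other = set(grp["peak_chrom"]) - {primary_chrom[transcript]}
        if other:
            out.append(transcript)
    return sorted(out)


def direction_summary(records: pd.DataFrame, subset=None) -> dict:
    """Fraction of eQTLs whose GK allele downregulates expression (ER < 0).

    Records with ER exactly 0 are excluded from the denominator and counted
    separately.  An empty subset yields ``fraction = nan`` with a flag.
    """
    sub = records if subset is None else records.loc[records["transcript"].isin(set(subset))]
    er = sub["er"].to_numpy(float)
    n_zero = int(np.sum(er == 0.0))
    informative = er[er != 0.0]
    if informative.size == 0:
        return {"fraction_gk_down": np.nan, "n": 0, "n_zero": n_zero, "defined": False}
    return {
        "fraction_gk_down": float(np.mean(informative < 0)),
        "n": int(informative.size),
        "n_zero": n_zero,
        "defined": True,
    }
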