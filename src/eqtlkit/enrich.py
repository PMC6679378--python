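"""Hypergeometric gene-set (pathway / GO) enrichment.

Enrichment of an eQTL gene list is tested against the background of genes
with detectable expression, not the whole annotation: for each set,
p = P(X >= k) with X ~ Hypergeometric(N = |background|,
K = |set intersected with background|, n = |query|).  Multiple probes per
gene must be collapsed to genes before testing; identifiers are treated as
opaque strings.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .scan import fdr_adjust


def read_gmt(path) -> dict:
    """Parse a GMT file: one set per line, ``id<TAB>description<TAB>members...``."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {"description": parts[1], "genes": [g for g in parts[2:] if g]}
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name, val in sets.items():
            genes = val["genes"] if isinstance(val, dict) else list(val)
            desc = val.get("description", "") if isinstance(val, dict) else ""
            fh.write("\t".join([name, desc, *genes]) + "\n")


def hypergeom_enrich(query, collection: dict, background) -> pd.DataFrame:
    """Per-set hypergeometric over-representation of ``query`` in ``collection``.

    ``query`` must be a subset of ``background``; each set is intersected
    with the background before testing and sets with an empty intersection
    are skipped.  Returns a table (set, description, k, K, n, N, p, q)
    sorted by p, where q is the Benjamini-Hochberg adjustment over the
    tested sets.
    """
    query = set(query)
    background = set(background)
    offenders = sorted(query - background)
    if offenders:
        raise ValueError(f"query genes outside the background: {offenders[:10]}")
    n, N = len(query), len(background)
    rows = []
    for name, val in collection.items():
        genes = set(val["genes"] if isinstance(val, dict) else val)
        desc = val.get("description", "") if isinstance(val, dict) else ""
        K = len(genes & background)
        if K == 0:
            continue
        k = len(genes & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "description": desc, "k": k, "K": K, "n": n, "N": N,
                     "p": min(p, 1.0)})
    result = pd.DataFrame(rows, columns=["set", "description", "k", "K", "n", "N", "p"])
    if len(result):
        result["q"] = adjust_enrichment(result["p"].to_numpy())
        result = result.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    else:
        result["q"] = pd.Series(dtype=float)
    return result


def adjust_enrichment(pvalues):
    """BH q-values over the tested sets (same step-up as the scan module)."""
    return fdr_adjust(pvalues)
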