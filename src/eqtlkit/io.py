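"""Delimited-text readers/writers for every pipeline artifact.

All on-disk formats are plain TSV/CSV so runs are diffable and portable:
map TSV (marker, chrom, cm, mb); genotype CSV (individuals x markers with
AA/AB/BB codes plus sex and cross columns); expression TSV (probes x
individuals); long genotype-probability TSV; scan-record and truth tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._types import CrossData, GeneticMap, GenoProbs


def write_map(gmap: GeneticMap, path) -> None:
    gmap.markers.to_csv(path, sep="\t", index=False)


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return GeneticMap(df)


def write_genotypes(cross: CrossData, path) -> None:
    out = cross.genotypes.copy()
    out.insert(0, "sex", cross.sex)
    out.insert(1, "cross", cross.cross)
    out.to_csv(path, index_label="individual")


def read_genotypes(path) -> CrossData:
    df = pd.read_csv(path, index_col="individual")
    sex = df.pop("sex").astype(int)
    cross = df.pop("cross").astype(int)
    geno = df.where(df.notna(), np.nan)
    return CrossData(geno, sex, cross)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="probe")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe")


def write_genoprobs(gp: GenoProbs, path) -> None:
    """Long format: individual, locus, chrom, cm, mb, p_aa, p_ab, p_bb."""
    n, L = gp.n_individuals, gp.n_loci
    ind = np.repeat(gp.individuals if gp.individuals else np.arange(n), L)
    loci = pd.concat([gp.loci] * n, ignore_index=True)
    flat = gp.probs.reshape(n * L, 3)
    out = pd.DataFrame(
        {
            "individual": ind,
            "locus": loci["locus"],
            "chrom": loci["chrom"],
            "cm": loci["cm"],
            "mb": loci["mb"],
            "p_aa": flat[:, 0],
            "p_ab": flat[:, 1],
            "p_bb": flat[:, 2],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_genoprobs(path) -> GenoProbs:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    individuals = list(dict.fromkeys(df["individual"]))
    loci = df.loc[df["individual"] == individuals[0], ["locus", "chrom", "cm", "mb"]].reset_index(
        drop=True
    )
    loci["is_marker"] = ~loci["locus"].str.contains(r"\.loc", regex=True)
    probs = df[["p_aa", "p_ab", "p_bb"]].to_numpy().reshape(len(individuals), len(loci), 3)
    return GenoProbs(probs, loci, individuals)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
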