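"""Core containers shared across the pipeline.

Conventions used everywhere in this package:

* Genotypes of an F2 individual are coded ``AA``/``AB``/``BB`` where the
  ``B`` allele is the GK allele; the allele dosage therefore counts GK
  alleles (AA=0, AB=1, BB=2).
* ``sex`` is coded 0 = male, 1 = female; ``cross`` is the reciprocal cross
  direction, 0 = BN grandmother, 1 = GK grandmother.
* Genetic positions are centimorgans (cM), physical positions megabases (Mb).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPE_CODES = ("AA", "AB", "BB")
_CODE_TO_DOSAGE = {"AA": 0, "AB": 1, "BB": 2}


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker map: one row per marker with genetic and physical position.

    ``markers`` columns: ``marker`` (unique name), ``chrom``, ``cm``, ``mb``.
    Within each chromosome both coordinate systems must be strictly
    increasing (so cM and Mb orders agree).
    """

    markers: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker", "chrom", "cm", "mb"}
        missing = required - set(self.markers.columns)
        if missing:
            raise ValueError(f"map is missing columns: {sorted(missing)}")
        if self.markers["marker"].duplicated().any():
            dups = self.markers.loc[self.markers["marker"].duplicated(), "marker"]
            raise ValueError(f"duplicated marker names: {sorted(set(dups))}")
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            cm = grp["cm"].to_numpy(float)
            mb = grp["mb"].to_numpy(float)
            if np.any(np.diff(cm) <= 0) or np.any(np.diff(mb) <= 0):
                raise ValueError(
                    f"marker positions on chromosome {chrom} must be strictly "
                    "increasing in both cM and Mb"
                )

    @property
    def chromosomes(self) -> list:
        """Chromosome names in order of first appearance."""
        return list(dict.fromkeys(self.markers["chrom"]))

    def chrom_markers(self, chrom) -> pd.DataFrame:
        sub = self.markers[self.markers["chrom"] == chrom]
        if sub.empty:
            raise KeyError(f"chromosome {chrom!r} not on the map")
        return sub

    def chrom_length_cm(self, chrom) -> float:
        return float(self.chrom_markers(chrom)["cm"].max())

    def interp_mb(self, chrom, cm) -> np.ndarray:
        """Physical position(s) at genetic position(s) by linear interpolation."""
        sub = self.chrom_markers(chrom)
        return np.interp(np.asarray(cm, float), sub["cm"].to_numpy(), sub["mb"].to_numpy())

    def interp_cm(self, chrom, mb) -> np.ndarray:
        sub = self.chrom_markers(chrom)
        return np.interp(np.asarray(mb, float), sub["mb"].to_numpy(), sub["cm"].to_numpy())

    def __len__(self) -> int:
        return len(self.markers)


@dataclass
class CrossData:
    """Observed F2 data: marker genotypes plus sex and cross-direction labels.

    ``genotypes``: individuals x markers DataFrame of ``AA``/``AB``/``BB``
    strings with ``NaN`` for missing calls. ``sex`` and ``cross`` are integer
    Series indexed like the genotype rows.
    """

    genotypes: pd.DataFrame
    sex: pd.Series
    cross: pd.Series

    def __post_init__(self) -> None:
        vals = set(pd.unique(self.genotypes.to_numpy().ravel()))
        bad = {v for v in vals if isinstance(v, str) and v not in GENOTYPE_CODES}
        if bad:
            raise ValueError(f"unknown genotype codes: {sorted(bad)}")
        for name, s in (("sex", self.sex), ("cross", self.cross)):
            if len(s) != len(self.genotypes):
                raise ValueError(f"{name} length does not match genotype rows")
            if not set(np.unique(s)).issubset({0, 1}):
                raise ValueError(f"{name} must be coded 0/1")

    @property
    def n_individuals(self) -> int:
        return len(self.genotypes)

    @property
    def individuals(self) -> list:
        return list(self.genotypes.index)

    def dosage(self) -> pd.DataFrame:
        """GK-allele dosage (0/1/2) with NaN for missing calls."""
        return self.genotypes.apply(lambda c: c.map(_CODE_TO_DOSAGE)).astype(float)

    def covariates(self) -> pd.DataFrame:
        """Standard additive covariates (cross direction and sex)."""
        return pd.DataFrame(
            {"cross": self.cross.to_numpy(int), "sex": self.sex.to_numpy(int)},
            index=self.genotypes.index,
        )

    def strata(self) -> np.ndarray:
        """Sex x cross-direction cell index per individual (0..3)."""
        return (2 * self.sex.to_numpy(int) + self.cross.to_numpy(int)).astype(int)


@dataclass
class GenoProbs:
    """Conditional genotype probabilities on a pseudomarker grid.

    ``probs`` has shape (n_individuals, n_loci, 3) in state order
    (AA, AB, BB). ``loci`` columns: ``locus``, ``chrom``, ``cm``, ``mb``,
    ``is_marker``.
    """

    probs: np.ndarray
    loci: pd.DataFrame
    individuals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, float)
        if self.probs.ndim != 3 or self.probs.shape[2] != 3:
            raise ValueError("probs must have shape (n_individuals, n_loci, 3)")
        if self.probs.shape[1] != len(self.loci):
            raise ValueError("loci table does not match probs")
        if np.any(self.probs < -1e-12):
            raise ValueError("negative genotype probabilities")
        sums = self.probs.sum(axis=2)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("genotype probabilities must sum to 1")

    @property
    def n_individuals(self) -> int:
        return self.probs.shape[0]

    @property
    def n_loci(self) -> int:
        return self.probs.shape[1]

    def additive_score(self) -> np.ndarray:
        """Expected GK-allele contrast a = P(BB) - P(AA), shape (n, L)."""
        return self.probs[:, :, 2] - self.probs[:, :, 0]

    def dominance_score(self) -> np.ndarray:
        """Heterozygote probability h = P(AB), shape (n, L)."""
        return self.probs[:, :, 1]

    def subset_loci(self, mask) -> "GenoProbs":
        mask = np.asarray(mask)
        return GenoProbs(
            self.probs[:, mask, :],
            self.loci.loc[mask].reset_index(drop=True),
            self.individuals,
        )
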