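"""Conditional genotype probabilities for an F2 intercross.

Observed framework-marker genotypes are expanded onto a pseudomarker grid by
a three-state hidden Markov model (states AA/AB/BB = 0/1/2 GK alleles).
Because the two gametes of an F2 individual are exchangeable, the genotype
process along a chromosome is itself Markov, with transition probabilities
determined by the recombination fraction between adjacent loci under the
Haldane map function (no crossover interference).  A forward-backward pass
per individual and chromosome yields P(true genotype | all markers on the
chromosome), allowing for a small genotyping-error rate and missing calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._types import CrossData, GeneticMap, GenoProbs

#: stationary F2 genotype distribution (Mendelian 1:2:1)
F2_PRIOR = np.array([0.25, 0.5, 0.25])

DEFAULT_ERROR_RATE = 0.002


def haldane_r(d_cm):
    """Recombination fraction for a genetic distance in cM (Haldane, no interference).

    r = (1 - exp(-2 d / 100)) / 2, which lies in [0, 0.5).
    """
    d = np.asarray(d_cm, float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return r if r.ndim else float(r)


def f2_transition_matrix(r) -> np.ndarray:
    """3x3 genotype transition matrix between two loci at recombination fraction r.

    Rows/columns ordered (AA, AB, BB); each meiosis recombines independently
    with probability r, so e.g. P(AA -> AA) = (1-r)^2.
    """
    r = float(r)
    if not 0.0 <= r <= 0.5:
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    s = 1.0 - r
    return np.array(
        [
            [s * s, 2 * r * s, r * r],
            [r * s, s * s + r * r, r * s],
            [r * r, 2 * r * s, s * s],
        ]
    )


def expand_grid(gmap: GeneticMap, step_cm: float) -> pd.DataFrame:
    """Pseudomarker grid: typed markers plus interpolated loci at <= step spacing.

    Between each pair of adjacent markers, the smallest number of equally
    spaced pseudomarkers is inserted so that no gap exceeds ``step_cm``.
    Pseudomarker Mb positions are linearly interpolated from the flanking
    markers.  Returns a table with columns locus/chrom/cm/mb/is_marker,
    ordered by chromosome then cM.
    """
    if step_cm <= 0:
        raise ValueError("grid step must be positive")
    rows = []
    for chrom in gmap.chromosomes:
        sub = gmap.chrom_markers(chrom)
        cm = sub["cm"].to_numpy(float)
        mb = sub["mb"].to_numpy(float)
        names = sub["marker"].tolist()
        for i in range(len(cm)):
            rows.append((names[i], chrom, cm[i], mb[i], True))
            if i + 1 < len(cm):
                gap = cm[i + 1] - cm[i]
                n_seg = int(np.ceil(gap / step_cm - 1e-9))
                for k in range(1, n_seg):
                    pos = cm[i] + gap * k / n_seg
                    rows.append(
                        (
                            f"c{chrom}.loc{pos:g}",
                            chrom,
                            pos,
                            float(np.interp(pos, cm, mb)),
                            False,
                        )
                    )
    grid = pd.DataFrame(rows, columns=["locus", "chrom", "cm", "mb", "is_marker"])
    return grid.sort_values(["chrom", "cm"], kind="mergesort", key=_chrom_sort_key(gmap)).reset_index(
        drop=True
    )


def _chrom_sort_key(gmap: GeneticMap):
    order = {c: i for i, c in enumerate(gmap.chromosomes)}

    def key(col: pd.Series):
        if col.name == "chrom":
            return col.map(order)
        return col

    return key


def forward_backward(
    obs: np.ndarray, rec_fracs: np.ndarray, error_rate: float = 0.0
) -> np.ndarray:
    """Posterior genotype probabilities along one chromosome.

    Parameters
    ----------
    obs : (n_individuals, n_loci) int array of observed dosages 0/1/2,
        with -1 for missing or untyped (pseudomarker) loci.
    rec_fracs : (n_loci - 1,) recombination fractions between adjacent loci.
    error_rate : probability that a typed genotype is mis-called; a wrong
        call is one of the two other genotypes with equal probability.

    Returns
    -------
    (n_individuals, n_loci, 3) posterior probabilities, state order AA/AB/BB.
    """
    obs = np.asarray(obs, int)
    n, m = obs.shape
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    if len(rec_fracs) != m - 1:
        raise ValueError("need one recombination fraction per marker interval")

    # emission[i, j, s] = P(observed obs[i,j] | true state s)
    emit = np.ones((n, m, 3))
    typed = obs >= 0
    if error_rate == 0.0:
        for s in range(3):
            emit[:, :, s] = np.where(typed, (obs == s).astype(float), 1.0)
    else:
        for s in range(3):
            emit[:, :, s] = np.where(
                typed, np.where(obs == s, 1.0 - error_rate, error_rate / 2.0), 1.0
            )

    trans = [f2_transition_matrix(r) for r in rec_fracs]

    alpha = np.empty((n, m, 3))
    scale = np.empty((n, m))
    alpha[:, 0] = F2_PRIOR * emit[:, 0]
    scale[:, 0] = alpha[:, 0].sum(axis=1)
    alpha[:, 0] /= scale[:, 0, None]
    for j in range(1, m):
        alpha[:, j] = (alpha[:, j - 1] @ trans[j - 1]) * emit[:, j]
        scale[:, j] = alpha[:, j].sum(axis=1)
        if np.any(scale[:, j] <= 0):
            raise ValueError("impossible genotype configuration (zero likelihood)")
        alpha[:, j] /= scale[:, j, None]

    beta = np.empty((n, m, 3))
    beta[:, m - 1] = 1.0
    for j in range(m - 2, -1, -1):
        beta[:, j] = (beta[:, j + 1] * emit[:, j + 1]) @ trans[j].T
        beta[:, j] /= beta[:, j].sum(axis=1, keepdims=True)

    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)
    return post


def genotype_probabilities(
    cross: CrossData,
    gmap: GeneticMap,
    step_cm: float = 2.5,
    error_rate: float = DEFAULT_ERROR_RATE,
) -> GenoProbs:
    """Impute genotype probabilities for every individual on the pseudomarker grid.

    Typed, non-missing markers with ``error_rate=0`` get degenerate
    probabilities at the observed genotype; fully missing individuals fall
    back to the F2 prior (1/4, 1/2, 1/4) everywhere.
    """
    known = set(gmap.markers["marker"])
    unknown = [m for m in cross.genotypes.columns if m not in known]
    if unknown:
        raise ValueError(f"markers absent from the map: {unknown}")

    grid = expand_grid(gmap, step_cm)
    dosage = cross.dosage()
    n = cross.n_individuals
    probs = np.empty((n, len(grid), 3))

    for chrom in gmap.chromosomes:
        mask = (grid["chrom"] == chrom).to_numpy()
        sub = grid.loc[mask]
        cm = sub["cm"].to_numpy(float)
        obs = np.full((n, len(sub)), -1, int)
        for j, (name, is_marker) in enumerate(zip(sub["locus"], sub["is_marker"])):
            if is_marker and name in dosage.columns:
                col = dosage[name].to_numpy()
                obs[:, j] = np.where(np.isnan(col), -1, col).astype(int)
        rec = haldane_r(np.diff(cm))
        probs[:, mask, :] = forward_backward(obs, np.atleast_1d(rec), error_rate)

    return GenoProbs(probs, grid, individuals=cross.individuals)
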