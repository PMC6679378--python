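"""Haley-Knott LOD, interaction LODf, permutations and FDR."""

import logging

import numpy as np
import pandas as pd
import pytest

from eqtlkit import GenoProbs
from eqtlkit.scan import (
    allele_effect,
    fdr_adjust,
    genome_scan,
    hk_lod,
    hk_lod_interactive,
    permutation_adjusted_p,
    scan_transcripts,
)


def _ols_lod(y, X0, X1):
    """Two-regression oracle via explicit normal equations."""
    def rss(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return float(r @ r)

    return len(y) / 2.0 * np.log10(rss(X0) / rss(X1))


def _degenerate_probs(dosage):
    """Fully typed marker: probability 1 on the observed genotype."""
    p = np.zeros((len(dosage), 3))
    p[np.arange(len(dosage)), dosage] = 1.0
    return p


@pytest.fixture()
def toy():
    rng = np.random.default_rng(7)
    n = 20
    dosage = rng.integers(0, 3, n)
    covs = pd.DataFrame({"cross": rng.integers(0, 2, n), "sex": rng.integers(0, 2, n)})
    y = 0.8 * (dosage - 1) + 0.3 * covs["sex"].to_numpy() + rng.normal(0, 1, n)
    return y, dosage, covs


class TestHkLod:
    def test_matches_two_regression_oracle(self, toy):
        y, dosage, covs = toy
        probs = _degenerate_probs(dosage)
        a, h = probs[:, 2] - probs[:, 0], probs[:, 1]
        X0 = np.column_stack([np.ones(len(y)), covs.to_numpy()])
        X1 = np.column_stack([X0, a, h])
        assert abs(hk_lod(y, probs, covs) - _ols_lod(y, X0, X1)) < 1e-10

    def test_constant_probabilities_give_zero(self, toy):
        y, _, covs = toy
        probs = np.tile([0.25, 0.5, 0.25], (len(y), 1))
        assert hk_lod(y, probs, covs) == pytest.approx(0.0, abs=1e-9)

    def test_perfect_fit_capped(self):
        rng = np.random.default_rng(3)
        probs = _degenerate_probs(rng.integers(0, 3, 30))
        y = probs[:, 2] - probs[:, 0]  # y identically the additive score
        assert hk_lod(y, probs) == 300.0

    def test_affine_invariance(self, toy):
        y, dosage, covs = toy
        probs = _degenerate_probs(dosage)
        base = hk_lod(y, probs, covs)
        assert hk_lod(3.5 * y - 11.0, probs, covs) == pytest.approx(base, abs=1e-9)

    def test_constant_phenotype_gives_zero(self, toy):
        _, dosage, covs = toy
        probs = _degenerate_probs(dosage)
        assert hk_lod(np.full(len(dosage), 4.2), probs, covs) == 0.0


class TestInteraction:
    def test_lodf_nonnegative_and_nested(self, rng):
        covs = pd.DataFrame({"cross": rng.integers(0, 2, 60), "sex": rng.integers(0, 2, 60)})
        for _ in range(20):
            probs = _degenerate_probs(rng.integers(0, 3, 60))
            y = rng.normal(size=60)
            lod_int, lodf = hk_lod_interactive(y, probs, covs, "sex")
            lod_add = hk_lod(y, probs, covs)
            assert lodf >= 0.0
            assert lod_int >= lod_add - 1e-9

    def test_null_interaction_lodf_near_zero(self, rng):
        # genes with no genotype x sex interaction: median LODf < 0.5
        covs = pd.DataFrame({"cross": rng.integers(0, 2, 123), "sex": rng.integers(0, 2, 123)})
        lodfs = []
        for _ in range(200):
            probs = _degenerate_probs(rng.integers(0, 3, 123))
            y = 0.5 * (probs[:, 2] - probs[:, 0]) + rng.normal(size=123)
            lodfs.append(hk_lod_interactive(y, probs, covs, "sex")[1])
        assert np.median(lodfs) < 0.5

    def test_pure_interaction_dominates_additive(self, rng):
        # b_g = 0, gs large, low noise: LODf >> LOD_add, and the
        # sex-stratified slopes confirm the effect is female-specific
        n = 200
        sex = np.repeat([0, 1], n // 2)
        covs = pd.DataFrame({"cross": rng.integers(0, 2, n), "sex": sex})
        dosage = rng.integers(0, 3, n)
        probs = _degenerate_probs(dosage)
        g = dosage - 1.0
        y = 2.0 * sex * g + rng.normal(0, 0.2, n)
        lod_int, lodf = hk_lod_interactive(y, probs, covs, "sex")
        lod_add = hk_lod(y, probs, covs)
        # with 0/1 sex coding the additive term absorbs the sex-averaged
        # slope, so LOD_add is substantial but LODf still dominates
        assert lodf > 3 * lod_add and lodf > 50
        slope_f = np.polyfit(g[sex == 1], y[sex == 1], 1)[0]
        slope_m = np.polyfit(g[sex == 0], y[sex == 0], 1)[0]
        assert slope_f == pytest.approx(2.0, abs=0.1)
        assert slope_m == pytest.approx(0.0, abs=0.1)


class TestGenomeScan:
    def test_single_locus_grid(self, rng):
        loci = pd.DataFrame(
            {"locus": ["m1"], "chrom": ["1"], "cm": [0.0], "mb": [0.0], "is_marker": [True]}
        )
        probs = _degenerate_probs(rng.integers(0, 3, 40))[:, None, :]
        gp = GenoProbs(probs, loci)
        res = genome_scan(rng.normal(size=40), gp)
        assert len(res.curve) == 1
        assert res.peak["locus"] == "m1"

    def test_null_transcript_curve_valid(self, genoprobs123, rng):
        res = genome_scan(rng.normal(size=123), genoprobs123)
        assert np.all(res.curve["lod"] >= 0)
        assert np.isfinite(res.peak["lod"])
        assert res.peak["lod"] == res.curve["lod"].max()

    def test_interactive_mode_nesting_along_genome(self, genoprobs123, cross123, rng):
        y = rng.normal(size=123)
        res = genome_scan(y, genoprobs123, cross123.covariates(), mode="sex_int")
        assert np.all(res.curve["lod_int"] >= res.curve["lod_add"] - 1e-9)
        assert np.all(res.curve["lodf"] >= 0)

    def test_unknown_mode_rejected(self, genoprobs123, rng):
        with pytest.raises(ValueError):
            genome_scan(rng.normal(size=123), genoprobs123, mode="dominance")


class TestPermutations:
    def test_strong_signal_minimal_p(self, genoprobs123, cross123):
        a = genoprobs123.additive_score()[:, 12]
        p, null_max = permutation_adjusted_p(
            a * 5.0, genoprobs123, cross123.covariates(),
            n_perm=200, seed=1, strata=cross123.strata(),
        )
        assert p == pytest.approx(1.0 / 201.0)
        assert len(null_max) == 200

    def test_constant_phenotype_p_one(self, genoprobs123):
        y = np.full(123, 2.0)
        p, _ = permutation_adjusted_p(y, genoprobs123, n_perm=100, seed=2)
        assert p == 1.0

    def test_too_few_permutations_rejected(self, genoprobs123, rng):
        with pytest.raises(ValueError):
            permutation_adjusted_p(rng.normal(size=123), genoprobs123, n_perm=5)

    def test_low_permutations_warn(self, genoprobs123, rng, caplog):
        with caplog.at_level(logging.WARNING):
            permutation_adjusted_p(rng.normal(size=123), genoprobs123, n_perm=50, seed=3)
        assert any("low" in r.message for r in caplog.records)


class TestFdr:
    def test_hand_computed_step_up(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal(self):
        assert np.allclose(fdr_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_single_p(self):
        assert fdr_adjust([0.031])[0] == pytest.approx(0.031)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(1e-6, 1.0, 50)
        q = fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.5], [np.nan, 0.5]])
    def test_invalid_p_rejected(self, bad):
        with pytest.raises(ValueError):
            fdr_adjust(bad)


class TestAlleleEffect:
    def test_null_effect_near_zero(self, rng):
        probs = _degenerate_probs(rng.integers(0, 3, 2000))
        y = rng.normal(size=2000)
        assert abs(allele_effect(y, probs)["er"]) < 0.15

    def test_additive_effect_doubles_per_genotype(self, rng):
        probs = _degenerate_probs(rng.integers(0, 3, 500))
        g = probs[:, 2] - probs[:, 0]
        y = 0.5 * g + rng.normal(0, 0.05, 500)
        eff = allele_effect(y, probs)
        assert eff["er"] == pytest.approx(1.0, abs=0.05)

    def test_er_antisymmetric_under_allele_swap(self, rng):
        probs = _degenerate_probs(rng.integers(0, 3, 300))
        y = 0.7 * (probs[:, 2] - probs[:, 0]) + rng.normal(0, 0.3, 300)
        er = allele_effect(y, probs)["er"]
        er_swapped = allele_effect(y, probs[:, ::-1])["er"]
        assert er_swapped == pytest.approx(-er, abs=1e-9)

    def test_absent_class_flagged(self, rng):
        dosage = rng.integers(0, 2, 100)  # no BB individuals
        probs = _degenerate_probs(dosage)
        eff = allele_effect(rng.normal(size=100), probs)
        assert eff["class_observed"]["GKGK"] is False
        assert eff["class_observed"]["BNBN"] is True


class TestScanTranscripts:
    def test_missing_phenotypes_dropped_per_transcript(self, genoprobs123, cross123):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(
            rng.normal(size=(3, 123)), index=["t1", "t2", "t3"], columns=cross123.individuals
        )
        expr.iloc[1, :10] = np.nan
        records, _ = scan_transcripts(
            expr, genoprobs123, cross123.covariates(), cross123.strata(),
            n_perm=100, seed=4,
        )
        assert records.set_index("transcript").loc["t1", "n_used"] == 123
        assert records.set_index("transcript").loc["t2", "n_used"] == 113

    def test_secondary_peaks_on_other_chromosomes(self, genoprobs123, cross123):
        # two independent strong loci on different chromosomes
        a = genoprobs123.additive_score()
        chroms = genoprobs123.loci["chrom"].to_numpy()
        i1 = np.nonzero(chroms == "1")[0][5]
        i2 = np.nonzero(chroms == "3")[0][5]
        rng = np.random.default_rng(6)
        y = 2.0 * a[:, i1] + 1.5 * a[:, i2] + rng.normal(0, 0.5, 123)
        expr = pd.DataFrame([y], index=["poly"], columns=cross123.individuals)
        records, secondary = scan_transcripts(
            expr, genoprobs123, cross123.covariates(), cross123.strata(),
            n_perm=200, seed=7,
        )
        assert records.at[0, "peak_chrom"] == "1"
        assert "3" in set(secondary["peak_chrom"])
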