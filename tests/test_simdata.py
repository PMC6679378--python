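"""Synthetic-cross generator: maps, meiosis, expression model, fixtures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eqtlkit import simulate_expression, simulate_f2_genotypes, simulate_map
from eqtlkit.genoprob import haldane_r
from eqtlkit.simdata import (
    GeneEffect,
    SimArchitecture,
    annotation_from_truth,
    inject_probe_artifacts,
    simulate_raw_intensities,
    standard_architecture,
)


class TestSimulateMap:
    @pytest.mark.parametrize(
        "lengths,spacing,expected_total",
        [([100.0], 2.5, 41), ([50.0, 50.0], 10.0, 12), ([100.0] * 5, 10.0, 55)],
    )
    def test_marker_counts(self, lengths, spacing, expected_total):
        gmap = simulate_map(lengths, spacing)
        assert len(gmap) == expected_total

    def test_two_chromosomes_evenly_split(self):
        gmap = simulate_map([50.0, 50.0], 10.0)
        per_chrom = gmap.markers.groupby("chrom").size()
        assert (per_chrom == 6).all()

    def test_physical_positions_scale_with_cm(self):
        gmap = simulate_map([20.0], 10.0, mb_per_cm=3.0)
        assert list(gmap.markers["mb"]) == [0.0, 30.0, 60.0]

    @pytest.mark.parametrize("bad", [0.0, -2.5])
    def test_invalid_spacing_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_map([100.0], bad)

    def test_invalid_length_rejected(self):
        with pytest.raises(ValueError):
            simulate_map([0.0], 2.5)


class TestSimulateGenotypes:
    def test_mendelian_segregation(self):
        gmap = simulate_map([1.0], 2.5)  # single marker
        arch = SimArchitecture(n_individuals=10_000, seed=7)
        cross = simulate_f2_genotypes(gmap, arch)
        counts = cross.genotypes.iloc[:, 0].value_counts()
        observed = [counts.get(g, 0) for g in ("AA", "AB", "BB")]
        p = stats.chisquare(observed, f_exp=[2500, 5000, 2500]).pvalue
        assert p > 0.001

    def test_tightly_linked_markers_identical(self):
        gmap = simulate_map([1e-6], 1e-6)  # two markers, vanishing distance
        assert len(gmap) == 2
        cross = simulate_f2_genotypes(gmap, SimArchitecture(n_individuals=500, seed=1))
        g = cross.genotypes
        assert (g.iloc[:, 0] == g.iloc[:, 1]).all()

    def test_recombination_matches_haldane(self):
        # count recombinant gametes between markers 10 cM apart
        gmap = simulate_map([10.0], 10.0)
        arch = SimArchitecture(n_individuals=20_000, seed=11)
        _, gametes = simulate_f2_genotypes(gmap, arch, return_gametes=True)
        g1, g2 = gametes["1"]
        switches = np.concatenate([g1[:, 0] != g1[:, 1], g2[:, 0] != g2[:, 1]])
        r_hat = switches.mean()
        r_true = haldane_r(10.0)
        se = np.sqrt(r_true * (1 - r_true) / len(switches))
        assert abs(r_hat - r_true) < 3 * se

    def test_labels_follow_fractions(self, gmap5):
        arch = SimArchitecture(n_individuals=123, seed=3)
        cross = simulate_f2_genotypes(gmap5, arch)
        assert cross.sex.sum() == 63  # females
        assert cross.cross.sum() == 55  # GK-grandmother lineage

    def test_deterministic_under_seed(self, gmap5):
        arch = SimArchitecture(n_individuals=40, seed=5)
        a = simulate_f2_genotypes(gmap5, arch)
        b = simulate_f2_genotypes(gmap5, arch)
        pd.testing.assert_frame_equal(a.genotypes, b.genotypes)
        assert (a.sex == b.sex).all() and (a.cross == b.cross).all()

    def test_missing_rate_applied(self, gmap5):
        arch = SimArchitecture(n_individuals=200, missing_rate=0.1, seed=5)
        cross = simulate_f2_genotypes(gmap5, arch)
        frac = cross.genotypes.isna().to_numpy().mean()
        assert 0.05 < frac < 0.15

    def test_invalid_architecture_rejected(self, gmap5):
        with pytest.raises(ValueError):
            simulate_f2_genotypes(gmap5, SimArchitecture(n_individuals=0))
        with pytest.raises(ValueError):
            simulate_f2_genotypes(gmap5, SimArchitecture(female_fraction=1.5))


class TestSimulateExpression:
    def test_null_gene_uncorrelated_with_genotype(self, gmap5):
        arch = SimArchitecture(
            n_individuals=2000, genes=[GeneEffect(gene="nullg")], seed=9
        )
        cross = simulate_f2_genotypes(gmap5, arch)
        expr, truth = simulate_expression(cross, gmap5, arch)
        y = expr.loc["nullg"].to_numpy()
        dos = cross.dosage().iloc[:, 0].to_numpy()
        r = np.corrcoef(y, dos)[0, 1]
        assert abs(r) < 0.08
        assert not truth.loc["nullg", "has_eqtl"]

    def test_group_means_step_by_one_per_allele(self, gmap5):
        # additive effect 1 with vanishing noise: exactly one unit per dosage step
        gene = GeneEffect(gene="g", chrom="1", pos_cm=50.0, additive=1.0, residual_sd=1e-9)
        arch = SimArchitecture(n_individuals=300, genes=[gene], seed=13)
        cross = simulate_f2_genotypes(gmap5, arch)
        expr, _ = simulate_expression(cross, gmap5, arch)
        y = pd.Series(expr.loc["g"].to_numpy(), index=cross.individuals)
        dos = cross.dosage()["c1m6"]  # marker at 50 cM on chromosome 1
        resid = y - cross.cross * 0.0
        means = resid.groupby(dos).mean()
        assert means[1.0] - means[0.0] == pytest.approx(1.0, abs=1e-6)
        assert means[2.0] - means[1.0] == pytest.approx(1.0, abs=1e-6)

    def test_sex_interaction_recovered_by_stratified_ols(self, gmap5):
        gene = GeneEffect(
            gene="g", chrom="2", pos_cm=50.0, sex_interaction=2.0, residual_sd=0.1
        )
        arch = SimArchitecture(n_individuals=1000, genes=[gene], seed=17)
        cross = simulate_f2_genotypes(gmap5, arch)
        expr, _ = simulate_expression(cross, gmap5, arch)
        y = expr.loc["g"].to_numpy()
        g = cross.dosage()["c2m6"].to_numpy() - 1.0
        sex = cross.sex.to_numpy()
        slope_f = np.polyfit(g[sex == 1], y[sex == 1], 1)[0]
        slope_m = np.polyfit(g[sex == 0], y[sex == 0], 1)[0]
        assert slope_f == pytest.approx(2.0, abs=0.1)
        assert slope_m == pytest.approx(0.0, abs=0.1)

    def test_truth_effects_refit_by_ols(self, gmap5):
        # at vanishing residual sd the design coefficients are recovered exactly
        gene = GeneEffect(
            gene="g", chrom="1", pos_cm=30.0, additive=0.8, sex_main=0.4,
            cross_main=-0.3, baseline=7.0, residual_sd=1e-8,
        )
        arch = SimArchitecture(n_individuals=200, genes=[gene], seed=19)
        cross = simulate_f2_genotypes(gmap5, arch)
        expr, _ = simulate_expression(cross, gmap5, arch)
        y = expr.loc["g"].to_numpy()
        g = cross.dosage()["c1m4"].to_numpy() - 1.0  # marker at 30 cM
        X = np.column_stack(
            [np.ones(len(y)), cross.cross.to_numpy(), cross.sex.to_numpy(), g]
        )
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(beta, [7.0, -0.3, 0.4, 0.8], atol=1e-5)

    def test_off_map_effect_locus_rejected(self, gmap5):
        gene = GeneEffect(gene="g", chrom="1", pos_cm=150.0)
        arch = SimArchitecture(n_individuals=10, genes=[gene], seed=1)
        with pytest.raises(ValueError, match="off"):
            simulate_f2_genotypes(gmap5, arch)

    def test_deterministic_and_subset_stable(self, gmap5):
        arch = standard_architecture(gmap5, n_null=3, n_cis=2, seed=23)
        cross = simulate_f2_genotypes(gmap5, arch)
        e1, t1 = simulate_expression(cross, gmap5, arch)
        e2, _ = simulate_expression(cross, gmap5, arch)
        pd.testing.assert_frame_equal(e1, e2)
        assert len(t1) == 5


class TestProbeArtifacts:
    @pytest.fixture()
    def fixture(self, gmap5):
        arch = standard_architecture(gmap5, n_null=4, seed=29)
        cross = simulate_f2_genotypes(gmap5, arch)
        expr, truth = simulate_expression(cross, gmap5, arch)
        return cross, expr, annotation_from_truth(truth)

    def test_attenuation_one_is_identity(self, fixture, gmap5):
        cross, expr, ann = fixture
        out = inject_probe_artifacts(expr, ["null0001"], 1.0, cross, gmap5, ann)
        pd.testing.assert_frame_equal(out, expr)

    def test_empty_list_is_identity(self, fixture, gmap5):
        cross, expr, ann = fixture
        out = inject_probe_artifacts(expr, [], 0.5, cross, gmap5, ann)
        pd.testing.assert_frame_equal(out, expr)

    def test_unknown_gene_rejected(self, fixture, gmap5):
        cross, expr, ann = fixture
        with pytest.raises(KeyError, match="nosuch"):
            inject_probe_artifacts(expr, ["nosuch"], 0.5, cross, gmap5, ann)

    def test_artifact_creates_spurious_cis_signal(self, fixture, gmap5):
        from eqtlkit.genoprob import genotype_probabilities
        from eqtlkit.scan import genome_scan

        cross, expr, ann = fixture
        out = inject_probe_artifacts(expr, ["null0001"], 0.5, cross, gmap5, ann)
        gp = genotype_probabilities(cross, gmap5, step_cm=10.0, error_rate=0.0)
        res = genome_scan(out.loc["null0001"].to_numpy(), gp, cross.covariates())
        own_chrom = ann.set_index("gene").at["null0001", "chrom"]
        assert res.peak["chrom"] == own_chrom
        assert res.peak["lod"] > 5.0


class TestRawIntensities:
    def test_pure_background_mean(self):
        expr = pd.DataFrame(np.zeros((100, 50)))
        raw, _ = simulate_raw_intensities(expr, 100.0, 10.0, 1e-9, seed=1)
        assert raw.to_numpy().mean() == pytest.approx(100.0, abs=0.5)

    def test_detection_scores_uniform_for_background(self):
        expr = pd.DataFrame(np.zeros((200, 50)))
        _, det = simulate_raw_intensities(expr, 100.0, 10.0, 1e-9, seed=2)
        p = stats.kstest(det.to_numpy().ravel(), "uniform").pvalue
        assert p > 0.001

    def test_signal_raises_detection(self):
        expr = pd.DataFrame(np.full((50, 20), 200.0))
        _, det = simulate_raw_intensities(expr, 100.0, 10.0, 1e-9, seed=3)
        assert (det.to_numpy() > 0.99).mean() > 0.99

    @pytest.mark.parametrize("bg_sd,scale", [(0.0, 50.0), (10.0, 0.0), (-1.0, 50.0)])
    def test_invalid_parameters_rejected(self, bg_sd, scale):
        expr = pd.DataFrame(np.zeros((10, 10)))
        with pytest.raises(ValueError):
            simulate_raw_intensities(expr, 100.0, bg_sd, scale, seed=1)
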