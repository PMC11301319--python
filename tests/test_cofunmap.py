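"""The composite functional-mapping likelihood, LR scan and permutation test."""

import numpy as np
import pytest

from plastiqtl.cofunmap import (
    ScanConfig,
    fit_alternative,
    fit_null,
    gaussian_loglik,
    lr_statistic,
    permutation_threshold,
    quantile_threshold,
    scan,
)
from plastiqtl.growth import LogisticParams, TimeGrid, logistic_mean
from plastiqtl.plasticity import PlasticityTrait, compute_plasticity
from plastiqtl.sad import SAD1Params, sad1_covariance

from conftest import planted_qtl


def _synthetic_trait(n=60, seed=0, shift_codes=None, shift_size=0.0):
    """Trait from paired environment panels with known generating curves."""
    rng = np.random.default_rng(seed)
    t = np.arange(1, 9.0)
    fx = logistic_mean(t, LogisticParams(17.0, 10.0, 0.7))
    fy = logistic_mean(t, LogisticParams(10.0, 8.0, 0.9))
    cx = sad1_covariance(SAD1Params(0.7, 0.05), 8)
    cy = sad1_covariance(SAD1Params(0.6, 0.04), 8)
    X = fx + rng.multivariate_normal(np.zeros(8), cx, size=n)
    Y = fy + rng.multivariate_normal(np.zeros(8), cy, size=n)
    if shift_codes is not None:
        direction = np.where(shift_codes == 0, 1.0, -1.0)[:, None]
        X = X + shift_size / 2 * direction * (t / 8)[None, :]
    Z = X - Y
    rils = [f"R{i}" for i in range(n)]
    return PlasticityTrait("pWPP", "L", "H", rils, Z, x_values=X, y_values=Y), (fx, fy, cx + cy)


class TestLRStatistic:
    def test_definition(self):
        assert lr_statistic(-10.0, -10.0) == 0.0
        assert lr_statistic(-10.0, -7.0) == pytest.approx(6.0)

    def test_negative_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            assert lr_statistic(-5.0, -5.1) == 0.0


class TestQuantileThreshold:
    def test_degenerate_maxima(self):
        assert quantile_threshold(np.full(100, 3.7), 0.05) == 3.7

    def test_monotone_in_alpha(self):
        maxima = np.random.default_rng(0).exponential(size=100)
        assert quantile_threshold(maxima, 0.01) >= quantile_threshold(maxima, 0.05)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ScanConfig(n_perm=10)
        with pytest.raises(ValueError):
            ScanConfig(alpha=0.0)
        with pytest.raises(ValueError):
            ScanConfig(alpha=0.01, n_perm=50)  # 0.99 quantile needs more maxima


class TestFitNull:
    def test_recovers_generating_curve_and_beats_truth_loglik(self, grid8):
        trait, (fx, fy, sigma) = _synthetic_trait(n=100, seed=42)
        fit = fit_null(trait, grid8)
        np.testing.assert_allclose(fit.mean_curve(grid8), fx - fy, atol=0.15)
        ll_truth = gaussian_loglik(trait.values, fx - fy, sigma)
        assert fit.loglik >= ll_truth - 1e-6

    def test_loglik_matches_dense_gaussian_evaluation(self, grid8):
        # the engine evaluates the likelihood through sufficient statistics;
        # a direct per-row Gaussian computation is the independent oracle
        trait, _ = _synthetic_trait(n=40, seed=3)
        fit = fit_null(trait, grid8)
        dense = gaussian_loglik(trait.values, fit.mean_curve(grid8), fit.covariance.matrix)
        assert fit.loglik == pytest.approx(dense, abs=1e-6)

    def test_duplicating_rils_doubles_loglik(self, grid8):
        trait, _ = _synthetic_trait(n=30, seed=7)
        doubled = PlasticityTrait(
            "pWPP", "L", "H",
            trait.ril_ids + [f"{r}b" for r in trait.ril_ids],
            np.vstack([trait.values] * 2),
            x_values=np.vstack([trait.x_values] * 2),
            y_values=np.vstack([trait.y_values] * 2),
        )
        f1 = fit_null(trait, grid8)
        f2 = fit_null(doubled, grid8)
        assert f2.loglik == pytest.approx(2 * f1.loglik, rel=1e-9)

    def test_optimality_spot_check(self, grid8):
        trait, _ = _synthetic_trait(n=40, seed=9)
        fit = fit_null(trait, grid8)
        worse_mean = fit.mean_curve(grid8) + 0.3
        assert fit.loglik >= gaussian_loglik(
            trait.values, worse_mean, fit.covariance.matrix
        )
        worse_cov = fit.covariance.matrix * 1.4
        assert fit.loglik >= gaussian_loglik(
            trait.values, fit.mean_curve(grid8), worse_cov
        )


class TestFitAlternative:
    def test_single_class_collapses_to_null(self, grid8):
        trait, _ = _synthetic_trait(n=30, seed=1)
        model, l1 = fit_alternative(trait, np.zeros(30, dtype=int), grid8)
        null = fit_null(trait, grid8)
        assert l1 == pytest.approx(null.loglik, abs=1e-9)
        assert model.J == 1

    def test_small_classes_are_dropped(self, grid8):
        trait, _ = _synthetic_trait(n=30, seed=1)
        codes = np.zeros(30, dtype=int)
        codes[:3] = 2  # below n_min
        model, _ = fit_alternative(trait, codes, grid8)
        assert [c.code for c in model.classes] == [0]

    def test_joint_permutation_invariance(self, grid8):
        trait, _ = _synthetic_trait(n=40, seed=5)
        codes = (np.arange(40) % 2) * 2
        _, l1 = fit_alternative(trait, codes, grid8)
        perm = np.random.default_rng(0).permutation(40)
        permuted = PlasticityTrait(
            "pWPP", "L", "H",
            [trait.ril_ids[i] for i in perm],
            trait.values[perm],
            x_values=trait.x_values[perm],
            y_values=trait.y_values[perm],
        )
        _, l1p = fit_alternative(permuted, codes[perm], grid8)
        assert l1p == pytest.approx(l1, abs=1e-8)

    def test_recovers_planted_class_gap(self, grid8):
        codes = (np.arange(100) % 2) * 2
        trait, _ = _synthetic_trait(n=100, seed=11, shift_codes=codes, shift_size=8.0)
        model, _ = fit_alternative(trait, codes, grid8)
        by = {c.code: c for c in model.classes}
        gap = by[0].mean_curve(grid8)[-1] - by[2].mean_curve(grid8)[-1]
        assert gap == pytest.approx(8.0, rel=0.15)


@pytest.fixture(scope="module")
def planted_scan(small_genotypes, planted_experiment, grid8):
    trait = compute_plasticity("pWPP", planted_experiment.panels)
    cfg = ScanConfig(alpha=0.05, n_perm=40, seed=17)
    return scan(trait, small_genotypes, grid8, cfg)


class TestScan:
    def test_planted_qtl_detected(self, planted_scan):
        row = planted_scan.table.iloc[10]
        assert row["significant"]
        assert row["LR"] == planted_scan.table["LR"].max()

    def test_empirical_p_consistent_with_threshold(self, planted_scan):
        tab = planted_scan.table[planted_scan.table["usable"]]
        above = tab[tab["LR"] >= planted_scan.threshold.threshold]
        assert (above["p_emp"] <= planted_scan.threshold.alpha + 1e-12).all()

    def test_null_lr_distribution_below_planted(self, planted_scan):
        # SNPs on the chromosome without the QTL act as the null reference
        tab = planted_scan.table
        null_lrs = tab[tab["chrom"] == "chr2"]["LR"].to_numpy()
        assert tab.iloc[10]["LR"] > np.quantile(null_lrs, 0.95)

    def test_deterministic_given_seed(self, small_genotypes, planted_experiment, grid8, planted_scan):
        trait = compute_plasticity("pWPP", planted_experiment.panels)
        again = scan(trait, small_genotypes, grid8, ScanConfig(alpha=0.05, n_perm=40, seed=17))
        assert again.table.equals(planted_scan.table)
        np.testing.assert_array_equal(
            again.threshold.maxima, planted_scan.threshold.maxima
        )

    def test_duplicated_snp_has_identical_lr(self, planted_experiment, small_genotypes, grid8):
        import copy

        trait = compute_plasticity("pWPP", planted_experiment.panels)
        geno = copy.deepcopy(small_genotypes)
        geno.codes = np.vstack([geno.codes, geno.codes[10][None, :]])
        geno.chrom = np.append(geno.chrom, "chr2")
        geno.pos = np.append(geno.pos, 999.0)
        result = scan(trait, geno, grid8, ScanConfig(alpha=0.05, n_perm=25, seed=2))
        assert result.table.iloc[-1]["LR"] == result.table.iloc[10]["LR"]

    def test_empty_ril_intersection_rejected(self, small_genotypes, grid8):
        trait, _ = _synthetic_trait(n=20, seed=0)  # ids R0.. not RILxxx
        with pytest.raises(ValueError, match="no RILs shared"):
            scan(trait, small_genotypes, grid8, ScanConfig(n_perm=20))


class TestPermutationThreshold:
    def test_requires_enough_permutations(self, small_genotypes, planted_experiment, grid8):
        trait = compute_plasticity("pWPP", planted_experiment.panels)
        with pytest.raises(ValueError):
            permutation_threshold(trait, small_genotypes, grid8, n_perm=10)

    def test_threshold_is_quantile_of_maxima(self, small_genotypes, null_experiment, grid8):
        trait = compute_plasticity("pWPP", null_experiment.panels)
        rec = permutation_threshold(
            trait, small_genotypes, grid8, n_perm=25, alpha=0.2, seed=5
        )
        assert rec.threshold == quantile_threshold(rec.maxima, 0.2)
        assert rec.maxima.shape == (25,)
        assert (rec.maxima >= 0).all()
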