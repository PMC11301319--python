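"""Replicate averaging, contrast algebra and significance summaries."""

import numpy as np
import pandas as pd
import pytest

from plastiqtl.growth import LogisticParams, logistic_mean
from plastiqtl.plasticity import (
    CONTRASTS,
    PlasticityTrait,
    TrajectoryPanel,
    _compact_letters,
    asymptotic_summary,
    average_replicates,
    compute_plasticity,
    test_contrasts as contrast_tests,
)


def _long_row(ril, treatment, rep, week, value):
    return {
        "ril_id": ril,
        "treatment": treatment,
        "replicate": rep,
        "week": week,
        "leaf_number": value,
    }


class TestAverageReplicates:
    def test_arithmetic_mean_and_missing_handling(self, grid8):
        rows = []
        for wk in range(1, 9):
            rows += [
                _long_row("r1", "H", 1, wk, 4.0),
                _long_row("r1", "H", 2, wk, 6.0),
                _long_row("r1", "H", 3, wk, np.nan),
                _long_row("r2", "H", 1, wk, 3.0),
            ]
        panels = average_replicates(pd.DataFrame(rows), grid8)
        p = panels["H"]
        assert p.values[p.ril_ids.index("r1")].tolist() == [5.0] * 8
        assert p.values[p.ril_ids.index("r2")].tolist() == [3.0] * 8

    def test_ril_dropped_when_a_week_has_no_observations(self, grid8):
        rows = [
            _long_row("r1", "H", 1, wk, 2.0) for wk in range(1, 9)
        ] + [
            _long_row("r2", "H", 1, wk, 2.0) for wk in range(1, 8)  # week 8 absent
        ]
        panels = average_replicates(pd.DataFrame(rows), grid8)
        assert panels["H"].ril_ids == ["r1"]

    def test_malformed_week_rejected(self, grid8):
        rows = [_long_row("r1", "H", 1, 99, 2.0)]
        with pytest.raises(ValueError):
            average_replicates(pd.DataFrame(rows), grid8)


class TestComputePlasticity:
    def _panels(self, x, y):
        rils = [f"r{i}" for i in range(len(x))]
        return {
            "L": TrajectoryPanel("L", rils, np.asarray(x, float)),
            "H": TrajectoryPanel("H", rils, np.asarray(y, float)),
        }

    def test_componentwise_difference(self):
        panels = self._panels([[3, 5, 8], [4, 6, 9]], [[1, 2, 3], [1, 1, 1]])
        trait = compute_plasticity("pWPP", panels)
        assert trait.values.tolist() == [[2.0, 3.0, 5.0], [3.0, 5.0, 8.0]]
        assert (trait.minuend, trait.subtrahend) == ("L", "H")

    def test_identical_panels_give_zero(self):
        panels = self._panels([[4, 5, 6]] * 3, [[4, 5, 6]] * 3)
        assert np.all(compute_plasticity("pWPP", panels).values == 0)

    def test_antisymmetry_under_role_swap(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(5, 1, (4, 8)), rng.normal(5, 1, (4, 8))
        rils = list("abcd")
        panels = {
            "LL": TrajectoryPanel("LL", rils, x),
            "L": TrajectoryPanel("L", rils, y),
            "HH": TrajectoryPanel("HH", rils, y),
            "H": TrajectoryPanel("H", rils, x),
        }
        # TPP_L = LL - L and TPP_H = HH - H use swapped matrices here
        t1 = compute_plasticity("TPP_L", panels)
        t2 = compute_plasticity("TPP_H", panels)
        np.testing.assert_allclose(t1.values, -t2.values)

    def test_restricted_to_shared_rils(self):
        panels = {
            "L": TrajectoryPanel("L", ["a", "b", "c"], np.ones((3, 4))),
            "H": TrajectoryPanel("H", ["b", "c", "d"], np.zeros((3, 4))),
        }
        trait = compute_plasticity("pWPP", panels)
        assert trait.ril_ids == ["b", "c"]

    def test_errors(self):
        panels = self._panels([[1, 2, 3]] * 2, [[1, 2, 3]] * 2)
        with pytest.raises(ValueError):
            compute_plasticity("nope", panels)
        with pytest.raises(ValueError):
            compute_plasticity("TPP_H", panels)  # HH panel absent
        disjoint = {
            "L": TrajectoryPanel("L", ["a", "x"], np.ones((2, 3))),
            "H": TrajectoryPanel("H", ["b", "y"], np.ones((2, 3))),
        }
        with pytest.raises(ValueError):
            compute_plasticity("pWPP", disjoint)


def _simulated_panels(seed=0, n=12):
    """Six consistent panels with arbitrary smooth trajectories."""
    rng = np.random.default_rng(seed)
    rils = [f"r{i}" for i in range(n)]
    return {
        tr: TrajectoryPanel(
            tr, rils, np.cumsum(rng.uniform(0.3, 1.5, (n, 8)), axis=1)
        )
        for tr in ("H", "L", "HH", "HL", "LH", "LL")
    }


class TestContrastAlgebra:
    def test_telescoping_identities_exact(self):
        panels = _simulated_panels()
        t = {name: compute_plasticity(name, panels).values for name in CONTRASTS}
        # TPP_L - TPP_H = MPP_L + oWPP_H - pWPP  (expand and telescope);
        # equality holds to machine precision (the float op order differs)
        np.testing.assert_allclose(
            t["TPP_L"] - t["TPP_H"], t["MPP_L"] + t["oWPP_H"] - t["pWPP"],
            rtol=0, atol=1e-12,
        )
        # MPP_L + oWPP_H = LL - HH
        np.testing.assert_allclose(
            t["MPP_L"] + t["oWPP_H"],
            panels["LL"].values - panels["HH"].values,
            rtol=0, atol=1e-12,
        )


class TestAsymptoticSummary:
    def test_exact_logistic_panel(self, grid8):
        y = logistic_mean(grid8.values, LogisticParams(14.0, 6.0, 0.8))
        panel = TrajectoryPanel("H", list("abc"), np.tile(y, (3, 1)))
        out = asymptotic_summary({"H": panel}, grid8)
        assert out.loc[0, "mean_asymptote"] == pytest.approx(14.0, rel=1e-5)
        assert out.loc[0, "se"] == pytest.approx(0.0, abs=1e-5)

    def test_textbook_standard_error(self, grid8):
        rows = [
            logistic_mean(grid8.values, LogisticParams(a, 6.0, 0.8))
            for a in (10.0, 12.0, 14.0)
        ]
        panel = TrajectoryPanel("L", list("abc"), np.stack(rows))
        out = asymptotic_summary({"L": panel}, grid8)
        assert out.loc[0, "mean_asymptote"] == pytest.approx(12.0, rel=1e-5)
        assert out.loc[0, "se"] == pytest.approx(2.0 / np.sqrt(3), rel=1e-4)

    def test_fallback_uses_final_week(self, grid8, monkeypatch):
        import plastiqtl.plasticity as mod

        def always_fail(y, grid):
            raise RuntimeError("forced failure")

        monkeypatch.setattr(mod, "fit_logistic", always_fail)
        panel = TrajectoryPanel("H", ["a"], np.arange(8.0)[None, :] + 1)
        out = asymptotic_summary({"H": panel}, grid8)
        assert out.loc[0, "mean_asymptote"] == 8.0
        assert out.loc[0, "n_fallback"] == 1


def _trait_from_asymptotes(name, ax, ay, grid):
    """Trait whose per-RIL trajectories are exact logistic curves."""
    minu, subt = CONTRASTS[name]
    x = np.stack([logistic_mean(grid.values, LogisticParams(a, 6.0, 0.8)) for a in ax])
    y = np.stack([logistic_mean(grid.values, LogisticParams(a, 6.0, 0.8)) for a in ay])
    rils = [f"r{i}" for i in range(len(ax))]
    return PlasticityTrait(name, minu, subt, rils, x - y, x_values=x, y_values=y)


class TestTestContrasts:
    def test_identical_contrasts_not_separated(self, grid8):
        rng = np.random.default_rng(5)
        ax = rng.uniform(10, 14, 10)
        ay = rng.uniform(8, 10, 10)
        traits = {
            "TPP_H": _trait_from_asymptotes("TPP_H", ax, ay, grid8),
            "TPP_L": _trait_from_asymptotes("TPP_L", ax, ay, grid8),
        }
        out = contrast_tests(traits, grid8, comparisons=[("TPP_H", "TPP_L")])
        pair = out[out["test"] == "pairwise"].iloc[0]
        assert pair["p_raw"] == pytest.approx(1.0)
        letters = out[out["test"] == "one_sample"]["letter"]
        assert letters.iloc[0] == letters.iloc[1]

    def test_type_one_error_of_null_contrast(self, grid8):
        # per-RIL plasticity drawn around zero: the one-sample test should
        # reject at roughly its nominal 5% level
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 30
        for _ in range(n_rep):
            ax = 12.0 + rng.normal(0, 0.8, 25)
            ay = 12.0 + rng.normal(0, 0.8, 25)
            traits = {"pWPP": _trait_from_asymptotes("pWPP", ax, ay, grid8)}
            out = contrast_tests(traits, grid8, comparisons=[])
            rejections += out.loc[0, "p_raw"] < 0.05
        assert rejections <= 6  # Bin(30, 0.05): P(X > 6) < 1e-3

    def test_separated_contrasts_detected(self, grid8):
        # planted difference 3 leaves vs within-group sd ~0.7: power ~ 1
        rng = np.random.default_rng(13)
        traits = {
            "oWPP_L": _trait_from_asymptotes(
                "oWPP_L", 16 + rng.normal(0, 0.5, 30), 12 + rng.normal(0, 0.5, 30), grid8
            ),
            "oWPP_H": _trait_from_asymptotes(
                "oWPP_H", 13 + rng.normal(0, 0.5, 30), 12 + rng.normal(0, 0.5, 30), grid8
            ),
        }
        out = contrast_tests(traits, grid8, comparisons=[("oWPP_L", "oWPP_H")])
        pair = out[out["test"] == "pairwise"].iloc[0]
        assert pair["p_adj"] < 0.05
        letters = out[out["test"] == "one_sample"]["letter"]
        assert letters.iloc[0] != letters.iloc[1]

    def test_zero_variance_handling(self, grid8):
        traits = {"pWPP": _trait_from_asymptotes("pWPP", [12.0] * 5, [10.0] * 5, grid8)}
        out = contrast_tests(traits, grid8, comparisons=[])
        # equal constant values, nonzero mean: flagged as certain difference
        assert out.loc[0, "p_raw"] == 0.0


def test_compact_letters_partition():
    sig = np.array(
        [
            [False, True, True],
            [True, False, False],
            [True, False, False],
        ]
    )
    letters = _compact_letters(["a", "b", "c"], sig)
    assert letters["b"] == letters["c"]
    assert set(letters["a"]) & set(letters["b"]) == set()
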