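"""Relative fitness, origin regressions, AICc selection, threshold sweep."""

import numpy as np
import pandas as pd
import pytest

from maprove.interchange import GrowthTable
from maprove.models import (
    ModelError,
    ModelFit,
    aicc,
    default_grid,
    environment_interaction_pretest,
    fit_origin_lm,
    fit_origin_mixed,
    icc_and_variance,
    model_selection_table,
    relative_fitness,
    threshold_sweep,
)


def growth_frame(rows):
    return GrowthTable(pd.DataFrame(rows, columns=[
        "line_id", "role", "ancestor_id", "environment", "block", "replicate",
        "growth_rate"]))


class TestRelativeFitness:
    def test_identical_to_control_is_zero(self):
        g = growth_frame([
            ("L1", "ma", "a", "e", "b1", 1, 1.0),
            ("L1", "ma", "a", "e", "b1", 2, 1.0),
            ("c", "control", "a", "e", "b1", 1, 1.0),
            ("c", "control", "a", "e", "b1", 2, 1.0),
        ])
        out = relative_fitness(g)
        assert out.loc[0, "relative_fitness"] == pytest.approx(0.0, abs=1e-12)

    def test_block_offset_invariance(self, rng):
        rows = []
        for b in ("b1", "b2"):
            for r in range(4):
                rows.append(("L1", "ma", "a", "e", b, r, 1.0 + rng.normal(0, 0.1)))
                rows.append(("c", "control", "a", "e", b, r, 1.0 + rng.normal(0, 0.1)))
        base = relative_fitness(growth_frame(rows))
        shifted_rows = [
            (l, role, a, e, b, r, v + (0.7 if b == "b2" else 0.0))
            for (l, role, a, e, b, r, v) in rows
        ]
        shifted = relative_fitness(growth_frame(shifted_rows))
        assert shifted.loc[0, "relative_fitness"] == pytest.approx(
            base.loc[0, "relative_fitness"], abs=1e-12)

    def test_single_measurement_per_line(self):
        g = growth_frame([
            ("L1", "ma", "a", "e", "b1", 1, 0.8),
            ("c", "control", "a", "e", "b1", 1, 1.0),
            ("c", "control", "a", "e", "b1", 2, 1.2),
        ])
        out = relative_fitness(g)
        assert out.loc[0, "relative_fitness"] == pytest.approx(0.8 - 1.1, abs=1e-12)

    def test_absolute_mode(self):
        g = growth_frame([
            ("L1", "ma", "a", "e", "b1", 1, 0.8),
            ("c", "control", "a", "e", "b1", 1, 1.0),
        ])
        out = relative_fitness(g, response_mode="absolute")
        assert out.loc[0, "relative_fitness"] == pytest.approx(0.2, abs=1e-12)

    def test_missing_control_errors_unless_allowed(self):
        rows = [("L1", "ma", "a", "e1", "b1", 1, 1.0),
                ("c", "control", "a", "e2", "b1", 1, 1.0)]
        with pytest.raises(ModelError, match="no matched control"):
            relative_fitness(growth_frame(rows))
        out = relative_fitness(growth_frame(rows), allow_missing_controls=True)
        assert len(out) == 1


class TestIcc:
    def test_perfect_repeatability(self):
        rows = []
        for i, mean in enumerate((0.5, 1.0, 1.5, 2.0)):
            for r in range(3):
                rows.append((f"L{i}", "ma", "a", "e", "b1", r, mean))
        rows.append(("c", "control", "a", "e", "b1", 1, 1.0))
        icc, pct = icc_and_variance(growth_frame(rows))
        assert icc == pytest.approx(1.0, abs=1e-6)
        assert pct == pytest.approx(100.0, abs=1e-4)

    def test_iid_null_near_zero(self, rng):
        rows = [(f"L{i}", "ma", "a", "e", "b1", r, float(rng.normal()))
                for i in range(30) for r in range(5)]
        rows.append(("c", "control", "a", "e", "b1", 1, 0.0))
        icc, _ = icc_and_variance(growth_frame(rows))
        assert icc < 0.1

    def test_matches_anova_oracle_balanced(self, rng):
        k, n = 15, 6
        effects = rng.normal(0, 0.4, k)
        rows = []
        y = np.empty((k, n))
        for i in range(k):
            for r in range(n):
                y[i, r] = 1.0 + effects[i] + rng.normal(0, 0.8)
                rows.append((f"L{i}", "ma", "a", "e", "b1", r, y[i, r]))
        rows.append(("c", "control", "a", "e", "b1", 1, 1.0))
        icc, _ = icc_and_variance(growth_frame(rows))
        msb = n * np.var(y.mean(axis=1), ddof=1)
        msw = float(np.mean(np.var(y, axis=1, ddof=1)))
        var_line = (msb - msw) / n
        want = var_line / (var_line + msw)
        assert icc == pytest.approx(want, abs=1e-3)

    def test_no_replication_rejected(self):
        rows = [("L1", "ma", "a", "e", "b1", 1, 1.0),
                ("L2", "ma", "a", "e", "b1", 1, 1.1),
                ("c", "control", "a", "e", "b1", 1, 1.0)]
        with pytest.raises(ModelError):
            icc_and_variance(growth_frame(rows))


class TestFitOriginLm:
    def test_exact_line_through_origin(self):
        data = pd.DataFrame({"x": [1.0, 2.0], "relative_fitness": [-1.0, -2.0]})
        fit = fit_origin_lm(data, "relative_fitness", ("x",))
        assert fit.coefficients["x"] == pytest.approx(-1.0, abs=1e-12)

    def test_slope_closed_form(self, rng):
        x = rng.normal(3, 1, 50)
        y = -0.5 * x + rng.normal(0, 0.3, 50)
        data = pd.DataFrame({"x": x, "relative_fitness": y})
        fit = fit_origin_lm(data, "relative_fitness", ("x",))
        assert fit.coefficients["x"] == pytest.approx(
            float(np.sum(x * y) / np.sum(x * x)), abs=1e-10)

    def test_free_intercept_is_distinct_code_path(self, rng):
        x = rng.normal(3, 1, 30)
        y = 0.4 + -0.5 * x + rng.normal(0, 0.1, 30)
        data = pd.DataFrame({"x": x, "relative_fitness": y})
        fixed = fit_origin_lm(data, "relative_fitness", ("x",))
        free = fit_origin_lm(data, "relative_fitness", ("x",), free_intercept=True)
        assert "const" in free.coefficients and "const" not in fixed.coefficients
        assert free.K == fixed.K + 1
        # adding an origin data point to a free fit is NOT the fixed fit
        augmented = pd.concat([data, pd.DataFrame({"x": [0.0], "relative_fitness": [0.0]})])
        aug = fit_origin_lm(augmented, "relative_fitness", ("x",), free_intercept=True)
        assert aug.coefficients["x"] != pytest.approx(fixed.coefficients["x"], abs=1e-12)

    def test_multi_predictor_decomposition(self, rng):
        # psi_del + psi_non_del together: both slopes recovered
        n = 80
        d = rng.poisson(2, n).astype(float)
        nd = rng.poisson(3, n).astype(float)
        y = -0.05 * d - 0.01 * nd + rng.normal(0, 0.02, n)
        data = pd.DataFrame({"psi_del": d, "psi_non_del": nd, "relative_fitness": y})
        fit = fit_origin_lm(data, "relative_fitness", ("psi_del", "psi_non_del"))
        assert fit.coefficients["psi_del"] == pytest.approx(-0.05, abs=0.01)
        assert fit.coefficients["psi_non_del"] == pytest.approx(-0.01, abs=0.01)

    def test_all_zero_predictor_rejected(self):
        data = pd.DataFrame({"x": [0.0, 0.0], "relative_fitness": [1.0, 2.0]})
        with pytest.raises(ModelError, match="identically zero"):
            fit_origin_lm(data, "relative_fitness", ("x",))


class TestFitOriginMixed:
    def test_recovery_of_fixed_slope(self, rng):
        # 6 groups x 14 lines, group slopes ~ N(-0.02, 0.005)
        rows = []
        for g in range(6):
            slope = rng.normal(-0.02, 0.005)
            for _ in range(14):
                x = float(rng.poisson(6))
                y = slope * x + rng.normal(0, 0.02)
                rows.append((f"anc{g}", x, y))
        data = pd.DataFrame(rows, columns=["anc", "x", "relative_fitness"])
        fit = fit_origin_mixed(data, "relative_fitness", "x", "anc")
        se = 0.005 / np.sqrt(6) + 1e-3
        assert abs(fit.coefficients["x"] - (-0.02)) < 3 * se

    def test_zero_between_group_variance_flagged_or_tiny(self, rng):
        rows = []
        for g in range(4):
            for _ in range(12):
                x = float(rng.poisson(6))
                rows.append((f"anc{g}", x, -0.02 * x + rng.normal(0, 0.01)))
        data = pd.DataFrame(rows, columns=["anc", "x", "relative_fitness"])
        fit = fit_origin_mixed(data, "relative_fitness", "x", "anc")
        assert fit.random_slope_sd < 0.01 or "singular" in fit.flags

    def test_needs_two_groups(self):
        data = pd.DataFrame({"anc": ["a"] * 5, "x": [1.0] * 5,
                             "relative_fitness": [0.0] * 5})
        with pytest.raises(ModelError):
            fit_origin_mixed(data, "relative_fitness", "x", "anc")


class TestAicc:
    def test_formula_example(self):
        # K=2, lnL=0, n=10 -> AIC 4, AICc 4 + 12/7
        assert aicc(0.0, 2, 10) == pytest.approx(4 + 12 / 7, abs=1e-12)

    def test_can_be_negative_with_large_likelihood(self):
        fit = ModelFit("m", ("x",), {"x": 1.0}, {}, {"x": 0.5}, log_likelihood=30.0,
                       K=2, n=20)
        assert fit.AIC < 0 and fit.AICc < 0

    def test_aicc_approaches_aic_for_large_n(self):
        assert abs(aicc(0.0, 3, 10**6) - 6.0) < 1e-3

    def test_aicc_geq_aic(self):
        fit = ModelFit("m", ("x",), {}, {}, {}, log_likelihood=5.0, K=3, n=12)
        assert fit.AICc >= fit.AIC


class TestModelSelection:
    def _fit(self, name, lnl, n=20, K=2):
        return ModelFit(name, ("x",), {}, {}, {}, log_likelihood=lnl, K=K, n=n)

    def test_ranking_and_delta(self):
        table = model_selection_table([self._fit("a", 1.0), self._fit("b", 5.0)])
        assert list(table["model"]) == ["b", "a"]
        assert table.loc[0, "delta_AICc"] == 0.0
        assert table.loc[1, "delta_AICc"] > 0

    def test_mismatched_n_rejected(self):
        with pytest.raises(ModelError, match="different response"):
            model_selection_table([self._fit("a", 1.0, n=20), self._fit("b", 1.0, n=19)])


class TestThresholdSweep:
    def _setup(self, rng, n_lines=24):
        scores = []
        fitness_rows = []
        for i in range(n_lines):
            line = f"L{i}"
            k = rng.poisson(4) + 1
            s = rng.normal(-3, 2, k)
            for v in s:
                scores.append((line, float(v)))
            fitness_rows.append((line, float(-0.02 * (s < -2.5).sum() + rng.normal(0, 0.01))))
        return (pd.DataFrame(scores, columns=["line_id", "score"]),
                pd.DataFrame(fitness_rows, columns=["line_id", "relative_fitness"]))

    def test_proportion_monotone_and_degenerate_undefined(self, rng):
        scores, fitness = self._setup(rng)
        grid = default_grid(-20, 0, 1.0)
        res = threshold_sweep(scores, fitness, grid)
        assert np.all(np.diff(res.proportion_deleterious) >= 0)
        below_all = grid < scores["score"].min()
        assert np.isnan(res.AICc_per_threshold[below_all]).all()
        assert (res.proportion_deleterious[below_all] == 0).all()

    def test_best_threshold_minimises_aicc(self, rng):
        scores, fitness = self._setup(rng)
        res = threshold_sweep(scores, fitness, default_grid(-8, 0, 0.5))
        k = int(np.nanargmin(res.AICc_per_threshold))
        assert res.best_threshold == res.thresholds[k]

    def test_empty_grid_rejected(self, rng):
        scores, fitness = self._setup(rng)
        with pytest.raises(ModelError, match="empty"):
            threshold_sweep(scores, fitness, np.array([]))


class TestEnvironmentPretest:
    def test_null_interaction_not_significant(self, rng):
        rows = []
        for env in ("e1", "e2"):
            for role, base in (("ma", 0.9), ("control", 1.0)):
                for i in range(30):
                    rows.append((f"{role}{i}", role, "a", env, "b1", i,
                                 base + rng.normal(0, 0.05)))
        f, p = environment_interaction_pretest(growth_frame(rows))
        assert p > 0.01
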