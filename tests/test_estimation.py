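"""Outcome model, beta/pi plug-ins, sandwich and bootstrap inference."""

import math

import numpy as np
import pandas as pd
import pytest

import benefitsens as bs
from benefitsens._guards import expit, logit


def no_covariate_data(seed=5, n=400, p0=0.4, p1=0.65):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n)
    y = (rng.random(n) < np.where(x == 1, p1, p0)).astype(int)
    return bs.TrialData(pd.DataFrame({"X": x, "Y": y}))


class TestTrialData:
    def test_rejects_nonbinary_codes(self):
        df = pd.DataFrame({"X": [0, 1, 2], "Y": [0, 1, 0]})
        with pytest.raises(ValueError, match="0/1"):
            bs.TrialData(df)

    def test_rejects_missing(self):
        df = pd.DataFrame({"X": [0, 1, 1], "Y": [0, None, 1]})
        with pytest.raises(ValueError, match="missing"):
            bs.TrialData(df)

    def test_rejects_empty_arm(self):
        df = pd.DataFrame({"X": [1, 1, 1], "Y": [0, 1, 1]})
        with pytest.raises(ValueError, match="arms"):
            bs.TrialData(df)

    def test_four_cell_check(self):
        df = pd.DataFrame({"X": [0, 0, 1, 1], "Y": [0, 1, 1, 1]})
        data = bs.TrialData(df)
        with pytest.raises(ValueError, match="empty"):
            data.require_four_cells()

    def test_from_dataframe_renames(self):
        df = pd.DataFrame({"treat": [0, 1], "resp": [1, 0], "age": [40.0, 50.0]})
        data = bs.TrialData.from_dataframe(df, treatment="treat", outcome="resp")
        assert data.covariates == ["age"] and data.n == 2


class TestOutcomeModel:
    def test_no_covariates_reduces_to_proportions(self):
        data = no_covariate_data()
        model = bs.fit_outcome_model(data)
        obs = data.margins()
        assert model.predict(data, arm=1) == pytest.approx(obs.pY1_X1, abs=1e-8)
        assert model.predict(data, arm=0) == pytest.approx(obs.pY1_X0, abs=1e-8)

    def test_scenario1_consistency_at_large_n(self):
        data = bs.sample_trial(bs.scenario("I", n=50_000), seed=17)
        model = bs.fit_outcome_model(data)
        intercept, coef_x, coef_z = model.params
        assert intercept == pytest.approx(1.0, abs=0.05)
        assert coef_x == pytest.approx(1.0, abs=0.05)
        assert coef_z == pytest.approx(0.0, abs=0.05)

    def test_misspecified_formula_accepted(self):
        data = bs.sample_trial(bs.scenario("III", n=2000), seed=2)
        model = bs.fit_outcome_model(data, formula="X + np.log(np.abs(Z))")
        preds = model.predict(data, arm=1)
        assert np.all((preds > 0) & (preds < 1))

    def test_per_arm_mode(self):
        data = bs.sample_trial(bs.scenario("III", n=2000), seed=3)
        model = bs.fit_outcome_model(data, mode="per-arm")
        preds = model.predict(data, arm=0)
        assert preds.shape == (2000,)
        with pytest.raises(ValueError, match="joint"):
            bs.sandwich_se(data, model, (1, 0), 0.0)

    def test_singular_design_signals(self):
        data = bs.sample_trial(bs.scenario("I", n=200), seed=4)
        df = data.df.assign(Z2=data.df.Z)  # perfectly collinear
        with pytest.raises(bs.ModelFitError, match="singular"):
            bs.fit_outcome_model(bs.TrialData(df, covariates=["Z", "Z2"]))


class TestEstimateBeta:
    def test_no_covariates_collapses_to_margin_logit(self):
        data = no_covariate_data()
        model = bs.fit_outcome_model(data)
        obs = data.margins()
        for y in (0, 1):
            assert bs.estimate_beta(data, model, (1, y)) == pytest.approx(
                float(logit(obs.pY1_X1)), abs=1e-8
            )
            assert bs.estimate_beta(data, model, (0, y)) == pytest.approx(
                float(logit(obs.pY1_X0)), abs=1e-8
            )

    def test_scenario3_beta11_consistent(self, truths):
        data = bs.sample_trial(bs.scenario("III", n=50_000), seed=21)
        model = bs.fit_outcome_model(data)
        beta11 = bs.estimate_beta(data, model, (1, 1))
        assert beta11 == pytest.approx(truths["III"].beta_xy[bs.CellIndex(1, 1)], abs=0.05)

    def test_empty_stratum_signals(self):
        df = pd.DataFrame({"X": [0, 0, 1, 1], "Y": [1, 1, 0, 1]})
        data = bs.TrialData(df)
        model = bs.fit_outcome_model(data)
        with pytest.raises(ValueError, match="undefined"):
            bs.estimate_beta(data, model, (1, 0))  # needs Y=0, X=0 subjects


class TestEstimatePi:
    def test_delta_zero_no_covariates_is_product(self):
        data = no_covariate_data()
        model = bs.fit_outcome_model(data)
        obs = data.margins()
        est = bs.estimate_pi(data, model, (1, 0), delta=0.0, method="none")
        assert est.value == pytest.approx(obs.pY1_X1 * (1 - obs.pY1_X0), abs=1e-10)

    def test_worked_example_table_as_data(self, worked_example):
        data = bs.TrialData(worked_example[["X", "Y"]].copy())
        model = bs.fit_outcome_model(data)
        est = bs.estimate_pi(data, model, (1, 0), delta=0.0, method="none")
        assert est.value == pytest.approx(0.25, abs=1e-10)

    def test_consistency_at_true_delta(self, truths):
        for name in ("I", "II", "III"):
            t = truths[name]
            data = bs.sample_trial(bs.scenario(name, n=50_000), seed=33)
            model = bs.fit_outcome_model(data)
            for cell in bs.ALL_CELLS:
                est = bs.estimate_pi(data, model, cell, t.delta_xy[cell], method="none")
                assert abs(est.value - t.pi) < 0.01, (name, cell)

    def test_cell_agreement_with_linked_deltas(self, scenario3_n2000):
        data, model = scenario3_n2000
        obs = data.margins()
        betas = {c: bs.estimate_beta(data, model, c) for c in bs.ALL_CELLS}
        base = bs.CellIndex(1, 0)
        deltas = {base: -0.3}
        deltas.update(bs.convert_delta_cell(base, -0.3, betas, obs))
        values = [
            bs.estimate_pi(data, model, c, deltas[c], method="none").value
            for c in bs.ALL_CELLS
        ]
        assert max(values) - min(values) < 1e-8


class TestSandwich:
    def test_matches_closed_form_without_covariates(self):
        # with no covariates the estimator is a smooth function of the two
        # arm proportions; the delta method gives its variance in closed form
        data = no_covariate_data(n=800)
        obs = data.margins()
        m1, m0 = obs.pY1_X1, obs.pY1_X0
        n1 = int((data.X == 1).sum())
        n0 = data.n - n1
        delta = 0.4
        h = float(expit(delta + logit(m1)))
        dpi_dm1 = (1 - m0) * h * (1 - h) / (m1 * (1 - m1))
        dpi_dm0 = -h
        var = dpi_dm1**2 * m1 * (1 - m1) / n1 + dpi_dm0**2 * m0 * (1 - m0) / n0
        model = bs.fit_outcome_model(data)
        se = bs.sandwich_se(data, model, (1, 0), delta)
        assert se == pytest.approx(math.sqrt(var), rel=1e-4)

    def test_agrees_with_bootstrap_on_fixed_dataset(self, scenario3_n2000):
        data, model = scenario3_n2000
        cell, delta = bs.CellIndex(1, 0), -0.157
        se_sand = bs.sandwich_se(data, model, cell, delta)
        se_boot, _, _, _ = bs.bootstrap_ci(
            data, (None, "joint"), cell, delta, B=1000, seed=8
        )
        assert se_sand == pytest.approx(se_boot, rel=0.10)


class TestBootstrap:
    def test_deterministic_given_seed(self, scenario3_n2000):
        data, _ = scenario3_n2000
        a = bs.bootstrap_ci(data, (None, "joint"), (1, 0), 0.0, B=50, seed=123)
        b = bs.bootstrap_ci(data, (None, "joint"), (1, 0), 0.0, B=50, seed=123)
        assert a == b

    def test_requires_two_resamples(self, scenario3_n2000):
        data, _ = scenario3_n2000
        with pytest.raises(ValueError, match="B"):
            bs.bootstrap_ci(data, (None, "joint"), (1, 0), 0.0, B=1)


class TestIvwCombine:
    def make(self, value, se, cell=(1, 0)):
        return bs.PiEstimate(
            value=value, se=se, ci=(value - 1.96 * se, value + 1.96 * se),
            cell=bs.CellIndex.of(cell), delta=0.0, beta_hat=0.0, method="sandwich",
        )

    def test_identical_inputs(self):
        est = self.make(0.3, 0.02)
        out = bs.ivw_combine([est, est])
        assert out.value == pytest.approx(0.3)

    def test_weighted_mean_arithmetic(self):
        out = bs.ivw_combine([self.make(0.2, 0.02), self.make(0.3, 0.04)])
        assert out.value == pytest.approx(0.22)

    def test_nonfinite_se_excluded(self):
        good = [self.make(0.2, 0.02), self.make(0.3, 0.04)]
        bad = self.make(0.9, float("inf"))
        with pytest.warns(UserWarning, match="dropped"):
            out = bs.ivw_combine([*good, bad])
        assert out.value == pytest.approx(0.22)

    def test_pipeline_bootstrap_se(self, scenario3_n2000):
        data, model = scenario3_n2000
        obs = data.margins()
        betas = {c: bs.estimate_beta(data, model, c) for c in bs.ALL_CELLS}
        base = bs.CellIndex(1, 0)
        deltas = {base: -0.157}
        deltas.update(bs.convert_delta_cell(base, -0.157, betas, obs))
        ests = [
            bs.estimate_pi(data, model, c, deltas[c], method="sandwich")
            for c in bs.ALL_CELLS
        ]
        out = bs.ivw_combine(ests, data=data, model_spec=(None, "joint"), B=60, seed=5)
        assert out.method == "ivw+bootstrap"
        assert 0.0 < out.se <= max(e.se for e in ests) * 1.5


class TestSensitivityCurve:
    def test_singleton_grid_reduces_to_estimate(self, scenario3_n2000):
        data, model = scenario3_n2000
        curve = bs.sensitivity_curve(data, model, (1, 0), [0.0])
        single = bs.estimate_pi(data, model, (1, 0), 0.0)
        assert curve.points[0][1].value == single.value
        assert curve.spanned == single.ci

    @pytest.mark.parametrize("cell", [(1, 0), (0, 1)], ids=str)
    def test_monotone_along_grid(self, scenario3_n2000, cell):
        data, model = scenario3_n2000
        grid = np.linspace(-1, 1, 7)
        curve = bs.sensitivity_curve(data, model, cell, grid, method="none")
        vals = [est.value for _, est in curve.points]
        diffs = np.diff(vals)
        assert np.all(diffs > 0) if cell[1] == 0 else np.all(diffs < 0)

    def test_endpoint_fast_path_matches_full_grid(self, scenario3_n2000):
        data, model = scenario3_n2000
        grid = np.linspace(-0.8, 0.9, 11)
        full = bs.sensitivity_curve(data, model, (1, 0), grid)
        fast = bs.sensitivity_curve(data, model, (1, 0), grid, endpoints_only=True)
        assert fast.spanned == full.spanned
        assert len(fast.points) == 2


class TestMarginalizedBounds:
    def test_no_covariates_equals_marginal_bounds(self):
        data = no_covariate_data()
        model = bs.fit_outcome_model(data)
        lo, hi = bs.marginalized_bounds(data, model)
        lo_m, hi_m = bs.np_bounds(data.margins().marginals)
        assert lo == pytest.approx(lo_m, abs=1e-8)
        assert hi == pytest.approx(hi_m, abs=1e-8)

    def test_ordered_unit_interval(self, scenario3_n2000):
        data, model = scenario3_n2000
        lo, hi = bs.marginalized_bounds(data, model)
        assert 0.0 <= lo <= hi <= 1.0


class TestSelectCell:
    def test_strategies(self, scenario3_n2000):
        data, _ = scenario3_n2000
        vi = bs.select_cell(data, "variation-independent")
        assert vi == bs.variation_independent_cell(data.margins().marginals)
        largest = bs.select_cell(data, "largest-stratum")
        counts = {c: int(data.stratum_mask(c).sum()) for c in bs.ALL_CELLS}
        assert counts[largest] == max(counts.values())
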