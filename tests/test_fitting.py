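"""Nonlinearity fitting, adjusted R^2, LOOCV and model selection."""

import numpy as np
import pytest

from icxfreq.fitting import (
    FitResult,
    ScatterData,
    adjusted_r2,
    compare_models,
    fit_model,
    loocv_mse,
    predict,
    select_model,
)


class TestAdjustedR2:
    def test_perfect_fit(self):
        assert adjusted_r2(0.0, 10.0, 20, 2) == pytest.approx(1.0)

    def test_hand_value(self):
        # 1 - (1/3)/(10/4)
        assert adjusted_r2(1.0, 10.0, 5, 1) == pytest.approx(0.8667, abs=1e-4)

    def test_null_model(self):
        assert adjusted_r2(10.0, 10.0, 12, 0) == pytest.approx(0.0)

    def test_undefined_penalty(self):
        with pytest.raises(ValueError):
            adjusted_r2(1.0, 10.0, 3, 2)


NOISELESS_TRUTHS = {
    "linear": {"b0": 1.0, "b1": 2.0},
    "quadratic": {"b0": 0.5, "b1": 0.1, "b2": 0.05},
    "relu": {"a0": 2.0, "a1": 3.0},
    "stack_sigmoid": {"b0": 0.5, "b1": 0.15, "b2": 8.0, "b3": 1.2, "b4": 5.0},
    "spiking_sigmoid": {"c0": 12.0, "c1": 0.9, "c2": 5.0, "alpha": 1.3},
}


class TestNoiselessRecovery:
    @pytest.mark.parametrize("model", list(NOISELESS_TRUTHS))
    def test_exact_parameters_recovered(self, model):
        truth = NOISELESS_TRUTHS[model]
        x = np.linspace(-2.0, 4.0, 21) if model == "relu" else np.linspace(0.0, 10.0, 21)
        y = predict(model, truth, x)
        fit = fit_model(ScatterData(x, y), model)
        for name, val in truth.items():
            if name == "alpha":
                # the hard threshold is identifiable only up to the gap
                # between the last zeroed and first active x
                active = x[x >= val]
                zeroed = x[x < val]
                assert fit.params["alpha"] <= active.min() + 1e-9
                assert fit.params["alpha"] > zeroed.max() - 1e-9
            else:
                assert fit.params[name] == pytest.approx(val, abs=1e-4)
        assert fit.rss < 1e-12

    def test_quadratic_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(-3, 7, 25)
        y = 0.4 - 1.1 * x + 0.3 * x**2 + rng.normal(0, 0.5, 25)
        fit = fit_model(ScatterData(x, y), "quadratic")
        design = np.column_stack([np.ones_like(x), x, x**2])
        oracle = np.linalg.solve(design.T @ design, design.T @ y)
        assert fit.params["b0"] == pytest.approx(oracle[0], abs=1e-8)
        assert fit.params["b1"] == pytest.approx(oracle[1], abs=1e-8)
        assert fit.params["b2"] == pytest.approx(oracle[2], abs=1e-8)


class TestLoocv:
    def test_exact_line_gives_zero(self):
        x = np.linspace(0, 10, 12)
        d = ScatterData(x, 3.0 - 0.5 * x)
        assert loocv_mse(d, "linear") == pytest.approx(0.0, abs=1e-18)

    def test_three_point_brute_force(self):
        # leave-out errors: 4 (line y=2-x predicts 2 at x=0),
        # 1 (line y=0 predicts 0 at x=1), 4 (line y=x predicts 2 at x=2)
        d = ScatterData(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 0.0]), min_n=3)
        assert loocv_mse(d, "linear") == pytest.approx(3.0)

    @pytest.mark.parametrize("model", ["linear", "quadratic", "stack_sigmoid"])
    def test_matches_naive_per_point_refit_oracle(self, model):
        """Independent leave-one-out loop (mask, refit, predict) agrees to
        1e-8 on random small datasets."""
        from icxfreq.fitting import _fit_params  # independent of loocv_mse

        rng = np.random.default_rng(17)
        for rep in range(4):
            n = int(rng.integers(9, 13))
            x = np.sort(rng.uniform(0, 10, n))
            y = 0.5 + 0.8 * x + rng.normal(0, 0.8, n)
            d = ScatterData(x, y)
            errs = []
            for i in range(n):
                mask = np.ones(n, bool)
                mask[i] = False
                params = _fit_params(x[mask], y[mask], model)
                errs.append((y[i] - predict(model, params, x[i : i + 1])[0]) ** 2)
            assert loocv_mse(d, model) == pytest.approx(np.mean(errs), abs=1e-8)


class TestSelectModel:
    def _fit(self, name, r2a, cv):
        return FitResult(model=name, params={}, rss=1.0, adjusted_r2=r2a, loocv_mse=cv)

    def test_dominance_names_winner(self):
        comp = select_model([self._fit("a", 0.9, 1.0), self._fit("b", 0.8, 2.0)])
        assert comp.winner == "a"

    def test_disagreement_is_inconclusive(self):
        comp = select_model([self._fit("a", 0.9, 2.0), self._fit("b", 0.8, 1.0)])
        assert comp.winner == "inconclusive"

    def test_three_way_dominance(self):
        comp = select_model(
            [self._fit("a", 0.7, 3.0), self._fit("b", 0.9, 1.0), self._fit("c", 0.8, 2.0)]
        )
        assert comp.winner == "b"

    def test_needs_two_fits(self):
        with pytest.raises(ValueError):
            select_model([self._fit("a", 0.9, 1.0)])


class TestRedundantParameters:
    def test_rss_never_increases_but_adjustment_can_penalize(self):
        """A quadratic never has larger RSS than the nested line, yet its
        adjusted R^2 can be lower when the curvature is spurious."""
        rng = np.random.default_rng(23)
        x = np.linspace(0, 10, 15)
        y = 2.0 + 0.5 * x + rng.normal(0, 0.3, 15)
        d = ScatterData(x, y)
        lin = fit_model(d, "linear")
        quad = fit_model(d, "quadratic")
        assert quad.rss <= lin.rss + 1e-12
        assert quad.adjusted_r2 < lin.adjusted_r2 + (lin.rss - quad.rss)

    def test_sparse_response_flagged(self):
        x = np.linspace(0, 10, 12)
        y = np.zeros(12)
        y[5] = 1.0
        fit = fit_model(ScatterData(x, y), "linear")
        assert not fit.converged
        assert "sparse" in fit.note or "adjusted" in fit.note


class TestCompareModels:
    def test_clean_sigmoid_data_selects_sigmoid(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 10, 30)
        truth = {"b0": 1.0, "b1": 0.05, "b2": 8.0, "b3": 1.5, "b4": 5.0}
        y = predict("stack_sigmoid", truth, x) + rng.normal(0, 0.2, 30)
        comp = compare_models(ScatterData(x, y), ("linear", "quadratic", "stack_sigmoid"))
        assert comp.winner == "stack_sigmoid"
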