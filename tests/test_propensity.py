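import numpy as np
import pytest
from scipy import optimize

from msmcal.config import scenario_config
from msmcal.dgm import expit, simulate_panel
from msmcal.propensity import (
    DegenerateFitError,
    PositivityError,
    WeightSet,
    fit_pooled_logistic,
    product_weights,
    stabilized_weights,
    truncate_weights,
    write_weights_csv,
)
from conftest import make_panel


def _logit(p):
    return np.log(p / (1 - p))


class TestFitPooledLogistic:
    def test_intercept_only_recovers_event_fraction(self):
        n, t = 10, 5
        A = np.zeros((n, t), dtype=np.int8)
        A[:8] = 1  # event fraction 0.8
        panel = make_panel(np.ones((n, t)), A, np.zeros((n, t)),
                           np.full((n, t), 9.0), np.zeros((n, 3)))
        fit = fit_pooled_logistic(panel, "treatment", regressor_spec=())
        assert fit.coefficients["const"] == pytest.approx(_logit(0.8), abs=1e-8)
        assert fit.converged

    def test_score_at_mle_is_zero(self, scenario4_panel):
        fit = fit_pooled_logistic(scenario4_panel, "visit")
        assert fit.max_score <= 1e-6
        assert np.all((fit.fitted_probabilities > 0) & (fit.fitted_probabilities < 1))

    def test_coefficient_recovery(self):
        # n*t = 1e5 cells; visit-scope treatment model is the generating model
        cfg = scenario_config(1, n_subjects=20_000, n_intervals=5, seed=21)
        panel = simulate_panel(cfg)
        fit = fit_pooled_logistic(panel, "treatment", modelled=panel.V == 1)
        coef = fit.coefficients
        truth = {"const": 0.0, "v_lag": 0.1, "last_y": 0.1, "l_cur": 0.1,
                 "a_lag": 0.0, "x1": 0.3, "x2": 0.3, "x3": 0.6}
        for name, value in truth.items():
            assert coef[name] == pytest.approx(value, abs=0.08), name

    def test_perfect_separation_flagged(self):
        V = np.ones((2, 1), dtype=np.int8)
        A = np.array([[1], [0]], dtype=np.int8)
        L = np.array([[1], [0]], dtype=np.int8)
        panel = make_panel(V, A, L, np.full((2, 1), 9.0), np.zeros((2, 3)))
        fit = fit_pooled_logistic(panel, "treatment", regressor_spec=("l_cur",))
        assert fit.separation_flagged
        assert not fit.converged

    def test_constant_event_raises(self):
        panel = make_panel(np.ones((4, 3)), np.ones((4, 3)), np.zeros((4, 3)),
                           np.full((4, 3), 9.0), np.zeros((4, 3)))
        with pytest.raises(DegenerateFitError):
            fit_pooled_logistic(panel, "treatment", regressor_spec=())


class TestStabilizedWeights:
    def test_identical_specs_give_unit_weights(self, scenario1_panel):
        w = stabilized_weights(
            scenario1_panel, "treatment",
            numerator_spec=("v_lag", "a_lag", "x1", "x2", "x3"),
            denominator_spec=("v_lag", "a_lag", "x1", "x2", "x3"),
        )
        np.testing.assert_allclose(w.sw, 1.0, atol=1e-12)

    def test_telescoping(self, scenario4_panel):
        w = stabilized_weights(scenario4_panel, "treatment")
        np.testing.assert_allclose(w.sw[:, 1:], w.sw[:, :-1] * w.ratios[:, 1:],
                                   rtol=1e-12)
        w = stabilized_weights(scenario4_panel, "visit")
        np.testing.assert_allclose(w.sw[:, 1:], w.sw[:, :-1] * w.ratios[:, 1:],
                                   rtol=1e-12)

    def test_hand_computed_toy_oracle(self):
        # 3 subjects x 2 intervals; fits recomputed independently with a
        # generic optimizer on the pooled Bernoulli likelihood
        V = np.ones((3, 2), dtype=np.int8)
        A = np.array([[1, 0], [0, 1], [1, 1]], dtype=np.int8)
        L = np.array([[1, 0], [1, 0], [0, 1]], dtype=np.int8)
        panel = make_panel(V, A, L, np.full((3, 2), 9.0), np.zeros((3, 3)))
        w = stabilized_weights(
            panel, "treatment",
            numerator_spec=("a_lag",), denominator_spec=("a_lag", "l_cur"),
            fit_scope="all",
        )

        y = A.ravel().astype(float)

        def neg_loglik(beta, cols):
            lin = cols @ beta
            return np.sum(np.log1p(np.exp(lin)) - y * lin)

        ones = np.ones(6)
        a_lag = np.array([0, 1, 0, 0, 0, 1], dtype=float)
        l_cur = L.ravel().astype(float)
        num_cols = np.column_stack([ones, a_lag])
        den_cols = np.column_stack([ones, a_lag, l_cur])
        bn = optimize.minimize(neg_loglik, np.zeros(2), args=(num_cols,),
                               method="BFGS", tol=1e-14).x
        bd = optimize.minimize(neg_loglik, np.zeros(3), args=(den_cols,),
                               method="BFGS", tol=1e-14).x
        p_num = expit(num_cols @ bn).reshape(3, 2)
        p_den = expit(den_cols @ bd).reshape(3, 2)
        obs_num = np.where(A == 1, p_num, 1 - p_num)
        obs_den = np.where(A == 1, p_den, 1 - p_den)
        expected = np.cumprod(obs_num / obs_den, axis=1)
        np.testing.assert_allclose(w.sw, expected, atol=1e-6)

    @pytest.mark.parametrize("n,tol", [(100, 0.25), (5000, 0.05)])
    def test_mean_one_per_interval(self, n, tol):
        cfg = scenario_config(1, n_subjects=n, seed=31)
        panel = simulate_panel(cfg)
        w = stabilized_weights(panel, "treatment")
        assert np.max(np.abs(w.sw.mean(axis=0) - 1.0)) <= tol

    def test_non_visit_cells_contribute_unit_ratio(self, scenario4_panel):
        w = stabilized_weights(scenario4_panel, "treatment")
        assert np.all(w.ratios[scenario4_panel.V == 0] == 1.0)

    def test_positivity_violation_raises(self):
        rng = np.random.default_rng(1)
        L = rng.integers(0, 2, (40, 4)).astype(np.int8)
        panel = make_panel(np.ones((40, 4)), L.copy(), L,
                           np.full((40, 4), 9.0), rng.standard_normal((40, 3)))
        with pytest.raises(PositivityError):
            stabilized_weights(panel, "treatment")


class TestProductWeights:
    def test_identity_element(self, scenario4_panel):
        w = stabilized_weights(scenario4_panel, "visit")
        ones = WeightSet(sw=np.ones_like(w.sw), kind="product")
        np.testing.assert_array_equal(product_weights([ones, w]).sw, w.sw)

    def test_cellwise_product(self):
        parts = [
            WeightSet(sw=np.full((1, 1), v), kind="product")
            for v in (2.0, 0.5, 3.0)
        ]
        assert product_weights(parts).sw[0, 0] == pytest.approx(3.0)

    def test_order_invariance(self, scenario4_panel):
        wt = stabilized_weights(scenario4_panel, "treatment")
        wv = stabilized_weights(scenario4_panel, "visit")
        np.testing.assert_allclose(
            product_weights([wt, wv]).sw, product_weights([wv, wt]).sw
        )

    def test_joint_weight_mean_near_one(self, scenario4_panel):
        wt = stabilized_weights(scenario4_panel, "treatment")
        wv = stabilized_weights(scenario4_panel, "visit")
        joint = product_weights([wt, wv])
        assert np.max(np.abs(joint.sw.mean(axis=0) - 1.0)) <= 0.3

    def test_misaligned_rejected(self):
        a = WeightSet(sw=np.ones((2, 3)), kind="product")
        b = WeightSet(sw=np.ones((3, 2)), kind="product")
        with pytest.raises(ValueError):
            product_weights([a, b])


class TestTruncateWeights:
    def test_full_range_unchanged(self, scenario4_panel):
        w = stabilized_weights(scenario4_panel, "treatment")
        np.testing.assert_array_equal(truncate_weights(w, 0.0, 1.0).sw, w.sw)

    def test_known_quantiles(self):
        w = WeightSet(sw=np.arange(1.0, 101.0).reshape(10, 10), kind="product")
        t = truncate_weights(w, 0.01, 0.99)
        assert t.sw.min() == pytest.approx(1.99)
        assert t.sw.max() == pytest.approx(99.01)

    def test_constant_unchanged(self):
        w = WeightSet(sw=np.full((3, 3), 2.5), kind="product")
        np.testing.assert_array_equal(truncate_weights(w, 0.01, 0.99).sw, w.sw)

    def test_invalid_quantiles(self):
        w = WeightSet(sw=np.ones((2, 2)), kind="product")
        with pytest.raises(ValueError):
            truncate_weights(w, 0.5, 0.5)


def test_weights_csv_export(tmp_path, scenario4_panel):
    import pandas as pd

    w = stabilized_weights(scenario4_panel, "visit")
    path = tmp_path / "w.csv"
    write_weights_csv(w, path)
    frame = pd.read_csv(path)
    assert list(frame.columns) == ["id", "interval", "weight", "kind"]
    np.testing.assert_allclose(frame["weight"].to_numpy().reshape(w.shape), w.sw)
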