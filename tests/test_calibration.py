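import numpy as np
import pytest

from msmcal.calibration import (
    ConstraintSystem,
    assemble_system,
    build_balance_constraints,
    build_subject_constraints,
    build_unity_constraints,
    calibrate,
    calibration_report,
    constraint_residuals,
    solve_lambda,
    subject_effect_propensities,
)
from msmcal.config import scenario_config
from msmcal.dgm import simulate_panel
from msmcal.propensity import WeightSet, panel_history_terms, stabilized_weights


class TestConstraintBuilders:
    def test_zero_residuals_give_zero_columns(self):
        res = np.zeros((4, 3))
        basis = {"const": np.ones((4, 3))}
        cols, labels = build_balance_constraints(res, basis)
        assert labels == ["balance:const"]
        np.testing.assert_array_equal(cols[0], 0.0)

    def test_cumulative_inner_sums(self):
        res = np.array([[0.5, -0.5]])
        cols, _ = build_balance_constraints(res, {"const": np.ones((1, 2))})
        np.testing.assert_allclose(cols[0], [0.5, 0.0])

    def test_unity_columns_are_interval_indicators(self):
        cols, labels = build_unity_constraints(2, 3)
        assert labels == ["unity:1", "unity:2", "unity:3"]
        np.testing.assert_array_equal(cols[0], [1, 0, 0, 1, 0, 0])

    def test_subject_columns_carry_own_residuals(self):
        res = np.array([[0.25, -0.5], [0.0, 0.0]])
        cols, labels = build_subject_constraints(res)
        np.testing.assert_allclose(cols[0], [0.25, -0.5, 0.0, 0.0])
        np.testing.assert_array_equal(cols[1], 0.0)  # vacuous subject

    def test_vacuous_columns_pruned(self, scenario1_panel):
        base = stabilized_weights(scenario1_panel, "treatment")
        system = assemble_system(
            base, scenario1_panel,
            e_hat=np.asarray(scenario1_panel.A, dtype=float),  # zero residuals
            families=("balance",),
        )
        assert system.n_constraints == 0


class TestSolveLambda:
    def _unity_toy(self):
        base = WeightSet(sw=np.array([[2.0], [0.5]]), kind="product")
        return ConstraintSystem(
            K=np.ones((2, 1)),
            targets=np.array([2.0]),
            base_weights=base,
            residual_labels=["unity:1"],
        )

    def test_closed_form_unity_toy(self):
        # 2 e^lam + 0.5 e^lam = 2  =>  lam = ln 0.8
        result = solve_lambda(self._unity_toy())
        assert result.converged
        assert result.lambda_[0] == pytest.approx(np.log(0.8), abs=1e-8)
        np.testing.assert_allclose(result.calibrated.sw.ravel(), [1.6, 0.4], atol=1e-7)

    def test_empty_system_is_identity(self, scenario1_panel):
        base = stabilized_weights(scenario1_panel, "treatment")
        system = ConstraintSystem(
            K=np.zeros((base.sw.size, 0)),
            targets=np.zeros(0),
            base_weights=base,
            residual_labels=[],
        )
        result = solve_lambda(system)
        assert result.converged
        assert result.iterations == 0
        np.testing.assert_array_equal(result.calibrated.sw, base.sw)

    def test_root_at_zero_reproduces_base_bitwise(self):
        base = WeightSet(sw=np.array([[1.25], [0.75]]), kind="product")
        system = ConstraintSystem(
            K=np.ones((2, 1)),
            targets=np.array([2.0]),  # already satisfied at lambda = 0
            base_weights=base,
            residual_labels=["unity:1"],
        )
        result = solve_lambda(system)
        assert result.converged
        assert result.calibrated.sw.tolist() == base.sw.tolist()


class TestCalibrate:
    def test_balance_and_unity_contracts(self, scenario1_panel):
        base = stabilized_weights(scenario1_panel, "treatment")
        result = calibrate(base, scenario1_panel, families=("balance", "unity"))
        assert result.converged
        # independent recomputation, not solver internals
        res = constraint_residuals(result.system, result.calibrated.sw)
        assert np.max(np.abs(res)) <= 1e-6
        means = result.calibrated.sw.mean(axis=0)
        assert np.max(np.abs(means - 1.0)) <= 1e-6

    def test_subject_contracts(self, scenario2_panel):
        base = stabilized_weights(scenario2_panel, "treatment")
        result = calibrate(base, scenario2_panel,
                           families=("balance", "unity", "subject"))
        assert result.converged
        res = constraint_residuals(result.system, result.calibrated.sw)
        subject_rows = [
            k for k, lab in enumerate(result.system.residual_labels)
            if lab.startswith("subject:")
        ]
        assert len(subject_rows) > 0
        assert np.max(np.abs(res[subject_rows])) <= 1e-6

    def test_positivity_of_calibrated_weights(self, scenario2_panel):
        base = stabilized_weights(scenario2_panel, "treatment")
        result = calibrate(base, scenario2_panel,
                           families=("balance", "unity", "subject"))
        assert np.all(result.calibrated.sw > 0)

    def test_high_correlation_with_base(self):
        # loose stochastic property on scenario-1 replicates
        for seed in (1, 2, 3):
            panel = simulate_panel(scenario_config(1, seed=seed))
            base = stabilized_weights(panel, "treatment")
            result = calibrate(base, panel, families=("balance", "unity"))
            assert result.converged
            corr = np.corrcoef(base.sw.ravel(), result.calibrated.sw.ravel())[0, 1]
            assert corr >= 0.9

    def test_visit_family_calibrates_independently(self, scenario4_panel):
        base = stabilized_weights(scenario4_panel, "visit")
        result = calibrate(base, scenario4_panel, families=("balance", "unity"))
        assert result.converged
        res = constraint_residuals(result.system, result.calibrated.sw)
        assert np.max(np.abs(res)) <= 1e-6

    def test_report_structure(self, scenario1_panel):
        base = stabilized_weights(scenario1_panel, "treatment")
        result = calibrate(base, scenario1_panel, families=("balance", "unity"))
        report = calibration_report(result)
        assert report["converged"]
        assert report["residual_norm_after"] <= 1e-6
        assert set(report["constraints_by_family"]) == {"balance", "unity"}

    def test_unknown_family_rejected(self, scenario1_panel):
        base = stabilized_weights(scenario1_panel, "treatment")
        with pytest.raises(ValueError):
            calibrate(base, scenario1_panel, families=("balance", "magic"))


class TestSubjectEffectPropensities:
    def test_per_subject_score_property(self, scenario2_panel):
        # residual sums vanish per subject at the subject-intercept MLE
        terms = panel_history_terms(scenario2_panel)
        e_hat = subject_effect_propensities(
            np.asarray(scenario2_panel.A, dtype=float), terms, ["v_lag", "a_lag"]
        )
        sums = (scenario2_panel.A - e_hat).sum(axis=1)
        assert np.max(np.abs(sums)) <= 1e-4

    def test_degenerate_subjects_have_zero_residuals(self):
        event = np.array([[1, 1, 1], [0, 1, 0]], dtype=float)
        terms = {"const": np.ones((2, 3))}
        e_hat = subject_effect_propensities(event, terms, [])
        np.testing.assert_array_equal(e_hat[0], event[0])


class TestConvergenceStability:
    def test_scenario2_calibrations_converge(self):
        n_conv = 0
        for seed in range(10):
            panel = simulate_panel(scenario_config(2, seed=seed))
            base = stabilized_weights(panel, "treatment")
            result = calibrate(base, panel, families=("balance", "unity", "subject"))
            n_conv += result.converged
        assert n_conv >= 9
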