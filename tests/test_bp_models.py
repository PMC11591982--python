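"""BMI, the empirical BP formula, NM-PSO calibration and OLS regression."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palmbp import generate_cohort
from palmbp.bp_models import (
    BPFormulaParams,
    RegressionParams,
    bmi_interval_lookup,
    compute_bmi,
    fit_nmpso,
    fit_regression,
    formula_value,
    predict_formula,
    predict_regression,
)
from palmbp.errors import (
    DegenerateFitError,
    InsufficientDataError,
    InvalidArgumentError,
    OutOfRangeError,
    SingularMatrixError,
)
from palmbp.evaluation import rmse
from palmbp.synthetic_data import SubjectRecord

ALPHA_SBP = (60.0, 40.0, 0.5)
ALPHA_DBP = (40.0, 20.0, 0.3)
WIDE = [(10.0, 60.0)]


class TestComputeBMI:
    def test_reference_values(self):
        assert compute_bmi(1.75, 70) == pytest.approx(22.857142857142858)
        assert compute_bmi(2.0, 80) == pytest.approx(20.0)

    @pytest.mark.parametrize("h,w", [(0, 70), (-1.7, 70), (1.7, 0)])
    def test_non_positive_inputs_rejected(self, h, w):
        with pytest.raises(InvalidArgumentError):
            compute_bmi(h, w)


class TestPredictFormula:
    def test_hand_evaluations(self):
        p = BPFormulaParams(0.0, 1.0, 0.0)
        assert predict_formula(100.0, 22.0, p) == pytest.approx(122.0)
        p = BPFormulaParams(50.0, 0.5, 0.0)
        assert predict_formula(100.0, 0.0, p) == pytest.approx(100.0)
        p = BPFormulaParams(10.0, 2.0, 0.1)
        # 10 + 2*3 + 20*(1 + 0.1*3) = 42
        assert predict_formula(3.0, 20.0, p) == pytest.approx(42.0)

    def test_zero_interaction_reduces_to_regression(self):
        # alpha2=0 makes the formula the plane g0 + 1*BMI + g1*x
        a0, a1 = 55.0, 30.0
        fp = BPFormulaParams(a0, a1, 0.0)
        rp = RegressionParams(a0, 1.0, a1)
        for x, bmi in [(0.3, 18.0), (0.7, 31.0), (0.51, 24.0)]:
            assert predict_formula(x, bmi, fp) == pytest.approx(
                predict_regression(bmi, x, rp), abs=1e-12
            )


class TestFitNMPSO:
    def test_noiseless_cohort_recovered(self):
        records = generate_cohort(
            40, ALPHA_SBP, ALPHA_DBP, feature_range=(0.2, 0.8), noise_sd=0.0, seed=1
        )
        table = fit_nmpso(records, "SBP", WIDE)
        pred = [predict_formula(r.e_peak, r.bmi, table[0]) for r in records]
        actual = [r.sbp_device for r in records]
        assert rmse(actual, pred) <= 0.5

    def test_fitted_mse_at_least_matches_the_generator(self):
        records = generate_cohort(
            40, ALPHA_SBP, ALPHA_DBP, feature_range=(0.2, 0.8), noise_sd=0.0, seed=2
        )
        table = fit_nmpso(records, "SBP", WIDE)
        x = np.array([r.e_peak for r in records])
        bmi = np.array([r.bmi for r in records])
        y = np.array([r.sbp_device for r in records])
        true_mse = float(np.mean((formula_value(ALPHA_SBP, x, bmi) - y) ** 2))
        assert table[0].fit_mse <= true_mse + 1e-6

    def test_heldout_error_near_the_noise_floor(self):
        errs = []
        for seed in range(10):
            records = generate_cohort(
                200, ALPHA_SBP, ALPHA_DBP, bmi_range=(18, 32),
                feature_range=(0.2, 0.8), noise_sd=2.0, seed=seed,
            )
            table = fit_nmpso(records[:150], "SBP", [(18.0, 32.0)])
            pred = [predict_formula(r.e_peak, r.bmi, table[0]) for r in records[150:]]
            actual = [r.sbp_device for r in records[150:]]
            errs.append(rmse(actual, pred))
        assert all(1.5 <= e <= 3.5 for e in errs)

    def test_constant_feature_flagged_as_degenerate(self):
        records = [
            SubjectRecord(bmi=20 + i, sbp_device=120 + i, dbp_device=70, e_peak=0.5, e_valley=0.3)
            for i in range(10)
        ]
        with pytest.raises(DegenerateFitError):
            fit_nmpso(records, "SBP", WIDE)

    def test_underpopulated_interval_named(self):
        records = generate_cohort(2, ALPHA_SBP, ALPHA_DBP, feature_range=(0.2, 0.8), seed=0)
        with pytest.raises(InsufficientDataError, match=r"\[10.0, 60.0\)"):
            fit_nmpso(records, "SBP", WIDE)


class TestFitRegression:
    def test_exact_interpolation_recovers_coefficients(self):
        rng = np.random.default_rng(0)
        bmi = rng.uniform(18, 32, 20)
        e = rng.uniform(0.2, 0.8, 20)
        y = 100.0 + 0.5 * bmi + 10.0 * e
        records = [
            SubjectRecord(bmi=b, sbp_device=s, dbp_device=s - 40, e_peak=x, e_valley=x / 2)
            for b, s, x in zip(bmi, y, e)
        ]
        params = fit_regression(records, "SBP")
        assert np.allclose(params.gamma, (100.0, 0.5, 10.0), atol=1e-8)

    def test_matches_normal_equation_solution(self):
        records = generate_cohort(
            200, ALPHA_SBP, ALPHA_DBP, feature_range=(0.2, 0.8), noise_sd=3.0, seed=4
        )
        params = fit_regression(records, "SBP")
        X = np.column_stack(
            [np.ones(len(records)), [r.bmi for r in records], [r.e_peak for r in records]]
        )
        y = np.array([r.sbp_device for r in records])
        beta = np.linalg.inv(X.T @ X) @ X.T @ y  # explicit normal equations
        assert np.allclose(params.gamma, beta, atol=1e-8)

    def test_residuals_orthogonal_to_design_and_truth_covered(self):
        records = generate_cohort(
            200, ALPHA_SBP, ALPHA_DBP, feature_range=(0.2, 0.8), noise_sd=2.0, seed=5
        )
        # generator truth restated in regression form requires alpha2 small;
        # here just check OLS internals: residual orthogonality + plane fit
        params = fit_regression(records, "DBP")
        X = np.column_stack(
            [np.ones(len(records)), [r.bmi for r in records], [r.e_valley for r in records]]
        )
        y = np.array([r.dbp_device for r in records])
        resid = y - X @ np.array(params.gamma)
        assert np.max(np.abs(X.T @ resid)) < 1e-6

    def test_collinear_design_rejected(self):
        records = [
            SubjectRecord(bmi=25.0, sbp_device=120 + i, dbp_device=70, e_peak=0.5, e_valley=0.3)
            for i in range(5)
        ]  # BMI and feature both constant
        with pytest.raises(SingularMatrixError):
            fit_regression(records, "SBP")

    def test_too_few_records_rejected(self):
        records = generate_cohort(2, ALPHA_SBP, ALPHA_DBP, feature_range=(0.2, 0.8), seed=0)
        with pytest.raises(InsufficientDataError):
            fit_regression(records, "SBP")


class TestBMIIntervalLookup:
    TABLE = [
        BPFormulaParams(1.0, 0.0, 0.0, bmi_interval=(18.5, 24.0)),
        BPFormulaParams(2.0, 0.0, 0.0, bmi_interval=(24.0, 27.0)),
    ]

    def test_boundary_belongs_to_upper_interval(self):
        assert bmi_interval_lookup(24.0, self.TABLE).alpha0 == 2.0
        assert bmi_interval_lookup(23.999, self.TABLE).alpha0 == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(OutOfRangeError):
            bmi_interval_lookup(17.0, self.TABLE)

    @settings(derandomize=True, max_examples=100)
    @given(bmi=st.floats(min_value=18.5, max_value=26.999))
    def test_exactly_one_interval_matches(self, bmi):
        hits = [
            p for p in self.TABLE if p.bmi_interval[0] <= bmi < p.bmi_interval[1]
        ]
        assert len(hits) == 1
        assert bmi_interval_lookup(bmi, self.TABLE) is hits[0]
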