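"""Calibrators: constrained polynomial, Platt sigmoid, isotonic/PAV."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from calens.calibration import (
    CalibrationTrainingSet,
    apply_calibrator,
    calibrator_from_dict,
    fit_isotonic,
    fit_platt,
    fit_rpr,
    select_rpr_hyperparams,
)
from calens.errors import (
    ConfigError,
    DegenerateTrainingError,
    NotFittedError,
)


def _uniform_bernoulli(n, seed):
    rng = np.random.default_rng(seed)
    s = rng.uniform(0, 1, n)
    y = (rng.uniform(0, 1, n) < s).astype(int)
    return CalibrationTrainingSet(s, y)


def _check_rpr_constraints(cal, tol=1e-6):
    lo, hi = cal.score_range
    a = cal.coefficients
    assert np.abs(a).sum() <= cal.l1_bound + tol
    powers = np.arange(len(a))
    assert a @ lo**powers >= -tol
    assert a @ hi**powers <= 1 + tol
    grid = np.linspace(lo, hi, 201)
    deriv = (grid[:, None] ** np.clip(powers - 1, 0, None) * powers) @ a
    assert deriv.min() >= -tol


class TestRpr:
    def test_zero_l1_bound_forces_zero_polynomial(self):
        data = _uniform_bernoulli(50, 0)
        cal = fit_rpr(data, k=3, lam=0.0)
        assert np.allclose(cal.coefficients, 0.0, atol=1e-7)
        assert np.allclose(cal.predict(data.scores), 0.0, atol=1e-7)

    def test_exact_linear_interpolant(self):
        # targets on the identity line: a0=0, a1=1 is feasible (l1 = 1 <= 2)
        # and interpolates with zero residual, so it is the unique optimum
        s = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        data = CalibrationTrainingSet(s, s)
        cal = fit_rpr(data, k=1, lam=2.0)
        _check_rpr_constraints(cal)
        assert cal.coefficients[0] == pytest.approx(0.0, abs=1e-5)
        assert cal.coefficients[1] == pytest.approx(1.0, abs=1e-5)
        assert np.allclose(cal.predict(s), s, atol=1e-5)

    def test_recovers_identity_map(self):
        data = _uniform_bernoulli(2000, 1)
        cal = fit_rpr(data, k=5, lam=4.0)
        _check_rpr_constraints(cal)
        grid = np.linspace(*cal.score_range, 500)
        assert np.abs(cal.predict(grid) - grid).max() <= 0.05

    def test_degree_cap(self):
        with pytest.raises(ConfigError):
            fit_rpr(_uniform_bernoulli(50, 0), k=26, lam=4.0)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ConfigError):
            fit_rpr(_uniform_bernoulli(50, 0), k=3, lam=-1.0)

    def test_single_class_rejected(self):
        data = CalibrationTrainingSet([0.1, 0.5, 0.9], [1, 1, 1])
        with pytest.raises(DegenerateTrainingError):
            fit_rpr(data, k=2, lam=4.0)

    def test_serialization_round_trip(self):
        cal = fit_rpr(_uniform_bernoulli(200, 2), k=4, lam=4.0)
        clone = calibrator_from_dict(cal.to_dict())
        s = np.linspace(0, 1, 50)
        assert np.allclose(cal.predict(s), clone.predict(s))


class TestSelectRprHyperparams:
    def test_single_point_grid_returned(self):
        data = _uniform_bernoulli(200, 3)
        assert select_rpr_hyperparams(
            data, degrees=(5,), lambdas=(4.0,), seed=1
        ) == (5, 4.0)

    def test_deterministic_under_seed(self):
        data = _uniform_bernoulli(300, 4)
        grid = dict(degrees=(4, 6), lambdas=(1.0, 4.0))
        assert select_rpr_hyperparams(data, seed=9, **grid) == (
            select_rpr_hyperparams(data, seed=9, **grid)
        )

    def test_selected_model_no_worse_than_most_complex(self):
        # linear true map: the chosen (k, lam) must not lose to the most
        # complex grid corner by more than CV noise
        data = _uniform_bernoulli(600, 5)
        degrees, lambdas = (4, 8, 20), (4.0, 1024.0)
        k, lam = select_rpr_hyperparams(
            data, degrees=degrees, lambdas=lambdas, seed=2
        )

        def cv_err(kk, ll):
            from calens.calibration import _stratified_cv_folds

            folds = _stratified_cv_folds(data.labels, 3, 2)
            errs = []
            for val in folds:
                mask = np.ones(len(data), bool)
                mask[val] = False
                c = fit_rpr(
                    CalibrationTrainingSet(data.scores[mask], data.labels[mask]),
                    kk, ll,
                )
                errs.append(np.mean((c.predict(data.scores[val]) - data.labels[val]) ** 2))
            return np.mean(errs)

        assert cv_err(k, lam) <= cv_err(20, 1024.0) + 1e-9

    def test_too_small_set_rejected(self):
        with pytest.raises(ConfigError):
            select_rpr_hyperparams(_uniform_bernoulli(8, 0), n_folds=3)


class TestPlatt:
    def test_symmetric_configuration_maps_midpoint_to_half(self):
        scores = np.array([0.2] * 10 + [0.8] * 10)
        labels = np.array([0] * 10 + [1] * 10)
        cal = fit_platt(CalibrationTrainingSet(scores, labels))
        assert cal.predict(np.array([0.5]))[0] == pytest.approx(0.5, abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateTrainingError):
            fit_platt(CalibrationTrainingSet([0.2, 0.8], [1, 1]))

    def test_uninformative_scores_give_prevalence(self):
        rng = np.random.default_rng(6)
        s = rng.uniform(0, 1, 5000)
        y = (rng.uniform(0, 1, 5000) < 0.3).astype(int)
        cal = fit_platt(CalibrationTrainingSet(s, y))
        assert abs(cal.A) < 0.3
        preds = cal.predict(np.linspace(0.05, 0.95, 10))
        assert np.allclose(preds, 0.3, atol=0.03)

    def test_serialization_round_trip(self):
        cal = fit_platt(_uniform_bernoulli(500, 7))
        clone = calibrator_from_dict(cal.to_dict())
        s = np.linspace(0, 1, 50)
        assert np.allclose(cal.predict(s), clone.predict(s))


class TestIsotonic:
    def test_monotone_labels_are_their_own_fit(self):
        data = CalibrationTrainingSet([0.1, 0.2, 0.6, 0.9], [0, 0, 1, 1])
        cal = fit_isotonic(data)
        assert np.allclose(cal.predict(np.array([0.1, 0.2, 0.6, 0.9])), [0, 0, 1, 1])

    def test_violator_pooling_fixture(self):
        # brute-force monotone least squares on 4 points gives (0,.5,.5,1)
        data = CalibrationTrainingSet([0.1, 0.2, 0.3, 0.4], [0, 1, 0, 1])
        cal = fit_isotonic(data)
        assert np.allclose(cal.values, [0, 0.5, 0.5, 1])

    def test_two_point_reversal_pools_to_half(self):
        cal = fit_isotonic(CalibrationTrainingSet([0.1, 0.2], [1, 0]))
        assert np.allclose(cal.values, [0.5, 0.5])

    def test_tied_scores_pooled_before_pav(self):
        data = CalibrationTrainingSet([0.5, 0.5, 0.5, 0.9], [1, 0, 1, 1])
        cal = fit_isotonic(data)
        assert np.allclose(cal.breakpoints, [0.5, 0.9])
        assert np.allclose(cal.values, [2 / 3, 1.0])

    def test_below_range_clamps_to_first_value(self):
        data = CalibrationTrainingSet([0.1, 0.2, 0.3, 0.4], [0, 1, 0, 1])
        cal = fit_isotonic(data)
        assert cal.predict(np.array([0.05]))[0] == 0.0
        assert cal.predict(np.array([0.99]))[0] == 1.0

    def test_matches_sklearn_on_random_data(self, rng):
        # independent cross-check at the sample points
        from sklearn.isotonic import IsotonicRegression

        s = rng.uniform(0, 1, 200)
        y = rng.integers(0, 2, 200)
        ours = fit_isotonic(CalibrationTrainingSet(s, y)).predict(s)
        theirs = IsotonicRegression().fit(s, y).predict(s)
        assert np.allclose(ours, theirs, atol=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ConfigError):
            fit_isotonic(CalibrationTrainingSet([0.5], [1]))

    def test_serialization_round_trip(self):
        cal = fit_isotonic(_uniform_bernoulli(100, 8))
        clone = calibrator_from_dict(cal.to_dict())
        s = np.linspace(-0.2, 1.2, 50)
        assert np.allclose(cal.predict(s), clone.predict(s))


@pytest.fixture(scope="module")
def calibrators():
    data = _uniform_bernoulli(800, 9)
    return [
        fit_rpr(data, 5, 4.0),
        fit_platt(data),
        fit_isotonic(data),
    ]


class TestApplyCalibrator:
    def test_unfitted_rejected(self):
        with pytest.raises(NotFittedError):
            apply_calibrator(None, np.array([0.5]))

    def test_outputs_in_unit_interval(self, calibrators, rng):
        s = rng.uniform(-0.5, 1.5, 300)  # includes out-of-range queries
        for cal in calibrators:
            out = apply_calibrator(cal, s)
            assert out.min() >= 0.0 and out.max() <= 1.0

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(raw=st.lists(st.floats(0.0, 1.0), min_size=2, max_size=50))
    def test_monotone_in_input(self, calibrators, raw):
        s = np.sort(np.asarray(raw))
        for cal in calibrators:
            out = apply_calibrator(cal, s)
            assert np.all(np.diff(out) >= -1e-9)
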