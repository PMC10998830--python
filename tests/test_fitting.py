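"""Fitting engine: exact recovery, SEs, model comparison, KIE statistics."""

import numpy as np
import pytest
from sklearn.base import clone

from hekie import fitting, models
from hekie.fitting import (
    MMRTModel,
    MichaelisMentenModel,
    TitrationModel,
    TwoStepBurstModel,
    ValueWithError,
    compare_models,
    initial_guess,
    propagate_ratio,
    t_test_kcat,
)


def _exact_case(model_id):
    """(x, y, truth, extra estimator kwargs) with y generated noise-free."""
    if model_id == "melt":
        x = np.arange(25.0, 94.0, 1.0)
        truth = {"ll": 0.1, "ul": 1.3, "tm": 55.0, "c": 2.1}
        y = models.melt_fraction(x, **truth)
        return x, y, truth, {}
    if model_id == "michaelis":
        x = np.array([0.025, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6])
        truth = {"kcat": 2.95, "km": 0.111}
        y = models.mm_rate(x, **truth)
        return x, y, truth, {}
    if model_id == "titration":
        x = np.array([0.0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.5])
        truth = {"vmax": 3.0, "kd_app": 0.09}
        y = models.titration_rate(x, truth["vmax"], truth["kd_app"], 0.04)
        return x, y, truth, {"g_conc": 0.04}
    if model_id == "dose_response":
        x = np.array([0.0, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0])
        truth = {"ic50": 11.0, "hill_n": 1.8}
        y = models.dose_response(x, **truth)
        return x, y, truth, {}
    if model_id == "two_step":
        x = np.linspace(0.0, 1.0, 120)[1:]
        truth = {"es": 80.0, "k2": 30.0, "k3": 8.0}
        y = models.two_step_product(x, **truth)
        return x, y, truth, {}
    if model_id == "viscosity":
        x = np.array([1.0, 1.1, 1.2, 1.3, 1.4, 1.5])
        truth = {"m": 0.97}
        y = models.viscosity_ratio(x, **truth)
        return x, y, truth, {}
    if model_id == "eyring":
        x = np.arange(278.0, 319.0, 5.0)
        truth = {"dh": 60000.0, "ds": -35.0}
        y = models.eyring_log_rate(x, **truth)
        return x, y, truth, {}
    if model_id == "mmrt":
        x = np.arange(278.0, 319.0, 5.0)
        truth = {"dh_t0": 60000.0, "ds_t0": -35.0, "dcp": -3000.0}
        y = models.mmrt_log_rate(x, **truth, t0=298.0)
        return x, y, truth, {"t0": 298.0}
    if model_id == "single_exp":
        x = np.linspace(0.0, 0.2, 100)[1:]
        truth = {"a": 80.0, "k_sto": 44.0}
        y = models.single_exp_product(x, **truth)
        return x, y, truth, {}
    raise AssertionError(model_id)


ALL_MODELS = list(fitting.MODEL_REGISTRY)


@pytest.mark.parametrize("model_id", ALL_MODELS)
def test_exact_data_recovery(model_id):
    """Noise-free synthetic data returns the generating parameters."""
    x, y, truth, kwargs = _exact_case(model_id)
    res = fitting.fit(model_id, x, y, **kwargs)
    assert res.converged
    for name, value in truth.items():
        assert res.estimates[name] == pytest.approx(value, rel=1e-6, abs=1e-9)
        # and the residual uncertainty collapses with the residuals
        assert res.standard_errors[name] == pytest.approx(0.0, abs=1e-4 * max(abs(value), 1))


@pytest.mark.parametrize("model_id", ALL_MODELS)
def test_fit_invariant_to_point_order(model_id, rng):
    x, y, _, kwargs = _exact_case(model_id)
    noisy = y + rng.normal(0, 0.01 * np.ptp(y), size=y.shape)
    res1 = fitting.fit(model_id, x, noisy, **kwargs)
    perm = rng.permutation(x.size)
    res2 = fitting.fit(model_id, x[perm], noisy[perm], **kwargs)
    for name in res1.param_names:
        assert res2.estimates[name] == pytest.approx(res1.estimates[name], rel=1e-6)


def test_two_step_fit_symmetric_under_rate_exchange():
    x, y, truth, _ = _exact_case("two_step")
    est = TwoStepBurstModel(init={"k2": 5.0, "k3": 40.0}).fit(x, y)
    fast, slow = est.rates_()
    assert fast == pytest.approx(30.0, rel=1e-5)
    assert slow == pytest.approx(8.0, rel=1e-5)


def test_two_step_fixed_amplitude_mode():
    x, y, _, _ = _exact_case("two_step")
    est = TwoStepBurstModel(fix_amplitude=80.0).fit(x, y)
    assert est.params_["es"] == 80.0
    assert est.se_["es"] == 0.0
    assert sorted([est.params_["k2"], est.params_["k3"]]) == pytest.approx([8.0, 30.0], rel=1e-6)


def test_estimators_expose_sklearn_api():
    est = MichaelisMentenModel()
    params = est.get_params()
    assert "init" in params and "max_restarts" in params
    cloned = clone(est)
    x, y, _, _ = _exact_case("michaelis")
    cloned.fit(x.reshape(-1, 1), y)  # column input accepted
    assert cloned.kcat_ == pytest.approx(2.95, rel=1e-6)
    pred = cloned.predict(x)
    np.testing.assert_allclose(pred, y, rtol=1e-6)
    # R^2 through the sklearn mixin
    assert cloned.score(x, y) == pytest.approx(1.0)


def test_fit_refuses_underdetermined_and_degenerate_data():
    with pytest.raises(ValueError):
        fitting.fit("michaelis", [0.1, 0.2], [1.0, 1.5])
    with pytest.raises(ValueError):
        fitting.fit("michaelis", [0.1, 0.2, 0.4, 0.8], [1.0, 1.0, 1.0, 1.0])


def test_nonconvergence_is_flagged_not_raised():
    # single-exponential model cannot chase a decreasing, negative signal;
    # whatever the solver returns must carry an explicit convergence verdict
    x = np.linspace(0.01, 1.0, 30)
    y = -5.0 + np.cos(40 * x)
    res = fitting.fit("single_exp", x, y)
    assert res.converged in (True, False)
    assert res.message


@pytest.mark.parametrize(
    "model_id, expectation",
    [
        ("michaelis", lambda x, y, g: g["km"] >= x.min() and g["km"] <= x.max()),
        ("melt", lambda x, y, g: x.min() <= g["tm"] <= x.max()),
    ],
)
def test_initial_guess_heuristics_land_in_range(model_id, expectation):
    x, y, _, kwargs = _exact_case(model_id)
    guess = initial_guess(model_id, x, y, **kwargs)
    assert expectation(x, y, guess)


def test_initial_guess_two_step_tail_rate_within_factor_three():
    x, y, _, _ = _exact_case("two_step")
    guess = initial_guess("two_step", x, y)
    slow = min(guess["k2"], guess["k3"])
    assert 8.0 / 3.0 <= slow <= 8.0 * 3.0


def test_initial_guess_rejects_degenerate():
    with pytest.raises(ValueError):
        initial_guess("michaelis", [0.1, 0.2, 0.4], [1.0, 1.0, 1.0])


# --- model comparison -------------------------------------------------------


def test_compare_models_requires_identical_data():
    x, y, _, _ = _exact_case("single_exp")
    a = fitting.fit("single_exp", x, y)
    b = fitting.fit("two_step", x[:-1], y[:-1])
    with pytest.raises(ValueError):
        compare_models([a, b])


def test_lag_data_select_two_step_and_exponential_data_select_single_exp(rng):
    t = np.linspace(0.0, 1.0, 200)[1:]
    n_two = n_one = 0
    reps = 20
    for i in range(reps):
        noise = rng.normal(0, 0.8, size=t.size)
        y_lag = models.two_step_product(t, 80.0, 12.0, 9.0) + noise
        y_exp = models.single_exp_product(t, 80.0, 10.0) + noise
        fits_lag = [fitting.fit("two_step", t, y_lag), fitting.fit("single_exp", t, y_lag)]
        fits_exp = [fitting.fit("two_step", t, y_exp), fitting.fit("single_exp", t, y_exp)]
        n_two += compare_models(fits_lag).selected_id == "two_step"
        n_one += compare_models(fits_exp).selected_id == "single_exp"
    assert n_two >= 0.95 * reps
    assert n_one >= 0.95 * reps


def test_curved_eyring_rejected_by_f_test(rng):
    t_grid = np.tile(np.arange(278.0, 319.0, 5.0), 2)
    y_true = models.mmrt_log_rate(t_grid, 60000.0, -35.0, -3000.0)
    y = y_true + rng.normal(0, 0.03, size=t_grid.size)
    lin = fitting.fit("eyring", t_grid, y)
    cur = fitting.fit("mmrt", t_grid, y, t0=298.0)
    cmp_ = compare_models([lin, cur], nested=True)
    assert cmp_.selected_id == "mmrt"
    assert cmp_.p_value < 0.05


def test_linear_eyring_retained_when_no_curvature(rng):
    t_grid = np.tile(np.arange(278.0, 319.0, 5.0), 2)
    y = models.eyring_log_rate(t_grid, 60000.0, -35.0) + rng.normal(0, 0.03, t_grid.size)
    lin = fitting.fit("eyring", t_grid, y)
    cur = fitting.fit("mmrt", t_grid, y, t0=298.0)
    assert compare_models([lin, cur], nested=True).selected_id == "eyring"


# --- statistics -------------------------------------------------------------


def test_propagate_ratio_reproduces_printed_kie_table():
    cases = [
        ((2.95, 0.03), (2.95, 0.03), (1.00, 0.01)),
        ((2.95, 0.03), (2.87, 0.06), (1.03, 0.02)),
        ((2.95, 0.03), (2.27, 0.06), (1.30, 0.04)),
        ((2.95, 0.03), (2.05, 0.03), (1.44, 0.03)),
        ((2.95, 0.03), (1.92, 0.04), (1.54, 0.04)),
    ]
    for num, den, (r_exp, se_exp) in cases:
        r = propagate_ratio(num, den)
        assert round(r.value, 2) == pytest.approx(r_exp)
        assert round(r.se, 2) == pytest.approx(se_exp)


def test_propagate_ratio_self_ratio_and_domain():
    r = propagate_ratio((2.95, 0.03), (2.95, 0.03))
    assert r.value == 1.0
    assert r.se == pytest.approx(np.sqrt(2) * 0.03 / 2.95)
    with pytest.raises(ValueError):
        propagate_ratio((1.0, 0.1), (0.0, 0.1))


def test_propagate_ratio_matches_monte_carlo(rng):
    a, sa, b, sb = 2.95, 0.06, 1.92, 0.08  # CVs ~2-4%
    draws = rng.normal(a, sa, 100_000) / rng.normal(b, sb, 100_000)
    mc_se = draws.std(ddof=1)
    r = propagate_ratio((a, sa), (b, sb))
    assert r.se == pytest.approx(mc_se, rel=0.05)


def test_t_test_worked_examples():
    heavy = t_test_kcat(ValueWithError(2.95, 0.03, 16), ValueWithError(1.92, 0.04, 16))
    assert heavy.t == pytest.approx(20.6, abs=0.05)
    assert heavy.p < 0.01
    light = t_test_kcat(ValueWithError(2.95, 0.03, 16), ValueWithError(2.87, 0.06, 16))
    assert light.t == pytest.approx(1.19, abs=0.02)
    assert light.p > 0.01
    same = t_test_kcat(ValueWithError(2.0, 0.05, 10), ValueWithError(2.0, 0.05, 10))
    assert same.t == 0.0 and same.p == pytest.approx(1.0)


def test_t_test_requires_valid_errors_and_dof():
    with pytest.raises(ValueError):
        t_test_kcat(ValueWithError(1.0, 0.0, 10), ValueWithError(1.0, 0.1, 10))
    with pytest.raises(ValueError):
        t_test_kcat(ValueWithError(1.0, 0.1, None), ValueWithError(1.0, 0.1, 10))


def test_monte_carlo_se_calibration(rng):
    """Reported fitting errors track the replicate scatter of estimates."""
    x = np.tile(np.array([0.025, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6]), 2)
    y_true = models.mm_rate(x, 2.95, 0.111)
    sd = 0.02 * y_true.max()
    kcats, ses = [], []
    for _ in range(100):
        res = fitting.fit("michaelis", x, y_true + rng.normal(0, sd, x.size))
        kcats.append(res.estimates["kcat"])
        ses.append(res.standard_errors["kcat"])
    assert np.median(np.abs(np.array(kcats) - 2.95)) < np.median(ses) * 1.2
    assert np.std(kcats, ddof=1) == pytest.approx(np.median(ses), rel=0.3)
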