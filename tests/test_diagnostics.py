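import numpy as np
import pytest

from rackstack import (
    CalibrationResult,
    ValidationError,
    calibrate,
    cronbach_alpha,
    fit_statistics,
    psychometric_panel,
    separation_reliability,
    simulate_responses,
    variance_explained,
)
from rackstack.calibration import result_from_parameters

from conftest import make_matrix


# ---------------------------------------------------------------------------
# separation / reliability
# ---------------------------------------------------------------------------

def test_separation_reliability_closed_form():
    # SD = 1, all se = 0.6: T = 0.64, R = 0.64, G = 0.8/0.6
    rng = np.random.default_rng(1)
    measures = rng.normal(0, 1, 2000)
    measures = (measures - measures.mean()) / measures.std(ddof=1)  # SD exactly 1
    rel, sep = separation_reliability(measures, np.full(2000, 0.6))
    assert rel == pytest.approx(0.64, abs=1e-9)
    assert sep == pytest.approx(0.8 / 0.6, abs=1e-9)


def test_zero_error_variance_caps_reliability():
    with pytest.warns(RuntimeWarning):
        rel, _ = separation_reliability([0.0, 1.0, 2.0], [0.0, 0.0, 0.0])
    assert rel == 1.0


def test_no_true_spread_gives_zero():
    rel, sep = separation_reliability([0.5, 0.5, 0.5], [0.4, 0.4, 0.4])
    assert (rel, sep) == (0.0, 0.0)
    # error variance exceeding observed variance also truncates to zero
    rel, sep = separation_reliability([0.0, 0.1, -0.1], [2.0, 2.0, 2.0])
    assert (rel, sep) == (0.0, 0.0)


def test_reliability_separation_identity(infant_pre_cal):
    panel = psychometric_panel(infant_pre_cal)
    for r, g in ((panel.person_reliability, panel.person_separation),
                 (panel.item_reliability, panel.item_separation)):
        assert r == pytest.approx(g**2 / (1 + g**2), abs=1e-9)


# ---------------------------------------------------------------------------
# Cronbach's alpha
# ---------------------------------------------------------------------------

def test_alpha_parallel_items_is_one():
    col = np.array([0., 1., 2., 1., 0., 2.])
    mat = make_matrix(np.column_stack([col, col, col]))
    assert cronbach_alpha(mat) == pytest.approx(1.0, abs=1e-12)


def test_alpha_hand_worked_table():
    vals = np.array([[0, 1, 2], [1, 1, 1], [2, 2, 2], [0, 0, 1]], dtype=float)
    # definitional formula worked by hand: k=3, item variances (sample)
    # 0.9167+0.6667+0.3333 = 1.9167; total scores (3,3,6,1) variance 4.25
    # alpha = 1.5 * (1 - 1.9167/4.25)
    expected = 1.5 * (1 - (11 / 12 + 2 / 3 + 1 / 3) / 4.25)
    assert cronbach_alpha(make_matrix(vals)) == pytest.approx(expected, abs=1e-12)


def test_alpha_independent_items_near_zero():
    rng = np.random.default_rng(42)
    vals = rng.integers(0, 3, size=(10_000, 8)).astype(float)
    assert abs(cronbach_alpha(make_matrix(vals))) < 0.05


def test_alpha_zero_total_variance_errors():
    mat = make_matrix(np.array([[1., 1.], [0., 2.], [2., 0.]]))
    with pytest.raises(ValidationError):
        cronbach_alpha(mat)


def test_alpha_uses_listwise_complete_persons():
    vals = np.array([[0, 1, 2], [1, 1, 1], [2, 2, 2], [0, 0, 1]], dtype=float)
    holed = vals.copy()
    holed[1, 2] = np.nan
    a_full = cronbach_alpha(make_matrix(vals[[0, 2, 3]][:, :]))
    a_holed = cronbach_alpha(make_matrix(holed))
    assert a_holed == pytest.approx(a_full, abs=1e-12)


# ---------------------------------------------------------------------------
# fit statistics
# ---------------------------------------------------------------------------

def test_infit_near_one_under_the_model():
    rng = np.random.default_rng(5)
    theta = rng.normal(0, 1.5, 1000)
    delta = np.linspace(-2, 2, 13)
    data = simulate_responses(theta, delta, (-1.0, 1.0), rng)
    cal = calibrate(data)
    _, items = fit_statistics(cal)
    assert items["infit"].mean() == pytest.approx(1.0, abs=0.1)
    assert items["outfit"].mean() == pytest.approx(1.0, abs=0.15)


def test_random_responder_shows_high_outfit():
    rng = np.random.default_rng(9)
    theta = rng.normal(0, 1.0, 300)
    delta = np.linspace(-2, 2, 13)
    data = simulate_responses(theta, delta, (-1.0, 1.0), rng)
    data.values[0] = rng.integers(0, 3, 13)  # guessing person
    cal = calibrate(data)
    persons, _ = fit_statistics(cal)
    outfit = persons["outfit"]
    assert outfit.iloc[0] > np.median(outfit)


def test_perfect_reproduction_gives_zero_fit(mat_5x4):
    cal = calibrate(mat_5x4)
    fake = CalibrationResult(
        params=cal.params, expected=mat_5x4.values.copy(),
        resid_var=cal.resid_var, std_resid=np.zeros_like(mat_5x4.values),
        converged=True, n_iter=1, max_residual=0.0, data=mat_5x4)
    persons, items = fit_statistics(fake)
    assert (persons == 0).all().all()
    assert (items == 0).all().all()


# ---------------------------------------------------------------------------
# variance explained / residual contrast
# ---------------------------------------------------------------------------

def test_no_measure_spread_explains_nothing():
    rng = np.random.default_rng(2)
    theta = np.zeros(100)
    delta = np.zeros(6)
    data = simulate_responses(theta, delta, (-1.0, 1.0), rng,
                              item_ids=[f"i{k}" for k in range(6)])
    from rackstack import RaschParameters
    params = RaschParameters(data.person_ids, data.item_ids, theta, delta,
                             np.array([-1.0, 1.0]), np.ones(100), np.ones(6),
                             np.zeros(100, bool), np.zeros(6, bool))
    cal = result_from_parameters(data, params)
    raw_pct, _, _ = variance_explained(cal)
    assert raw_pct == pytest.approx(0.0, abs=1e-9)


def test_wide_ability_spread_explains_over_forty_percent():
    rng = np.random.default_rng(3)
    theta = rng.normal(0, 3.0, 400)
    delta = np.linspace(-2, 2, 11)
    data = simulate_responses(theta, delta, (-1.0, 1.0), rng)
    cal = calibrate(data)
    raw_pct, _, _ = variance_explained(cal)
    assert raw_pct > 40.0


def test_first_contrast_near_one_for_noise_residuals():
    # independent residuals: lambda_1 ~ 1 + O(sqrt(I/N))
    rng = np.random.default_rng(7)
    n, i = 500, 13
    z = rng.standard_normal((n, i))
    dummy = CalibrationResult(
        params=None, expected=np.full((n, i), 1.0),
        resid_var=np.full((n, i), 0.5), std_resid=z,
        converged=True, n_iter=1, max_residual=0.0, data=None)
    _, lam1, _ = variance_explained(dummy)
    assert 1.0 <= lam1 <= 1.0 + 3.0 * np.sqrt(i / n)


def test_contrast_undefined_below_three_items():
    rng = np.random.default_rng(8)
    theta = rng.normal(0, 1, 50)
    data = simulate_responses(theta, np.array([-0.5, 0.5]), (-1.0, 1.0), rng)
    cal = calibrate(data)
    _, lam1, pct = variance_explained(cal)
    assert np.isnan(lam1) and np.isnan(pct)


def test_panel_is_deterministic(infant_pre_cal):
    p1 = psychometric_panel(infant_pre_cal)
    p2 = psychometric_panel(infant_pre_cal)
    assert p1 == p2
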