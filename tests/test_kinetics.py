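"""Drying-curve kinetics: basis conversion, rate analysis and the
first-term sphere inverse problem."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from beandry import kinetics as kin
from beandry import reference as ref
from beandry import synthetic


# ---------------------------------------------------------------------------
# moisture basis and rate analysis
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("value, frm, to, expected", [
    (45.0, "wet", "dry", 81.8182),   # initial moisture of the study beans
    (12.0, "wet", "dry", 13.6364),   # final moisture target
    (50.0, "dry", "wet", 33.3333),
])
def test_convert_basis_examples(value, frm, to, expected):
    assert kin.convert_basis(value, frm, to) == pytest.approx(expected, abs=1e-4)


@settings(derandomize=True, max_examples=50)
@given(st.floats(min_value=0.5, max_value=99.5))
def test_convert_basis_round_trip(w):
    d = kin.convert_basis(w, "wet", "dry")
    assert kin.convert_basis(d, "dry", "wet") == pytest.approx(w, rel=1e-12)


def test_convert_basis_rejects_saturated_wet_basis():
    with pytest.raises(ValueError):
        kin.convert_basis(100.0, "wet", "dry")


def test_drying_rate_finite_differences():
    curve = kin.DryingCurve(40.0, [0, 2, 4], [40, 30, 25])
    mid, rate = kin.drying_rate(curve)
    np.testing.assert_allclose(rate, [-5.0, -2.5])
    np.testing.assert_allclose(mid, [35.0, 27.5])


def test_drying_rate_constant_curve_is_zero():
    curve = kin.DryingCurve(40.0, [0, 1, 2, 3], [20.0] * 4)
    _, rate = kin.drying_rate(curve)
    np.testing.assert_array_equal(rate, 0.0)


def test_drying_rate_matches_analytic_derivative_at_midpoints():
    # exponential decay: central differences are O(dt^2) accurate at midpoints
    k = 0.11
    t = np.arange(0, 10.01, 0.25)
    m = 12 + 60 * np.exp(-k * t)
    curve = kin.DryingCurve(40.0, t, m)
    mid_t = 0.5 * (t[:-1] + t[1:])
    _, rate = kin.drying_rate(curve)
    analytic = -k * 60 * np.exp(-k * mid_t)
    assert np.max(np.abs(rate - analytic)) < 0.01 * np.max(np.abs(analytic))


def _two_regime_curve(m_crit=23.0, const_rate=-2.0, m0=40.0, meq=12.0):
    """Constant drying rate above m_crit, rate falling linearly to 0 below."""
    times, m = [0.0], [m0]
    dt = 0.5
    while m[-1] > meq + 0.05:
        mm = m[-1]
        rate = const_rate if mm >= m_crit else const_rate * (mm - meq) / (m_crit - meq)
        m.append(mm + rate * dt)
        times.append(times[-1] + dt)
    return kin.DryingCurve(40.0, times, m)


def test_critical_moisture_recovers_planted_breakpoint():
    for planted in (22.97, 23.83):  # bracketing the reported transition range
        res = kin.critical_moisture(_two_regime_curve(m_crit=planted))
        assert res.detected
        assert abs(res.critical_moisture - planted) < 1.0  # one sampling interval


def test_critical_moisture_reports_no_transition_on_single_slope():
    t = np.arange(0, 10.0, 1.0)
    curve = kin.DryingCurve(40.0, t, 40 - 2.5 * t)
    res = kin.critical_moisture(curve)
    assert not res.detected and res.critical_moisture is None


def test_critical_moisture_needs_four_points():
    with pytest.raises(ValueError):
        kin.critical_moisture(kin.DryingCurve(40.0, [0, 1, 2], [40, 30, 25]))


def test_equilibrium_moisture_minimum_and_plateau_entry():
    curve = kin.DryingCurve(40.0, [0, 1, 2, 3, 4], [40, 20, 13, 12, 12])
    meq, t_at = kin.equilibrium_moisture(curve)
    assert meq == 12 and t_at == 3
    dec = kin.DryingCurve(40.0, [0, 1, 2], [40, 30, 25])
    assert kin.equilibrium_moisture(dec)[0] == 25


def test_equilibrium_moisture_with_noise_near_truth():
    spec = synthetic.CurveGenSpec(noise_sd=0.1, seed=3, duration_h=80.0,
                                  meq=12.0, n_terms=1)
    sim = synthetic.gen_drying_curve(spec)
    meq, _ = kin.equilibrium_moisture(sim.curve)
    assert abs(meq - 12.0) < 0.3  # 3 sigma


# ---------------------------------------------------------------------------
# moisture ratio and the linearized fit
# ---------------------------------------------------------------------------

def test_moisture_ratio_values_and_units():
    curve = kin.DryingCurve(30.0, [0, 5], [80.0, 46.0])
    series = kin.moisture_ratio(curve, meq=12.0)
    assert series.log_ratio[0] == 0.0
    assert series.log_ratio[1] == pytest.approx(math.log(0.5), abs=1e-9)
    assert series.times_s[1] == 5 * 3600.0


def test_moisture_ratio_drops_points_at_meq(caplog):
    curve = kin.DryingCurve(30.0, [0, 5, 10], [80.0, 46.0, 12.0])
    with caplog.at_level("WARNING"):
        series = kin.moisture_ratio(curve, meq=12.0)
    assert series.times_s.size == 2
    assert "dropped 1" in caplog.text


def test_moisture_ratio_requires_m0_above_meq():
    curve = kin.DryingCurve(30.0, [0, 5], [80.0, 46.0])
    with pytest.raises(ValueError):
        kin.moisture_ratio(curve, meq=85.0)


def test_linearized_fit_exact_line():
    a, b = -1.46982169e-5, -0.59745164
    t_h = np.arange(1, 30.0, 2.0)
    m = 12 + (80 - 12) * np.exp(a * t_h * 3600 + b)
    curve = kin.DryingCurve(30.0, t_h, m)
    fit = kin.linearized_fit(kin.moisture_ratio(curve, meq=12.0, m0=80.0))
    assert fit.slope_a == pytest.approx(a, rel=1e-10)
    assert fit.intercept_b == pytest.approx(b, rel=1e-10)
    assert fit.mse == pytest.approx(0.0, abs=1e-18)


def test_linearized_fit_matches_grid_search_oracle():
    t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    y = np.array([0.1, -0.8, -2.2, -2.9, -4.1])
    series = kin.MoistureRatioSeries(times_s=t, log_ratio=y, m0=80, meq=12)
    fit = kin.linearized_fit(series)
    a_grid = np.linspace(fit.slope_a - 0.5, fit.slope_a + 0.5, 401)
    b_grid = np.linspace(fit.intercept_b - 0.5, fit.intercept_b + 0.5, 401)
    sse = ((a_grid[:, None, None] * t + b_grid[None, :, None] - y) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    assert a_grid[i] == pytest.approx(fit.slope_a, abs=(a_grid[1] - a_grid[0]))
    assert b_grid[j] == pytest.approx(fit.intercept_b, abs=(b_grid[1] - b_grid[0]))


def test_slope_magnitude_increases_with_temperature_on_refit():
    slopes = []
    for temp, (a, b) in sorted(ref.DRYING_LINE_COEFFS.items()):
        t_h = np.arange(1.0, ref.DRYING_TIMES_H[temp], 2.0)
        m = 13.6 + (81.8 - 13.6) * np.exp(a * t_h * 3600 + b)
        fit = kin.linearized_fit(
            kin.moisture_ratio(kin.DryingCurve(temp, t_h, m), 13.6, m0=81.8))
        slopes.append(fit.slope_a)
    assert all(s2 < s1 for s1, s2 in zip(slopes, slopes[1:]))  # more negative


# ---------------------------------------------------------------------------
# eigenvalue algebra
# ---------------------------------------------------------------------------

def test_shape_intercept_reference_pairs():
    assert kin.shape_intercept(2.256442) == pytest.approx(-0.597452, abs=1e-6)
    assert kin.shape_intercept(2.058683) == pytest.approx(-0.444017, abs=1e-6)


def test_shape_intercept_limit_and_monotonicity():
    assert abs(kin.shape_intercept(1e-4)) < 1e-6  # b -> 0 as mu -> 0+
    grid = np.linspace(0.01, math.pi - 0.01, 1000)
    vals = [kin.shape_intercept(m) for m in grid]
    assert all(v2 < v1 for v1, v2 in zip(vals, vals[1:]))


def test_shape_intercept_domain():
    for mu in (0.0, math.pi, 4.0, -1.0):
        with pytest.raises(ValueError):
            kin.shape_intercept(mu)


@pytest.mark.parametrize("b, mu_expected", [
    (-0.59745164, 2.256442),
    (-0.67151457, 2.333156),
])
def test_solve_mu_reference_intercepts(b, mu_expected):
    assert kin.solve_mu_from_intercept(b) == pytest.approx(mu_expected, abs=1e-6)


def test_solve_mu_inverse_identity():
    for b in np.arange(-3.0, -0.009, 0.1):
        mu = kin.solve_mu_from_intercept(b)
        assert kin.shape_intercept(mu) == pytest.approx(b, abs=1e-10)


def test_solve_mu_rejects_nonnegative_intercept():
    with pytest.raises(ValueError):
        kin.solve_mu_from_intercept(0.1)


def test_biot_from_mu_values_and_limits():
    assert kin.biot_from_mu(2.256442) == pytest.approx(2.845864, abs=1e-6)
    assert kin.biot_from_mu(math.pi / 2) == pytest.approx(1.0, rel=1e-12)
    mu = 1e-4
    assert kin.biot_from_mu(mu) == pytest.approx(mu ** 2 / 3, rel=1e-4)
    grid = np.linspace(0.01, math.pi - 0.01, 1000)
    vals = [kin.biot_from_mu(m) for m in grid]
    assert all(v2 > v1 for v1, v2 in zip(vals, vals[1:]))


@pytest.mark.parametrize("biot", [0.5, 2.0925, 2.8459, 10.0])
def test_roots_bracketing_and_scipy_cross_check(biot):
    roots = kin.roots_for_biot(biot, 6).roots
    for n, mu in enumerate(roots, start=1):
        assert (n - 1) * math.pi < mu < n * math.pi
        # independent solver on the same bracket
        oracle = brentq(lambda m: 1 - m / math.tan(m) - biot,
                        (n - 1) * math.pi + 1e-9, n * math.pi - 1e-9)
        assert mu == pytest.approx(oracle, abs=1e-10)
    assert np.all(np.diff(roots) > 0)


def test_roots_dirichlet_limit():
    mu1 = kin.roots_for_biot(1e8, 1).roots[0]
    assert abs(mu1 - math.pi) < 1e-3


def test_d_eff_and_h_m_algebra():
    d = kin.d_eff_from_slope(-1.46982169e-5, 2.256442, 3.968e-4)
    assert d == pytest.approx(4.5453e-13, rel=1e-4)
    assert kin.d_eff_from_slope(-1e-5, 2.0, 2 * 3.968e-4) == pytest.approx(
        4 * kin.d_eff_from_slope(-1e-5, 2.0, 3.968e-4), rel=1e-12)
    assert kin.h_m_from(1.0, 5e-13, 5e-13) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        kin.d_eff_from_slope(1e-5, 2.0, 3.968e-4)


def test_transport_params_internal_consistency():
    p = kin.transport_from_line(-2.48775171e-5, -0.44401679, ref.BEAN_RADIUS_M)
    assert abs(1 - p.mu / math.tan(p.mu) - p.biot) < 1e-9
    assert p.h_m * p.radius_L == pytest.approx(p.biot * p.d_eff, rel=1e-14)


# ---------------------------------------------------------------------------
# full estimation pipeline
# ---------------------------------------------------------------------------

def test_estimate_transport_noise_free_first_term_recovery():
    spec = synthetic.CurveGenSpec(d_eff_true=5e-13, biot_true=3.0, n_terms=1,
                                  noise_sd=0.0, duration_h=40.0)
    sim = synthetic.gen_drying_curve(spec)
    est = kin.estimate_transport(sim.curve, spec.meq, spec.radius_L, m0=spec.m0)
    assert est.d_eff == pytest.approx(5e-13, rel=0.01)
    assert est.biot == pytest.approx(3.0, rel=0.01)


def test_estimate_transport_noisy_monte_carlo():
    # noise on the log-ratio scale ~0.2: estimates stay within 15% of truth
    spec0 = synthetic.CurveGenSpec(d_eff_true=5e-13, biot_true=3.0, n_terms=1,
                                   noise_sd=0.0, duration_h=40.0)
    d_errs, b_errs = [], []
    for seed in range(100):
        sim = synthetic.gen_drying_curve(
            synthetic.CurveGenSpec(d_eff_true=5e-13, biot_true=3.0, n_terms=1,
                                   noise_sd=0.2, duration_h=40.0, seed=seed))
        est = kin.estimate_transport(sim.curve, spec0.meq, spec0.radius_L,
                                     m0=spec0.m0)
        d_errs.append(abs(est.d_eff - 5e-13) / 5e-13)
        b_errs.append(abs(est.biot - 3.0) / 3.0)
    assert np.median(d_errs) < 0.15 and np.median(b_errs) < 0.15


def test_series_phi_first_term_dominates_at_large_fourier():
    one = kin.series_phi(1.0, 2.0, 3.0, n_terms=1)
    many = kin.series_phi(1.0, 2.0, 3.0, n_terms=50)
    assert one / many == pytest.approx(1.0, abs=1e-6)


def test_series_phi_initial_condition_converges_slowly():
    partial = [abs(kin.series_phi(1.0, 0.0, 3.0, n) - 1.0)
               for n in (10, 50, 200)]
    assert partial[0] > partial[1] > partial[2]
    assert partial[2] < 0.05


def test_series_phi_center_uses_sinc_limit():
    val = kin.series_phi(0.0, 0.5, 3.0, n_terms=20)
    assert np.isfinite(val) and val > 0
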