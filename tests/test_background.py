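"""Background estimation: rolling mean, check loss, spline basis, quantile fit."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.interpolate import CubicSpline

import nearsource as ns
from nearsource.background import ns_basis_from_knots


# ---------------------------------------------------------------- rolling mean

def test_rolling_mean_constant_series_unchanged():
    t = np.arange(100.0)
    out = ns.rolling_mean(np.full(100, 5.0), t, window_s=10.0)
    assert np.allclose(out, 5.0)


def test_rolling_mean_wide_window_pools_everything():
    out = ns.rolling_mean(np.array([0.0, 10.0]), np.array([0.0, 1.0]), window_s=10.0)
    assert np.allclose(out, [5.0, 5.0])


def test_rolling_mean_matches_naive_double_loop():
    rng = np.random.default_rng(0)
    t = np.sort(rng.uniform(0, 500, 1000))
    v = rng.normal(size=1000)
    v[rng.choice(1000, 50, replace=False)] = np.nan
    out = ns.rolling_mean(v, t, window_s=10.0)
    for i in range(0, 1000, 37):
        sel = np.abs(t - t[i]) <= 5.0
        vals = v[sel]
        vals = vals[np.isfinite(vals)]
        expect = vals.mean() if vals.size else np.nan
        assert np.isclose(out[i], expect, equal_nan=True)


def test_rolling_mean_all_missing_window_gives_nan():
    v = np.array([np.nan, np.nan, 1.0])
    t = np.array([0.0, 1.0, 100.0])
    out = ns.rolling_mean(v, t, window_s=2.0)
    assert np.isnan(out[0]) and np.isnan(out[1]) and out[2] == 1.0


# ------------------------------------------------------------------ check loss

@pytest.mark.parametrize(
    "z,tau,expected",
    [(2.0, 0.1, 0.2), (-2.0, 0.1, 1.8), (0.0, 0.3, 0.0), (0.0, 0.9, 0.0)],
)
def test_check_loss_values(z, tau, expected):
    assert ns.check_loss(z, tau) == pytest.approx(expected)


@given(st.floats(-1e6, 1e6, allow_subnormal=False), st.floats(0.01, 0.99))
def test_check_loss_nonnegative_zero_only_at_origin(z, tau):
    val = ns.check_loss(z, tau)
    assert val >= 0
    assert (val == 0) == (z == 0)


def test_check_loss_rejects_bad_tau():
    with pytest.raises(ValueError):
        ns.check_loss(1.0, 1.5)


# ---------------------------------------------------------------- spline basis

def test_basis_df1_is_linear_and_reproduces_lines():
    t = np.linspace(0, 1000, 50)
    B, knots = ns.natural_spline_basis(t, df=1)
    assert B.shape == (50, 1)
    X = np.column_stack([np.ones(50), B])
    coef, *_ = np.linalg.lstsq(X, 3.0 + 0.5 * t, rcond=None)
    assert np.allclose(X @ coef, 3.0 + 0.5 * t, rtol=1e-10)


@pytest.mark.parametrize("df", [2, 4, 6])
def test_basis_linear_beyond_boundary_knots(df):
    t = np.linspace(0, 1000, 200)
    _, knots = ns.natural_spline_basis(t, df=df)
    grid = np.linspace(1000, 1400, 60)  # beyond the upper boundary knot
    B = ns_basis_from_knots(grid, knots)
    # second differences on a uniform grid vanish for linear functions
    d2 = np.diff(B, n=2, axis=0)
    assert np.max(np.abs(d2)) < 1e-8
    grid_lo = np.linspace(-400, 0, 60)
    d2 = np.diff(ns_basis_from_knots(grid_lo, knots), n=2, axis=0)
    assert np.max(np.abs(d2)) < 1e-8


def test_basis_spans_natural_cubic_spline_on_same_knots():
    t = np.linspace(0, 1000, 400)
    B, knots = ns.natural_spline_basis(t, df=4)
    rng = np.random.default_rng(1)
    target = CubicSpline(knots, rng.normal(size=knots.size), bc_type="natural")(t)
    X = np.column_stack([np.ones(t.size), B])
    coef, *_ = np.linalg.lstsq(X, target, rcond=None)
    resid = target - X @ coef
    assert np.max(np.abs(resid)) / np.max(np.abs(target)) < 1e-8


def test_basis_rejects_degenerate_times():
    with pytest.raises(ValueError):
        ns.natural_spline_basis(np.full(10, 3.0), df=2)


# ---------------------------------------------------------------- quantile fit

def test_intercept_only_median_fit():
    y = np.arange(1.0, 101.0)
    qf = ns.fit_quantile_spline(y, np.empty((100, 0)), tau=0.5)
    # any value in the central order-statistic interval [50, 51] minimises
    assert 50.0 <= qf.coef[0] <= 51.0
    med_obj = ns.check_loss(y - np.median(y), 0.5).sum()
    assert qf.objective == pytest.approx(med_obj, rel=1e-9)


def test_intercept_only_tenth_percentile_fit():
    y = np.arange(1.0, 101.0)
    qf = ns.fit_quantile_spline(y, np.empty((100, 0)), tau=0.1)
    assert 10.0 <= qf.coef[0] <= 11.0


def _enumerate_line_objective(x, y, tau):
    """Brute-force oracle: an optimal tau-quantile line interpolates two
    observations, so enumerate all pairs."""
    best = np.inf
    n = len(y)
    for i in range(n):
        for j in range(i + 1, n):
            if x[i] == x[j]:
                continue
            slope = (y[j] - y[i]) / (x[j] - x[i])
            inter = y[i] - slope * x[i]
            obj = ns.check_loss(y - inter - slope * x, tau).sum()
            best = min(best, obj)
    return best


@pytest.mark.parametrize("tau", [0.1, 0.5, 0.9])
def test_quantile_line_fit_matches_enumeration_oracle(tau):
    rng = np.random.default_rng(42)
    x = rng.uniform(0, 10, 20)
    y = 2.0 + 0.7 * x + rng.standard_t(3, 20)
    qf = ns.fit_quantile_spline(y, x[:, None], tau=tau)
    oracle = _enumerate_line_objective(x, y, tau)
    assert qf.objective == pytest.approx(oracle, abs=1e-8)


def test_quantile_fit_rejects_constant_y():
    with pytest.raises(ValueError):
        ns.fit_quantile_spline(np.full(50, 2.0), np.empty((50, 0)), tau=0.1)


# --------------------------------------------------------- session-level fits

def test_noiseless_session_recovers_true_background(quiet_session):
    session, truth = quiet_session
    fit = ns.estimate_background(session, "NO")
    bg = truth.background[session.session_id]
    assert np.max(np.abs(fit.fitted - bg)) / bg.mean() < 1e-6


def test_df_equals_rounded_hours():
    cfg = ns.ScenarioConfig(seed=3, sample_interval_s=5.0, plume_rate_per_h=0.0)
    route = ns.make_route(cfg)
    wind = ns.simulate_wind(cfg, 12)
    session, _ = ns.simulate_session(cfg, route, wind, duration_h=3.0)
    fit = ns.estimate_background(session, "NO")
    assert fit.df == 3


def test_short_session_rejected_by_name():
    cfg = ns.ScenarioConfig(seed=3, sample_interval_s=5.0)
    route = ns.make_route(cfg)
    wind = ns.simulate_wind(cfg, 12)
    session, _ = ns.simulate_session(cfg, route, wind, duration_h=0.4)
    with pytest.raises(ValueError, match=session.session_id):
        ns.estimate_background(session, "NO")


def test_sign_count_property_on_noisy_session():
    cfg = ns.ScenarioConfig(seed=9, sample_interval_s=5.0, noise_sdlog=0.2)
    route = ns.make_route(cfg)
    wind = ns.simulate_wind(cfg, 12)
    session, _ = ns.simulate_session(cfg, route, wind, duration_h=2.0)
    fit = ns.estimate_background(session, "NO", tau=0.10)
    y = session.channels["NO"]
    n = y.size
    frac_below = np.mean(y < fit.fitted)
    slack = (fit.df + 1) / n
    assert 0.10 - slack <= frac_below <= 0.10 + slack


def test_spike_robustness_positive_residuals_can_grow():
    rng = np.random.default_rng(5)
    x = rng.uniform(0, 10, 25)
    y = 5.0 + 0.3 * x + rng.normal(0, 1, 25)
    qf = ns.fit_quantile_spline(y, x[:, None], tau=0.1)
    resid = y - qf.fitted
    y2 = np.where(resid > 1e-9, y * 10.0, y)
    qf2 = ns.fit_quantile_spline(y2, x[:, None], tau=0.1)
    assert np.allclose(qf.coef, qf2.coef, atol=1e-7)


def test_lower_tau_curve_lies_below_median_curve(quiet_session):
    session, _ = quiet_session
    rng = np.random.default_rng(8)
    session = ns.SessionSeries(
        session_id="tau",
        start_time=session.start_time,
        times=session.times,
        xy=session.xy,
        channels={"NO": session.channels["NO"] * rng.lognormal(0, 0.3, session.times.size)},
        units={"NO": "ppb"},
    )
    lo = ns.estimate_background(session, "NO", tau=0.05)
    hi = ns.estimate_background(session, "NO", tau=0.5)
    assert np.all(lo.fitted <= hi.fitted + 1e-8)


# --------------------------------------------------------------------- summary

def test_background_fraction_limits(quiet_session):
    session, _ = quiet_session
    fit = ns.estimate_background(session, "NO")
    # background identical to observations -> fraction 1
    table, _ = ns.background_summary([session], [fit])
    assert table["background_fraction"].iloc[0] == pytest.approx(1.0, abs=1e-9)
    zero = ns.BackgroundFit(
        session_id=session.session_id, channel="NO", tau=0.1, df=fit.df,
        knots=fit.knots, coef=np.zeros_like(fit.coef),
        fitted=np.zeros_like(fit.fitted), objective=0.0,
    )
    table, _ = ns.background_summary([session], [zero])
    assert table["background_fraction"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_background_fraction_recovered_on_plumey_session():
    cfg = ns.ScenarioConfig(
        seed=21, true_beta=(0, 0, 0, 0, 0), sample_interval_s=2.0,
        plume_rate_per_h=20.0,
    )
    route = ns.make_route(cfg)
    wind = ns.simulate_wind(cfg, 12)
    session, truth = ns.simulate_session(cfg, route, wind, duration_h=3.0)
    bg = truth.background[session.session_id]
    true_frac = bg.mean() / session.channels["NO"].mean()
    fit = ns.estimate_background(session, "NO")
    table, _ = ns.background_summary([session], [fit])
    assert table["background_fraction"].iloc[0] == pytest.approx(true_frac, abs=0.05)
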