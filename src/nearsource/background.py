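"""Urban-background estimation by natural-spline quantile regression.

A mobile-monitoring time series is the sum of a slowly varying regional
("background") level and short positive excursions from local plumes.  The
background is estimated per session as a low conditional quantile (default
the 10th) of concentration as a smooth function of time: a cubic natural
spline basis in time, with degrees of freedom equal to the number of hours
in the session, fitted by minimising the check loss

    rho_tau(z) = z * tau        if z > 0
                 z * (tau - 1)  if z <= 0

The minimisation is solved exactly as a linear program, so the classical
quantile sign-count property holds: at most ~tau*n observations fall
strictly below the fitted curve.  Because positive residuals are only
weighted by tau, the fit is insensitive to the magnitude of plume spikes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.interpolate import CubicSpline
from scipy.optimize import linprog

__all__ = [
    "SessionSeries",
    "BackgroundFit",
    "QuantileFit",
    "rolling_mean",
    "check_loss",
    "natural_spline_basis",
    "ns_basis_from_knots",
    "fit_quantile_spline",
    "estimate_background",
    "background_summary",
]


@dataclass
class SessionSeries:
    """One mobile-monitoring session: timestamped, georeferenced channels.

    Attributes
    ----------
    session_id
        Identifier, e.g. ``"S03"``.
    start_time
        Absolute session start (used to look up hourly wind records).
    times
        Seconds since session start, strictly increasing.
    xy
        (n, 2) planar positions in meters.
    channels
        Channel name -> (n,) concentration array.  NaN marks missing values
        (instruments report at different native rates).
    units
        Channel name -> unit string (ug/m3, ppb, cm-3, Mm-1, ...).
    motion
        Optional per-record in-motion flag.
    """

    session_id: str
    start_time: pd.Timestamp
    times: np.ndarray
    xy: np.ndarray
    channels: dict[str, np.ndarray]
    units: dict[str, str] = field(default_factory=dict)
    motion: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"session {self.session_id}: times not strictly increasing")
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.shape != (self.times.size, 2):
            raise ValueError(f"session {self.session_id}: xy shape mismatch")
        for name, v in self.channels.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.times.shape:
                raise ValueError(f"session {self.session_id}: channel {name} length mismatch")
            self.channels[name] = v

    @property
    def duration_h(self) -> float:
        return float(self.times[-1] - self.times[0]) / 3600.0

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.start_time + pd.to_timedelta(self.times, unit="s")


def rolling_mean(values: np.ndarray, times: np.ndarray, window_s: float) -> np.ndarray:
    """Centered time-window rolling mean, ignoring missing values.

    Output i is the mean of finite input values with |t - t_i| <= window/2
    (both ends inclusive); NaN where the window holds no finite value.
    Used to pre-smooth noisy aromatic channels with a 10 s window.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be increasing")
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    vv = np.where(finite, v, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(vv)])
    ccnt = np.concatenate([[0], np.cumsum(finite)])
    half = window_s / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    n = ccnt[hi] - ccnt[lo]
    s = csum[hi] - csum[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n > 0, s / n, np.nan)
    return out


def check_loss(z: np.ndarray | float, tau: float) -> np.ndarray | float:
    """Asymmetric absolute ("check") loss rho_tau(z).

    Returns z*tau for z > 0 and z*(tau-1) for z <= 0; nonnegative, zero
    only at z = 0.  Minimising its sum over residuals yields the tau-th
    conditional quantile.
    """
    if not 0 < tau < 1:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    z = np.asarray(z, dtype=float)
    out = np.where(z > 0, z * tau, z * (tau - 1.0))
    return float(out) if out.ndim == 0 else out


def _ns_columns(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (no intercept) on given knots.

    Truncated-power construction: with knots k_1 < ... < k_K the columns are
    x and d_j(x) - d_{K-1}(x) for j = 1..K-2, where
    d_j(x) = [(x-k_j)_+^3 - (x-k_K)_+^3] / (k_K - k_j).
    Each column is piecewise cubic, C^2, and linear beyond the boundary
    knots.  K = df + 1 knots give df columns.
    """
    K = knots.size
    cols = [x]
    if K > 2:
        kK = knots[-1]

        def d(j: int) -> np.ndarray:
            return (
                np.clip(x - knots[j], 0, None) ** 3 - np.clip(x - kK, 0, None) ** 3
            ) / (kK - knots[j])

        dlast = d(K - 2)
        for j in range(K - 2):
            cols.append(d(j) - dlast)
    return np.column_stack(cols)


def natural_spline_basis(times: np.ndarray, df: int) -> tuple[np.ndarray, np.ndarray]:
    """Natural cubic spline basis of time with ``df`` degrees of freedom.

    Boundary knots sit at min/max time and the df-1 interior knots at
    equally spaced quantiles of the observation times, which is robust to
    the uneven sampling produced by stationary stops.  df = 1 gives a
    plain linear column.

    Returns
    -------
    basis : (n, df) array, intercept excluded.
    knots : the df + 1 knots in original time units (for re-evaluation).
    """
    t = np.asarray(times, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if t.size <= df:
        raise ValueError(f"need more than df={df} observations, got {t.size}")
    lo, hi = float(t.min()), float(t.max())
    if hi <= lo:
        raise ValueError("degenerate time range: all times equal")
    probs = np.linspace(0, 1, df + 1)
    knots = np.quantile(t, probs)
    knots[0], knots[-1] = lo, hi
    if np.any(np.diff(knots) <= 0):
        raise ValueError("duplicate knots: time distribution too degenerate for this df")
    return ns_basis_from_knots(t, knots), knots


def ns_basis_from_knots(times: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Evaluate the natural-spline basis defined by ``knots`` at new times."""
    t = np.asarray(times, dtype=float)
    knots = np.asarray(knots, dtype=float)
    # affine rescale to [0, 1] for conditioning; spans the same space
    lo, hi = knots[0], knots[-1]
    return _ns_columns((t - lo) / (hi - lo), (knots - lo) / (hi - lo))


@dataclass
class QuantileFit:
    """Solution of a check-loss minimisation: coefficients and fitted values."""

    coef: np.ndarray
    fitted: np.ndarray
    objective: float
    tau: float


def fit_quantile_spline(
    y: np.ndarray, basis: np.ndarray, tau: float
) -> QuantileFit:
    """Exact quantile regression of ``y`` on [1 | basis] at level ``tau``.

    Solves min_beta sum_i rho_tau(y_i - X_i beta) as the standard linear
    program (residuals split into positive/negative parts) with the HiGHS
    solver, so the returned objective is the global minimum.  Rows with
    non-finite y are excluded from the fit; fitted values are returned for
    every row.
    """
    if not 0 < tau < 1:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    y = np.asarray(y, dtype=float)
    basis = np.asarray(basis, dtype=float)
    if basis.ndim != 2 or basis.shape[0] != y.size:
        raise ValueError("basis must be (n, df) matching y")
    X_all = np.column_stack([np.ones_like(y), basis])
    ok = np.isfinite(y)
    Xf, yf = X_all[ok], y[ok]
    n, p = Xf.shape
    if n <= p + 1:
        raise ValueError(f"too few finite observations ({n}) for {p} coefficients")
    if np.unique(yf).size < 2:
        raise ValueError("y needs at least 2 distinct finite values")
    # variables: [beta (free), u >= 0, v >= 0]; X beta + u - v = y
    c = np.concatenate([np.zeros(p), np.full(n, tau), np.full(n, 1.0 - tau)])
    A = sp.hstack([sp.csc_matrix(Xf), sp.eye(n, format="csc"), -sp.eye(n, format="csc")])
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A, b_eq=yf, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(
            f"quantile LP failed (status {res.status}): {res.message}"
        )
    coef = res.x[:p]
    fitted = X_all @ coef
    return QuantileFit(coef=coef, fitted=fitted, objective=float(res.fun), tau=tau)


@dataclass
class BackgroundFit:
    """Fitted background curve for one session x channel.

    ``fitted`` is the spline evaluated at every observation time (including
    times where the channel value is missing).  ``predict`` re-evaluates
    the curve at arbitrary times within the session.
    """

    session_id: str
    channel: str
    tau: float
    df: int
    knots: np.ndarray
    coef: np.ndarray
    fitted: np.ndarray
    objective: float

    def predict(self, times: np.ndarray) -> np.ndarray:
        B = ns_basis_from_knots(times, self.knots)
        return self.coef[0] + B @ self.coef[1:]


def estimate_background(
    session: SessionSeries, channel: str, tau: float = 0.10
) -> BackgroundFit:
    """Estimate the smooth background curve for one session channel.

    Degrees of freedom follow the session length: df = max(1,
    round(duration in hours)).  A warning-level diagnostic is attached if
    the fitted curve goes negative (no positivity floor is applied, which
    would break the quantile sign-count property).
    """
    if channel not in session.channels:
        raise KeyError(f"session {session.session_id} has no channel {channel!r}")
    y = session.channels[channel]
    ok = np.isfinite(y)
    if ok.sum() < 2:
        raise ValueError(f"session {session.session_id}: channel {channel} all missing")
    span_s = session.times[ok][-1] - session.times[ok][0]
    if span_s < 1800:
        raise ValueError(
            f"session {session.session_id}: only {span_s / 60:.1f} min of finite "
            f"{channel} data; need at least 30 min"
        )
    df = max(1, int(np.floor(session.duration_h + 0.5)))
    basis, knots = natural_spline_basis(session.times, df)
    qf = fit_quantile_spline(y, basis, tau)
    if np.any(qf.fitted < 0):
        import warnings

        warnings.warn(
            f"session {session.session_id} / {channel}: fitted background "
            f"dips below zero (min {qf.fitted.min():.3g})"
        )
    return BackgroundFit(
        session_id=session.session_id,
        channel=channel,
        tau=tau,
        df=df,
        knots=knots,
        coef=qf.coef,
        fitted=qf.fitted,
        objective=qf.objective,
    )


def background_summary(
    sessions: list[SessionSeries], fits: list[BackgroundFit]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Session mean, background mean and background fraction per channel.

    The background fraction -- mean fitted background over mean observed
    concentration -- measures how much of a session's signal is regional
    rather than local.  Means are taken over times with finite observations
    so both numerator and denominator cover the same records.

    Returns
    -------
    per_session : one row per session x channel.
    grand : across-session mean and standard deviation per channel.
    """
    by_id = {s.session_id: s for s in sessions}
    rows = []
    for fit in fits:
        s = by_id[fit.session_id]
        y = s.channels[fit.channel]
        ok = np.isfinite(y)
        smean = float(np.mean(y[ok]))
        bmean = float(np.mean(fit.fitted[ok]))
        frac = bmean / smean if smean != 0 else np.nan
        rows.append(
            {
                "session_id": fit.session_id,
                "channel": fit.channel,
                "session_mean": smean,
                "background_mean": bmean,
                "background_fraction": frac,
                "undefined_fraction": smean == 0,
            }
        )
    per_session = pd.DataFrame(rows)
    grand = (
        per_session.groupby("channel")[["session_mean", "background_mean", "background_fraction"]]
        .agg(["mean", "std"])
        .reset_index()
    )
    grand.columns = ["_".join(c).rstrip("_") for c in grand.columns]
    return per_session, grand
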