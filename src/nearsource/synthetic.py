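"""Synthetic mobile-monitoring scenarios with known ground truth.

The generator emulates the statistical structure of a near-railyard mobile
campaign: a van drives labelled routes beside and through a rectangular
yard while hourly winds switch between calm and four directional sectors.
Each 1-3 s concentration record is

    c(t) = background(t) * exp(local(t)) * noise(t) + plume(t)

where ``background`` is a smooth strictly positive curve (regional urban
signal), ``local`` applies the true regression coefficients
(b0, calm, railyard, downwind, distance) to the vehicle's current position
and the hour's wind category, ``noise`` is multiplicative lognormal
instrument noise, and ``plume`` adds transient positive exponential pulses
with lognormal amplitudes (spiky local emissions above the smooth floor).
Pre-aggregated segment tables can also be drawn directly from the
regression model with Gaussian-process errors (exponential covariance with
sill/nugget/range) for parameter-recovery studies.

All randomness flows from ``ScenarioConfig.seed``; identical configs give
bit-identical output.  No atmospheric dispersion physics is modelled: the
generator matches the analysis model, not plume transport.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from shapely.geometry import LineString, Polygon

from .background import SessionSeries
from .spatial import (
    RoadSegment,
    RouteGeometry,
    RoutePolyline,
    SECTOR_BOUNDS,
    WindCategory,
    classify_wind,
    distance_to_yard,
    downwind_indicator,
    segment_route,
)

__all__ = ["ScenarioConfig", "ScenarioTruth", "make_route", "simulate_wind",
           "simulate_session", "simulate_aggregated", "simulate_scenario"]

#: Sector centers (deg, wind blowing *from*) for directional categories.
_SECTOR_CENTER = {
    WindCategory.NNE: 45.0,
    WindCategory.SE: 135.0,
    WindCategory.SSW: 225.0,
    WindCategory.NW: 315.0,
}


@dataclass
class ScenarioConfig:
    """All generating parameters of a synthetic campaign.

    Defaults mirror the study conditions: 19 sessions of 1.2-5.9 h at 1 s
    sampling, a constant in-motion speed of 5.4 m/s (~12 mph), a 50 m
    segment grid, calm threshold 0.5 m/s, and a distance effect of
    exp(-0.693) = 0.5 per km.  The yard is a 500 x 2000 m rectangle with
    its long axis north-south, so NNE/SSW winds are the cross-yard sectors
    and the east/west route offsets sit up- or downwind of it.
    """

    seed: int = 0
    n_sessions: int = 19
    session_duration_h: tuple[float, float] = (1.2, 5.9)
    sample_interval_s: float = 1.0
    segment_length_m: float = 50.0
    yard_size_m: tuple[float, float] = (500.0, 2000.0)  # (east-west, north-south)
    #: Signed east (+) / west (-) offsets of route polylines from the yard
    #: edge, meters; 0 denotes the through-yard transect.
    route_offsets_m: tuple[float, ...] = (150.0, -150.0, 450.0, -450.0, 800.0, -800.0, 0.0)
    vehicle_speed_ms: float = 5.4
    # background curve: per-session control values around a common level
    background_level: float = 10.0
    background_rel_variation: float = 0.15
    #: Control points of the background curve; None places one per hour
    #: (plus endpoints), matching the hour-scale variation of urban
    #: background that motivates the df = hours spline rule.
    background_n_control: int | None = None
    background_controls: tuple[float, ...] | None = None
    # transient plume pulses
    plume_rate_per_h: float = 12.0
    plume_amp_meanlog: float = np.log(10.0)
    plume_amp_sdlog: float = 1.0
    plume_decay_s: float = 30.0
    # multiplicative lognormal instrument noise (sd of log)
    noise_sdlog: float = 0.05
    # regression truth (log scale): intercept, calm, railyard, downwind, distance/km
    true_beta: tuple[float, float, float, float, float] = (
        np.log(10.0), 0.3, 0.5, 0.4, -0.6931471805599453,
    )
    # GP error truth for aggregated draws
    true_sill_sigma2: float = 0.25
    true_nugget_tau2: float = 0.1
    true_range_phi: float = 1.0 / 200.0
    # hourly wind regime
    wind_probs: dict[WindCategory, float] = field(
        default_factory=lambda: {
            WindCategory.CALM: 0.2,
            WindCategory.NNE: 0.2,
            WindCategory.SSW: 0.2,
            WindCategory.SE: 0.25,
            WindCategory.NW: 0.15,
        }
    )
    #: SD (deg) of normal jitter about the sector center, clipped to the
    #: sector; None draws directions uniformly within the sector.
    direction_jitter_deg: float | None = None
    channel: str = "NO"
    unit: str = "ppb"

    def __post_init__(self) -> None:
        lo, hi = self.session_duration_h
        if not (0 < lo <= hi <= 24):
            raise ValueError("session_duration_h bounds must lie in (0, 24]")
        if self.sample_interval_s <= 0:
            raise ValueError("sample_interval_s must be positive")
        if self.background_level <= 0:
            raise ValueError("background level must be strictly positive")
        if self.background_controls is not None and any(
            v <= 0 for v in self.background_controls
        ):
            raise ValueError("background control values must be strictly positive")
        if self.plume_rate_per_h < 0:
            raise ValueError("plume rate must be nonnegative")
        if self.true_sill_sigma2 < 0 or self.true_nugget_tau2 < 0:
            raise ValueError("sill and nugget must be nonnegative")
        if self.true_range_phi <= 0:
            raise ValueError("range phi must be positive")
        total = sum(self.wind_probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"wind category probabilities sum to {total}, not 1")

    def rng(self, *spawn_key: int) -> np.random.Generator:
        """Deterministic child generator for a named stage."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=spawn_key))


@dataclass
class ScenarioTruth:
    """Generating quantities retained for recovery tests."""

    true_beta: np.ndarray
    true_cov: tuple[float, float, float]  # (sigma2, tau2, phi)
    background: dict[str, np.ndarray] = field(default_factory=dict)  # session -> curve
    expected_log: dict[str, np.ndarray] = field(default_factory=dict)  # per-record linear predictor
    wind_category_by_hour: pd.Series | None = None


def make_route(cfg: ScenarioConfig) -> RouteGeometry:
    """Build the yard polygon and labelled route polylines.

    The yard rectangle is centered at the origin.  Each nonzero offset
    produces a north-south polyline that far east (+) or west (-) of the
    yard edge; offset 0 produces the through-yard transect running down the
    yard's spine (strictly inside the polygon).
    """
    wx, wy = cfg.yard_size_m
    if wx <= 0 or wy <= 0:
        raise ValueError(f"degenerate yard polygon: size {cfg.yard_size_m}")
    hx, hy = wx / 2.0, wy / 2.0
    yard = Polygon([(-hx, -hy), (hx, -hy), (hx, hy), (-hx, hy)])
    polylines = []
    for off in cfg.route_offsets_m:
        if off == 0:
            geom = LineString([(0.0, -(hy - 1.0)), (0.0, hy - 1.0)])
            zone = "within"
        else:
            x = np.sign(off) * (hx + abs(off))
            geom = LineString([(x, -hy), (x, hy)])
            zone = "east" if off > 0 else "west"
        polylines.append(RoutePolyline(geometry=geom, zone=zone))
    return RouteGeometry(polylines=polylines, yard=yard)


def simulate_wind(
    cfg: ScenarioConfig,
    n_hours: int,
    start: pd.Timestamp | str = "2012-05-01 00:00",
) -> pd.DataFrame:
    """Hourly wind records (speed m/s, direction deg 'from') under the regime.

    Calm hours draw speeds in (0, 0.5] with direction uniform on [0, 360);
    directional hours draw speeds in (0.5, 8] and a direction inside the
    category's sector (uniform, or jittered about the center when
    ``direction_jitter_deg`` is set).
    """
    if n_hours < 1:
        raise ValueError("need at least one hour of wind")
    rng = cfg.rng(1)
    cats = list(cfg.wind_probs.keys())
    probs = np.array([cfg.wind_probs[c] for c in cats])
    draw = rng.choice(len(cats), size=n_hours, p=probs)
    speed = np.empty(n_hours)
    direction = np.empty(n_hours)
    for i, k in enumerate(draw):
        cat = cats[k]
        if cat is WindCategory.CALM:
            speed[i] = rng.uniform(0.05, 0.5)
            direction[i] = rng.uniform(0.0, 360.0)
        else:
            speed[i] = rng.uniform(0.8, 8.0)
            direction[i] = _draw_direction(rng, cat, cfg.direction_jitter_deg)
    times = pd.Timestamp(start) + pd.to_timedelta(np.arange(n_hours), unit="h")
    return pd.DataFrame({"time": times, "speed_ms": speed, "direction_deg": direction})


def _draw_direction(
    rng: np.random.Generator, cat: WindCategory, jitter: float | None
) -> float:
    lo, hi = SECTOR_BOUNDS[cat]
    width = (hi - lo) % 360.0
    if jitter is None:
        return (lo + rng.uniform(0.0, width)) % 360.0
    center = _SECTOR_CENTER[cat]
    # offset from center, clipped just inside the half-open sector
    off = np.clip(rng.normal(0.0, jitter), -width / 2.0, width / 2.0 - 1e-6)
    return (center + off) % 360.0


def _positions_along_tour(route: RouteGeometry, dist: np.ndarray) -> np.ndarray:
    """Vehicle position after travelling ``dist`` meters along the looped tour.

    The tour visits each polyline in order (the hop between polylines is
    instantaneous, an idealisation of connector driving)."""
    lengths = np.array([pl.geometry.length for pl in route.polylines])
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    total = cum[-1]
    d = np.mod(dist, total)
    which = np.clip(np.searchsorted(cum, d, side="right") - 1, 0, len(lengths) - 1)
    out = np.empty((d.size, 2))
    for j, pl in enumerate(route.polylines):
        sel = which == j
        if not sel.any():
            continue
        local = d[sel] - cum[j]
        verts = np.asarray(pl.geometry.coords)
        vdist = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(verts, axis=0), axis=1))])
        out[sel, 0] = np.interp(local, vdist, verts[:, 0])
        out[sel, 1] = np.interp(local, vdist, verts[:, 1])
    return out


def _background_curve(cfg: ScenarioConfig, rng: np.random.Generator, times: np.ndarray) -> np.ndarray:
    """Smooth strictly positive background over the session via a natural
    cubic interpolating spline through positive control values."""
    if cfg.background_controls is not None:
        ctrl = np.asarray(cfg.background_controls, dtype=float)
    else:
        n_ctrl = cfg.background_n_control
        if n_ctrl is None:
            duration_h = (times[-1] - times[0]) / 3600.0
            n_ctrl = max(2, int(np.floor(duration_h + 0.5)) + 1)
        ctrl = cfg.background_level * (
            1.0 + cfg.background_rel_variation * rng.uniform(-1.0, 1.0, n_ctrl)
        )
    tc = np.linspace(times[0], times[-1], ctrl.size)
    if ctrl.size < 2:
        return np.full_like(times, float(ctrl[0]))
    curve = CubicSpline(tc, ctrl, bc_type="natural")(times)
    if np.any(curve <= 0):
        raise ValueError("background curve dipped non-positive; reduce variation")
    return curve


def simulate_session(
    cfg: ScenarioConfig,
    route: RouteGeometry,
    wind: pd.DataFrame,
    session_idx: int = 0,
    start: pd.Timestamp | str = "2012-05-01 00:00",
    duration_h: float | None = None,
) -> tuple[SessionSeries, ScenarioTruth]:
    """Simulate one driving session over the route under the given winds.

    The wind table must cover the session window (hourly records).  The
    truth object carries the background curve at sample times and the
    per-record linear predictor.
    """
    rng = cfg.rng(2, session_idx)
    if duration_h is None:
        duration_h = float(rng.uniform(*cfg.session_duration_h))
    start = pd.Timestamp(start)
    times = np.arange(0.0, duration_h * 3600.0, cfg.sample_interval_s)
    stamps = start + pd.to_timedelta(times, unit="s")
    wind_idx = wind.set_index("time")
    hours = stamps.floor("h")
    if not hours.isin(wind_idx.index).all():
        raise ValueError("wind series does not cover the session window")
    wrec = wind_idx.loc[hours]
    cat = np.array(
        [classify_wind(s, d) for s, d in zip(wrec["speed_ms"], wrec["direction_deg"])],
        dtype=object,
    )

    # vehicle path: start at a session-specific point along the looped tour
    lengths = sum(pl.geometry.length for pl in route.polylines)
    offset0 = rng.uniform(0.0, lengths)
    xy = _positions_along_tour(route, offset0 + cfg.vehicle_speed_ms * times)

    dist_km = distance_to_yard(xy, route.yard)
    inside = dist_km == 0.0
    # zone for the downwind indicator comes from the vehicle's x position
    zone = np.where(inside, "within", np.where(xy[:, 0] > 0, "east", "west"))
    calm = np.array([c is WindCategory.CALM for c in cat], dtype=float)
    dwind = np.array([downwind_indicator(z, c) for z, c in zip(zone, cat)], dtype=float)
    b0, b1, b2, b3, b4 = cfg.true_beta
    local = b0 + b1 * calm + b2 * inside.astype(float) + b3 * dwind + b4 * dist_km

    background = _background_curve(cfg, rng, times)
    noise = rng.lognormal(0.0, cfg.noise_sdlog, times.size) if cfg.noise_sdlog > 0 else np.ones(times.size)
    conc = background * np.exp(local) * noise

    n_events = rng.poisson(cfg.plume_rate_per_h * duration_h)
    if n_events > 0:
        t_ev = np.sort(rng.uniform(times[0], times[-1], n_events))
        amp = rng.lognormal(cfg.plume_amp_meanlog, cfg.plume_amp_sdlog, n_events)
        plume = np.zeros_like(times)
        for tk, a in zip(t_ev, amp):
            mask = times >= tk
            plume[mask] += a * np.exp(-(times[mask] - tk) / cfg.plume_decay_s)
        conc = conc + plume

    session = SessionSeries(
        session_id=f"S{session_idx:02d}",
        start_time=start,
        times=times,
        xy=xy,
        channels={cfg.channel: conc},
        units={cfg.channel: cfg.unit},
    )
    truth = ScenarioTruth(
        true_beta=np.asarray(cfg.true_beta, dtype=float),
        true_cov=(cfg.true_sill_sigma2, cfg.true_nugget_tau2, cfg.true_range_phi),
        background={session.session_id: background},
        expected_log={session.session_id: local + np.log(background)},
        wind_category_by_hour=pd.Series(
            [classify_wind(s, d) for s, d in zip(wind["speed_ms"], wind["direction_deg"])],
            index=wind["time"],
        ),
    )
    return session, truth


def _segment_covariates(cfg: ScenarioConfig, route: RouteGeometry) -> tuple[list[RoadSegment], pd.DataFrame]:
    segments = segment_route(route, cfg.segment_length_m)
    cents = np.array([s.centroid for s in segments])
    dist = distance_to_yard(cents, route.yard)
    rows = []
    for cat in WindCategory:
        for j, seg in enumerate(segments):
            rows.append(
                {
                    "segment_id": seg.id,
                    "zone": seg.zone,
                    "seg_x": seg.centroid[0],
                    "seg_y": seg.centroid[1],
                    "wind_category": cat.value,
                    "channel": cfg.channel,
                    "n_obs": 10,
                    "distance_km": 0.0 if seg.zone == "within" else float(dist[j]),
                    "calm": int(cat is WindCategory.CALM),
                    "railyard": int(seg.zone == "within"),
                    "downwind": downwind_indicator(seg.zone, cat),
                }
            )
    return segments, pd.DataFrame(rows)


def simulate_aggregated(
    cfg: ScenarioConfig, route: RouteGeometry, replicate: int = 0
) -> tuple[pd.DataFrame, ScenarioTruth]:
    """Draw a segment x wind-category table directly from the regression model.

    Log concentrations are the linear predictor plus a Gaussian-process
    error with covariance sigma^2 exp(-phi d) + tau^2 1{same record},
    independent across wind categories.  Returns the table in the
    aggregated-records contract (median = exp(log draw)) and the truth.
    """
    segments, table = _segment_covariates(cfg, route)
    if len(segments) < 2:
        raise ValueError("need at least 2 segments")
    rng = cfg.rng(3, replicate)
    b = np.asarray(cfg.true_beta, dtype=float)
    X = table[["calm", "railyard", "downwind", "distance_km"]].to_numpy(dtype=float)
    eta = b[0] + X @ b[1:]
    sigma2, tau2, phi = cfg.true_sill_sigma2, cfg.true_nugget_tau2, cfg.true_range_phi
    err = np.zeros(len(table))
    coords = table[["seg_x", "seg_y"]].to_numpy(dtype=float)
    for cat in table["wind_category"].unique():
        idx = np.flatnonzero((table["wind_category"] == cat).to_numpy())
        C = coords[idx]
        diff = C[:, None, :] - C[None, :, :]
        D = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        cov = sigma2 * np.exp(-phi * D) + tau2 * np.eye(idx.size)
        err[idx] = _mvn_draw(rng, cov)
    logc = eta + err
    out = table.copy()
    out["median"] = np.exp(logc)
    out = out[
        ["segment_id", "zone", "seg_x", "seg_y", "wind_category", "channel",
         "median", "n_obs", "distance_km", "calm", "railyard", "downwind"]
    ]
    truth = ScenarioTruth(
        true_beta=b,
        true_cov=(sigma2, tau2, phi),
        expected_log={"aggregated": eta},
    )
    return out, truth


def _mvn_draw(rng: np.random.Generator, cov: np.ndarray) -> np.ndarray:
    """Zero-mean multivariate normal draw.

    Tiny negative eigenvalues from rounding are clipped to zero; a
    genuinely indefinite matrix is a hard error.
    """
    n = cov.shape[0]
    z = rng.standard_normal(n)
    if not np.any(cov):
        return np.zeros(n)
    # eigendecomposition rather than Cholesky: a singular covariance (two
    # coincident segments, no nugget) must give *identical* draws, not
    # draws split by a vanishing pivot
    vals, vecs = np.linalg.eigh(cov)
    tol = 1e-10 * max(vals.max(), 1.0)
    if vals.min() < -tol:
        raise np.linalg.LinAlgError(
            f"covariance matrix indefinite (min eigenvalue {vals.min():.3g})"
        )
    return (vecs * np.sqrt(np.clip(vals, 0.0, None))) @ z


def simulate_scenario(
    cfg: ScenarioConfig, start: pd.Timestamp | str = "2012-05-01 06:00"
) -> tuple[list[SessionSeries], pd.DataFrame, RouteGeometry, ScenarioTruth]:
    """Full campaign: route, wind series and all sessions, with pooled truth.

    Sessions start at consecutive offsets (one session per simulated day,
    staggered start hour) so each sees its own stretch of the hourly wind
    series.
    """
    route = make_route(cfg)
    rng = cfg.rng(4)
    start = pd.Timestamp(start)
    durations = rng.uniform(*cfg.session_duration_h, cfg.n_sessions)
    starts = [start + pd.Timedelta(days=i, hours=int(rng.integers(0, 12))) for i in range(cfg.n_sessions)]
    horizon_h = int(
        np.ceil((max(s + pd.Timedelta(hours=d) for s, d in zip(starts, durations)) - start).total_seconds() / 3600.0)
    ) + 2
    wind = simulate_wind(cfg, horizon_h, start=start.floor("h"))
    sessions: list[SessionSeries] = []
    truth = ScenarioTruth(
        true_beta=np.asarray(cfg.true_beta, dtype=float),
        true_cov=(cfg.true_sill_sigma2, cfg.true_nugget_tau2, cfg.true_range_phi),
    )
    for i in range(cfg.n_sessions):
        s, t = simulate_session(
            cfg, route, wind, session_idx=i, start=starts[i], duration_h=float(durations[i])
        )
        sessions.append(s)
        truth.background.update(t.background)
        truth.expected_log.update(t.expected_log)
    truth.wind_category_by_hour = pd.Series(
        [classify_wind(s, d) for s, d in zip(wind["speed_ms"], wind["direction_deg"])],
        index=wind["time"],
    )
    return sessions, wind, route, truth
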