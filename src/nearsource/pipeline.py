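"""End-to-end orchestration: smoothing -> background -> aggregation -> fits.

``run_pipeline`` chains the full analysis on a set of session files (or
in-memory sessions), writing every intermediate artifact: per-session
background curves, the aggregated segment table, regression results for
both error models, the multiplicative-effect table and the pollutant
correlation matrix.  Every output is stamped with a hash of the
configuration that produced it, and all randomness (only the synthetic
generator uses any) flows from the single configured seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nsio
from .background import (
    BackgroundFit,
    SessionSeries,
    background_summary,
    estimate_background,
    rolling_mean,
)
from .regression import (
    FitResult,
    build_design,
    correlation_matrix,
    fit_independent,
    fit_spatial,
    interpret_effects,
)
from .spatial import (
    RouteGeometry,
    aggregate_medians,
    apply_filters,
    assign_measurements,
    classify_wind,
    distance_to_yard,
    segment_route,
)

log = logging.getLogger("nearsource")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "sessions_to_records"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; YAML-serialisable.

    ``smooth_channels`` are pre-smoothed with a centered rolling mean of
    ``smooth_window_s`` seconds (meant for noisy aromatic channels).
    ``models`` selects the error structures fitted per channel.
    """

    sessions: list[str] = field(default_factory=list)  # session CSV paths
    wind: str = ""  # wind CSV path
    route: str = ""  # route+yard GeoJSON path
    output_dir: str = "nearsource_out"
    tau: float = 0.10
    segment_length_m: float = 50.0
    snap_max_m: float = 30.0
    min_n: int = 5
    max_dist_km: float = 1.0
    smooth_channels: list[str] = field(default_factory=list)
    smooth_window_s: float = 10.0
    channels: list[str] | None = None  # None = all channels found
    models: tuple[str, ...] = ("independent", "spatial")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.tau < 1:
            raise ValueError("tau must be in (0, 1)")
        if self.segment_length_m <= 0 or self.snap_max_m <= 0:
            raise ValueError("lengths must be positive")
        if self.min_n < 1 or self.max_dist_km <= 0:
            raise ValueError("filter parameters out of range")
        for m in self.models:
            if m not in ("independent", "spatial"):
                raise ValueError(f"unknown model {m!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "models" in data:
            data["models"] = tuple(data["models"])
        return cls(**data)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    """In-memory bundle mirroring the files written by :func:`run_pipeline`."""

    background_fits: list[BackgroundFit]
    background_table: pd.DataFrame
    background_grand: pd.DataFrame
    aggregated: pd.DataFrame
    excluded_fraction: dict[str, float]
    fits: dict[str, dict[str, FitResult]]
    effects: dict[str, dict[str, pd.DataFrame]]
    correlations: pd.DataFrame
    config_hash: str


def sessions_to_records(
    sessions: list[SessionSeries],
    wind: pd.DataFrame,
    route: RouteGeometry,
    segment_length_m: float = 50.0,
    snap_max_m: float = 30.0,
    channels: list[str] | None = None,
):
    """Assign every measurement to a segment and wind category.

    Returns (segments, tidy records DataFrame) ready for
    :func:`nearsource.spatial.aggregate_medians`.
    """
    segments = segment_route(route, segment_length_m)
    wind_idx = wind.set_index("time")
    frames = []
    for s in sessions:
        seg_idx = assign_measurements(s.xy, segments, snap_max_m)
        dist = distance_to_yard(s.xy, route.yard)
        hours = s.timestamps.floor("h")
        missing = ~hours.isin(wind_idx.index)
        if missing.any():
            raise ValueError(
                f"session {s.session_id}: {int(missing.sum())} records outside the wind series"
            )
        wrec = wind_idx.loc[hours]
        cat = [
            classify_wind(sp, dr).value
            for sp, dr in zip(wrec["speed_ms"], wrec["direction_deg"])
        ]
        use = channels if channels is not None else list(s.channels)
        for ch in use:
            frames.append(
                pd.DataFrame(
                    {
                        "segment_idx": seg_idx,
                        "wind_category": cat,
                        "channel": ch,
                        "value": s.channels[ch],
                        "distance_km": dist,
                    }
                )
            )
    return segments, pd.concat(frames, ignore_index=True)


def run_pipeline(
    config: PipelineConfig,
    sessions: list[SessionSeries] | None = None,
    wind: pd.DataFrame | None = None,
    route: RouteGeometry | None = None,
) -> PipelineResult:
    """Run the whole analysis; inputs may be paths (in config) or objects.

    Stages: per-channel smoothing, per-session background fits and the
    background-fraction table, segment/wind-category median aggregation
    with the sparse/distant filters, both regression fits per channel,
    multiplicative effect tables and the log-median correlation matrix.
    Any stage failure aborts with the stage named in the exception.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    log.info("pipeline start: config_hash=%s seed=%d", chash, config.seed)

    def stage(name: str):
        log.info("stage: %s", name)
        return name

    current = stage("load")
    try:
        if sessions is None:
            sessions = [nsio.read_session_csv(p) for p in config.sessions]
        if wind is None:
            wind = nsio.read_wind_csv(config.wind)
        if route is None:
            route = nsio.read_route_geojson(config.route)
        if not sessions:
            raise ValueError("no sessions provided")

        current = stage("smooth")
        for s in sessions:
            for ch in config.smooth_channels:
                if ch in s.channels:
                    s.channels[ch] = rolling_mean(s.channels[ch], s.times, config.smooth_window_s)

        channels = config.channels or sorted({c for s in sessions for c in s.channels})

        current = stage("background")
        fits: list[BackgroundFit] = []
        for s in sessions:
            for ch in channels:
                if ch in s.channels:
                    fits.append(estimate_background(s, ch, tau=config.tau))
        bg_table, bg_grand = background_summary(sessions, fits)
        for fit in fits:
            s = next(x for x in sessions if x.session_id == fit.session_id)
            df = pd.DataFrame(
                {"time_s": s.times, "observed": s.channels[fit.channel], "fitted": fit.fitted}
            )
            nsio._write_csv(df, outdir / f"background_{fit.session_id}_{fit.channel}.csv", chash)
        nsio._write_csv(bg_table, outdir / "background_summary.csv", chash)
        nsio._write_csv(bg_grand, outdir / "background_summary_grand.csv", chash)

        current = stage("aggregate")
        segments, records = sessions_to_records(
            sessions, wind, route, config.segment_length_m, config.snap_max_m, channels
        )
        n_assigned = int((records["segment_idx"] >= 0).sum())
        log.info("aggregate: %d/%d records assigned", n_assigned, len(records))
        agg = aggregate_medians(records, segments)

        current = stage("filter")
        agg_f, excluded = apply_filters(agg, config.min_n, config.max_dist_km)
        for ch, frac in excluded.items():
            log.info("filter: %s excluded %.1f%% of segments", ch, 100 * frac)
        nsio._write_csv(agg_f, outdir / "aggregated.csv", chash)

        current = stage("fit")
        fit_results: dict[str, dict[str, FitResult]] = {}
        effects: dict[str, dict[str, pd.DataFrame]] = {}
        for ch in channels:
            design = build_design(agg_f, ch)
            fit_results[ch] = {}
            effects[ch] = {}
            if "independent" in config.models:
                fr = fit_independent(design)
                fit_results[ch]["independent"] = fr
                effects[ch]["independent"] = interpret_effects(fr)
            if "spatial" in config.models:
                fr = fit_spatial(design)
                fit_results[ch]["spatial"] = fr
                if fr.converged:
                    effects[ch]["spatial"] = interpret_effects(fr)
        nsio.write_fit_json(fit_results, outdir / "fits.json", chash)
        _write_coefficient_table(fit_results, outdir / "coefficients.csv", chash)

        current = stage("correlate")
        corr = correlation_matrix(agg_f)
        nsio._write_csv(corr.reset_index(names="channel"), outdir / "correlations.csv", chash)

        log.info("pipeline done: %d aggregated rows, %d channels", len(agg_f), len(channels))
        return PipelineResult(
            background_fits=fits,
            background_table=bg_table,
            background_grand=bg_grand,
            aggregated=agg_f,
            excluded_fraction=excluded,
            fits=fit_results,
            effects=effects,
            correlations=corr,
            config_hash=chash,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage '{current}': {exc}") from exc


def _write_coefficient_table(
    fits: dict[str, dict[str, FitResult]], path: Path, chash: str
) -> None:
    """Report-style table: one row per channel with paired
    independent/spatial estimate (SE) columns, significance starred."""
    from .regression import COEF_NAMES

    rows = []
    for ch, models in fits.items():
        row: dict[str, object] = {"channel": ch}
        for model, fr in models.items():
            for name, b, se, sig in zip(COEF_NAMES, fr.beta, fr.se, fr.significant):
                star = "*" if sig else ""
                row[f"{name}_{model}"] = f"{b:.3g} ({se:.2g}){star}"
        rows.append(row)
    nsio._write_csv(pd.DataFrame(rows), path, chash)
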