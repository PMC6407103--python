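"""File-format contracts: session/wind CSV, route GeoJSON, fit JSON.

Sessions travel as CSV with ISO-8601 timestamps, planar coordinates in
meters and one column per pollutant channel with its unit embedded in the
header as ``name (unit)``.  Geometry travels as GeoJSON FeatureCollections
in the local planar frame (LineString features carrying a ``zone``
property; one Polygon feature named ``yard``).  Numeric output is written
at full precision; CSV writers prepend a ``#`` comment line recording the
configuration hash so every artifact is traceable to the run that made it.
"""
from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .background import BackgroundFit, SessionSeries
from .regression import FitResult
from .spatial import RouteGeometry, RoutePolyline

__all__ = [
    "read_session_csv", "write_session_csv",
    "read_wind_csv", "write_wind_csv",
    "read_route_geojson", "write_route_geojson",
    "write_fit_json", "read_fit_json",
]

_CHANNEL_RE = re.compile(r"^(?P<name>.+?)\s*\((?P<unit>[^)]+)\)\s*$")
_REQUIRED = ("timestamp", "x_m", "y_m")


def write_session_csv(session: SessionSeries, path: str | Path, config_hash: str | None = None) -> None:
    df = pd.DataFrame({"timestamp": session.timestamps, "x_m": session.xy[:, 0], "y_m": session.xy[:, 1]})
    for name, vals in session.channels.items():
        unit = session.units.get(name, "1")
        df[f"{name} ({unit})"] = vals
    if session.motion is not None:
        df["in_motion"] = session.motion.astype(int)
    _write_csv(df, path, config_hash, float_format="%.12g")


def read_session_csv(path: str | Path, session_id: str | None = None) -> SessionSeries:
    """Read and validate one session file.

    Channel units are parsed from ``name (unit)`` headers.  Rows with
    unparseable timestamps are dropped; if no row parses, or the surviving
    times are not strictly increasing, a ValueError names the file (and the
    first offending row for the monotonicity case).
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    for col in _REQUIRED:
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad = ts.isna()
    if bad.all():
        raise ValueError(f"{path.name}: no parseable timestamps")
    if bad.any():
        df = df[~bad]
        ts = ts[~bad]
    t0 = ts.iloc[0]
    times = (ts - t0).dt.total_seconds().to_numpy()
    nonmono = np.flatnonzero(np.diff(times) <= 0)
    if nonmono.size:
        # +3: header line, 1-based numbering, second element of the pair
        raise ValueError(
            f"{path.name}: non-monotone timestamp at file row {int(nonmono[0]) + 3}"
        )
    channels: dict[str, np.ndarray] = {}
    units: dict[str, str] = {}
    for col in df.columns:
        if col in _REQUIRED or col == "in_motion":
            continue
        m = _CHANNEL_RE.match(col)
        name, unit = (m.group("name"), m.group("unit")) if m else (col, "1")
        channels[name] = df[col].to_numpy(dtype=float)
        units[name] = unit
    motion = df["in_motion"].to_numpy(dtype=bool) if "in_motion" in df.columns else None
    return SessionSeries(
        session_id=session_id or path.stem,
        start_time=t0,
        times=times,
        xy=df[["x_m", "y_m"]].to_numpy(dtype=float),
        channels=channels,
        units=units,
        motion=motion,
    )


def write_wind_csv(wind: pd.DataFrame, path: str | Path, config_hash: str | None = None) -> None:
    _write_csv(wind[["time", "speed_ms", "direction_deg"]], path, config_hash, float_format="%.12g")


def read_wind_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    for col in ("time", "speed_ms", "direction_deg"):
        if col not in df.columns:
            raise ValueError(f"{Path(path).name}: missing required column {col!r}")
    df["time"] = pd.to_datetime(df["time"])
    return df


def write_route_geojson(route: RouteGeometry, path: str | Path) -> None:
    features = [
        {"type": "Feature", "geometry": mapping(pl.geometry), "properties": {"zone": pl.zone}}
        for pl in route.polylines
    ]
    features.append(
        {"type": "Feature", "geometry": mapping(route.yard), "properties": {"name": "yard"}}
    )
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_route_geojson(path: str | Path) -> RouteGeometry:
    doc = json.loads(Path(path).read_text())
    polylines, yard = [], None
    for feat in doc.get("features", []):
        geom = shape(feat["geometry"])
        props = feat.get("properties") or {}
        if geom.geom_type == "Polygon":
            yard = geom
        elif geom.geom_type == "LineString":
            if "zone" not in props:
                raise ValueError(f"{Path(path).name}: LineString feature lacks 'zone' property")
            polylines.append(RoutePolyline(geometry=geom, zone=props["zone"]))
    if yard is None:
        raise ValueError(f"{Path(path).name}: no yard Polygon feature")
    if not polylines:
        raise ValueError(f"{Path(path).name}: no route LineString features")
    return RouteGeometry(polylines=polylines, yard=yard)


def write_fit_json(fits: dict[str, dict[str, FitResult]], path: str | Path, config_hash: str | None = None) -> None:
    """Serialise {channel: {model: FitResult}} with coefficient names."""
    from .regression import COEF_NAMES

    doc: dict = {"config_hash": config_hash, "channels": {}}
    for channel, models in fits.items():
        doc["channels"][channel] = {}
        for model, fr in models.items():
            entry = {
                "beta": dict(zip(COEF_NAMES, map(float, fr.beta))),
                "se": dict(zip(COEF_NAMES, map(float, fr.se))),
                "pvalues": dict(zip(COEF_NAMES, map(float, fr.pvalues))),
                "significant": dict(zip(COEF_NAMES, map(bool, fr.significant))),
                "loglik": fr.loglik,
                "converged": fr.converged,
                "n_rows": fr.n_rows,
            }
            if fr.cov_params is not None:
                entry["cov_params"] = {
                    "sill_sigma2": fr.cov_params.sill_sigma2,
                    "nugget_tau2": fr.cov_params.nugget_tau2,
                    "range_phi": fr.cov_params.range_phi,
                }
            doc["channels"][channel][model] = entry
    Path(path).write_text(json.dumps(doc, indent=1))


def read_fit_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _write_csv(df: pd.DataFrame, path: str | Path, config_hash: str | None, **kwargs) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False, **kwargs)
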