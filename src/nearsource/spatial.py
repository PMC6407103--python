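"""Road-segment aggregation of mobile-monitoring data by wind category.

Measurements collected while driving a fixed route near an emission source
(here, a freight railyard) are snapped to 50 m road segments and summarised
as the median concentration per segment and hourly wind category.  Medians
resist the extreme transients produced by passing exhaust plumes.  Each
aggregated record carries the covariates used downstream by the
source-proximity regression: a calm-wind indicator, a within-yard indicator,
a downwind indicator, and the mean distance of its member measurements to
the yard edge.

All geometry is planar, in meters (a local tangent frame); distances are
Euclidean.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import substring

__all__ = [
    "WindCategory",
    "CALM_SPEED_MS",
    "SECTOR_BOUNDS",
    "RoutePolyline",
    "RouteGeometry",
    "RoadSegment",
    "classify_wind",
    "classify_wind_series",
    "segment_route",
    "assign_measurements",
    "distance_to_yard",
    "downwind_indicator",
    "aggregate_medians",
    "apply_filters",
    "zone_summary",
]

#: Hourly wind speed at or below this (m/s) is classified as calm.
CALM_SPEED_MS = 0.5


class WindCategory(str, Enum):
    """Five hourly wind categories relative to the yard's long (N-S) axis.

    NNE and SSW are cross-yard sectors, SE and NW run parallel to the yard,
    and CALM covers hours with speed <= 0.5 m/s where plume direction is
    undefined.
    """

    CALM = "CALM"
    NNE = "NNE"
    SSW = "SSW"
    SE = "SE"
    NW = "NW"


#: Half-open [low, high) direction sectors in meteorological degrees
#: ("blowing from").  NNE wraps through north (337.5 -> 112.5).
SECTOR_BOUNDS: dict[WindCategory, tuple[float, float]] = {
    WindCategory.NNE: (337.5, 112.5),
    WindCategory.SE: (112.5, 157.5),
    WindCategory.SSW: (157.5, 292.5),
    WindCategory.NW: (292.5, 337.5),
}


def classify_wind(speed_ms: float, direction_deg: float) -> WindCategory:
    """Classify one hourly wind observation into a :class:`WindCategory`.

    Parameters
    ----------
    speed_ms
        Hourly mean wind speed, m/s.  Must be >= 0.
    direction_deg
        Meteorological direction the wind blows *from*, degrees in [0, 360).
        Values outside the range are normalised modulo 360 with a warning.

    Notes
    -----
    Sector intervals are half-open [low, high); the NNE sector owns the wrap
    through 0 degrees, so 337.5 is NNE and 112.5 is SE.  Speeds <= 0.5 m/s
    are CALM regardless of direction.
    """
    if speed_ms < 0:
        raise ValueError(f"wind speed must be nonnegative, got {speed_ms}")
    if not (0 <= direction_deg < 360):
        warnings.warn(
            f"wind direction {direction_deg} outside [0, 360); normalising",
            stacklevel=2,
        )
        direction_deg = direction_deg % 360.0
    if speed_ms <= CALM_SPEED_MS:
        return WindCategory.CALM
    if 112.5 <= direction_deg < 157.5:
        return WindCategory.SE
    if 157.5 <= direction_deg < 292.5:
        return WindCategory.SSW
    if 292.5 <= direction_deg < 337.5:
        return WindCategory.NW
    return WindCategory.NNE


def classify_wind_series(speed_ms: np.ndarray, direction_deg: np.ndarray) -> np.ndarray:
    """Vectorised :func:`classify_wind`; returns an object array of category values."""
    speed = np.asarray(speed_ms, dtype=float)
    direc = np.asarray(direction_deg, dtype=float) % 360.0
    out = np.empty(speed.shape, dtype=object)
    out[...] = WindCategory.NNE
    out[(112.5 <= direc) & (direc < 157.5)] = WindCategory.SE
    out[(157.5 <= direc) & (direc < 292.5)] = WindCategory.SSW
    out[(292.5 <= direc) & (direc < 337.5)] = WindCategory.NW
    out[speed <= CALM_SPEED_MS] = WindCategory.CALM
    return out


@dataclass(frozen=True)
class RoutePolyline:
    """One labelled route polyline: zone is 'east', 'west' or 'within'."""

    geometry: LineString
    zone: str


@dataclass
class RouteGeometry:
    """The monitoring route (labelled polylines) and the yard polygon."""

    polylines: list[RoutePolyline]
    yard: Polygon

    def __post_init__(self) -> None:
        if self.yard.is_empty or not self.yard.is_valid or self.yard.area <= 0:
            raise ValueError("yard polygon is degenerate")
        for pl in self.polylines:
            if pl.zone not in ("east", "west", "within"):
                raise ValueError(f"unknown zone label {pl.zone!r}")
            touches = pl.geometry.intersects(self.yard)
            if pl.zone == "within" and not touches:
                raise ValueError("'within' polyline does not intersect the yard")
            if pl.zone != "within" and touches:
                raise ValueError(f"'{pl.zone}' polyline intersects the yard")


@dataclass(frozen=True)
class RoadSegment:
    """A ~50 m piece of a route polyline with its zone and along-line midpoint."""

    id: str
    geometry: LineString
    zone: str
    centroid: tuple[float, float]


def segment_route(route: RouteGeometry, segment_length_m: float = 50.0) -> list[RoadSegment]:
    """Cut each route polyline into consecutive pieces of ``segment_length_m``.

    Pieces are non-overlapping and cover the polyline; the final piece of a
    polyline may be a shorter remainder.  The zone label is inherited from
    the parent polyline and the centroid is the along-line midpoint.
    """
    if segment_length_m <= 0:
        raise ValueError("segment_length_m must be positive")
    segments: list[RoadSegment] = []
    for i, pl in enumerate(route.polylines):
        total = pl.geometry.length
        if total < segment_length_m:
            raise ValueError(
                f"polyline {i} ({pl.zone}) shorter than one segment "
                f"({total:.1f} < {segment_length_m} m)"
            )
        start = 0.0
        k = 0
        while start < total - 1e-9:
            end = min(start + segment_length_m, total)
            geom = substring(pl.geometry, start, end)
            mid = geom.interpolate(0.5, normalized=True)
            segments.append(
                RoadSegment(
                    id=f"{pl.zone[0]}{i:02d}-{k:03d}",
                    geometry=geom,
                    zone=pl.zone,
                    centroid=(mid.x, mid.y),
                )
            )
            start = end
            k += 1
    return segments


def _segment_edges(segments: list[RoadSegment]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten segment polylines into (edge starts, edge ends, owning index)."""
    starts, ends, owner = [], [], []
    for j, seg in enumerate(segments):
        xy = np.asarray(seg.geometry.coords)
        starts.append(xy[:-1])
        ends.append(xy[1:])
        owner.append(np.full(len(xy) - 1, j))
    return np.vstack(starts), np.vstack(ends), np.concatenate(owner)


def assign_measurements(
    xy: np.ndarray, segments: list[RoadSegment], snap_max_m: float = 30.0
) -> np.ndarray:
    """Snap measurement positions to their nearest road segment.

    Parameters
    ----------
    xy
        (n, 2) planar positions in meters.
    segments
        Candidate segments; ties at equal distance break to the
        earlier-listed (lower-id) segment.
    snap_max_m
        Positions farther than this from every segment are unassigned.

    Returns
    -------
    (n,) integer array of segment indices, -1 for unassigned.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("xy must be (n, 2)")
    a, b, owner = _segment_edges(segments)
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0

    n = xy.shape[0]
    out = np.full(n, -1, dtype=int)
    # chunked to bound the (points x edges) distance matrix
    chunk = max(1, int(5e6 / max(1, len(owner))))
    nseg = len(segments)
    for lo in range(0, n, chunk):
        p = xy[lo : lo + chunk]
        # point-to-edge distance for every (point, edge) pair
        ap = p[:, None, :] - a[None, :, :]
        t = np.clip(np.einsum("pej,ej->pe", ap, ab) / denom, 0.0, 1.0)
        closest = a[None, :, :] + t[..., None] * ab[None, :, :]
        d = np.linalg.norm(p[:, None, :] - closest, axis=2)
        # reduce edges -> segments, keeping the lowest index at ties
        dseg = np.full((p.shape[0], nseg), np.inf)
        np.minimum.at(dseg.T, owner, d.T)
        best = np.argmin(dseg, axis=1)
        bestd = dseg[np.arange(p.shape[0]), best]
        assigned = bestd <= snap_max_m
        out[lo : lo + chunk][assigned] = best[assigned]
    return out


def distance_to_yard(xy: np.ndarray, yard: Polygon) -> np.ndarray:
    """Distance (km) from each point to the yard edge; 0 inside or on it."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    pts = shapely.points(xy)
    d = shapely.distance(pts, yard.exterior)
    inside = shapely.covers(yard, pts)
    d = np.where(inside, 0.0, d)
    return d / 1000.0


#: (zone, wind category) pairs for which a segment receives transported
#: yard emissions: SSW wind reaches the eastern side, NNE the western side.
_DOWNWIND = {("east", WindCategory.SSW), ("west", WindCategory.NNE)}


def downwind_indicator(zone: str, wind: WindCategory) -> int:
    """1 if a segment in ``zone`` is downwind of the yard under ``wind``.

    Only cross-yard winds create a downwind side; parallel (SE/NW) and calm
    hours, and segments within the yard, score 0.
    """
    if zone not in ("east", "west", "within"):
        raise ValueError(f"unknown zone {zone!r}")
    return int((zone, WindCategory(wind)) in _DOWNWIND)


def aggregate_medians(records: pd.DataFrame, segments: list[RoadSegment]) -> pd.DataFrame:
    """Median concentration per (segment, wind category, channel).

    Parameters
    ----------
    records
        Tidy measurement table with columns ``segment_idx`` (int index into
        ``segments``), ``wind_category``, ``channel``, ``value`` and
        ``distance_km`` (per-measurement distance to the yard edge).
        Non-finite values are ignored.
    segments
        The segment list used for assignment; supplies ids, zones and
        centroid coordinates.

    Returns
    -------
    DataFrame with one row per (segment, category, channel):
    ``segment_id, zone, seg_x, seg_y, wind_category, channel, median,
    n_obs, distance_km, calm, railyard, downwind``.  This is the exact
    input contract of the regression module.
    """
    req = {"segment_idx", "wind_category", "channel", "value", "distance_km"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    df = records[records["segment_idx"] >= 0].copy()
    df = df[np.isfinite(df["value"].to_numpy(dtype=float))]
    grouped = (
        df.groupby(["segment_idx", "wind_category", "channel"], sort=True, observed=True)
        .agg(median=("value", "median"), n_obs=("value", "size"), distance_km=("distance_km", "mean"))
        .reset_index()
    )
    seg_idx = grouped["segment_idx"].to_numpy()
    grouped["segment_id"] = [segments[i].id for i in seg_idx]
    grouped["zone"] = [segments[i].zone for i in seg_idx]
    grouped["seg_x"] = [segments[i].centroid[0] for i in seg_idx]
    grouped["seg_y"] = [segments[i].centroid[1] for i in seg_idx]
    cats = [WindCategory(w) for w in grouped["wind_category"]]
    grouped["wind_category"] = [c.value for c in cats]
    grouped["calm"] = [int(c is WindCategory.CALM) for c in cats]
    grouped["railyard"] = (grouped["zone"] == "within").astype(int)
    grouped["downwind"] = [
        downwind_indicator(z, c) for z, c in zip(grouped["zone"], cats)
    ]
    # measurements inside the yard have distance 0 by construction; force the
    # within-zone mean to 0 to guard against snapping artefacts at the edge
    grouped.loc[grouped["railyard"] == 1, "distance_km"] = 0.0
    cols = [
        "segment_id", "zone", "seg_x", "seg_y", "wind_category", "channel",
        "median", "n_obs", "distance_km", "calm", "railyard", "downwind",
    ]
    return grouped[cols]


def apply_filters(
    records: pd.DataFrame, min_n: int = 5, max_dist_km: float = 1.0
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Drop sparsely sampled or distant aggregated records.

    Retains records with at least ``min_n`` member measurements and mean
    distance within ``max_dist_km`` of the yard edge (both bounds
    inclusive).  Returns the filtered table and the excluded fraction per
    channel.
    """
    keep = (records["n_obs"] >= min_n) & (records["distance_km"] <= max_dist_km)
    excluded: dict[str, float] = {}
    for ch, grp in records.groupby("channel", observed=True):
        k = keep.loc[grp.index]
        excluded[str(ch)] = float(1.0 - k.mean()) if len(grp) else 0.0
    out = records[keep].reset_index(drop=True)
    if out.empty:
        raise ValueError(
            f"no aggregated records survive the filters (min_n={min_n}, "
            f"max_dist_km={max_dist_km})"
        )
    return out, excluded


def zone_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Geometric mean and quartiles of segment medians per zone x wind x channel.

    The geometric mean is exp(mean(log median)), the natural summary for
    log-normal concentration data.  Non-positive medians are excluded with
    a warning.
    """
    df = records.copy()
    bad = df["median"] <= 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} non-positive medians from zone summary")
        df = df[~bad]
    out = (
        df.groupby(["zone", "wind_category", "channel"], observed=True)["median"]
        .agg(
            geometric_mean=lambda v: float(np.exp(np.mean(np.log(v)))),
            q25=lambda v: float(np.quantile(v, 0.25)),
            q75=lambda v: float(np.quantile(v, 0.75)),
            n="size",
        )
        .reset_index()
    )
    return out
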