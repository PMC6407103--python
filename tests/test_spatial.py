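"""Segmentation, wind classification, assignment, aggregation and filters."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from shapely.geometry import LineString, Point, Polygon

import nearsource as ns
from nearsource.spatial import RoutePolyline, WindCategory


def _line_route(length, yard=None):
    yard = yard or Polygon([(-50, -50), (-40, -50), (-40, 50), (-50, 50)])
    pl = RoutePolyline(geometry=LineString([(0, 0), (length, 0)]), zone="east")
    return ns.RouteGeometry(polylines=[pl], yard=yard)


# ----------------------------------------------------------------- segmentation

def test_exact_multiple_gives_equal_segments():
    segs = ns.segment_route(_line_route(1000.0), 50.0)
    assert len(segs) == 20
    assert all(abs(s.geometry.length - 50.0) < 1e-6 for s in segs)


def test_remainder_segment_kept():
    segs = ns.segment_route(_line_route(1025.0), 50.0)
    assert len(segs) == 21
    assert segs[-1].geometry.length == pytest.approx(25.0, abs=1e-6)


def test_segment_union_conserves_length(default_route):
    segs = ns.segment_route(default_route, 50.0)
    total = sum(s.geometry.length for s in segs)
    expect = sum(pl.geometry.length for pl in default_route.polylines)
    assert total == pytest.approx(expect, abs=0.1)
    assert {s.zone for s in segs} == {"east", "west", "within"}


# ---------------------------------------------------------- wind classification

@pytest.mark.parametrize(
    "speed,direction,expected",
    [
        (0.4, 200.0, WindCategory.CALM),
        (0.5, 10.0, WindCategory.CALM),  # threshold is inclusive
        (2.0, 45.0, WindCategory.NNE),
        (2.0, 200.0, WindCategory.SSW),
        (2.0, 130.0, WindCategory.SE),
        (2.0, 300.0, WindCategory.NW),
        (2.0, 337.5, WindCategory.NNE),  # NNE owns the wrap through north
        (2.0, 112.5, WindCategory.SE),   # half-open sector boundaries
        (2.0, 0.0, WindCategory.NNE),
    ],
)
def test_classify_wind_examples(speed, direction, expected):
    assert ns.classify_wind(speed, direction) is expected


def test_direction_sweep_is_a_partition():
    dirs = np.arange(0.0, 360.0, 0.1)
    cats = [ns.classify_wind(2.0, d) for d in dirs]
    assert all(c is not WindCategory.CALM for c in cats)
    counts = pd.Series([c.value for c in cats]).value_counts()
    assert set(counts.index) == {"NNE", "SSW", "SE", "NW"}
    # sector widths: NNE 135, SSW 135, SE 45, NW 45 degrees
    assert counts["NNE"] == 1350 and counts["SSW"] == 1350
    assert counts["SE"] == 450 and counts["NW"] == 450


def test_out_of_range_direction_normalised_with_warning():
    with pytest.warns(UserWarning):
        assert ns.classify_wind(2.0, 405.0) is WindCategory.NNE


@given(st.floats(0.51, 30.0), st.floats(0.0, 359.999))
def test_vectorised_classification_matches_scalar(speed, direction):
    scalar = ns.classify_wind(speed, direction)
    vec = ns.spatial.classify_wind_series(np.array([speed]), np.array([direction]))[0]
    assert vec is scalar


# -------------------------------------------------------------------- snapping

def test_point_on_midline_assigned_to_that_segment():
    segs = ns.segment_route(_line_route(1000.0), 50.0)
    idx = ns.assign_measurements(np.array([[125.0, 0.0]]), segs, snap_max_m=30.0)
    assert segs[idx[0]].id == segs[2].id


def test_far_point_unassigned():
    segs = ns.segment_route(_line_route(1000.0), 50.0)
    idx = ns.assign_measurements(np.array([[500.0, 500.0]]), segs, snap_max_m=30.0)
    assert idx[0] == -1


def test_assignment_matches_brute_force_shapely():
    segs = ns.segment_route(_line_route(1000.0), 50.0)
    rng = np.random.default_rng(2)
    pts = np.column_stack([rng.uniform(-50, 1050, 1000), rng.uniform(-40, 40, 1000)])
    idx = ns.assign_measurements(pts, segs, snap_max_m=25.0)
    for k in range(0, 1000, 29):
        p = Point(pts[k])
        dists = np.array([s.geometry.distance(p) for s in segs])
        if dists.min() > 25.0:
            assert idx[k] == -1
        else:
            assert dists[idx[k]] == pytest.approx(dists.min(), abs=1e-9)


# ------------------------------------------------------------ distance to yard

def test_distance_to_yard_conventions(default_route):
    yard = default_route.yard
    centroid = np.array([[yard.centroid.x, yard.centroid.y]])
    assert ns.distance_to_yard(centroid, yard)[0] == 0.0
    east_edge_x = yard.bounds[2]
    assert ns.distance_to_yard(np.array([[east_edge_x + 250.0, 0.0]]), yard)[0] == pytest.approx(0.25)
    assert ns.distance_to_yard(np.array([[east_edge_x, 0.0]]), yard)[0] == 0.0


# ------------------------------------------------------------------- downwind

@pytest.mark.parametrize(
    "zone,wind,expected",
    [
        ("east", WindCategory.SSW, 1),
        ("west", WindCategory.NNE, 1),
        ("east", WindCategory.NNE, 0),
        ("west", WindCategory.SSW, 0),
        ("within", WindCategory.SSW, 0),
        ("east", WindCategory.CALM, 0),
        ("east", WindCategory.SE, 0),
        ("west", WindCategory.NW, 0),
    ],
)
def test_downwind_indicator_table(zone, wind, expected):
    assert ns.downwind_indicator(zone, wind) == expected


# ----------------------------------------------------------------- aggregation

def _records(values, cats=None, seg=0):
    n = len(values)
    return pd.DataFrame(
        {
            "segment_idx": [seg] * n,
            "wind_category": cats or ["SSW"] * n,
            "channel": ["NO"] * n,
            "value": values,
            "distance_km": [0.2] * n,
        }
    )


@pytest.fixture(scope="module")
def line_segments():
    return ns.segment_route(_line_route(1000.0), 50.0)


def test_median_resists_outlier(line_segments):
    agg = ns.aggregate_medians(_records([1.0, 2.0, 100.0]), line_segments)
    assert agg["median"].iloc[0] == 2.0
    assert agg["n_obs"].iloc[0] == 3


def test_even_count_median_is_midpoint(line_segments):
    agg = ns.aggregate_medians(_records([1.0, 2.0, 3.0, 4.0]), line_segments)
    assert agg["median"].iloc[0] == 2.5


def test_wind_categories_kept_separate(line_segments):
    rec = _records([1.0, 2.0, 3.0, 4.0], cats=["SSW", "SSW", "NNE", "NNE"])
    agg = ns.aggregate_medians(rec, line_segments)
    assert len(agg) == 2
    assert set(agg["wind_category"]) == {"SSW", "NNE"}
    # the east-zone segment is downwind only under SSW
    assert agg.set_index("wind_category")["downwind"].to_dict() == {"SSW": 1, "NNE": 0}


def test_member_counts_conserved(line_segments):
    rng = np.random.default_rng(3)
    n = 500
    rec = pd.DataFrame(
        {
            "segment_idx": rng.integers(-1, len(line_segments), n),
            "wind_category": rng.choice(["CALM", "SSW", "NNE"], n),
            "channel": "NO",
            "value": rng.lognormal(0, 1, n),
            "distance_km": rng.uniform(0, 0.5, n),
        }
    )
    agg = ns.aggregate_medians(rec, line_segments)
    assert agg["n_obs"].sum() == (rec["segment_idx"] >= 0).sum()


def test_aggregation_permutation_invariant(line_segments):
    rng = np.random.default_rng(4)
    rec = pd.DataFrame(
        {
            "segment_idx": rng.integers(0, 5, 200),
            "wind_category": rng.choice(["CALM", "SSW"], 200),
            "channel": "NO",
            "value": rng.lognormal(0, 1, 200),
            "distance_km": rng.uniform(0, 0.5, 200),
        }
    )
    a = ns.aggregate_medians(rec, line_segments)
    b = ns.aggregate_medians(rec.sample(frac=1.0, random_state=1), line_segments)
    pd.testing.assert_frame_equal(
        a.reset_index(drop=True), b.reset_index(drop=True), check_exact=False
    )


# --------------------------------------------------------------------- filters

def _agg_row(n_obs, dist):
    return pd.DataFrame(
        {
            "segment_id": ["s0"], "zone": ["east"], "seg_x": [0.0], "seg_y": [0.0],
            "wind_category": ["SSW"], "channel": ["NO"], "median": [1.0],
            "n_obs": [n_obs], "distance_km": [dist], "calm": [0], "railyard": [0],
            "downwind": [1],
        }
    )


def test_filters_drop_sparse_and_distant_keep_boundary():
    ok = _agg_row(5, 0.99)
    sparse = _agg_row(4, 0.2)
    far = _agg_row(10, 1.2)
    records = pd.concat([ok, sparse, far], ignore_index=True)
    kept, excluded = ns.apply_filters(records, min_n=5, max_dist_km=1.0)
    assert len(kept) == 1
    assert kept["distance_km"].iloc[0] == 0.99
    assert excluded["NO"] == pytest.approx(2 / 3)


def test_filters_hard_error_when_everything_excluded():
    with pytest.raises(ValueError, match="min_n"):
        ns.apply_filters(_agg_row(1, 2.0))


# ---------------------------------------------------------------- zone summary

def test_zone_summary_geometric_means():
    rows = []
    for v in (1.0, 100.0):
        r = _agg_row(10, 0.2)
        r["median"] = v
        rows.append(r)
    out = ns.zone_summary(pd.concat(rows, ignore_index=True))
    assert out["geometric_mean"].iloc[0] == pytest.approx(10.0)

    rows = []
    for v in (2.0, 8.0, 32.0):
        r = _agg_row(10, 0.2)
        r["median"] = v
        rows.append(r)
    out = ns.zone_summary(pd.concat(rows, ignore_index=True))
    assert out["geometric_mean"].iloc[0] == pytest.approx(8.0)


def test_zone_summary_single_record_is_identity():
    out = ns.zone_summary(_agg_row(10, 0.2).assign(median=7.0))
    assert out["geometric_mean"].iloc[0] == pytest.approx(7.0)


def test_zone_summary_warns_on_nonpositive():
    rec = pd.concat([_agg_row(10, 0.2).assign(median=v) for v in (4.0, 0.0)], ignore_index=True)
    with pytest.warns(UserWarning):
        out = ns.zone_summary(rec)
    assert out["geometric_mean"].iloc[0] == pytest.approx(4.0)
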