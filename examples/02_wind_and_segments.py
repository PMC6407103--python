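"""Classify winds and aggregate measurements onto 50 m road segments.

Builds the study route, simulates a short campaign, snaps every
measurement to its nearest segment and summarises the medians by the five
hourly wind categories.
"""
import nearsource as ns
from nearsource.pipeline import sessions_to_records
from nearsource.spatial import aggregate_medians, apply_filters, zone_summary

cfg = ns.ScenarioConfig(seed=21, n_sessions=4, sample_interval_s=3.0,
                        session_duration_h=(1.5, 2.5))
sessions, wind, route, _ = ns.simulate_scenario(cfg)

segments, records = sessions_to_records(sessions, wind, route)
print("wind categories observed while driving:",
      records["wind_category"].value_counts().to_dict())
print(f"{len(segments)} segments of 50 m; "
      f"{(records['segment_idx'] >= 0).mean():.0%} of records snapped within 30 m")

agg = aggregate_medians(records, segments)
agg, excluded = apply_filters(agg, min_n=5, max_dist_km=1.0)
print(f"{len(agg)} segment x wind-category medians kept "
      f"(excluded fraction: {excluded['NO']:.2f})")
print("\ngeometric-mean concentration by zone (ppb):")
print(zone_summary(agg).to_string(index=False))
print("\nconcentrations are highest on the within-yard transect and fall "
      "off with distance on the flanking roads")
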