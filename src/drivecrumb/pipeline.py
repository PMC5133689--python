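"""End-to-end pipeline: files in, driver profiles out.

Order of operations: read -> flag defective devices (on raw data, since the
defect signature *is* the zero coordinates that cleaning removes) ->
coordinate filter with whole-trip propagation -> timestamp dedupe -> trip
filters -> trip reconstruction -> time-zone / local-time / light-phase
assignment -> spatial profile -> optional road annotation -> behavioral
profile -> per-driver-month assembly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, ingest, roads, spatial, timekit
from .config import M_PER_FT, ProfileConfig

__all__ = ["PipelineResult", "run_pipeline", "run_pipeline_frames"]


@dataclass
class PipelineResult:
    config: ProfileConfig
    crumbs: pd.DataFrame                     # cleaned, localized breadcrumbs
    activity: pd.DataFrame                   # cleaned trip records
    trips: list                              # reconstructed Trip objects
    trip_table: pd.DataFrame                 # one row per usable trip
    profiles: list                           # DriverProfile records
    profiles_frame: pd.DataFrame
    cleaning_report: ingest.CleaningReport
    defective_vehicles: list[str]
    primaries: dict                          # driver -> [PrimaryLocation]
    overlaps: dict                           # driver -> OverlapMetrics
    projections: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.crumbs.drop(columns=["x", "y"], errors="ignore").to_csv(
            out / "breadcrumbs_clean.csv", index=False)
        self.activity.to_csv(out / "activity_clean.csv", index=False)
        self.trip_table.to_csv(out / "trips.csv", index=False)
        self.profiles_frame.to_csv(out / "profiles.csv", index=False)
        self.cleaning_report.to_json(out / "cleaning_report.json")
        feats = []
        for driver, prims in self.primaries.items():
            for p in prims:
                feats.append({
                    "type": "Feature",
                    "properties": {"driver_id": driver, "kind": "primary_location",
                                   "share": p.share, "n_ignition_on": p.n_ignition_on},
                    "geometry": {"type": "Point",
                                 "coordinates": [p.centroid_lon, p.centroid_lat]},
                })
        (out / "primary_locations.geojson").write_text(
            json.dumps({"type": "FeatureCollection", "features": feats}, indent=1))
        overlaps = {
            d: {"periods": m.periods, "common_all_km2": m.common_all_km2,
                "total_km2": m.total_km2, "ratio": m.ratio,
                "pairwise_km2": {f"{a}|{b}": v for (a, b), v in m.pairwise_km2.items()}}
            for d, m in self.overlaps.items()
        }
        (out / "overlap_metrics.json").write_text(json.dumps(overlaps, indent=1))


def _period_label(ts_local: pd.Timestamp, period: str) -> str:
    return f"{ts_local:%G-W%V}" if period == "week" else f"{ts_local:%Y-%m}"


def run_pipeline(
    config: ProfileConfig,
    breadcrumb_paths,
    activity_paths,
    streets_path: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full pipeline from CSV inputs; see `run_pipeline_frames`."""
    crumbs, bc_report = ingest.read_breadcrumbs(breadcrumb_paths)
    activity, act_report = ingest.read_activity(activity_paths)
    if not len(crumbs):
        raise ValueError("no breadcrumbs read (all files empty, missing or rejected)")
    result = run_pipeline_frames(config, crumbs, activity, streets_path=streets_path)
    for path, reason in bc_report.rejected + act_report.rejected:
        result.cleaning_report.log("file", f"rejected: {reason}", path=path)
    if out_dir is not None:
        result.write(out_dir)
    return result


def run_pipeline_frames(
    config: ProfileConfig,
    crumbs: pd.DataFrame,
    activity: pd.DataFrame,
    streets_path: str | Path | None = None,
) -> PipelineResult:
    """Pipeline body operating on already-read tables."""
    report = ingest.CleaningReport(
        n_input_breadcrumbs=len(crumbs), n_input_trips=len(activity))

    # -- defective devices are detected on raw data ----------------------
    defective = ingest.flag_defective_devices(
        crumbs, window_days=config.defect_window_days,
        zero_fraction_threshold=config.defect_zero_fraction,
        min_crumbs=config.defect_min_crumbs)
    report.defective_vehicle_ids = defective

    # -- cleaning: coordinates (with trip propagation) then duplicates ---
    prov = ingest.assign_provisional_trips(crumbs)
    crumbs, _, report = ingest.filter_coordinates(
        crumbs, bbox=config.conus_bbox, trip_ids=prov, report=report)
    crumbs, _, report = ingest.dedupe_timestamps(crumbs, report=report)
    activity, _, report = ingest.filter_trips(activity, report=report)

    # -- trips ------------------------------------------------------------
    trips, quarantined = ingest.reconstruct_trips(
        crumbs, abandoned_gap_s=config.abandoned_gap_s,
        abandoned_max_intervening=config.abandoned_max_intervening)
    for q in quarantined:
        report.log("breadcrumb", "unmatched_ignition_off", row=int(q))
    usable = [t for t in ingest.usable_trips(trips) if t.vehicle_id not in defective]

    # -- local time and light phase ---------------------------------------
    tz_map = timekit.TimeZoneMap.from_geojson(
        config.tz_polygons or None,
        fast_bbox=config.tz_fast_bbox, fast_zone=config.tz_fast_zone)
    tz_ids = tz_map.lookup_many(
        crumbs["latitude"].to_numpy(), crumbs["longitude"].to_numpy())
    crumbs = crumbs.assign(tz_id=tz_ids)
    local = pd.Series(pd.NaT, index=crumbs.index, dtype=object)
    for tz, grp in crumbs.groupby("tz_id", sort=True):
        if tz:
            local.loc[grp.index] = grp["timestamp_utc"].dt.tz_convert(tz)
    crumbs = crumbs.assign(timestamp_local=local)
    crumbs = crumbs.assign(period=[
        _period_label(ts, config.period) if ts is not pd.NaT else ""
        for ts in crumbs["timestamp_local"]])

    trip_rows = []
    for t in usable:
        start = crumbs.loc[t.indices[0]]
        if start["tz_id"] == "" or start["timestamp_local"] is pd.NaT:
            continue  # unresolved zone: excluded from local-time analyses
        phase = timekit.classify_trip_light(
            start["timestamp_local"].to_pydatetime(),
            start["latitude"], start["longitude"],
            night_definition=config.night_definition)
        trip_rows.append({
            "vehicle_id": t.vehicle_id, "trip_id": t.trip_id,
            "start_utc": start["timestamp_utc"],
            "start_local": start["timestamp_local"],
            "period": _period_label(start["timestamp_local"], config.period),
            "phase": phase, "n_crumbs": t.n_crumbs,
            "no_ignition_off": t.no_ignition_off,
        })
    trip_table = pd.DataFrame(trip_rows)

    # -- match trips to activity records for distance/duration ------------
    if len(trip_table) and len(activity):
        dist, dur, os_dur = [], [], []
        acounts = {"n_sudden_accel": [], "n_hard_braking": [], "n_overspeeding": []}
        for _, row in trip_table.iterrows():
            cand = activity[activity["vehicle_id"] == row["vehicle_id"]]
            match = None
            if len(cand):
                delta = (cand["start_time_utc"] - row["start_utc"]).abs()
                j = delta.idxmin()
                if delta.loc[j].total_seconds() <= 60:
                    match = activity.loc[j]
            dist.append(float(match["distance_mi"]) if match is not None else np.nan)
            dur.append(float(match["duration_s"]) if match is not None else np.nan)
            os_dur.append(float(match["overspeeding_duration_s"])
                          if match is not None else np.nan)
            for k in acounts:
                acounts[k].append(int(match[k]) if match is not None else 0)
        trip_table["distance_mi"] = dist
        trip_table["duration_s"] = dur
        trip_table["overspeeding_duration_s"] = os_dur
        for k, v in acounts.items():
            trip_table[k] = v
    elif len(trip_table):
        trip_table["distance_mi"] = np.nan
        trip_table["duration_s"] = np.nan
        trip_table["overspeeding_duration_s"] = np.nan
        for k in ("n_sudden_accel", "n_hard_braking", "n_overspeeding"):
            trip_table[k] = 0

    # -- alerts ------------------------------------------------------------
    events, discrepancies = behavior.extract_alerts(crumbs, usable, activity)
    for d in discrepancies:
        report.log("alert", "activity_breadcrumb_count_mismatch", **d)
    ev_by_trip: dict[int, dict[str, int]] = {}
    for ev in events:
        if ev.trip_id is not None:
            ev_by_trip.setdefault(ev.trip_id, {}).setdefault(ev.kind, 0)
            ev_by_trip[ev.trip_id][ev.kind] += 1

    # -- optional road annotation ------------------------------------------
    projections: dict[str, spatial.LocalProjection] = {}
    analysis = crumbs[~crumbs["vehicle_id"].isin(defective)]
    seg_index = None
    if streets_path is not None:
        # street tables are lon/lat; share one projection centred on the data
        proj_all = spatial.LocalProjection.for_points(
            analysis["latitude"].to_numpy(), analysis["longitude"].to_numpy())
        segs = roads.load_segments_geojson(streets_path, projection=proj_all)
        seg_index = roads.build_segment_index(segs)
        x, y = proj_all.forward(crumbs["latitude"].to_numpy(),
                                crumbs["longitude"].to_numpy())
        crumbs = crumbs.assign(x=x, y=y)
        crumbs = roads.annotate_breadcrumbs(
            crumbs, seg_index, max_snap_m=config.max_snap_m)
        projections["__shared__"] = proj_all

    # -- spatial profile per driver ----------------------------------------
    link_m = config.aggregate_distance_ft * M_PER_FT
    primaries: dict[str, list] = {}
    overlaps: dict[str, spatial.OverlapMetrics] = {}
    profiles = []
    drivers = sorted(analysis["vehicle_id"].unique())
    all_periods = sorted(p for p in analysis["period"].unique() if p)

    for driver in drivers:
        dc = analysis[analysis["vehicle_id"] == driver]
        proj = spatial.LocalProjection.for_points(
            dc["latitude"].to_numpy(), dc["longitude"].to_numpy())
        projections[driver] = proj
        x, y = proj.forward(dc["latitude"].to_numpy(), dc["longitude"].to_numpy())
        dxy = np.column_stack([x, y])
        ign_mask = (dc["event_type"] == "ignition_on").to_numpy()
        clusters = spatial.cluster_ignition_points(
            dxy[ign_mask], link_distance_m=link_m,
            min_size=config.min_cluster_size)
        prims = spatial.detect_primary_locations(
            clusters, int(ign_mask.sum()),
            share_threshold=config.primary_share, projection=proj)
        primaries[driver] = prims

        dareas = []
        dtrips = trip_table[trip_table["vehicle_id"] == driver] if len(trip_table) \
            else pd.DataFrame()
        for period in all_periods:
            in_p = (dc["period"] == period).to_numpy()
            pxy = dxy[in_p]
            area = spatial.compute_driving_area(pxy, driver, period)
            dareas.append(area)
            mc = spatial.compute_mean_center(pxy, driver, period, projection=proj) \
                if len(pxy) else None
            dest_counts = {
                r: spatial.count_unique_destinations(
                    dxy[in_p & ign_mask], r, driver, period).n_destinations
                for r in config.destination_radii_ft
            }
            ptrips = dtrips[dtrips["period"] == period] if len(dtrips) else pd.DataFrame()
            lc = {ph: int((ptrips["phase"] == ph).sum()) if len(ptrips) else 0
                  for ph in timekit.PHASES}
            ac: dict[str, int] = {}
            atc: dict[str, int] = {}
            if len(ptrips):
                for tid in ptrips["trip_id"]:
                    for kind, cnt in ev_by_trip.get(tid, {}).items():
                        ac[kind] = ac.get(kind, 0) + cnt
                        atc[kind] = atc.get(kind, 0) + 1
            miles = float(np.nansum(ptrips["distance_mi"])) if len(ptrips) else 0.0
            hours = float(np.nansum(ptrips["duration_s"]) / 3600.0) if len(ptrips) else 0.0
            profiles.append(behavior.assemble_profile(
                driver, period,
                light_counts=lc, alert_counts=ac, alert_trip_counts=atc,
                total_miles=miles, driving_hours=hours,
                driving_area_km2=None if area.degenerate else area.area_km2,
                mean_center=(mc.lat, mc.lon) if mc is not None else None,
                primary_locations=prims, destinations=dest_counts))
        overlaps[driver] = spatial.overlap_metrics(dareas, total_mode=config.overlap_total)

    # defective vehicles: explicit null-marked rows
    for driver in defective:
        for period in all_periods:
            profiles.append(behavior.assemble_profile(
                driver, period, null_reason="defective_device"))

    return PipelineResult(
        config=config, crumbs=crumbs, activity=activity, trips=trips,
        trip_table=trip_table, profiles=profiles,
        profiles_frame=behavior.profiles_to_frame(profiles),
        cleaning_report=report, defective_vehicles=defective,
        primaries=primaries, overlaps=overlaps, projections=projections)
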