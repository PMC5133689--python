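"""Adverse-driving alerts, day/night trip tallies, and the driver profile.

Three alert kinds reflect aggressive driving independent of context:
*overspeeding* (driving at least 6 mph over the posted-limit proxy),
*hard braking* (a 1-s speed drop of at least 8 mph) and *sudden
acceleration* (a 1-s speed gain of at least 10 mph). The in-vehicle device
reports these directly (``device_reported``); this module can additionally
recompute them from speed traces (``recomputed``) as a validation channel —
note the 30-s breadcrumb cadence cannot certify 1-s deltas, so braking and
acceleration recomputation applies to 1-Hz traces only. The headline
profile counts device-reported events.

The monthly :class:`DriverProfile` assembles spatial, temporal and
behavioral components into one record per driver-month; its summary columns
mirror the deposited study table (``numtripsover5mo``,
``trips_at_night5mo``, ``trips_w_HB5mo``, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

from .ingest import ALERT_EVENT_TYPES, Trip

__all__ = [
    "AlertEvent", "DriverProfile",
    "extract_alerts", "recompute_overspeeding", "recompute_accel_events",
    "count_trips_by_light", "trip_statistics", "assemble_profile",
    "cohort_summary", "load_deposited_summary",
]

_KIND_BY_EVENT = {
    "overspeeding": "overspeeding",
    "hard_braking": "hard_braking",
    "sudden_acceleration": "sudden_acceleration",
}


@dataclass
class AlertEvent:
    vehicle_id: str
    kind: str                       # overspeeding | hard_braking | sudden_acceleration
    time_utc: datetime
    latitude: float = float("nan")
    longitude: float = float("nan")
    peak_speed: float = float("nan")
    avg_event_speed: float = float("nan")
    initial_speed: float = float("nan")
    final_speed: float = float("nan")
    source: str = "device_reported"  # or "recomputed"
    trip_id: int | None = None
    orphan: bool = False             # alert fix outside any reconstructed trip


def extract_alerts(
    crumbs: pd.DataFrame,
    trips: list[Trip],
    activity: pd.DataFrame | None = None,
) -> tuple[list[AlertEvent], list[dict]]:
    """Collect device-reported alert rows and reconcile with trip-log counts.

    Each alert-typed breadcrumb becomes one event, attributed to the trip
    whose crumb window contains it (orphans flagged, kept). When an activity
    table is given, per-trip alert counts from both channels are compared
    and mismatches returned as discrepancy records.
    """
    idx_to_trip: dict[int, Trip] = {}
    for t in trips:
        if t.abandoned:
            continue
        for i in t.indices:
            idx_to_trip[i] = t

    events: list[AlertEvent] = []
    mask = crumbs["event_type"].isin(ALERT_EVENT_TYPES)
    for idx, row in crumbs.loc[mask].iterrows():
        t = idx_to_trip.get(idx)
        events.append(AlertEvent(
            vehicle_id=str(row["vehicle_id"]),
            kind=_KIND_BY_EVENT[row["event_type"]],
            time_utc=row["timestamp_utc"],
            latitude=row["latitude"], longitude=row["longitude"],
            peak_speed=row.get("peak_speed_mph", float("nan")),
            avg_event_speed=row.get("avg_event_speed_mph", float("nan")),
            initial_speed=row.get("initial_speed_mph", float("nan")),
            final_speed=row.get("final_speed_mph", float("nan")),
            trip_id=t.trip_id if t is not None else None,
            orphan=t is None,
        ))

    discrepancies: list[dict] = []
    if activity is not None and len(activity):
        # match each usable trip to the activity row starting nearest in time
        counts: dict[int, dict[str, int]] = {}
        for ev in events:
            if ev.trip_id is not None:
                counts.setdefault(ev.trip_id, {}).setdefault(ev.kind, 0)
                counts[ev.trip_id][ev.kind] += 1
        act = activity.copy()
        for t in trips:
            if t.abandoned:
                continue
            start = crumbs.loc[t.indices[0], "timestamp_utc"]
            cand = act[(act["vehicle_id"] == t.vehicle_id)]
            if not len(cand):
                continue
            dt = (cand["start_time_utc"] - start).abs()
            j = dt.idxmin()
            if dt.loc[j].total_seconds() > 60:
                continue
            row = act.loc[j]
            got = counts.get(t.trip_id, {})
            for kind, col in (("sudden_acceleration", "n_sudden_accel"),
                              ("hard_braking", "n_hard_braking"),
                              ("overspeeding", "n_overspeeding")):
                if int(row[col]) != got.get(kind, 0):
                    discrepancies.append({
                        "trip_id": t.trip_id, "alert_kind": kind,
                        "activity_count": int(row[col]),
                        "breadcrumb_count": got.get(kind, 0),
                    })
    return events, discrepancies


def recompute_overspeeding(
    trip_crumbs: pd.DataFrame,
    margin_mph: float = 6.0,
    speed_col: str = "speed_mph",
    limit_col: str = "road_avg_speed",
) -> list[AlertEvent]:
    """Detect speeding runs against the nearest-road average-speed proxy.

    One event per maximal run of consecutive fixes with
    ``speed >= limit + margin``; the event carries the run's peak and mean
    speed and the time/location of its first fix.
    """
    df = trip_crumbs
    speed = df[speed_col].to_numpy(dtype=float)
    limit = df[limit_col].to_numpy(dtype=float)
    hot = np.isfinite(speed) & np.isfinite(limit) & (speed >= limit + margin_mph)
    events: list[AlertEvent] = []
    i, n = 0, len(df)
    while i < n:
        if not hot[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and hot[j + 1]:
            j += 1
        run = df.iloc[i:j + 1]
        events.append(AlertEvent(
            vehicle_id=str(run.iloc[0]["vehicle_id"]),
            kind="overspeeding",
            time_utc=run.iloc[0]["timestamp_utc"],
            latitude=run.iloc[0]["latitude"], longitude=run.iloc[0]["longitude"],
            peak_speed=float(run[speed_col].max()),
            avg_event_speed=float(run[speed_col].mean()),
            source="recomputed",
        ))
        i = j + 1
    return events


def recompute_accel_events(
    times_s: np.ndarray,
    speeds_mph: np.ndarray,
    braking_threshold_mphps: float = 8.0,
    accel_threshold_mphps: float = 10.0,
    vehicle_id: str = "",
    band_mode: bool = False,
) -> list[AlertEvent]:
    """Hard braking / sudden acceleration from a 1-Hz speed trace.

    Braking fires on a 1-s decrease of at least ``braking_threshold_mphps``;
    acceleration on a 1-s increase of at least ``accel_threshold_mphps``.
    Consecutive qualifying seconds merge into a single event.
    ``band_mode=True`` switches to the alternative reading of the
    definitions — a single 8-10 mph/s band applied to both directions.
    """
    t = np.asarray(times_s, dtype=float)
    v = np.asarray(speeds_mph, dtype=float)
    if len(t) != len(v):
        raise ValueError("times and speeds differ in length")
    dv = np.diff(v)
    dt = np.diff(t)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(dt > 0, dv / dt, 0.0)
    if band_mode:
        braking = (rate <= -braking_threshold_mphps) & (rate >= -accel_threshold_mphps)
        accel = (rate >= braking_threshold_mphps) & (rate <= accel_threshold_mphps)
    else:
        braking = rate <= -braking_threshold_mphps
        accel = rate >= accel_threshold_mphps

    def runs(mask: np.ndarray, kind: str) -> list[AlertEvent]:
        out = []
        i, n = 0, len(mask)
        while i < n:
            if not mask[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            out.append(AlertEvent(
                vehicle_id=vehicle_id, kind=kind,
                time_utc=float(t[i]),
                initial_speed=float(v[i]), final_speed=float(v[j + 1]),
                source="recomputed",
            ))
            i = j + 1
        return out

    events = runs(braking, "hard_braking") + runs(accel, "sudden_acceleration")
    events.sort(key=lambda e: e.time_utc)
    return events


# ----------------------------------------------------------------------
# Temporal tallies and trip statistics
# ----------------------------------------------------------------------

def count_trips_by_light(trip_table: pd.DataFrame, by: str = "month") -> pd.DataFrame:
    """Per-driver per-period trip counts split by light phase.

    ``trip_table`` needs ``vehicle_id``, ``period`` and ``phase`` columns
    (phase from the trip's start instant). Periods with zero trips in one
    phase get an explicit 0; phases always sum to the total.
    """
    if not len(trip_table):
        return pd.DataFrame(columns=["vehicle_id", "period", "n_trips",
                                     "n_day", "n_night", "n_dawn", "n_dusk"])
    pivot = (
        trip_table.groupby(["vehicle_id", "period", "phase"], sort=True)
        .size().unstack("phase", fill_value=0)
    )
    for ph in ("day", "night", "dawn", "dusk"):
        if ph not in pivot.columns:
            pivot[ph] = 0
    out = pivot.reset_index().rename(columns={
        "day": "n_day", "night": "n_night", "dawn": "n_dawn", "dusk": "n_dusk"})
    out["n_trips"] = out[["n_day", "n_night", "n_dawn", "n_dusk"]].sum(axis=1)
    return out[["vehicle_id", "period", "n_trips", "n_day", "n_night", "n_dawn", "n_dusk"]]


def trip_statistics(per_trip: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-driver study-window totals and cohort mean/SD (sample SD, n-1).

    ``per_trip`` needs one row per usable trip with ``vehicle_id``,
    ``distance_mi``, ``duration_s``, ``phase`` and per-trip alert counts
    (``n_hard_braking``, ``n_sudden_accel``, ``n_overspeeding``,
    ``overspeeding_duration_s``). Column names of the per-driver table
    follow the deposited study-table legend.
    """
    g = per_trip.groupby("vehicle_id", sort=True)
    drivers = pd.DataFrame({
        "id": g.size().index,
        "numtripsover5mo": g.size().to_numpy(),
        "trips_at_night5mo": g.apply(lambda d: int((d["phase"] == "night").sum()),
                                     include_groups=False).to_numpy(),
        "trips_w_HB5mo": g.apply(lambda d: int((d["n_hard_braking"] > 0).sum()),
                                 include_groups=False).to_numpy(),
        "trips_w_SA5mo": g.apply(lambda d: int((d["n_sudden_accel"] > 0).sum()),
                                 include_groups=False).to_numpy(),
        "trips_speeding5mo": g.apply(lambda d: int((d["n_overspeeding"] > 0).sum()),
                                     include_groups=False).to_numpy(),
        "hours_speeding5mo": (g["overspeeding_duration_s"].sum() / 3600.0).to_numpy(),
        "tot_dist_driven5mo": g["distance_mi"].sum().to_numpy(),
        "tot_drv_hrs5mo": (g["duration_s"].sum() / 3600.0).to_numpy(),
    }).reset_index(drop=True)
    drivers["avg_trip_miles5mo"] = drivers["tot_dist_driven5mo"] / drivers["numtripsover5mo"]
    drivers["avg_trip_mins5mo"] = drivers["tot_drv_hrs5mo"] * 60.0 / drivers["numtripsover5mo"]
    return drivers, cohort_summary(drivers)


def cohort_summary(drivers: pd.DataFrame) -> pd.DataFrame:
    """Cohort mean and sample SD for every numeric per-driver column."""
    num = drivers.select_dtypes("number")
    return pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)})


def load_deposited_summary(path) -> pd.DataFrame:
    """Read a deposited per-participant 5-month summary CSV (study legend columns)."""
    df = pd.read_csv(path)
    if "numtripsover5mo" not in df.columns:
        raise ValueError("not a study summary table: 'numtripsover5mo' column missing")
    return df


# ----------------------------------------------------------------------
# Profile assembly
# ----------------------------------------------------------------------

@dataclass
class DriverProfile:
    """One driver-month of spatial, temporal and behavioral metrics."""

    driver_id: str
    month: str
    n_trips: int = 0
    n_trips_day: int = 0
    n_trips_night: int = 0
    n_trips_dawn: int = 0
    n_trips_dusk: int = 0
    n_overspeeding: int = 0
    n_hard_braking: int = 0
    n_sudden_accel: int = 0
    trips_w_overspeeding: int = 0
    trips_w_hard_braking: int = 0
    trips_w_sudden_accel: int = 0
    total_miles: float = 0.0
    mean_miles_per_trip: float = float("nan")
    driving_hours: float = 0.0
    driving_area_km2: float | None = None
    mean_center: tuple[float, float] | None = None     # (lat, lon)
    primary_locations: list = field(default_factory=list)
    destinations: dict = field(default_factory=dict)    # radius_ft -> count
    null_reason: str | None = None                      # e.g. defective device

    def validate(self) -> None:
        phases = (self.n_trips_day + self.n_trips_night
                  + self.n_trips_dawn + self.n_trips_dusk)
        if self.null_reason is None and phases != self.n_trips:
            raise ValueError(f"phase counts {phases} != n_trips {self.n_trips}")


def assemble_profile(
    driver_id: str,
    month: str,
    light_counts: dict | None = None,
    alert_counts: dict | None = None,
    alert_trip_counts: dict | None = None,
    total_miles: float = 0.0,
    driving_hours: float = 0.0,
    driving_area_km2: float | None = None,
    mean_center: tuple[float, float] | None = None,
    primary_locations: list | None = None,
    destinations: dict | None = None,
    null_reason: str | None = None,
) -> DriverProfile:
    """Build and validate one driver-month profile record.

    Missing components stay explicitly null (with ``null_reason`` when the
    whole month is unusable, e.g. a defective device).
    """
    lc = light_counts or {}
    ac = alert_counts or {}
    atc = alert_trip_counts or {}
    n_trips = int(sum(lc.values()))
    prof = DriverProfile(
        driver_id=driver_id, month=month, n_trips=n_trips,
        n_trips_day=int(lc.get("day", 0)), n_trips_night=int(lc.get("night", 0)),
        n_trips_dawn=int(lc.get("dawn", 0)), n_trips_dusk=int(lc.get("dusk", 0)),
        n_overspeeding=int(ac.get("overspeeding", 0)),
        n_hard_braking=int(ac.get("hard_braking", 0)),
        n_sudden_accel=int(ac.get("sudden_acceleration", 0)),
        trips_w_overspeeding=int(atc.get("overspeeding", 0)),
        trips_w_hard_braking=int(atc.get("hard_braking", 0)),
        trips_w_sudden_accel=int(atc.get("sudden_acceleration", 0)),
        total_miles=float(total_miles),
        mean_miles_per_trip=float(total_miles) / n_trips if n_trips else float("nan"),
        driving_hours=float(driving_hours),
        driving_area_km2=driving_area_km2,
        mean_center=mean_center,
        primary_locations=primary_locations or [],
        destinations=destinations or {},
        null_reason=null_reason,
    )
    prof.validate()
    return prof


def profiles_to_frame(profiles: list[DriverProfile]) -> pd.DataFrame:
    """Tidy one-row-per-driver-month table of profile scalars."""
    rows = []
    for p in profiles:
        row = {
            "driver_id": p.driver_id, "month": p.month, "n_trips": p.n_trips,
            "n_trips_day": p.n_trips_day, "n_trips_night": p.n_trips_night,
            "n_trips_dawn": p.n_trips_dawn, "n_trips_dusk": p.n_trips_dusk,
            "n_overspeeding": p.n_overspeeding, "n_hard_braking": p.n_hard_braking,
            "n_sudden_accel": p.n_sudden_accel,
            "trips_w_overspeeding": p.trips_w_overspeeding,
            "trips_w_hard_braking": p.trips_w_hard_braking,
            "trips_w_sudden_accel": p.trips_w_sudden_accel,
            "total_miles": p.total_miles,
            "mean_miles_per_trip": p.mean_miles_per_trip,
            "driving_hours": p.driving_hours,
            "driving_area_km2": p.driving_area_km2,
            "n_primary_locations": len(p.primary_locations),
            "null_reason": p.null_reason or "",
        }
        for r, n in sorted(p.destinations.items()):
            row[f"destinations_{int(r)}ft"] = n
        rows.append(row)
    return pd.DataFrame(rows)
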