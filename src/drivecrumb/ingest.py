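"""Reading, validating, merging and cleaning breadcrumb and activity files.

The vendor delivers two daily CSV streams: *breadcrumb* files (one row per
30-s GPS fix, tagged with an event type such as ignition on/off or an
aggressive-driving alert) and *activity* files (one row per trip summary).
Device connect/disconnect glitches leave fixes at (0, 0) or wildly wrong
places, duplicate rows appear, trips end with NA coordinates after signal
loss, and a failing device can emit weeks of zero coordinates — so cleaning
is rule-based and fully audited: every removed row carries exactly one
reason, and kept + removed always equals the input.

Cleaning order is coordinates -> duplicate timestamps for breadcrumbs and
NA-end / zero-start filtering for activity rows; the two breadcrumb filters
commute because they test disjoint properties of a row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BREADCRUMB_COLUMNS", "ACTIVITY_COLUMNS", "EVENT_TYPES",
    "HeaderReport", "CleaningReport", "Trip",
    "read_breadcrumbs", "read_activity",
    "filter_coordinates", "dedupe_timestamps", "filter_trips",
    "flag_defective_devices", "reconstruct_trips", "assign_provisional_trips",
]

#: Canonical breadcrumb schema (column order as emitted by the generator).
BREADCRUMB_COLUMNS = [
    "vehicle_id", "timestamp_utc", "latitude", "longitude", "speed_mph",
    "odometer_mi", "event_type", "nearest_address", "peak_speed_mph",
    "avg_event_speed_mph", "initial_speed_mph", "final_speed_mph",
]

#: Canonical activity (trip summary) schema.
ACTIVITY_COLUMNS = [
    "vehicle_id", "start_time_utc", "start_lat", "start_lon", "end_lat",
    "end_lon", "start_address", "end_address", "duration_s", "distance_mi",
    "avg_speed_mph", "max_speed_mph", "n_sudden_accel", "n_hard_braking",
    "n_overspeeding", "overspeeding_duration_s",
]

EVENT_TYPES = frozenset({
    "regular", "ignition_on", "ignition_off", "hard_braking",
    "sudden_acceleration", "overspeeding", "idle_ping", "low_battery",
    "device_connect", "device_disconnect", "device_fault",
})

ALERT_EVENT_TYPES = ("overspeeding", "hard_braking", "sudden_acceleration")


@dataclass
class HeaderReport:
    accepted: list[str] = field(default_factory=list)
    rejected: list[tuple[str, str]] = field(default_factory=list)   # (path, reason)


@dataclass
class CleaningReport:
    """Audit of every row removed during cleaning."""

    n_input_breadcrumbs: int = 0
    n_input_trips: int = 0
    n_removed_bbox: int = 0
    n_removed_zero: int = 0
    n_removed_nonfinite: int = 0
    n_removed_trip_propagation: int = 0
    n_removed_duplicates: int = 0
    n_trips_removed_na: int = 0
    n_trips_removed_zero: int = 0
    defective_vehicle_ids: list[str] = field(default_factory=list)
    removal_log: list[dict] = field(default_factory=list)

    @property
    def n_removed_breadcrumbs(self) -> int:
        return (self.n_removed_bbox + self.n_removed_zero + self.n_removed_nonfinite
                + self.n_removed_trip_propagation + self.n_removed_duplicates)

    def log(self, kind: str, reason: str, **info) -> None:
        self.removal_log.append({"kind": kind, "reason": reason, **info})

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(self.__dict__, indent=2, default=str)
        if path is not None:
            Path(path).write_text(s)
        return s


# ----------------------------------------------------------------------
# Readers
# ----------------------------------------------------------------------

def _parse_timestamps(col: pd.Series) -> pd.Series:
    """Accept ISO-8601 strings or epoch seconds; always return tz-aware UTC."""
    if pd.api.types.is_numeric_dtype(col):
        return pd.to_datetime(col, unit="s", utc=True)
    return pd.to_datetime(col, utc=True, format="ISO8601")


def _read_csv_files(
    paths, expected_columns: list[str], timestamp_cols: list[str]
) -> tuple[pd.DataFrame, HeaderReport]:
    report = HeaderReport()
    frames = []
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(f"input file not found: {p}")
        try:
            df = pd.read_csv(p, comment="#")
        except Exception as exc:  # unreadable -> hard error naming the file
            raise OSError(f"could not read {p}: {exc}") from exc
        if set(df.columns) != set(expected_columns):
            missing = set(expected_columns) - set(df.columns)
            extra = set(df.columns) - set(expected_columns)
            report.rejected.append(
                (str(p), f"header mismatch (missing={sorted(missing)}, extra={sorted(extra)})")
            )
            continue
        df = df[expected_columns]
        df["source_file"] = str(p)
        frames.append(df)
        report.accepted.append(str(p))
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=expected_columns + ["source_file"])
    for c in timestamp_cols:
        if len(out):
            out[c] = _parse_timestamps(out[c])
        else:
            out[c] = pd.Series(dtype="datetime64[ns, UTC]")
    for c in out.columns:
        if c.endswith("address"):   # empty address cells are strings, not NA
            out[c] = out[c].fillna("")
    return out, report


def read_breadcrumbs(paths) -> tuple[pd.DataFrame, HeaderReport]:
    """Read and concatenate daily breadcrumb CSVs (input order preserved).

    Files whose header set does not match the breadcrumb schema are skipped
    and listed in the report. Unknown event-type codes are kept but flagged
    via the ``event_type_known`` column.
    """
    df, report = _read_csv_files(paths, BREADCRUMB_COLUMNS, ["timestamp_utc"])
    df["vehicle_id"] = df["vehicle_id"].astype(str)
    df["event_type_known"] = df["event_type"].isin(EVENT_TYPES)
    return df, report


def read_activity(paths) -> tuple[pd.DataFrame, HeaderReport]:
    """Read daily activity (trip) CSVs; NA/0 coordinates pass through untouched."""
    df, report = _read_csv_files(paths, ACTIVITY_COLUMNS, ["start_time_utc"])
    df["vehicle_id"] = df["vehicle_id"].astype(str)
    return df, report


# ----------------------------------------------------------------------
# Breadcrumb filters
# ----------------------------------------------------------------------

def filter_coordinates(
    crumbs: pd.DataFrame,
    bbox: tuple[float, float, float, float] = (24.5, 49.5, -125.0, -66.9),
    trip_ids: pd.Series | None = None,
    report: CleaningReport | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, CleaningReport]:
    """Drop fixes outside the study bounding box, at exactly (0, 0), or non-finite.

    When ``trip_ids`` maps rows to provisional trips, every other fix of a
    trip containing a removed fix is removed too (reason
    ``trip_contains_bad_coordinate``): a trip with one impossible location
    is untrustworthy end to end.
    """
    if report is None:
        report = CleaningReport()
    lat_min, lat_max, lon_min, lon_max = bbox
    lat = crumbs["latitude"].to_numpy(dtype=float)
    lon = crumbs["longitude"].to_numpy(dtype=float)
    finite = np.isfinite(lat) & np.isfinite(lon)
    zero = finite & (lat == 0.0) | finite & (lon == 0.0)
    inside = finite & ~zero & (lat >= lat_min) & (lat <= lat_max) \
        & (lon >= lon_min) & (lon <= lon_max)
    reason = np.full(len(crumbs), "", dtype=object)
    reason[~finite] = "nonfinite_coordinates"
    reason[zero] = "zero_coordinates"
    reason[finite & ~zero & ~inside] = "out_of_bbox"

    if trip_ids is not None:
        tid = np.asarray(trip_ids)
        bad_trips = set(tid[(reason != "") & (tid >= 0)].tolist())
        if bad_trips:
            propagate = (reason == "") & np.isin(tid, list(bad_trips))
            reason[propagate] = "trip_contains_bad_coordinate"

    removed_mask = reason != ""
    kept = crumbs.loc[~removed_mask].copy()
    removed = crumbs.loc[removed_mask].copy()
    removed["removal_reason"] = reason[removed_mask]
    report.n_removed_zero += int((reason == "zero_coordinates").sum())
    report.n_removed_nonfinite += int((reason == "nonfinite_coordinates").sum())
    report.n_removed_bbox += int((reason == "out_of_bbox").sum())
    report.n_removed_trip_propagation += int((reason == "trip_contains_bad_coordinate").sum())
    for i in np.flatnonzero(removed_mask):
        report.log("breadcrumb", str(reason[i]), row=int(crumbs.index[i]))
    return kept, removed, report


def dedupe_timestamps(
    crumbs: pd.DataFrame,
    report: CleaningReport | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, CleaningReport]:
    """Keep one fix per (vehicle, timestamp); first in file order wins.

    Duplicates are normally byte-identical device hiccups; duplicates that
    *disagree* on position are kept-first as well but flagged
    (``duplicate_conflict``) for manual review.
    """
    if report is None:
        report = CleaningReport()
    dup_mask = crumbs.duplicated(subset=["vehicle_id", "timestamp_utc"], keep="first")
    kept = crumbs.loc[~dup_mask].copy()
    removed = crumbs.loc[dup_mask].copy()
    conflict = []
    if len(removed):
        first = crumbs.loc[~dup_mask].set_index(["vehicle_id", "timestamp_utc"])
        for idx, row in removed.iterrows():
            ref = first.loc[(row["vehicle_id"], row["timestamp_utc"])]
            same = bool(
                np.isclose(ref["latitude"], row["latitude"], equal_nan=True)
                and np.isclose(ref["longitude"], row["longitude"], equal_nan=True)
            )
            conflict.append(not same)
            report.log("breadcrumb",
                       "duplicate_conflict" if not same else "duplicate_timestamp",
                       row=int(idx))
    removed["removal_reason"] = "duplicate_timestamp"
    removed["duplicate_conflict"] = conflict
    report.n_removed_duplicates += len(removed)
    return kept, removed, report


def filter_trips(
    activity: pd.DataFrame,
    report: CleaningReport | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, CleaningReport]:
    """Drop trip records with NA end coordinates or a zero start coordinate."""
    if report is None:
        report = CleaningReport()
    end_lat = pd.to_numeric(activity["end_lat"], errors="coerce")
    end_lon = pd.to_numeric(activity["end_lon"], errors="coerce")
    start_lat = pd.to_numeric(activity["start_lat"], errors="coerce")
    start_lon = pd.to_numeric(activity["start_lon"], errors="coerce")
    na_end = end_lat.isna() | end_lon.isna()
    zero_start = ~na_end & ((start_lat == 0.0) | (start_lon == 0.0) |
                            start_lat.isna() | start_lon.isna())
    reason = np.full(len(activity), "", dtype=object)
    reason[na_end.to_numpy()] = "na_end"
    reason[zero_start.to_numpy()] = "zero_start"
    removed_mask = reason != ""
    kept = activity.loc[~removed_mask].copy()
    removed = activity.loc[removed_mask].copy()
    removed["removal_reason"] = reason[removed_mask]
    report.n_trips_removed_na += int((reason == "na_end").sum())
    report.n_trips_removed_zero += int((reason == "zero_start").sum())
    for i in np.flatnonzero(removed_mask):
        report.log("trip", str(reason[i]), row=int(activity.index[i]))
    return kept, removed, report


def flag_defective_devices(
    crumbs: pd.DataFrame,
    window_days: float = 7.0,
    zero_fraction_threshold: float = 0.5,
    min_crumbs: int = 50,
) -> list[str]:
    """Vehicles whose device stopped reporting locations for an extended run.

    A vehicle is flagged when, within any rolling ``window_days`` window
    holding at least ``min_crumbs`` fixes, more than
    ``zero_fraction_threshold`` of fixes sit at a zero coordinate — the
    signature of a hardware fault rather than a transient glitch.
    """
    flagged = []
    zero = (crumbs["latitude"] == 0.0) | (crumbs["longitude"] == 0.0)
    for vid, grp in crumbs.assign(_zero=zero.astype(float)).groupby("vehicle_id", sort=True):
        s = grp.sort_values("timestamp_utc").set_index("timestamp_utc")["_zero"]
        roll = s.rolling(f"{window_days * 24}h", min_periods=min_crumbs)
        frac = roll.mean()
        if (frac > zero_fraction_threshold).any():
            flagged.append(str(vid))
    return flagged


# ----------------------------------------------------------------------
# Trip reconstruction
# ----------------------------------------------------------------------

@dataclass
class Trip:
    """Ordered breadcrumb sequence from ignition on to ignition off."""

    vehicle_id: str
    trip_id: int
    indices: list[int]                 # row labels into the breadcrumb table
    abandoned: bool = False            # start superseded seconds later
    no_ignition_off: bool = False      # closed at the next ignition event / stream end

    @property
    def n_crumbs(self) -> int:
        return len(self.indices)


def reconstruct_trips(
    crumbs: pd.DataFrame,
    abandoned_gap_s: float = 60.0,
    abandoned_max_intervening: int = 1,
) -> tuple[list[Trip], list[int]]:
    """Group fixes into trips between ignition-on and ignition-off events.

    Returns ``(trips, quarantined)`` where ``quarantined`` lists rows of
    ignition-off events with no open trip. Idle pings never join a trip. A
    second ignition-on arriving within ``abandoned_gap_s`` of an open start
    with at most ``abandoned_max_intervening`` fixes in between marks the
    first start as an abandoned trip (kept in the output, flagged, so the
    audit can count it); any other mid-trip ignition-on closes the open trip
    with a ``no_ignition_off`` flag.
    """
    trips: list[Trip] = []
    quarantined: list[int] = []
    counter = 0
    for vid, grp in crumbs.groupby("vehicle_id", sort=True):
        grp = grp.sort_values("timestamp_utc", kind="stable")
        open_trip: list[int] = []
        open_start_time = None
        for idx, row in grp.iterrows():
            ev = row["event_type"]
            if ev == "idle_ping":
                continue
            if ev == "ignition_on":
                if open_trip:
                    gap = (row["timestamp_utc"] - open_start_time).total_seconds()
                    intervening = len(open_trip) - 1
                    abandoned = (gap <= abandoned_gap_s
                                 and intervening <= abandoned_max_intervening)
                    trips.append(Trip(str(vid), counter, open_trip,
                                      abandoned=abandoned,
                                      no_ignition_off=not abandoned))
                    counter += 1
                open_trip = [idx]
                open_start_time = row["timestamp_utc"]
            elif ev == "ignition_off":
                if open_trip:
                    open_trip.append(idx)
                    trips.append(Trip(str(vid), counter, open_trip))
                    counter += 1
                    open_trip = []
                    open_start_time = None
                else:
                    quarantined.append(idx)
            else:
                if open_trip:
                    open_trip.append(idx)
                # fixes outside any trip (device events while parked) are
                # simply non-trip crumbs, not errors
        if open_trip:
            trips.append(Trip(str(vid), counter, open_trip, no_ignition_off=True))
            counter += 1
    return trips, quarantined


def assign_provisional_trips(crumbs: pd.DataFrame) -> pd.Series:
    """Trip id per row (-1 outside trips) for pre-cleaning trip propagation."""
    trips, _ = reconstruct_trips(crumbs)
    tid = pd.Series(-1, index=crumbs.index, dtype=int)
    for t in trips:
        tid.loc[t.indices] = t.trip_id
    return tid


def usable_trips(trips: list[Trip]) -> list[Trip]:
    """Trips that represent real driving: not abandoned starts."""
    return [t for t in trips if not t.abandoned]
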