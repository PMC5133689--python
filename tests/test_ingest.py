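"""File ingestion, cleaning rules, and trip reconstruction."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from drivecrumb import ingest
from drivecrumb.ingest import (
    ACTIVITY_COLUMNS, BREADCRUMB_COLUMNS, dedupe_timestamps, filter_coordinates,
    filter_trips, flag_defective_devices, read_activity, read_breadcrumbs,
    reconstruct_trips, assign_provisional_trips,
)
from drivecrumb.synth import EGYPT_LATLON, write_fixture_suite


def make_crumbs(rows: list[dict]) -> pd.DataFrame:
    base = dict(vehicle_id="v1", latitude=38.63, longitude=-90.20, speed_mph=30.0,
                odometer_mi=0.0, event_type="regular", nearest_address="",
                peak_speed_mph=np.nan, avg_event_speed_mph=np.nan,
                initial_speed_mph=np.nan, final_speed_mph=np.nan)
    out = pd.DataFrame([{**base, **r} for r in rows])
    out["timestamp_utc"] = pd.to_datetime(out["timestamp_utc"], utc=True)
    return out


def ts(i: int) -> str:
    return f"2016-07-01T12:{i // 2:02d}:{(i % 2) * 30:02d}+00:00"


# ----------------------------------------------------------------------
# Readers
# ----------------------------------------------------------------------

class TestReaders:
    def test_daily_files_concatenate_in_input_order(self, tmp_path):
        df = make_crumbs([{"timestamp_utc": ts(i)} for i in range(2)])
        paths = []
        for k in range(3):
            p = tmp_path / f"breadcrumbs_{k}.csv"
            df.to_csv(p, index=False)
            paths.append(p)
        out, rep = read_breadcrumbs(paths)
        assert len(out) == 6 and rep.rejected == []
        assert list(out["source_file"][:2].unique()) == [str(paths[0])]

    def test_renamed_column_rejects_the_file(self, tmp_path):
        df = make_crumbs([{"timestamp_utc": ts(0)}]).rename(
            columns={"latitude": "lat"})
        good = make_crumbs([{"timestamp_utc": ts(1)}])
        p_bad, p_good = tmp_path / "bad.csv", tmp_path / "good.csv"
        df.to_csv(p_bad, index=False)
        good.to_csv(p_good, index=False)
        out, rep = read_breadcrumbs([p_bad, p_good])
        assert len(out) == 1
        assert len(rep.rejected) == 1 and str(p_bad) in rep.rejected[0][0]

    def test_missing_file_is_a_hard_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_breadcrumbs([tmp_path / "nope.csv"])

    def test_unknown_event_type_is_kept_and_flagged(self, tmp_path):
        df = make_crumbs([{"timestamp_utc": ts(0), "event_type": "mystery"}])
        p = tmp_path / "b.csv"
        df.to_csv(p, index=False)
        out, _ = read_breadcrumbs([p])
        assert len(out) == 1 and not out["event_type_known"].iloc[0]

    def test_activity_na_coordinates_pass_through(self, tmp_path):
        fixtures = write_fixture_suite(tmp_path)
        out, rep = read_activity([fixtures["activity_na_end"]])
        assert len(out) == 3 and rep.rejected == []
        assert out["end_lat"].isna().iloc[0]

    def test_synthetic_files_round_trip_against_manifest(self, tmp_path, clean_scenario):
        sc = clean_scenario
        paths = sc.write(tmp_path / "sc")
        bc, _ = read_breadcrumbs(paths["breadcrumbs"])
        act, _ = read_activity(paths["activity"])
        assert len(bc) == len(sc.breadcrumbs)
        assert len(act) == len(sc.activity)
        for col in BREADCRUMB_COLUMNS:
            got, want = bc[col], sc.breadcrumbs[col]
            if got.dtype.kind == "f":
                assert np.allclose(got, want, equal_nan=True)
            else:
                assert (got.astype(str) == want.astype(str)).all()
        ntrips = len(sc.clean_trips())
        assert (act["n_hard_braking"].sum()
                == sum(t.n_hard_braking for t in sc.trips))


# ----------------------------------------------------------------------
# Coordinate filtering
# ----------------------------------------------------------------------

class TestFilterCoordinates:
    def test_zero_and_egypt_and_kept_cases(self):
        crumbs = make_crumbs([
            {"timestamp_utc": ts(0), "latitude": 0.0, "longitude": 0.0},
            {"timestamp_utc": ts(1)},                                   # St. Louis
            {"timestamp_utc": ts(2), "latitude": EGYPT_LATLON[0],
             "longitude": EGYPT_LATLON[1]},
        ])
        kept, removed, rep = filter_coordinates(crumbs)
        assert len(kept) == 1
        reasons = dict(zip(removed.index, removed["removal_reason"]))
        assert reasons[0] == "zero_coordinates" and reasons[2] == "out_of_bbox"
        assert rep.n_removed_zero == 1 and rep.n_removed_bbox == 1

    def test_bad_fix_removes_the_whole_trip(self):
        crumbs = make_crumbs([
            {"timestamp_utc": ts(0), "event_type": "ignition_on"},
            {"timestamp_utc": ts(1), "latitude": EGYPT_LATLON[0],
             "longitude": EGYPT_LATLON[1]},
            {"timestamp_utc": ts(2)},
            {"timestamp_utc": ts(3), "event_type": "ignition_off"},
            {"timestamp_utc": ts(8), "event_type": "idle_ping"},   # outside trip
        ])
        tid = assign_provisional_trips(crumbs)
        kept, removed, rep = filter_coordinates(crumbs, trip_ids=tid)
        assert len(kept) == 1 and kept["event_type"].iloc[0] == "idle_ping"
        assert (removed["removal_reason"] == "trip_contains_bad_coordinate").sum() == 3

    def test_filter_is_idempotent_and_conserves_rows(self):
        crumbs = make_crumbs(
            [{"timestamp_utc": ts(i), "latitude": 0.0 if i % 3 == 0 else 38.63,
              "longitude": 0.0 if i % 3 == 0 else -90.20} for i in range(9)])
        kept, removed, _ = filter_coordinates(crumbs)
        assert len(kept) + len(removed) == len(crumbs)
        kept2, removed2, _ = filter_coordinates(kept)
        assert len(removed2) == 0 and kept2.equals(kept)


# ----------------------------------------------------------------------
# Duplicate timestamps
# ----------------------------------------------------------------------

class TestDedupe:
    def test_exact_duplicate_keeps_first(self):
        crumbs = make_crumbs([{"timestamp_utc": ts(0)}, {"timestamp_utc": ts(0)}])
        kept, removed, rep = dedupe_timestamps(crumbs)
        assert len(kept) == 1 and kept.index[0] == 0
        assert rep.n_removed_duplicates == 1
        assert not removed["duplicate_conflict"].iloc[0]

    def test_conflicting_duplicate_is_flagged(self):
        crumbs = make_crumbs([
            {"timestamp_utc": ts(0)},
            {"timestamp_utc": ts(0), "latitude": 38.70},
        ])
        kept, removed, _ = dedupe_timestamps(crumbs)
        assert kept["latitude"].iloc[0] == 38.63   # first in file order wins
        assert removed["duplicate_conflict"].iloc[0]

    def test_same_timestamp_different_vehicles_both_kept(self):
        crumbs = make_crumbs([
            {"timestamp_utc": ts(0), "vehicle_id": "v1"},
            {"timestamp_utc": ts(0), "vehicle_id": "v2"},
        ])
        kept, removed, _ = dedupe_timestamps(crumbs)
        assert len(kept) == 2 and len(removed) == 0

    def test_dedupe_is_idempotent(self):
        crumbs = make_crumbs([{"timestamp_utc": ts(i % 2)} for i in range(6)])
        kept, _, _ = dedupe_timestamps(crumbs)
        kept2, removed2, _ = dedupe_timestamps(kept)
        assert len(removed2) == 0 and kept2.equals(kept)


def test_coordinate_and_duplicate_filters_commute():
    crumbs = make_crumbs(
        [{"timestamp_utc": ts(i)} for i in range(4)]
        + [{"timestamp_utc": ts(1)}]                       # duplicate
        + [{"timestamp_utc": ts(5), "latitude": 0.0, "longitude": 0.0}])
    a, _, _ = dedupe_timestamps(filter_coordinates(crumbs)[0])
    b, _, _ = filter_coordinates(dedupe_timestamps(crumbs)[0])
    assert sorted(a.index) == sorted(b.index)


# ----------------------------------------------------------------------
# Trip record filtering
# ----------------------------------------------------------------------

class TestFilterTrips:
    def make_activity(self, rows):
        base = dict(vehicle_id="v1", start_time_utc="2016-07-01T12:00:00+00:00",
                    start_lat=38.63, start_lon=-90.20, end_lat=38.64, end_lon=-90.21,
                    start_address="", end_address="", duration_s=300.0,
                    distance_mi=2.0, avg_speed_mph=25.0, max_speed_mph=35.0,
                    n_sudden_accel=0, n_hard_braking=0, n_overspeeding=0,
                    overspeeding_duration_s=0.0)
        df = pd.DataFrame([{**base, **r} for r in rows])
        df["start_time_utc"] = pd.to_datetime(df["start_time_utc"], utc=True)
        return df

    def test_na_end_and_zero_start_and_valid(self):
        act = self.make_activity([
            {"end_lat": np.nan, "end_lon": np.nan},
            {"start_lon": 0.0},
            {},
        ])
        kept, removed, rep = filter_trips(act)
        assert len(kept) == 1
        assert list(removed["removal_reason"]) == ["na_end", "zero_start"]
        assert rep.n_trips_removed_na == 1 and rep.n_trips_removed_zero == 1


# ----------------------------------------------------------------------
# Defective devices
# ----------------------------------------------------------------------

class TestDefectiveDevices:
    def test_mostly_zero_vehicle_is_flagged(self):
        t0 = pd.Timestamp("2016-07-01T00:00:00Z")
        rows = [{"timestamp_utc": (t0 + pd.Timedelta(minutes=30 * i)).isoformat(),
                 "latitude": 0.0, "longitude": 0.0}
                for i in range(14 * 48)]   # two weeks of zeros
        rows += [{"timestamp_utc": (t0 + pd.Timedelta(days=20, minutes=i)).isoformat()}
                 for i in range(60)]
        assert flag_defective_devices(make_crumbs(rows)) == ["v1"]

    def test_isolated_zero_crumb_is_not_flagged(self):
        t0 = pd.Timestamp("2016-07-01T00:00:00Z")
        rows = [{"timestamp_utc": (t0 + pd.Timedelta(minutes=30 * i)).isoformat()}
                for i in range(300)]
        rows[150]["latitude"] = 0.0
        rows[150]["longitude"] = 0.0
        assert flag_defective_devices(make_crumbs(rows)) == []

    def test_injected_dead_device_is_the_only_flagged_vehicle(self, corrupt_scenario):
        sc = corrupt_scenario
        flagged = flag_defective_devices(sc.breadcrumbs)
        assert flagged == [sc.corruption["defective_vehicle"]]


# ----------------------------------------------------------------------
# Trip reconstruction
# ----------------------------------------------------------------------

class TestReconstructTrips:
    def test_simple_trip_spans_on_to_off(self):
        crumbs = make_crumbs(
            [{"timestamp_utc": ts(0), "event_type": "ignition_on"}]
            + [{"timestamp_utc": ts(i)} for i in (1, 2, 3)]
            + [{"timestamp_utc": ts(4), "event_type": "ignition_off"}])
        trips, quarantined = reconstruct_trips(crumbs)
        assert len(trips) == 1 and trips[0].n_crumbs == 5 and not quarantined

    def test_second_start_seconds_later_abandons_the_first(self):
        t0 = pd.Timestamp("2016-07-01T12:00:00Z")
        crumbs = make_crumbs([
            {"timestamp_utc": t0.isoformat(), "event_type": "ignition_on"},
            {"timestamp_utc": (t0 + pd.Timedelta(seconds=8)).isoformat(),
             "event_type": "ignition_on"},
            {"timestamp_utc": (t0 + pd.Timedelta(seconds=38)).isoformat()},
            {"timestamp_utc": (t0 + pd.Timedelta(seconds=68)).isoformat(),
             "event_type": "ignition_off"},
        ])
        trips, _ = reconstruct_trips(crumbs)
        assert len(trips) == 2
        assert trips[0].abandoned and trips[0].n_crumbs == 1
        usable = ingest.usable_trips(trips)
        assert len(usable) == 1 and usable[0].n_crumbs == 3

    def test_orphan_ignition_off_is_quarantined(self):
        crumbs = make_crumbs([
            {"timestamp_utc": ts(0), "event_type": "ignition_off"},
            {"timestamp_utc": ts(1), "event_type": "ignition_on"},
            {"timestamp_utc": ts(2), "event_type": "ignition_off"},
        ])
        trips, quarantined = reconstruct_trips(crumbs)
        assert quarantined == [0] and len(trips) == 1

    def test_idle_pings_never_join_a_trip(self):
        crumbs = make_crumbs([
            {"timestamp_utc": ts(0), "event_type": "ignition_on"},
            {"timestamp_utc": ts(1), "event_type": "idle_ping"},
            {"timestamp_utc": ts(2), "event_type": "ignition_off"},
        ])
        trips, _ = reconstruct_trips(crumbs)
        assert trips[0].n_crumbs == 2

    def test_synthetic_stream_recovers_manifest_boundaries(self, clean_scenario):
        sc = clean_scenario
        trips, quarantined = reconstruct_trips(sc.breadcrumbs)
        usable = ingest.usable_trips(trips)
        assert not quarantined
        assert len(usable) == len(sc.trips)
        for got, want in zip(usable, sc.trips):
            assert got.n_crumbs == want.n_crumbs
            start = sc.breadcrumbs.loc[got.indices[0]]
            assert start["event_type"] == "ignition_on"
            assert start["timestamp_utc"] == want.start_utc


def test_cleaning_removes_exactly_the_injected_corruption(corrupt_scenario):
    """Per-reason removal counts equal the corruption manifest exactly."""
    sc = corrupt_scenario
    crumbs = sc.breadcrumbs
    tid = assign_provisional_trips(crumbs)
    kept, removed, rep = filter_coordinates(crumbs, trip_ids=tid)
    assert rep.n_removed_zero == (sc.corruption["zero_crumbs"]
                                  + sc.corruption["defective_rows"])
    assert rep.n_removed_bbox == 1                      # the Egypt fix
    assert rep.n_removed_bbox + rep.n_removed_trip_propagation \
        == sc.corruption["egypt_rows"]                  # whole corrupted trip
    kept2, removed2, rep2 = dedupe_timestamps(kept)
    assert rep2.n_removed_duplicates == sc.corruption["duplicates"]
    act_kept, act_removed, rep3 = filter_trips(sc.activity)
    assert rep3.n_trips_removed_na == sc.corruption["na_end_trips"]
    assert rep3.n_trips_removed_zero == sc.corruption["zero_start_trips"]
    # nothing else was removed
    n_clean_expected = (len(crumbs) - sc.corruption["zero_crumbs"]
                        - sc.corruption["defective_rows"]
                        - sc.corruption["egypt_rows"]
                        - sc.corruption["duplicates"])
    assert len(kept2) == n_clean_expected
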