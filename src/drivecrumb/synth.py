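"""Ground-truthed synthetic driver scenarios.

Real trajectory data from instrumented vehicles cannot be redistributed, so
every pipeline stage is validated against a simulator whose ground truth is
known exactly. A scenario is one driver living on a planar street grid:

* a road grid (default 500-m spacing) whose lines carry average speeds of
  25/35/55 mph mapped to CFCC-like road classes;
* *anchors* (home/second home) that originate a configured share of trips,
  so primary-location detection has a known answer;
* a trip schedule over local calendar months, with start times placed
  inside known light-phase windows (dawn/day/dusk/night) computed from the
  same solar model the pipeline uses, with safety margins wide enough that
  the intended phase is unambiguous;
* 30-s breadcrumbs along Manhattan routes with isotropic Gaussian GPS noise
  (5 ft parked, 15 ft moving — consumer-GPS magnitude, small enough to keep
  20-ft clustering meaningful), ignition on/off rows bracketing each trip,
  and idle pings every 3 h while parked;
* injected adverse-driving alerts (overspeeding runs above limit + 6 mph,
  hard-braking / sudden-acceleration event rows) mirrored into the
  activity file;
* optional corruption in the exact modes the cleaning stage targets:
  zero-coordinate rows, an out-of-country outlier fix, exact duplicate
  rows, NA-ended activity rows paired with abandoned trip starts,
  zero-start activity rows, and a defective device emitting weeks of zeros.

Regenerating with the same seed and config reproduces byte-identical files;
the manifest records every trip, alert and corrupted row.

Recorded speeds are only loosely consistent with 30-s displacements (the
pipeline never cross-checks them); position noise is applied after route
interpolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta, timezone
from pathlib import Path
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from .config import M_PER_FT, MI_PER_KM
from .roads import StreetSegment, segments_to_geojson
from .spatial import LocalProjection
from .timekit import solar_day

__all__ = ["ScenarioConfig", "Scenario", "generate_scenario",
           "generate_speed_trace", "make_road_grid", "write_fixture_suite"]

_SPEED_CYCLE = (25.0, 35.0, 55.0)
_CFCC = {25.0: "A41", 35.0: "A31", 55.0: "A21"}

EGYPT_LATLON = (30.04, 31.24)


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic driver."""

    base_lat: float = 38.63
    base_lon: float = -90.20
    tz_id: str = "America/Chicago"
    start_month: str = "2016-07"
    months: int = 5
    vehicle_id: str = "1000000001"

    grid_n: int = 13                   # grid_n x grid_n intersections
    grid_spacing_m: float = 500.0

    anchor_shares: tuple[float, ...] = (0.55, 0.25)
    n_destinations: int = 12

    trips_per_day: float = 3.5         # Poisson mean, capped at 5
    p_day: float = 0.78
    p_night: float = 0.12
    p_dusk: float = 0.07
    p_dawn: float = 0.03

    noise_parked_ft: float = 5.0
    noise_moving_ft: float = 15.0
    sampling_interval_s: float = 30.0
    idle_ping_interval_h: float = 3.0

    p_overspeed: float = 0.12          # per-trip injection probabilities
    p_hard_braking: float = 0.15
    p_sudden_accel: float = 0.08
    overspeed_margin_mph: float = 6.0

    # corruption (all off by default: a clean scenario)
    n_zero_crumbs: int = 0
    n_duplicate_crumbs: int = 0
    n_abandoned_starts: int = 0        # each pairs with one NA-end activity row
    n_zero_start_trips: int = 0
    egypt_outlier: bool = False
    defective_device: bool = False
    defective_days: int = 15

    def validate(self) -> None:
        if sum(self.anchor_shares) > 0.9:
            raise ValueError("anchor shares must sum to at most 0.9")
        if any(s <= 0 for s in self.anchor_shares):
            raise ValueError("anchor shares must be positive")
        probs = (self.p_day, self.p_night, self.p_dusk, self.p_dawn)
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("phase probabilities must sum to 1")
        if self.months < 1 or self.grid_n < 4 or self.n_destinations < 2:
            raise ValueError("infeasible scenario size")


@dataclass
class TripTruth:
    """Manifest record of one scheduled trip."""

    trip_no: int
    vehicle_id: str
    month: str                     # local "YYYY-MM" of the start
    phase: str
    start_utc: pd.Timestamp
    start_local: pd.Timestamp
    origin_label: str
    origin_lat: float
    origin_lon: float
    dest_label: str
    dest_lat: float
    dest_lon: float
    n_crumbs: int
    duration_s: float
    distance_m: float
    n_overspeeding: int = 0
    n_hard_braking: int = 0
    n_sudden_accel: int = 0
    corrupted: bool = False        # trip carries an injected impossible fix


@dataclass
class Scenario:
    """Generated files plus their ground-truth manifest."""

    config: ScenarioConfig
    seed: int
    projection: LocalProjection
    segments: list[StreetSegment]
    anchors: list[dict]            # {label, lat, lon, share_target, n_ignition_on}
    destinations: list[dict]
    trips: list[TripTruth]
    breadcrumbs: pd.DataFrame
    activity: pd.DataFrame
    corruption: dict = field(default_factory=dict)

    # ---- ground-truth summaries -----------------------------------
    @property
    def months(self) -> list[str]:
        out: list[str] = []
        for t in self.trips:
            if t.month not in out:
                out.append(t.month)
        return sorted(out)

    def clean_trips(self) -> list[TripTruth]:
        return [t for t in self.trips if not t.corrupted]

    def expected_phase_counts(self, month: str | None = None) -> dict[str, int]:
        counts = {"day": 0, "night": 0, "dawn": 0, "dusk": 0}
        for t in self.clean_trips():
            if month is None or t.month == month:
                counts[t.phase] += 1
        return counts

    def expected_alert_counts(self, month: str | None = None) -> dict[str, int]:
        c = {"overspeeding": 0, "hard_braking": 0, "sudden_acceleration": 0}
        for t in self.clean_trips():
            if month is None or t.month == month:
                c["overspeeding"] += t.n_overspeeding
                c["hard_braking"] += t.n_hard_braking
                c["sudden_acceleration"] += t.n_sudden_accel
        return c

    def manifest_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": dataclasses.asdict(self.config),
            "anchors": self.anchors,
            "destinations": self.destinations,
            "months": self.months,
            "corruption": self.corruption,
            "trips": [
                {**dataclasses.asdict(t),
                 "start_utc": t.start_utc.isoformat(),
                 "start_local": t.start_local.isoformat()}
                for t in self.trips
            ],
        }

    # ---- emission --------------------------------------------------
    def write(self, out_dir: str | Path, daily: bool = False) -> dict[str, list[Path]]:
        """Emit breadcrumb/activity CSVs, road GeoJSON and manifest JSON.

        ``daily=True`` splits both streams into one file per UTC date, as
        the vendor delivers them.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = f"# synthetic scenario seed={self.seed}\n"
        paths: dict[str, list[Path]] = {"breadcrumbs": [], "activity": []}

        def dump(df: pd.DataFrame, stem: str, key: str) -> None:
            p = out / f"{stem}.csv"
            with open(p, "w") as fh:
                fh.write(header)
                df.to_csv(fh, index=False)
            paths[key].append(p)

        bc = self.breadcrumbs.copy()
        bc["timestamp_utc"] = bc["timestamp_utc"].map(
            lambda t: t.isoformat(timespec="seconds"))
        act = self.activity.copy()
        act["start_time_utc"] = act["start_time_utc"].map(
            lambda t: t.isoformat(timespec="seconds"))
        if daily:
            for day, grp in bc.groupby(bc["timestamp_utc"].str[:10], sort=True):
                dump(grp, f"breadcrumbs_{day}", "breadcrumbs")
            for day, grp in act.groupby(act["start_time_utc"].str[:10], sort=True):
                dump(grp, f"activity_{day}", "activity")
        else:
            dump(bc, "breadcrumbs", "breadcrumbs")
            dump(act, "activity", "activity")
        (out / "streets.geojson").write_text(
            json.dumps(segments_to_geojson(self.segments, self.projection)))
        (out / "manifest.json").write_text(
            json.dumps(self.manifest_dict(), indent=1, sort_keys=True, default=str))
        return paths


# ----------------------------------------------------------------------
# Road grid
# ----------------------------------------------------------------------

def make_road_grid(n: int, spacing_m: float) -> tuple[list[StreetSegment], np.ndarray,
                                                      np.ndarray, np.ndarray]:
    """Square street grid centred on the origin of the local frame.

    Returns (segments, node_coords[n, n, 2], h_speeds[n], v_speeds[n]);
    horizontal line j and vertical line i carry cyclic speed classes.
    """
    half = (n - 1) / 2.0
    xs = (np.arange(n) - half) * spacing_m
    nodes = np.stack(np.meshgrid(xs, xs, indexing="ij"), axis=-1)  # nodes[i, j] = (x_i, y_j)
    h_speeds = np.array([_SPEED_CYCLE[j % 3] for j in range(n)])
    v_speeds = np.array([_SPEED_CYCLE[(i + 1) % 3] for i in range(n)])
    segs: list[StreetSegment] = []
    sid = 0
    for j in range(n):          # horizontal (east-west) streets
        for i in range(n - 1):
            segs.append(StreetSegment(
                segment_id=sid,
                coords=np.array([[xs[i], xs[j]], [xs[i + 1], xs[j]]]),
                name=f"EW-{j} St", cfcc=_CFCC[h_speeds[j]], avg_speed=h_speeds[j]))
            sid += 1
    for i in range(n):          # vertical (north-south) avenues
        for j in range(n - 1):
            segs.append(StreetSegment(
                segment_id=sid,
                coords=np.array([[xs[i], xs[j]], [xs[i], xs[j + 1]]]),
                name=f"NS-{i} Ave", cfcc=_CFCC[v_speeds[i]], avg_speed=v_speeds[i]))
            sid += 1
    return segs, nodes, h_speeds, v_speeds


def _route(origin_xy, o_node, dest_xy, d_node, xs, h_speeds, v_speeds):
    """Manhattan route origin -> grid -> destination as (start, end, limit) legs."""
    (oi, oj), (di, dj) = o_node, d_node
    legs = []
    p = np.asarray(origin_xy, dtype=float)
    q = np.array([p[0], xs[oj]])                 # driveway down to the EW street
    legs.append((p, q, 25.0))
    r = np.array([xs[di], xs[oj]])               # along EW street j=oj
    legs.append((q, r, float(h_speeds[oj])))
    s = np.array([xs[di], xs[dj]])               # along NS avenue i=di
    legs.append((r, s, float(v_speeds[di])))
    t = np.asarray(dest_xy, dtype=float)
    legs.append((s, t, 25.0))
    return [(a, b, v) for a, b, v in legs if np.linalg.norm(b - a) > 1e-9]


# ----------------------------------------------------------------------
# Speed traces (1-Hz validation channel)
# ----------------------------------------------------------------------

def generate_speed_trace(
    duration_s: int,
    limit_mph: float,
    events: list[tuple[int, str]] | None = None,
    hz: float = 1.0,
    seed: int | np.random.Generator = 0,
    braking_threshold_mphps: float = 8.0,
    accel_threshold_mphps: float = 10.0,
) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """1-Hz speed series with AR(1) noise and injected threshold events.

    ``events`` lists (second, kind) with kind ``hard_braking`` or
    ``sudden_acceleration``; each injects a single 1-s delta just past its
    threshold. Baseline 1-s deltas are clipped to +/-5 mph so only injected
    events qualify. Returns (times_s, speeds_mph, manifest).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(duration_s * hz) + 1
    t = np.arange(n) / hz
    # work in 1-s delta space: baseline deltas are AR(1) noise clipped to
    # +/-5 mph/s, so only injected deltas can cross a threshold
    dv = np.empty(n - 1)
    e = 0.0
    for k in range(n - 1):
        e = 0.7 * e + rng.normal(0.0, 1.5)
        dv[k] = np.clip(e, -5.0, 5.0)
    manifest = []
    for sec, kind in sorted(events or []):
        k = int(sec * hz)
        if not 0 <= k < n - 1:
            continue
        if kind == "hard_braking":
            dv[k] = -(braking_threshold_mphps + 0.5 + rng.uniform(0.0, 1.5))
        elif kind == "sudden_acceleration":
            dv[k] = accel_threshold_mphps + 0.5 + rng.uniform(0.0, 1.5)
        else:
            raise ValueError(f"unknown event kind {kind}")
        manifest.append({"second": int(sec), "kind": kind})
    v = np.empty(n)
    v[0] = max(limit_mph - 3.0, 15.0)
    v[1:] = v[0] + np.cumsum(dv)
    if v.min() < 1.0:   # uniform shift preserves every delta
        v += 1.0 - v.min()
    return t, v, manifest


# ----------------------------------------------------------------------
# Scenario generation
# ----------------------------------------------------------------------

def _month_range(start_month: str, months: int) -> list[tuple[int, int]]:
    y, m = (int(p) for p in start_month.split("-"))
    out = []
    for _ in range(months):
        out.append((y, m))
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return out


def _phase_window(sd, day_local: date, tz) -> dict[str, tuple[datetime, datetime] | None]:
    """Safe sampling windows per light phase for one local date."""
    win: dict[str, tuple[datetime, datetime] | None] = {
        "dawn": None, "day": None, "dusk": None, "night": None}
    m = timedelta(minutes=3)
    if sd.civil_dawn and sd.sunrise and sd.sunrise - sd.civil_dawn > 2 * m:
        win["dawn"] = (sd.civil_dawn + m, sd.sunrise - m)
    if sd.sunrise and sd.sunset:
        win["day"] = (sd.sunrise + timedelta(minutes=10),
                      sd.sunset - timedelta(minutes=45))
    if sd.sunset and sd.civil_dusk and sd.civil_dusk - sd.sunset > 2 * m:
        win["dusk"] = (sd.sunset + m, sd.civil_dusk - m)
    if sd.civil_dusk:
        night_end = datetime.combine(day_local, time(22, 30), tzinfo=tz)
        night_start = sd.civil_dusk + timedelta(minutes=20)
        if night_end > night_start:
            win["night"] = (night_start, night_end)
    return win


def generate_scenario(config: ScenarioConfig | None = None,
                      seed: int = 0) -> Scenario:
    """Simulate one driver and emit breadcrumb/activity tables plus manifest."""
    cfg = config or ScenarioConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    tz = ZoneInfo(cfg.tz_id)
    proj = LocalProjection(cfg.base_lat, cfg.base_lon)
    segments, nodes, h_speeds, v_speeds = make_road_grid(cfg.grid_n, cfg.grid_spacing_m)
    n = cfg.grid_n
    half = (n - 1) / 2.0
    xs = (np.arange(n) - half) * cfg.grid_spacing_m

    # --- anchors and destinations at distinct interior intersections ----
    interior = [(i, j) for i in range(1, n - 1) for j in range(1, n - 1)]
    picks = rng.choice(len(interior), size=len(cfg.anchor_shares) + cfg.n_destinations,
                       replace=False)
    places: list[dict] = []
    for k, pk in enumerate(picks):
        i, j = interior[pk]
        off = np.array([30.0 + rng.uniform(-5, 5), 10.0 + rng.uniform(-3, 3)])
        xy = np.array([xs[i], xs[j]]) + off
        lat, lon = proj.inverse(xy[0], xy[1])
        is_anchor = k < len(cfg.anchor_shares)
        places.append({
            "label": f"anchor{k}" if is_anchor else f"dest{k - len(cfg.anchor_shares)}",
            "node": (i, j), "xy": xy, "lat": float(lat), "lon": float(lon),
            "share_target": cfg.anchor_shares[k] if is_anchor else 0.0,
            "n_ignition_on": 0,
        })
    anchors = places[:len(cfg.anchor_shares)]
    dests = places[len(cfg.anchor_shares):]

    # --- schedule skeleton: per-day trip counts and phases ---------------
    days: list[date] = []
    for (yy, mm) in _month_range(cfg.start_month, cfg.months):
        d = date(yy, mm, 1)
        while d.month == mm:
            days.append(d)
            d += timedelta(days=1)
    day_counts = np.minimum(rng.poisson(cfg.trips_per_day, size=len(days)), 5)
    n_planned = int(day_counts.sum())

    # exact origin multiset so anchor shares hit their targets
    labels: list[int] = []
    for k, a in enumerate(anchors):
        labels += [k] * int(round(a["share_target"] * n_planned))
    while len(labels) < n_planned:
        labels.append(len(anchors) + int(rng.integers(len(dests))))
    origin_seq = rng.permutation(np.array(labels[:n_planned]))

    parked_sd = cfg.noise_parked_ft * M_PER_FT
    moving_sd = cfg.noise_moving_ft * M_PER_FT
    dt = cfg.sampling_interval_s

    rows: list[tuple] = []        # (sort_key_utc, seq, dict)
    seq = 0

    def add_row(ts: pd.Timestamp, vehicle: str, lat: float, lon: float,
                speed: float, odo: float, event: str, address: str = "",
                peak=np.nan, avg=np.nan, v0=np.nan, v1=np.nan):
        nonlocal seq
        rows.append((ts, seq, {
            "vehicle_id": vehicle,
            "timestamp_utc": ts,
            "latitude": round(float(lat), 6), "longitude": round(float(lon), 6),
            "speed_mph": round(float(speed), 1), "odometer_mi": round(float(odo), 2),
            "event_type": event, "nearest_address": address,
            "peak_speed_mph": _r1(peak), "avg_event_speed_mph": _r1(avg),
            "initial_speed_mph": _r1(v0), "final_speed_mph": _r1(v1),
        }))
        seq += 1

    def noisy(xy: np.ndarray, sd: float) -> tuple[float, float]:
        p = xy + rng.normal(0.0, sd, size=2)
        lat, lon = proj.inverse(p[0], p[1])
        return float(lat), float(lon)

    activity_rows: list[dict] = []
    trips: list[TripTruth] = []
    odometer = float(rng.uniform(10000, 40000))
    cursor: datetime | None = None            # end of the previous trip (local)
    last_event_local: datetime | None = None  # for idle pings
    trip_no = 0
    label_idx = 0
    vid = cfg.vehicle_id

    corruption = {
        "zero_crumbs": [], "duplicates": [], "na_end_trips": 0,
        "zero_start_trips": 0, "egypt_trip": None, "egypt_rows": 0,
        "defective_vehicle": None, "defective_rows": 0, "abandoned_starts": 0,
    }
    abandon_left = cfg.n_abandoned_starts

    for d_idx, day_local in enumerate(days):
        k = int(day_counts[d_idx])
        if k == 0:
            continue
        sd = solar_day(cfg.base_lat, cfg.base_lon, day_local, tz_id=cfg.tz_id)
        windows = _phase_window(sd, day_local, tz)
        phases = list(rng.choice(["day", "night", "dusk", "dawn"], size=k,
                                 p=[cfg.p_day, cfg.p_night, cfg.p_dusk, cfg.p_dawn]))
        # short twilight windows hold at most one trip each
        for ph in ("dawn", "dusk", "night"):
            while phases.count(ph) > 1:
                phases[phases.index(ph)] = "day"
        order = {"dawn": 0, "day": 1, "dusk": 2, "night": 3}
        phases.sort(key=order.get)
        n_day = phases.count("day")
        day_slot = 0
        for ph in phases:
            win = windows[ph]
            if win is None:
                continue
            w0, w1 = win
            if ph == "day" and n_day > 1:     # disjoint slots avoid overlap
                span = (w1 - w0) / n_day
                w0 = w0 + day_slot * span
                w1 = w0 + span - timedelta(minutes=15)
                day_slot += 1
                if w1 <= w0:
                    continue
            start_local = w0 + timedelta(seconds=float(rng.uniform(0, (w1 - w0).total_seconds())))
            if cursor is not None and start_local < cursor + timedelta(minutes=10):
                start_local = cursor + timedelta(minutes=10)
                if start_local > w1:
                    continue                   # window missed; trip dropped
            start_local = start_local.replace(microsecond=0)

            origin = places[int(origin_seq[label_idx])] if label_idx < len(origin_seq) \
                else places[int(rng.integers(len(places)))]
            label_idx += 1
            dest = dests[int(rng.integers(len(dests)))]
            while dest["label"] == origin["label"]:
                dest = dests[int(rng.integers(len(dests)))]

            legs = _route(origin["xy"], origin["node"], dest["xy"], dest["node"],
                          xs, h_speeds, v_speeds)
            total_len = sum(np.linalg.norm(b - a) for a, b, _ in legs)

            # idle pings while parked since the last event, at this origin
            start_utc = pd.Timestamp(start_local.astimezone(timezone.utc))
            ping_from = last_event_local or datetime.combine(
                days[0], time(0, 0), tzinfo=tz)
            t_ping = ping_from + timedelta(hours=cfg.idle_ping_interval_h)
            while t_ping < start_local:
                la, lo = noisy(origin["xy"], parked_sd)
                add_row(pd.Timestamp(t_ping.astimezone(timezone.utc)), vid, la, lo,
                        0.0, odometer, "idle_ping")
                t_ping += timedelta(hours=cfg.idle_ping_interval_h)

            # optional abandoned start a few seconds before the real one
            if abandon_left > 0 and rng.random() < 0.5:
                la, lo = noisy(origin["xy"], parked_sd)
                t_ab = start_utc - pd.Timedelta(seconds=8)
                add_row(t_ab, vid, la, lo, 0.0, odometer, "ignition_on")
                origin["n_ignition_on"] += 1
                activity_rows.append(_activity_row(
                    vid, t_ab, la, lo, None, None, 0.0, 0.0, 0.0, 0.0, 0, 0, 0, 0.0))
                corruption["na_end_trips"] += 1
                corruption["abandoned_starts"] += 1
                abandon_left -= 1

            # ignition on
            o_lat, o_lon = noisy(origin["xy"], parked_sd)
            add_row(start_utc, vid, o_lat, o_lon, 0.0, odometer, "ignition_on",
                    address=f"{origin['label']} Pl")
            origin["n_ignition_on"] += 1

            # walk the route at 30-s cadence
            crumb_rows = []
            dist = 0.0
            e_noise = 0.0
            t_s = 0.0
            leg_idx, leg_pos = 0, 0.0
            leg_lens = [np.linalg.norm(b - a) for a, b, _ in legs]
            speeds = []
            while dist < total_len:
                t_s += dt
                lim = legs[min(leg_idx, len(legs) - 1)][2]
                e_noise = 0.6 * e_noise + rng.normal(0.0, 1.2)
                sp = float(np.clip(lim - 3.0 + e_noise, 8.0, lim + 3.5))
                step = sp * 0.44704 * dt
                dist = min(dist + step, total_len)
                # advance along legs
                rem = dist
                li = 0
                while li < len(legs) and rem > leg_lens[li]:
                    rem -= leg_lens[li]
                    li += 1
                if li >= len(legs):
                    break
                leg_idx = li
                a, b, lim_here = legs[li]
                frac = rem / leg_lens[li]
                pos = a + frac * (b - a)
                # the recorded speed reflects the street the fix lands on
                # (a step can cross onto the next, differently-limited leg)
                sp = float(np.clip(lim_here - 3.0 + e_noise, 8.0, lim_here + 3.5))
                # drivers slow for crossings: near an intersection the
                # recorded speed stays below every adjoining street's limit
                node_d = float(np.hypot(pos[0] - xs[np.abs(xs - pos[0]).argmin()],
                                        pos[1] - xs[np.abs(xs - pos[1]).argmin()]))
                near_node = node_d < 40.0
                if near_node:
                    sp = float(min(lim_here, 25.0) - 3.0
                               + np.clip(e_noise, -2.0, 2.0))
                crumb_rows.append({"t": t_s, "xy": pos, "speed": sp,
                                   "limit": lim_here, "near_node": near_node})
                speeds.append(sp)
                if dist >= total_len:
                    break
            dur = t_s + dt          # arrival one interval after the last crumb
            n_cr = len(crumb_rows)

            # inject alerts (overspeeding runs stay clear of intersections so
            # the nearest-street speed limit of every run crumb is its own)
            n_os = n_hb = n_sa = 0
            os_candidates = [
                i for i in range(1, n_cr - 3)
                if not any(crumb_rows[j]["near_node"] for j in (i, i + 1, i + 2))
            ]
            if os_candidates and rng.random() < cfg.p_overspeed:
                r0 = os_candidates[int(rng.integers(len(os_candidates)))]
                boost = rng.uniform(2.0, 5.0)
                for c in crumb_rows[r0:r0 + 3]:
                    c["speed"] = c["limit"] + cfg.overspeed_margin_mph + boost
                crumb_rows[r0]["os_event"] = True
                n_os = 1
            hb_at = -1
            if n_cr >= 3 and rng.random() < cfg.p_hard_braking:
                hb_at = int(rng.integers(1, n_cr - 1))
                c = crumb_rows[hb_at]
                v0 = max(c["speed"], 15.0)
                c["hb"] = (v0, v0 - (8.0 + rng.uniform(0.5, 1.5)))
                n_hb = 1
            if n_cr >= 3 and rng.random() < cfg.p_sudden_accel:
                # distinct site: two event rows on one crumb would share a
                # timestamp and read as a duplicate
                sites = [i for i in range(1, n_cr - 1) if i != hb_at]
                if sites:
                    c = crumb_rows[sites[int(rng.integers(len(sites)))]]
                    v0 = c["speed"]
                    c["sa"] = (v0, v0 + 10.0 + rng.uniform(0.5, 1.5))
                    n_sa = 1

            for c in crumb_rows:
                la, lo = noisy(c["xy"], moving_sd)
                ts = start_utc + pd.Timedelta(seconds=c["t"])
                odometer += c["speed"] * dt / 3600.0
                if c.get("os_event"):
                    run = [cc["speed"] for cc in crumb_rows
                           if cc["t"] >= c["t"] and cc["t"] < c["t"] + 3 * dt]
                    add_row(ts, vid, la, lo, c["speed"], odometer, "overspeeding",
                            peak=max(run), avg=float(np.mean(run)))
                else:
                    add_row(ts, vid, la, lo, c["speed"], odometer, "regular")
                if "hb" in c:
                    v0, v1 = c["hb"]
                    add_row(ts + pd.Timedelta(seconds=1), vid, la, lo, v1, odometer,
                            "hard_braking", v0=v0, v1=v1)
                if "sa" in c:
                    v0, v1 = c["sa"]
                    add_row(ts + pd.Timedelta(seconds=1), vid, la, lo, v1, odometer,
                            "sudden_acceleration", v0=v0, v1=v1)

            # ignition off at the destination
            end_utc = start_utc + pd.Timedelta(seconds=round(dur))
            d_lat, d_lon = noisy(dest["xy"], parked_sd)
            add_row(end_utc, vid, d_lat, d_lon, 0.0, odometer, "ignition_off",
                    address=f"{dest['label']} Pl")

            dist_mi = round(total_len / 1000.0, 1) * MI_PER_KM  # vendor-style rounding
            activity_rows.append(_activity_row(
                vid, start_utc, o_lat, o_lon, d_lat, d_lon, round(dur),
                dist_mi, float(np.mean(speeds)) if speeds else 0.0,
                float(np.max(speeds)) if speeds else 0.0,
                n_sa, n_hb, n_os, n_os * 3 * dt))

            trips.append(TripTruth(
                trip_no=trip_no, vehicle_id=vid, month=f"{day_local:%Y-%m}",
                phase=ph, start_utc=start_utc,
                start_local=pd.Timestamp(start_local),
                origin_label=origin["label"], origin_lat=o_lat, origin_lon=o_lon,
                dest_label=dest["label"], dest_lat=d_lat, dest_lon=d_lon,
                n_crumbs=n_cr + 2 + n_hb + n_sa,   # incl. on/off and event rows
                duration_s=round(dur), distance_m=total_len,
                n_overspeeding=n_os, n_hard_braking=n_hb, n_sudden_accel=n_sa))
            trip_no += 1
            cursor = start_local + timedelta(seconds=round(dur))
            last_event_local = cursor

    # ------------------------------------------------------------------
    # corruption injection
    # ------------------------------------------------------------------
    bc = pd.DataFrame([r[2] for r in sorted(rows, key=lambda r: (r[0], r[1]))])

    if cfg.egypt_outlier and trips:
        # one mid-trip fix lands on another continent; the whole trip is junk
        candidates = [t for t in trips if t.n_crumbs >= 5]
        victim = candidates[int(rng.integers(len(candidates)))]
        mask = ((bc["timestamp_utc"] > victim.start_utc)
                & (bc["timestamp_utc"] < victim.start_utc
                   + pd.Timedelta(seconds=victim.duration_s))
                & (bc["event_type"] == "regular"))
        ridx = bc.index[mask]
        hit = ridx[len(ridx) // 2]
        bc.loc[hit, ["latitude", "longitude"]] = EGYPT_LATLON
        victim.corrupted = True
        corruption["egypt_trip"] = victim.trip_no
        corruption["egypt_rows"] = int(victim.n_crumbs
                                       + victim.n_hard_braking + victim.n_sudden_accel)

    zero_rows = []
    for k in range(cfg.n_zero_crumbs):
        day_local = days[int(rng.integers(len(days)))]
        t_loc = datetime.combine(day_local, time(3, 0), tzinfo=tz) \
            + timedelta(seconds=int(rng.integers(0, 3600)))
        zero_rows.append({
            "vehicle_id": vid,
            "timestamp_utc": pd.Timestamp(t_loc.astimezone(timezone.utc)),
            "latitude": 0.0, "longitude": 0.0, "speed_mph": 0.0,
            "odometer_mi": round(odometer, 2), "event_type": "device_connect",
            "nearest_address": "", "peak_speed_mph": np.nan,
            "avg_event_speed_mph": np.nan, "initial_speed_mph": np.nan,
            "final_speed_mph": np.nan,
        })
    corruption["zero_crumbs"] = len(zero_rows)

    defect_rows = []
    if cfg.defective_device:
        dvid = "9999999999"
        corruption["defective_vehicle"] = dvid
        t0 = datetime.combine(days[0], time(0, 15), tzinfo=tz)
        t_end = t0 + timedelta(days=cfg.defective_days)
        t = t0
        while t < t_end:
            defect_rows.append({
                "vehicle_id": dvid,
                "timestamp_utc": pd.Timestamp(t.astimezone(timezone.utc)),
                "latitude": 0.0, "longitude": 0.0, "speed_mph": 0.0,
                "odometer_mi": 0.0, "event_type": "regular", "nearest_address": "",
                "peak_speed_mph": np.nan, "avg_event_speed_mph": np.nan,
                "initial_speed_mph": np.nan, "final_speed_mph": np.nan,
            })
            t += timedelta(minutes=30)
        corruption["defective_rows"] = len(defect_rows)

    if zero_rows or defect_rows:
        bc = pd.concat([bc, pd.DataFrame(zero_rows + defect_rows)], ignore_index=True)
        bc = bc.sort_values("timestamp_utc", kind="stable").reset_index(drop=True)

    if cfg.n_duplicate_crumbs:
        # duplicate only located fixes: zero-coordinate rows would be caught
        # by the coordinate filter first and shift the audit attribution
        reg = bc.index[(bc["event_type"] == "regular") & (bc["latitude"] != 0.0)]
        pick = rng.choice(reg, size=min(cfg.n_duplicate_crumbs, len(reg)), replace=False)
        pick = np.sort(pick)
        parts, prev = [], 0
        for p in pick:
            parts.append(bc.iloc[prev:p + 1])
            parts.append(bc.iloc[[p]])           # exact copy right after the original
            prev = p + 1
        parts.append(bc.iloc[prev:])
        bc = pd.concat(parts, ignore_index=True)
        corruption["duplicates"] = int(len(pick))
    else:
        corruption["duplicates"] = 0

    act = pd.DataFrame(activity_rows)
    zero_start_rows = []
    for k in range(cfg.n_zero_start_trips):
        src = "9999999999" if cfg.defective_device else vid
        day_local = days[int(rng.integers(len(days)))]
        t_loc = datetime.combine(day_local, time(3, 30), tzinfo=tz)
        zero_start_rows.append(_activity_row(
            src, pd.Timestamp(t_loc.astimezone(timezone.utc)),
            0.0, 0.0, 0.0, 0.0, 300.0, 1.0, 20.0, 30.0, 0, 0, 0, 0.0))
    corruption["zero_start_trips"] = len(zero_start_rows)
    if zero_start_rows:
        act = pd.concat([act, pd.DataFrame(zero_start_rows)], ignore_index=True)
    act = act.sort_values("start_time_utc", kind="stable").reset_index(drop=True)

    sc = Scenario(
        config=cfg, seed=seed, projection=proj, segments=segments,
        anchors=[{k: v for k, v in a.items() if k not in ("xy", "node")} for a in anchors],
        destinations=[{k: v for k, v in d.items() if k not in ("xy", "node", "share_target",
                                                               "n_ignition_on")} for d in dests],
        trips=trips, breadcrumbs=bc, activity=act, corruption=corruption,
    )
    return sc


def _r1(x) -> float:
    return round(float(x), 1) if np.isfinite(x) else np.nan


def _activity_row(vid, start_utc, slat, slon, elat, elon, dur, dist_mi,
                  avg, vmax, n_sa, n_hb, n_os, os_dur) -> dict:
    return {
        "vehicle_id": vid, "start_time_utc": start_utc,
        "start_lat": round(float(slat), 6), "start_lon": round(float(slon), 6),
        "end_lat": round(float(elat), 6) if elat is not None else np.nan,
        "end_lon": round(float(elon), 6) if elon is not None else np.nan,
        "start_address": "", "end_address": "",
        "duration_s": float(dur), "distance_mi": round(float(dist_mi), 3),
        "avg_speed_mph": round(float(avg), 1), "max_speed_mph": round(float(vmax), 1),
        "n_sudden_accel": int(n_sa), "n_hard_braking": int(n_hb),
        "n_overspeeding": int(n_os), "overspeeding_duration_s": float(os_dur),
    }


# ----------------------------------------------------------------------
# Canonical micro-fixtures
# ----------------------------------------------------------------------

def write_fixture_suite(out_dir: str | Path) -> dict[str, Path]:
    """Deterministic mini-fixtures, one per cleaning rule / spatial metric.

    Covers the classic failure modes: a fix on another continent inside an
    otherwise-normal trip, an exact duplicate row, zero-coordinate fixes,
    an NA-ended trip record, and a two-primary-location ignition pattern.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def bc_file(name: str, rows: list[dict]) -> Path:
        df = pd.DataFrame(rows)
        p = out / name
        df.to_csv(p, index=False)
        paths[name.removesuffix(".csv")] = p
        return p

    base = dict(vehicle_id="1000000001", speed_mph=30.0, odometer_mi=100.0,
                nearest_address="", peak_speed_mph=np.nan, avg_event_speed_mph=np.nan,
                initial_speed_mph=np.nan, final_speed_mph=np.nan)

    def crumb(ts, lat, lon, ev="regular", **kw):
        return {**base, "timestamp_utc": ts, "latitude": lat, "longitude": lon,
                "event_type": ev, **kw}

    t0 = "2016-07-01T15:00:"
    bc_file("egypt_trip.csv", [
        crumb(t0 + "00+00:00", 38.6300, -90.2000, "ignition_on", speed_mph=0.0),
        crumb(t0 + "30+00:00", 38.6310, -90.2010),
        crumb("2016-07-01T15:01:00+00:00", EGYPT_LATLON[0], EGYPT_LATLON[1]),
        crumb("2016-07-01T15:01:30+00:00", 38.6330, -90.2030),
        crumb("2016-07-01T15:02:00+00:00", 38.6340, -90.2040, "ignition_off",
              speed_mph=0.0),
    ])
    bc_file("duplicate_rows.csv", [
        crumb(t0 + "00+00:00", 38.6300, -90.2000),
        crumb(t0 + "00+00:00", 38.6300, -90.2000),
        crumb(t0 + "30+00:00", 38.6310, -90.2010),
    ])
    bc_file("zero_coordinates.csv", [
        crumb(t0 + "00+00:00", 0.0, 0.0, "device_connect", speed_mph=0.0),
        crumb(t0 + "30+00:00", 38.6310, -90.2010),
    ])
    # two ignition-on clusters, 60% / 25% of fixes, well separated
    rng = np.random.default_rng(42)
    proj = LocalProjection(38.63, -90.20)
    rows = []
    t = pd.Timestamp("2016-07-01T12:00:00+00:00")
    for center, count in ((np.array([0.0, 0.0]), 12),
                          (np.array([2000.0, 1500.0]), 5),
                          (np.array([-3000.0, 800.0]), 3)):
        for _ in range(count):
            p = center + rng.normal(0, 5 * M_PER_FT, 2)
            lat, lon = proj.inverse(p[0], p[1])
            rows.append(crumb(t.isoformat(), round(float(lat), 6),
                              round(float(lon), 6), "ignition_on", speed_mph=0.0))
            t += pd.Timedelta(hours=6)
    bc_file("two_primary_clusters.csv", rows)

    act = pd.DataFrame([
        _activity_row("1000000001", pd.Timestamp("2016-07-01T15:00:00+00:00"),
                      38.63, -90.20, None, None, 120.0, 0.6, 25.0, 30.0, 0, 0, 0, 0.0),
        _activity_row("1000000001", pd.Timestamp("2016-07-01T16:00:00+00:00"),
                      0.0, -90.20, 38.64, -90.21, 300.0, 1.2, 25.0, 30.0, 0, 0, 0, 0.0),
        _activity_row("1000000001", pd.Timestamp("2016-07-01T17:00:00+00:00"),
                      38.63, -90.20, 38.65, -90.22, 300.0, 1.2, 25.0, 30.0, 0, 0, 0, 0.0),
    ])
    p = out / "activity_na_end.csv"
    act.to_csv(p, index=False)
    paths["activity_na_end"] = p
    return paths
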