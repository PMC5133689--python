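# Methods

This note records the models, parameters and design decisions behind
`drivecrumb`, and what validation on the synthetic simulator does and does
not establish about real data.

## Data model

A **breadcrumb** is one GPS observation of one vehicle: id, UTC timestamp,
WGS84 latitude/longitude, speed (mph), odometer (mi) and an event type
(`regular`, `ignition_on`, `ignition_off`, the three alert kinds,
`idle_ping`, and device housekeeping codes). Breadcrumbs arrive every 30 s
while driving and every 3 h while parked. A **trip** is the ordered
breadcrumb sequence between an `ignition_on` and the next `ignition_off`
of the same vehicle. The vendor's **activity** file summarises each trip
(endpoints, duration, distance rounded to 0.1 km then reported in miles,
mean/max speed, alert counts).

## Cleaning

Rules, applied in the order coordinates → duplicate timestamps for
breadcrumbs, independently NA-end → zero-start for activity rows:

1. Fixes outside a configurable bounding box (default CONUS envelope,
   lat 24.5–49.5, lon −125.0 to −66.9), at exactly (0, 0) on either
   coordinate, or non-finite are removed. Zero is tested exactly — it is a
   device-fault signature, not a measurement — so no epsilon ball. When a
   removed fix belongs to a trip, the whole trip's fixes are removed: one
   impossible location makes the trajectory untrustworthy.
2. For identical (vehicle, timestamp) pairs the first row in file order is
   kept. Duplicates disagreeing on position are additionally flagged
   (`duplicate_conflict`) for review rather than silently resolved.
3. Activity rows with NA end coordinates (signal loss, abandoned duplicate
   trip starts) or a zero start coordinate are removed with per-row
   reasons.

The two breadcrumb filters test disjoint row properties and commute; a
permutation test asserts this. All filters are idempotent, and
kept + removed = input holds for each (asserted as invariants).

**Defective devices.** A failing logger emits long runs of zero
coordinates. A vehicle is flagged when any rolling 7-day window containing
at least 50 fixes is more than 50% zero-coordinate. The window length
matches a multi-week outage pattern; the 50-fix floor keeps a sparse or
nearly-empty stream from being flagged on a handful of rows. Flagged
vehicles are excluded from profiles and their months null-marked. Flagging
runs on *raw* data, before the coordinate filter removes the evidence.

**Abandoned trip starts.** A second `ignition_on` within 60 s of an open
start, with at most one intervening fix, marks the first start as
abandoned (counted, flagged, excluded from usable trips). Any other
mid-trip `ignition_on` closes the open trip with a `no_ignition_off` flag;
an `ignition_off` with no open trip is quarantined.

## Local time and light phases

Zone assignment uses a fast bounding box (default: the interior of the
Central zone) and falls back to point-in-polygon lookup. The packaged
polygon set is synthetic — four meridian-cut rectangles over CONUS — and
exists so the pipeline and tests run self-contained; boundaries are not
survey-accurate and production users should supply a tz-boundary GeoJSON.
Offsets and DST rules always come from the system tz database, so
conversions are exact once the zone id is right. UTC→local conversion is
bijective; the local→UTC direction flags nonexistent (DST-gap) and
ambiguous (fold) wall times instead of silently shifting them.

Sunrise/sunset use the NOAA spreadsheet solar equations: sun-center
elevation −0.833° (refraction + solar radius) for sunrise/sunset, −6° for
civil twilight, with the declination/equation-of-time iterated at the
event estimate. Documented accuracy ±1 min for |lat| < 60°; polar
day/night return explicit absent events. The test oracle is a separate
formulation (Astronomical Almanac low-precision position + bisection), and
one frozen external reference (June solstice at St. Louis) pins absolute
correctness.

A trip's phase is decided by its **start** instant and start location —
profiles count trips *started* at night, and trips crossing sunset are not
split. `night` is strict (sun below −6°); a `not_day` switch folds dawn
and dusk into night for two-way day/night tables, since published
day-vs-night tallies rarely state which convention they use. Exactly one
phase per trip; the four phase counts always sum to the trip count.

## Spatial profile

All geometry runs in a per-driver planar frame: an azimuthal-equidistant
projection on the mean-radius sphere, centred on the driver's median fix.
Round-trips are exact to float precision (tested < 0.1 m within 200 km)
and local distances are within 0.5% at city scale, which dominates GPS
noise by orders of magnitude.

* **Primary locations.** Ignition-on fixes are clustered as connected
  components of the "within 20 ft" graph (0.3048 m/ft); components with
  < 3 points are discarded. A cluster whose member count reaches 10% of
  the driver's total ignition-on fixes over the whole analysis window is a
  primary location; its centroid is the member mean. Membership counts use
  the component itself, not a point-in-polygon recount — identical for
  convex hulls of the members, and robust when the hull is degenerate
  (collinear clusters get a nominal 1-m buffer). Zero, one or several
  primaries are all valid outcomes.
* **Driving area.** Convex hull of the period's fixes, area in km²
  (the source figures leave units unstated; km² is the package's choice).
  Fewer than 3 points or collinear fixes yield a degenerate record that
  overlap metrics skip.
* **Mean center.** Unweighted arithmetic mean in the projected plane; by
  convexity it always lies inside the period hull (tested).
* **Unique destinations.** Discs of radius r around ignition-on fixes
  merge exactly when center distance < 2r, so the dissolved-polygon count
  equals the component count of that graph; tangency (distance exactly 2r)
  does *not* merge — a documented tie-break, and the graph count is
  verified against an explicit shapely buffer-union on random sets.
  Counts are monotone non-increasing in radius.
* **Overlap.** Consecutive-period hull intersections, plus
  ratio = area common to *all* periods / union of all periods. "Total"
  could also mean the sum of period areas; that reading is available via
  `overlap_total = "sum"`.

Periods are local calendar months (default) or ISO weeks, cut at local
midnight, with a trip assigned to the period of its start.

## Road matching and behavioral metrics

Each fix snaps to the nearest street centerline (STR-tree, exact nearest
query; ties to the lowest segment id; planar point-to-segment distance).
Matches beyond 100 m are kept but flagged `off_network` so garage or
glitch fixes do not silently inherit road attributes — an intentional cap
on an otherwise unconditional join. The segment's average speed serves as
a posted-limit proxy.

Alerts: overspeeding = speed ≥ limit-proxy + 6 mph; hard braking = 1-s
decrease ≥ 8 mph; sudden acceleration = 1-s increase ≥ 10 mph. The
"8 to 10 mph in one second (decrease/increase respectively)" phrasing is
read as mapping the range across the two directions; the alternative
single 8–10 band for both is available (`band_mode`). A maximal run of
consecutive overspeeding fixes is one event, with no minimum duration.
Device-reported events are the headline numbers (the logger is the
instrument of record); recomputation is a validation channel, and braking/
acceleration recomputation applies only to 1-Hz traces — a 30-s breadcrumb
cadence cannot certify 1-s deltas. Per-driver study-window summaries use
the deposited-table column vocabulary (`numtripsover5mo`,
`trips_at_night5mo`, …); cohort dispersion is the sample SD (n − 1).

## Synthetic scenarios

The simulator emulates the data-generating process: a square street grid
(default 13×13 intersections, 500-m spacing, cyclic 25/35/55-mph speed
classes with CFCC-style codes A41/A31/A21), anchors and destinations at
grid intersections, ~3.5 trips/day (Poisson, capped at 5) routed Manhattan
over the grid, 30-s fixes with isotropic Gaussian noise (sd 5 ft parked /
15 ft moving — consumer-GPS magnitude, small enough that 20-ft clustering
stays meaningful), 3-h idle pings, vendor-style activity rows, and
phase-targeted start times placed with safety margins inside solar windows
computed at the scenario base point. Trip origins are drawn from an exact
multiset so anchor ignition-on shares hit their configured targets
(default 55%/25%). Simulated drivers slow below every adjoining street's
limit within 40 m of an intersection, and injected overspeeding runs avoid
those zones, so nearest-street attribution of speeding is unambiguous in
ground truth. Recorded speeds are only loosely consistent with 30-s
displacements; nothing downstream cross-checks them.

Corruption is injected per an explicit manifest: standalone (0, 0) rows,
one out-of-country fix inside a sacrificial trip, exact duplicate rows,
NA-ended activity rows paired with abandoned starts, zero-start activity
rows, and a defective second vehicle emitting ~15 days of zeros. One RNG
stream per scenario; the same seed reproduces byte-identical files, and
the emitted header line records the seed.

What passing on this simulator shows: the pipeline recovers exactly what
the generating process put in — trip boundaries, phase counts, alert
counts, anchor locations, corruption removals. What it does not show:
robustness to multipath/urban-canyon GPS error (noise here is isotropic
Gaussian), real road topology (planar grid, no curves or dead zones),
traffic-dependent speeds, or vendor schema drift. The cleaning rules
themselves encode field-observed failure modes, but their coverage of
unseen failure modes is untested by construction.

## Problem sizes and numerical notes

The shipped validation uses one-month scenarios (~100 trips, ~1.5 k fixes)
for the 25-scenario primary-location batch and a five-month corrupted
scenario (~500 trips, ~8 k fixes) for the end-to-end manifest check —
sizes chosen to exercise every path at sub-minute cost; all algorithms are
near-linear (KD-tree pair queries, STR-tree nearest) and scale to the
multi-hundred-thousand-fix range a real cohort produces. Destination/
cluster graphs use strict (`<`) or inclusive (`≤`) comparisons as
documented above; hull areas use exact shapely arithmetic; timestamps are
stored tz-aware UTC and serialised ISO-8601 at second resolution.

## Known limitations

* The packaged tz polygons are deliberately coarse; supply real boundaries
  for drivers near zone edges.
* Speeding detection inherits the bias of "average speed" as a limit
  proxy; under-speeding detection is not attempted (confounded by traffic
  and signal granularity).
* Trips are attributed whole to the period and phase of their start.
* Reverse geocoding, vendor transport, and driver identification are out
  of scope; the street-table source (e.g. Census TIGER) is the user's
  choice — only the GeoJSON schema is fixed.
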