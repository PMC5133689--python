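"""Spatial profile components against brute-force geometric oracles."""

from __future__ import annotations

import numpy as np
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point

from drivecrumb import spatial
from drivecrumb.config import M_PER_FT
from drivecrumb.spatial import (
    LocalProjection, cluster_ignition_points, compute_driving_area,
    compute_mean_center, count_unique_destinations, detect_primary_locations,
    haversine_m, overlap_metrics,
)

FT = M_PER_FT


# ----------------------------------------------------------------------
# Projection
# ----------------------------------------------------------------------

class TestLocalProjection:
    def test_center_maps_to_origin(self, stl_projection):
        x, y = stl_projection.forward(38.63, -90.20)
        assert abs(x) < 1e-9 and abs(y) < 1e-9

    def test_planar_distance_matches_haversine_at_1km(self, stl_projection):
        lat2 = 38.63 + 1.0 / 111.195  # ~1 km north
        d_true = haversine_m(38.63, -90.20, lat2, -90.20)
        x, y = stl_projection.forward(lat2, -90.20)
        assert abs(np.hypot(x, y) - d_true) / d_true < 0.005
        # and an oblique pair ~1 km apart
        x1, y1 = stl_projection.forward(38.636, -90.192)
        d_true = haversine_m(38.63, -90.20, 38.636, -90.192)
        assert abs(np.hypot(x1, y1) - d_true) / d_true < 0.005

    def test_round_trip_under_ten_centimeters(self, stl_projection, rng):
        lats = 38.63 + rng.uniform(-1.5, 1.5, 1000)   # within ~200 km
        lons = -90.20 + rng.uniform(-1.5, 1.5, 1000)
        x, y = stl_projection.forward(lats, lons)
        la, lo = stl_projection.inverse(x, y)
        err = haversine_m(lats, lons, la, lo) if np.isscalar(lats) else np.array(
            [haversine_m(a, b, c, d) for a, b, c, d in zip(lats, lons, la, lo)])
        assert np.max(err) < 0.1


# ----------------------------------------------------------------------
# Ignition clustering and primary locations
# ----------------------------------------------------------------------

def brute_force_components(xy: np.ndarray, link: float) -> np.ndarray:
    """O(n^2) union-find over all point pairs within the link distance."""
    n = len(xy)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(xy[i] - xy[j]) <= link:
                parent[find(i)] = find(j)
    return np.array([find(i) for i in range(n)])


class TestClustering:
    def test_chain_of_three_links_into_one_cluster(self):
        xy = np.array([[0, 0], [15 * FT, 0], [30 * FT, 0]])
        clusters = cluster_ignition_points(xy, link_distance_m=20 * FT, min_size=3)
        assert len(clusters) == 1 and clusters[0].size == 3

    def test_pair_below_min_size_is_not_a_cluster(self):
        xy = np.array([[0, 0], [5 * FT, 0]])
        assert cluster_ignition_points(xy, 20 * FT, min_size=3) == []

    def test_partition_matches_brute_force_union_find(self, rng):
        xy = rng.uniform(0, 60, size=(200, 2))   # meters; link 6.096 m
        labels = brute_force_components(xy, 20 * FT)
        clusters = cluster_ignition_points(xy, 20 * FT, min_size=1)
        got = {frozenset(c.indices.tolist()) for c in clusters}
        want = {frozenset(np.flatnonzero(labels == l).tolist())
                for l in np.unique(labels)}
        assert got == want

    def test_output_is_independent_of_point_order(self, rng):
        xy = rng.uniform(0, 40, size=(80, 2))
        perm = rng.permutation(80)
        a = cluster_ignition_points(xy, 20 * FT, min_size=3)
        b = cluster_ignition_points(xy[perm], 20 * FT, min_size=3)
        sets_a = {frozenset(map(tuple, np.round(xy[c.indices], 9))) for c in a}
        sets_b = {frozenset(map(tuple, np.round(xy[perm][c.indices], 9))) for c in b}
        assert sets_a == sets_b


class TestPrimaryLocations:
    def test_single_spot_gives_one_primary_with_full_share(self, rng):
        xy = rng.normal(0, 1.0, size=(20, 2))
        clusters = cluster_ignition_points(xy, 20 * FT, 3)
        prims = detect_primary_locations(clusters, 20)
        assert len(prims) == 1 and prims[0].share == pytest.approx(1.0)

    def test_two_clusters_above_threshold_give_two_primaries(self, rng):
        home = rng.normal(0, 1.0, size=(60, 2))
        work = np.array([5000.0, 3000.0]) + rng.normal(0, 1.0, size=(20, 2))
        stray = np.array([[-8000.0, 1000.0]])   # single fix, never clusters
        xy = np.vstack([home, work, stray])
        clusters = cluster_ignition_points(xy, 20 * FT, 3)
        prims = detect_primary_locations(clusters, len(xy), share_threshold=0.10)
        assert len(prims) == 2
        assert sorted(round(p.share, 3) for p in prims) == [
            pytest.approx(20 / 81, abs=1e-3), pytest.approx(60 / 81, abs=1e-3)]

    def test_share_just_below_threshold_is_rejected(self, rng):
        # 99 fixes at home, 11 elsewhere: 11/110 = 10%; 10/101 = 9.9% fails
        near = rng.normal(0, 0.5, size=(91, 2))
        far = np.array([4000.0, 0.0]) + rng.normal(0, 0.5, size=(10, 2))
        clusters = cluster_ignition_points(np.vstack([near, far]), 20 * FT, 3)
        prims = detect_primary_locations(clusters, 101, share_threshold=0.10)
        assert len(prims) == 1  # only the 91-fix cluster passes

    def test_centroid_lies_inside_cluster_polygon(self, rng):
        xy = rng.normal(0, 2.0, size=(30, 2))
        clusters = cluster_ignition_points(xy, 30.0, 3)
        prims = detect_primary_locations(clusters, 30)
        for p in prims:
            assert p.cluster_polygon.buffer(1e-9).contains(
                Point(p.centroid_xy))


# ----------------------------------------------------------------------
# Driving areas and mean centers
# ----------------------------------------------------------------------

def gift_wrap_hull(xy: np.ndarray) -> set[tuple[float, float]]:
    """O(n^2) Jarvis-march convex hull vertex set (strict turns)."""
    pts = [tuple(p) for p in xy]
    start = min(pts)
    hull = [start]
    cur = start
    while True:
        cand = pts[0] if pts[0] != cur else pts[1]
        for p in pts:
            if p == cur:
                continue
            cross = ((cand[0] - cur[0]) * (p[1] - cur[1])
                     - (cand[1] - cur[1]) * (p[0] - cur[0]))
            if cross < 0:
                cand = p
        if cand == start:
            break
        hull.append(cand)
        cur = cand
    return set(hull)


class TestDrivingArea:
    def test_unit_square_has_unit_area(self):
        xy = np.array([[0, 0], [1000, 0], [1000, 1000], [0, 1000]])
        area = compute_driving_area(xy)
        assert area.area_km2 == pytest.approx(1.0)

    def test_every_point_is_inside_or_on_hull(self, rng):
        xy = rng.normal(0, 500, size=(60, 2))
        hull = compute_driving_area(xy).hull.buffer(1e-6)
        assert all(hull.contains(Point(p)) for p in xy)

    def test_hull_vertices_match_gift_wrapping_oracle(self, rng):
        xy = rng.uniform(0, 1000, size=(500, 2))
        hull = compute_driving_area(xy).hull
        got = {(round(x, 6), round(y, 6)) for x, y in
               np.asarray(hull.exterior.coords)[:-1]}
        want = {(round(x, 6), round(y, 6)) for x, y in gift_wrap_hull(xy)}
        assert got == want

    def test_degenerate_inputs_are_flagged(self):
        assert compute_driving_area(np.array([[0, 0], [1, 1]])).degenerate
        collinear = np.array([[0, 0], [1, 1], [2, 2], [3, 3]])
        assert compute_driving_area(collinear).degenerate

    def test_adding_a_point_never_shrinks_the_hull(self, rng):
        xy = rng.normal(0, 300, size=(40, 2))
        base = compute_driving_area(xy).hull
        extra = compute_driving_area(np.vstack([xy, [[900.0, -900.0]]])).hull
        assert extra.buffer(1e-6).contains(base)
        assert extra.area >= base.area


class TestMeanCenter:
    def test_square_corners_average_to_center(self):
        xy = np.array([[0, 0], [1000, 0], [1000, 1000], [0, 1000]])
        mc = compute_mean_center(xy)
        assert (mc.x, mc.y) == (500.0, 500.0)

    def test_single_point_is_its_own_center(self):
        mc = compute_mean_center(np.array([[7.0, -3.0]]))
        assert (mc.x, mc.y) == (7.0, -3.0)

    def test_mean_center_lies_inside_convex_hull(self, rng):
        xy = rng.normal(0, 800, size=(100, 2))
        mc = compute_mean_center(xy)
        hull = compute_driving_area(xy).hull
        assert hull.buffer(1e-6).contains(Point(mc.x, mc.y))


# ----------------------------------------------------------------------
# Unique destinations: disc-union component counting
# ----------------------------------------------------------------------

def polygon_union_count(xy: np.ndarray, radius_m: float) -> int:
    """Oracle: explicitly dissolve the buffer discs and count polygons."""
    union = shapely.unary_union([Point(p).buffer(radius_m, quad_segs=64) for p in xy])
    return 1 if union.geom_type == "Polygon" else len(union.geoms)


class TestUniqueDestinations:
    def test_single_fix_is_one_destination_at_every_radius(self):
        for r in (100, 250, 500):
            assert count_unique_destinations(np.array([[0.0, 0.0]]), r).n_destinations == 1

    def test_two_fixes_merge_when_discs_overlap(self):
        xy = np.array([[0.0, 0.0], [250 * FT, 0.0]])
        assert count_unique_destinations(xy, 100).n_destinations == 2
        assert count_unique_destinations(xy, 250).n_destinations == 1

    def test_tangent_discs_stay_separate(self):
        xy = np.array([[0.0, 0.0], [200 * FT, 0.0]])   # distance exactly 2r
        assert count_unique_destinations(xy, 100).n_destinations == 2

    @pytest.mark.parametrize("radius_ft", [100, 250, 500])
    def test_counts_equal_polygon_union_oracle(self, radius_ft, rng):
        xy = rng.uniform(0, 2000, size=(100, 2))
        got = count_unique_destinations(xy, radius_ft).n_destinations
        assert got == polygon_union_count(xy, radius_ft * FT)

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_counts_monotone_nonincreasing_in_radius(self, seed):
        xy = np.random.default_rng(seed).uniform(0, 1500, size=(40, 2))
        counts = [count_unique_destinations(xy, r).n_destinations
                  for r in (100, 250, 500)]
        assert counts[0] >= counts[1] >= counts[2] >= 1


# ----------------------------------------------------------------------
# Overlap metrics
# ----------------------------------------------------------------------

def _square(x0, y0, side=1000.0):
    return np.array([[x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]])


class TestOverlap:
    def test_identical_months_give_ratio_one(self):
        areas = [compute_driving_area(_square(0, 0), "d", m)
                 for m in ("m1", "m2", "m3")]
        om = overlap_metrics(areas)
        assert om.ratio == pytest.approx(1.0)

    def test_disjoint_months_give_ratio_zero(self):
        areas = [compute_driving_area(_square(3000 * k, 0), "d", f"m{k}")
                 for k in range(3)]
        om = overlap_metrics(areas)
        assert om.ratio == 0.0

    def test_half_overlapping_translate_matches_analytic_geometry(self):
        a = compute_driving_area(_square(0, 0), "d", "m1")
        b = compute_driving_area(_square(500, 0), "d", "m2")
        om = overlap_metrics([a, b])
        assert om.pairwise_km2[("m1", "m2")] == pytest.approx(0.5)
        assert om.ratio == pytest.approx(0.5 / 1.5)

    def test_degenerate_month_is_skipped(self):
        a = compute_driving_area(_square(0, 0), "d", "m1")
        bad = compute_driving_area(np.array([[0, 0], [1, 1]]), "d", "m2")
        b = compute_driving_area(_square(0, 0), "d", "m3")
        om = overlap_metrics([a, bad, b])
        assert om.periods == ["m1", "m3"] and om.ratio == pytest.approx(1.0)

    def test_pairwise_overlap_bounded_by_smaller_area(self, rng):
        a = compute_driving_area(rng.normal(0, 500, (30, 2)), "d", "m1")
        b = compute_driving_area(rng.normal(200, 400, (30, 2)), "d", "m2")
        om = overlap_metrics([a, b])
        assert om.pairwise_km2[("m1", "m2")] <= min(a.area_km2, b.area_km2) + 1e-12
        assert 0.0 <= om.ratio <= 1.0

    def test_sum_total_mode_uses_summed_monthly_areas(self):
        a = compute_driving_area(_square(0, 0), "d", "m1")
        b = compute_driving_area(_square(500, 0), "d", "m2")
        om = overlap_metrics([a, b], total_mode="sum")
        assert om.total_km2 == pytest.approx(2.0)
        assert om.ratio == pytest.approx(0.5 / 2.0)
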