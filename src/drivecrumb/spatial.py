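"""Spatial driving-profile components.

Everything here works in a driver-local planar frame (meters) produced by
:class:`LocalProjection`, an azimuthal-equidistant projection centred on the
driver's median fix. The profile components are:

* **primary locations** — connected clusters of ignition-on fixes (points
  linked when within the 20-ft aggregation distance, clusters of at least
  three points) that hold at least 10% of the driver's ignition-on
  breadcrumbs; home and work fall out of the data this way.
* **driving areas** — the convex hull of all fixes in a period (week or
  month), the smallest convex polygon containing everywhere the car went.
* **mean centers** — the unweighted centroid of a period's fixes.
* **unique destinations** — the number of merged buffer polygons obtained by
  dissolving discs of 100/250/500 ft around ignition-on fixes; computed as
  connected components of the disc-overlap graph (centers closer than 2r),
  which is equivalent to counting the dissolved polygons.
* **overlap metrics** — month-to-month hull intersections and the ratio of
  the area common to all months over the total (union) area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Point, Polygon

from .config import M_PER_FT

EARTH_RADIUS_M = 6371008.8

__all__ = [
    "LocalProjection",
    "Cluster",
    "PrimaryLocation",
    "DrivingArea",
    "MeanCenter",
    "DestinationCount",
    "OverlapMetrics",
    "cluster_ignition_points",
    "detect_primary_locations",
    "compute_driving_area",
    "compute_mean_center",
    "count_unique_destinations",
    "overlap_metrics",
]


class LocalProjection:
    """Azimuthal-equidistant projection on the mean-radius sphere.

    Distances from the centre are exact; shape distortion stays negligible
    at the city scale these profiles cover (sub-0.5% within ~100 km).
    Forward maps (lat, lon) degrees to (x, y) meters; inverse is its exact
    analytic inverse, so round-trips are limited only by float precision.
    """

    def __init__(self, center_lat: float, center_lon: float):
        self.center_lat = float(center_lat)
        self.center_lon = float(center_lon)
        self._phi0 = math.radians(center_lat)
        self._lam0 = math.radians(center_lon)

    @classmethod
    def for_points(cls, lats: np.ndarray, lons: np.ndarray) -> "LocalProjection":
        """Projection centred on the median point (robust to outliers)."""
        return cls(float(np.median(lats)), float(np.median(lons)))

    def forward(self, lats, lons) -> tuple[np.ndarray, np.ndarray]:
        phi = np.radians(np.asarray(lats, dtype=float))
        lam = np.radians(np.asarray(lons, dtype=float))
        dlam = lam - self._lam0
        sin0, cos0 = math.sin(self._phi0), math.cos(self._phi0)
        cos_c = np.clip(sin0 * np.sin(phi) + cos0 * np.cos(phi) * np.cos(dlam), -1.0, 1.0)
        c = np.arccos(cos_c)
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 0, c / np.sin(c), 1.0)
        x = EARTH_RADIUS_M * k * np.cos(phi) * np.sin(dlam)
        y = EARTH_RADIUS_M * k * (cos0 * np.sin(phi) - sin0 * np.cos(phi) * np.cos(dlam))
        return x, y

    def inverse(self, xs, ys) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(xs, dtype=float)
        y = np.asarray(ys, dtype=float)
        rho = np.hypot(x, y)
        c = rho / EARTH_RADIUS_M
        sin0, cos0 = math.sin(self._phi0), math.cos(self._phi0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sin_phi = np.where(
                rho > 0,
                np.cos(c) * sin0 + y * np.sin(c) * cos0 / np.where(rho > 0, rho, 1.0),
                sin0,
            )
        phi = np.arcsin(np.clip(sin_phi, -1.0, 1.0))
        lam = self._lam0 + np.arctan2(
            x * np.sin(c), rho * cos0 * np.cos(c) - y * sin0 * np.sin(c)
        )
        # rho == 0 maps back to the centre exactly
        lam = np.where(rho > 0, lam, self._lam0)
        return np.degrees(phi), np.degrees(lam)


def project_local(lats, lons, projection: LocalProjection | None = None):
    """Project coordinates to a local planar frame; returns (x, y, projection)."""
    if projection is None:
        projection = LocalProjection.for_points(np.asarray(lats), np.asarray(lons))
    x, y = projection.forward(lats, lons)
    return x, y, projection


# ----------------------------------------------------------------------
# Clustering and primary locations
# ----------------------------------------------------------------------

@dataclass
class Cluster:
    """Connected component of ignition-on fixes within the link distance."""

    indices: np.ndarray            # indices into the input point array
    polygon: Polygon               # convex hull of members (buffered if degenerate)
    centroid_xy: tuple[float, float]

    @property
    def size(self) -> int:
        return len(self.indices)


@dataclass
class PrimaryLocation:
    centroid_lat: float
    centroid_lon: float
    centroid_xy: tuple[float, float]
    cluster_polygon: Polygon
    n_ignition_on: int
    share: float


def _components(xy: np.ndarray, link: float, strict: bool = False) -> np.ndarray:
    """Component label per point for the 'within link distance' graph.

    ``strict=False`` links pairs at distance <= link (clustering);
    ``strict=True`` requires distance < link (disc-overlap counting, where
    tangent discs do not merge).
    """
    n = len(xy)
    if n == 0:
        return np.empty(0, dtype=int)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=link, output_type="ndarray")
    if strict and len(pairs):
        d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
        pairs = pairs[d < link]
    if len(pairs) == 0:
        return np.arange(n)
    data = np.ones(len(pairs))
    graph = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    return labels


def _hull_polygon(points: np.ndarray) -> Polygon:
    hull = MultiPoint([tuple(p) for p in points]).convex_hull
    if hull.area == 0.0:  # single point or collinear members
        hull = hull.buffer(1.0)
    return hull


def cluster_ignition_points(
    xy: np.ndarray,
    link_distance_m: float = 20.0 * M_PER_FT,
    min_size: int = 3,
) -> list[Cluster]:
    """Aggregate ignition-on fixes into clusters.

    Clusters are connected components of the graph joining points within
    ``link_distance_m``; components smaller than ``min_size`` are dropped.
    Output order (by size descending, then centroid) does not depend on
    input point order.
    """
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    labels = _components(xy, link_distance_m, strict=False)
    clusters: list[Cluster] = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < min_size:
            continue
        pts = xy[idx]
        cen = (float(pts[:, 0].mean()), float(pts[:, 1].mean()))
        clusters.append(Cluster(indices=idx, polygon=_hull_polygon(pts), centroid_xy=cen))
    clusters.sort(key=lambda c: (-c.size, c.centroid_xy))
    return clusters


def detect_primary_locations(
    clusters: list[Cluster],
    total_ignition_on: int,
    share_threshold: float = 0.10,
    projection: LocalProjection | None = None,
) -> list[PrimaryLocation]:
    """Clusters holding at least ``share_threshold`` of all ignition-on fixes.

    The share denominator is the driver's total ignition-on count over the
    whole analysis window, not just clustered points. Zero, one, or several
    primaries are all legitimate outcomes.
    """
    if total_ignition_on <= 0:
        return []
    out = []
    for cl in clusters:
        share = cl.size / total_ignition_on
        if share >= share_threshold:
            cx, cy = cl.centroid_xy
            if projection is not None:
                lat, lon = projection.inverse(cx, cy)
                lat, lon = float(lat), float(lon)
            else:
                lat = lon = float("nan")
            out.append(
                PrimaryLocation(
                    centroid_lat=lat, centroid_lon=lon, centroid_xy=(cx, cy),
                    cluster_polygon=cl.polygon, n_ignition_on=cl.size, share=share,
                )
            )
    return out


# ----------------------------------------------------------------------
# Driving areas, mean centers, overlap
# ----------------------------------------------------------------------

@dataclass
class DrivingArea:
    driver_id: str
    period: str
    hull: Polygon | None
    area_km2: float
    degenerate: bool = False


@dataclass
class MeanCenter:
    driver_id: str
    period: str
    x: float
    y: float
    lat: float = float("nan")
    lon: float = float("nan")


@dataclass
class DestinationCount:
    driver_id: str
    period: str
    radius_ft: float
    n_destinations: int


@dataclass
class OverlapMetrics:
    driver_id: str
    periods: list[str]
    pairwise_km2: dict[tuple[str, str], float] = field(default_factory=dict)
    common_all_km2: float = 0.0
    total_km2: float = 0.0
    ratio: float = float("nan")


def compute_driving_area(xy: np.ndarray, driver_id: str = "", period: str = "") -> DrivingArea:
    """Convex hull of a driver-period's fixes, area in km^2.

    Fewer than three points, or collinear points, yield a degenerate
    zero-area record that overlap metrics skip.
    """
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    if len(xy) < 3:
        return DrivingArea(driver_id, period, None, 0.0, degenerate=True)
    hull = MultiPoint([tuple(p) for p in xy]).convex_hull
    if hull.area == 0.0:
        return DrivingArea(driver_id, period, None, 0.0, degenerate=True)
    return DrivingArea(driver_id, period, hull, hull.area / 1e6)


def compute_mean_center(
    xy: np.ndarray,
    driver_id: str = "",
    period: str = "",
    projection: LocalProjection | None = None,
) -> MeanCenter:
    """Unweighted arithmetic mean of fix positions in the projected plane."""
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    if len(xy) == 0:
        raise ValueError("mean center of zero points")
    mx, my = float(xy[:, 0].mean()), float(xy[:, 1].mean())
    mc = MeanCenter(driver_id, period, mx, my)
    if projection is not None:
        lat, lon = projection.inverse(mx, my)
        mc.lat, mc.lon = float(lat), float(lon)
    return mc


def count_unique_destinations(
    xy: np.ndarray,
    radius_ft: float,
    driver_id: str = "",
    period: str = "",
) -> DestinationCount:
    """Number of dissolved buffer polygons around ignition-on fixes.

    Discs of radius r merge exactly when their centers are closer than 2r,
    so the dissolved-polygon count equals the number of connected components
    of that graph; tangent discs (distance exactly 2r) stay separate.
    """
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    if len(xy) == 0:
        return DestinationCount(driver_id, period, radius_ft, 0)
    labels = _components(xy, 2.0 * radius_ft * M_PER_FT, strict=True)
    return DestinationCount(driver_id, period, radius_ft, int(labels.max()) + 1)


def overlap_metrics(
    areas: list[DrivingArea],
    total_mode: str = "union",
) -> OverlapMetrics:
    """Consecutive-period hull intersections and common/total area ratio.

    ``common`` is the intersection of every non-degenerate period hull;
    ``total`` is their union (or, with ``total_mode='sum'``, the sum of the
    period areas). Degenerate periods are skipped.
    """
    valid = [a for a in areas if not a.degenerate and a.hull is not None]
    om = OverlapMetrics(
        driver_id=valid[0].driver_id if valid else "",
        periods=[a.period for a in valid],
    )
    if not valid:
        return om
    for a, b in zip(valid, valid[1:]):
        om.pairwise_km2[(a.period, b.period)] = a.hull.intersection(b.hull).area / 1e6
    common = valid[0].hull
    for a in valid[1:]:
        common = common.intersection(a.hull)
    om.common_all_km2 = common.area / 1e6
    if total_mode == "sum":
        om.total_km2 = sum(a.area_km2 for a in valid)
    else:
        om.total_km2 = shapely.unary_union([a.hull for a in valid]).area / 1e6
    om.ratio = om.common_all_km2 / om.total_km2 if om.total_km2 > 0 else float("nan")
    return om


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in meters on the mean-radius sphere."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_M * math.asin(math.sqrt(a))
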