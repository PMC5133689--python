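"""Nearest-street annotation of breadcrumbs.

Each fix is snapped to the closest street centerline so its road context
(name, Census Feature Class Code, and the segment's average speed, which
serves as a posted-speed-limit proxy) can feed speeding detection. The
match mirrors a GIS "near" join: ``near_fid`` is the id of the closest
segment and ``near_dist`` the planar distance to it in meters. Fixes
farther than a configurable snap cap (default 100 m) keep their match but
are flagged off-network so garage/glitch fixes do not inherit road
attributes silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely import STRtree
from shapely.geometry import LineString

from .spatial import LocalProjection

__all__ = ["StreetSegment", "SegmentIndex", "RoadMatch", "load_segments_geojson",
           "build_segment_index", "nearest_segment", "annotate_breadcrumbs"]


@dataclass
class StreetSegment:
    """One street centerline piece with its descriptive attributes."""

    segment_id: int
    coords: np.ndarray           # (n, 2) planar meters
    name: str = ""
    cfcc: str = ""
    avg_speed: float = 0.0       # mph, proxy for the posted limit

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        if len(self.coords) < 2:
            raise ValueError("segment polyline needs at least 2 points")
        if self.avg_speed <= 0:
            raise ValueError("avg_speed must be positive")


@dataclass
class RoadMatch:
    near_fid: int
    near_dist: float
    name: str
    cfcc: str
    avg_speed: float
    off_network: bool = False


class SegmentIndex:
    """Exact nearest-segment queries backed by an STR packed R-tree."""

    def __init__(self, segments: list[StreetSegment]):
        if not segments:
            raise ValueError("empty segment set")
        # sort by id so tree order (and tie handling) is reproducible
        self.segments = sorted(segments, key=lambda s: s.segment_id)
        self._geoms = [LineString(s.coords) for s in self.segments]
        self._tree = STRtree(self._geoms)
        self._ids = np.array([s.segment_id for s in self.segments])

    def __len__(self) -> int:
        return len(self.segments)

    def nearest(self, x: float, y: float) -> RoadMatch:
        """Closest segment to one point; distance ties go to the lowest id."""
        pt = shapely.points(x, y)
        idx = self._tree.query_nearest(pt, all_matches=True)
        best = int(min(idx, key=lambda i: self._ids[i]))
        seg = self.segments[best]
        return RoadMatch(
            near_fid=seg.segment_id,
            near_dist=float(shapely.distance(pt, self._geoms[best])),
            name=seg.name, cfcc=seg.cfcc, avg_speed=seg.avg_speed,
        )

    def nearest_many(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised nearest query: (segment_index_array, distance_array)."""
        pts = shapely.points(np.asarray(xy, dtype=float))
        inp, tr = self._tree.query_nearest(pts, all_matches=True)
        d = shapely.distance(pts[inp], np.asarray(self._geoms, dtype=object)[tr])
        # lowest segment id among equidistant matches, per input point
        order = np.lexsort((self._ids[tr], inp))
        inp, tr, d = inp[order], tr[order], d[order]
        first = np.ones(len(inp), dtype=bool)
        first[1:] = inp[1:] != inp[:-1]
        out_idx = np.full(len(pts), -1, dtype=int)
        out_d = np.full(len(pts), np.nan)
        out_idx[inp[first]] = tr[first]
        out_d[inp[first]] = d[first]
        return out_idx, out_d


def build_segment_index(segments: list[StreetSegment]) -> SegmentIndex:
    """Build the spatial index used by `nearest_segment` and `annotate_breadcrumbs`."""
    return SegmentIndex(segments)


def nearest_segment(point: tuple[float, float], index: SegmentIndex) -> RoadMatch:
    return index.nearest(point[0], point[1])


def load_segments_geojson(
    path: str | Path | dict,
    projection: LocalProjection | None = None,
) -> list[StreetSegment]:
    """Read a street table from GeoJSON LineString features.

    Expected properties: ``segment_id``, ``name``, ``cfcc``, ``avg_speed``.
    Coordinates are (lon, lat) when ``projection`` is given (and are
    projected), otherwise already-planar (x, y) meters.
    """
    if isinstance(path, dict):
        gj = path
    else:
        gj = json.loads(Path(path).read_text())
    segs = []
    for feat in gj["features"]:
        geom = feat["geometry"]
        if geom["type"] != "LineString":
            raise ValueError(f"unsupported geometry type {geom['type']}")
        coords = np.asarray(geom["coordinates"], dtype=float)
        if projection is not None:
            x, y = projection.forward(coords[:, 1], coords[:, 0])
            coords = np.column_stack([x, y])
        p = feat["properties"]
        segs.append(
            StreetSegment(
                segment_id=int(p["segment_id"]), coords=coords,
                name=str(p.get("name", "")), cfcc=str(p.get("cfcc", "")),
                avg_speed=float(p["avg_speed"]),
            )
        )
    return segs


def segments_to_geojson(segments: list[StreetSegment], projection: LocalProjection) -> dict:
    """Serialise segments back to lon/lat GeoJSON."""
    feats = []
    for s in segments:
        lat, lon = projection.inverse(s.coords[:, 0], s.coords[:, 1])
        feats.append({
            "type": "Feature",
            "properties": {"segment_id": s.segment_id, "name": s.name,
                           "cfcc": s.cfcc, "avg_speed": s.avg_speed},
            "geometry": {"type": "LineString",
                         "coordinates": [[float(o), float(a)] for a, o in zip(lat, lon)]},
        })
    return {"type": "FeatureCollection", "features": feats}


def annotate_breadcrumbs(
    crumbs: pd.DataFrame,
    index: SegmentIndex,
    x_col: str = "x",
    y_col: str = "y",
    max_snap_m: float = 100.0,
) -> pd.DataFrame:
    """Attach nearest-road attributes to every fix.

    Adds ``near_fid``, ``near_dist``, ``road_name``, ``cfcc``,
    ``road_avg_speed`` and ``off_network`` columns; rows with non-finite
    coordinates get a null match.
    """
    out = crumbs.copy()
    xy = out[[x_col, y_col]].to_numpy(dtype=float)
    ok = np.isfinite(xy).all(axis=1)
    seg_idx = np.full(len(out), -1, dtype=int)
    dist = np.full(len(out), np.nan)
    if ok.any():
        si, d = index.nearest_many(xy[ok])
        seg_idx[np.flatnonzero(ok)] = si
        dist[np.flatnonzero(ok)] = d
    ids = np.where(seg_idx >= 0, index._ids[np.clip(seg_idx, 0, None)], -1)
    names = np.array([s.name for s in index.segments], dtype=object)
    cfccs = np.array([s.cfcc for s in index.segments], dtype=object)
    speeds = np.array([s.avg_speed for s in index.segments])
    valid = seg_idx >= 0
    out["near_fid"] = np.where(valid, ids, -1)
    out["near_dist"] = dist
    out["road_name"] = np.where(valid, names[np.clip(seg_idx, 0, None)], "")
    out["cfcc"] = np.where(valid, cfccs[np.clip(seg_idx, 0, None)], "")
    out["road_avg_speed"] = np.where(valid, speeds[np.clip(seg_idx, 0, None)], np.nan)
    out["off_network"] = valid & (dist > max_snap_m)
    return out
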