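"""Pipeline configuration.

Every numeric threshold used by the pipeline lives in :class:`ProfileConfig`
so a run is fully described by one flat config file plus a seed. Defaults
are the study values: 30-s breadcrumb sampling, 3-h idle pings, 20-ft
aggregation distance with 3-point minimum clusters and a 10% ignition-on
share for primary locations, destination radii of 100/250/500 ft, a 6-mph
overspeeding margin, and 8 / 10 mph-per-second braking / acceleration
thresholds.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

FT_PER_M = 3.280839895013123
M_PER_FT = 0.3048
MI_PER_KM = 0.621371192237334

#: Standard continental-US envelope (lat_min, lat_max, lon_min, lon_max).
CONUS_BBOX = (24.5, 49.5, -125.0, -66.9)

#: Interior of the (simplified) Central time zone used as the fast path for
#: time-zone assignment; points outside fall back to polygon lookup.
CENTRAL_FAST_BBOX = (26.0, 49.0, -101.0, -87.0)


@dataclass
class ProfileConfig:
    """Flat bag of pipeline parameters with study defaults."""

    sampling_interval_s: float = 30.0
    idle_ping_interval_h: float = 3.0

    # spatial profile
    aggregate_distance_ft: float = 20.0
    min_cluster_size: int = 3
    primary_share: float = 0.10
    destination_radii_ft: tuple[float, ...] = (100.0, 250.0, 500.0)
    period: str = "month"                     # "month" or "week"
    overlap_total: str = "union"              # "union" or "sum"

    # behavior
    overspeed_margin_mph: float = 6.0
    braking_threshold_mphps: float = 8.0
    accel_threshold_mphps: float = 10.0
    night_definition: str = "strict"          # "strict" (below civil) or "not_day"

    # cleaning
    bbox_lat_min: float = CONUS_BBOX[0]
    bbox_lat_max: float = CONUS_BBOX[1]
    bbox_lon_min: float = CONUS_BBOX[2]
    bbox_lon_max: float = CONUS_BBOX[3]
    defect_window_days: float = 7.0
    defect_zero_fraction: float = 0.5
    defect_min_crumbs: int = 50
    abandoned_gap_s: float = 60.0
    abandoned_max_intervening: int = 1

    # time zones
    tz_fast_bbox_lat_min: float = CENTRAL_FAST_BBOX[0]
    tz_fast_bbox_lat_max: float = CENTRAL_FAST_BBOX[1]
    tz_fast_bbox_lon_min: float = CENTRAL_FAST_BBOX[2]
    tz_fast_bbox_lon_max: float = CENTRAL_FAST_BBOX[3]
    tz_fast_zone: str = "America/Chicago"
    tz_polygons: str = ""                     # path to GeoJSON; "" = packaged set

    # road matching
    max_snap_m: float = 100.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        radii = tuple(self.destination_radii_ft)
        if any(r <= 0 for r in radii) or list(radii) != sorted(set(radii)):
            raise ValueError("destination_radii_ft must be positive and strictly increasing")
        for name in (
            "sampling_interval_s", "idle_ping_interval_h", "aggregate_distance_ft",
            "min_cluster_size", "primary_share", "overspeed_margin_mph",
            "braking_threshold_mphps", "accel_threshold_mphps", "max_snap_m",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.period not in ("month", "week"):
            raise ValueError("period must be 'month' or 'week'")
        if self.night_definition not in ("strict", "not_day"):
            raise ValueError("night_definition must be 'strict' or 'not_day'")
        if self.overlap_total not in ("union", "sum"):
            raise ValueError("overlap_total must be 'union' or 'sum'")

    @property
    def conus_bbox(self) -> tuple[float, float, float, float]:
        return (self.bbox_lat_min, self.bbox_lat_max, self.bbox_lon_min, self.bbox_lon_max)

    @property
    def tz_fast_bbox(self) -> tuple[float, float, float, float]:
        return (
            self.tz_fast_bbox_lat_min, self.tz_fast_bbox_lat_max,
            self.tz_fast_bbox_lon_min, self.tz_fast_bbox_lon_max,
        )

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["destination_radii_ft"] = list(self.destination_radii_ft)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProfileConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "destination_radii_ft" in d:
            d = dict(d, destination_radii_ft=tuple(d["destination_radii_ft"]))
        return cls(**d)

    def to_toml(self, path: str | Path) -> None:
        lines = []
        for key, val in self.to_dict().items():
            if isinstance(val, str):
                lines.append(f'{key} = "{val}"')
            elif isinstance(val, bool):
                lines.append(f"{key} = {str(val).lower()}")
            elif isinstance(val, list):
                lines.append(f"{key} = [{', '.join(repr(float(v)) for v in val)}]")
            else:
                lines.append(f"{key} = {val!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_toml(cls, path: str | Path) -> "ProfileConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))


def feet_to_meters(ft: float) -> float:
    return ft * M_PER_FT
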