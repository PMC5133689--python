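"""Summary tables over assembled driver profiles."""

from __future__ import annotations

import pandas as pd

__all__ = ["report_tables"]


def report_tables(profiles_frame: pd.DataFrame,
                  overlaps: dict | None = None) -> dict[str, pd.DataFrame]:
    """Per-driver-per-period summary tables.

    Returns tables keyed ``destinations`` (unique-destination counts by
    buffer radius), ``light`` (day/night/dawn/dusk trip counts),
    ``alerts`` (adverse-event counts) and, when overlap metrics are given,
    ``overlap`` (common/total driving-area ratios). Driver-periods with no
    trips appear as explicit zero/gap rows, never as missing rows.
    """
    pf = profiles_frame
    dest_cols = [c for c in pf.columns if c.startswith("destinations_")]
    tables = {
        "destinations": pf[["driver_id", "month"] + dest_cols].copy(),
        "light": pf[["driver_id", "month", "n_trips", "n_trips_day",
                     "n_trips_night", "n_trips_dawn", "n_trips_dusk"]].copy(),
        "alerts": pf[["driver_id", "month", "n_overspeeding", "n_hard_braking",
                      "n_sudden_accel", "trips_w_overspeeding",
                      "trips_w_hard_braking", "trips_w_sudden_accel"]].copy(),
    }
    if overlaps:
        tables["overlap"] = pd.DataFrame([
            {"driver_id": d, "common_all_km2": m.common_all_km2,
             "total_km2": m.total_km2, "ratio": m.ratio}
            for d, m in overlaps.items()
        ])
    return tables
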