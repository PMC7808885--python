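"""Zone assignment and daily occupancy (hot-spot) summaries.

Interactions are localized at zone granularity: the pings of both
participants during the interaction window vote for the zone, majority wins
(ties go to the earliest-pinged zone). Interactions with no pings land in an
explicit ``unassigned`` bucket so minute totals always balance.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthgen import ZoneMap

#: Sentinel zone label for interactions with no usable pings.
UNASSIGNED = "unassigned"


def _badge_ping_index(
    beacon: pd.DataFrame,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if beacon.empty:
        return out
    b = beacon.sort_values("timestamp", kind="stable")
    for badge, g in b.groupby("badge_id", sort=False):
        ts = g["timestamp"].values.astype("datetime64[ns]").astype(np.int64)
        out[badge] = (ts, g["beacon_id"].values)
    return out


def _majority_zone(
    ts: np.ndarray, zones: np.ndarray
) -> str:
    """Zone with most pings; ties broken by earliest ping time of the zone."""
    counts: dict[str, int] = {}
    first: dict[str, int] = {}
    for t, z in zip(ts, zones):
        counts[z] = counts.get(z, 0) + 1
        if z not in first:
            first[z] = int(t)
    best = max(counts.values())
    tied = [z for z, c in counts.items() if c == best]
    return min(tied, key=lambda z: first[z])


def assign_zones(
    interactions: pd.DataFrame,
    beacon: pd.DataFrame,
    zone_map: ZoneMap,
) -> pd.DataFrame:
    """Add a ``zone_id`` column by majority vote of both participants' pings.

    Pings referencing beacons outside the map are ignored (one warning with
    the total count). Interactions without any valid ping in ``[start, end)``
    get :data:`UNASSIGNED`.
    """
    out = interactions.copy()
    if out.empty:
        out["zone_id"] = pd.Series(dtype=object)
        return out
    b2z = zone_map.beacon_to_zone()
    index = _badge_ping_index(beacon)
    start_ns = out["start"].values.astype("datetime64[ns]").astype(np.int64)
    end_ns = out["end"].values.astype("datetime64[ns]").astype(np.int64)
    zone_col: list[str] = []
    unknown_pings = 0
    a_col = out["badge_a"].values
    b_col = out["badge_b"].values
    for k in range(len(out)):
        ts_all: list[np.ndarray] = []
        zs_all: list[np.ndarray] = []
        for badge in (a_col[k], b_col[k]):
            if badge not in index:
                continue
            ts, beacons = index[badge]
            i0 = np.searchsorted(ts, start_ns[k], side="left")
            i1 = np.searchsorted(ts, end_ns[k], side="left")
            if i1 > i0:
                ts_all.append(ts[i0:i1])
                zs_all.append(beacons[i0:i1])
        if not ts_all:
            zone_col.append(UNASSIGNED)
            continue
        ts_cat = np.concatenate(ts_all)
        zs_cat = np.concatenate(zs_all)
        zones = np.array([b2z.get(b) for b in zs_cat], dtype=object)
        valid = zones != None  # noqa: E711  (elementwise on object array)
        unknown_pings += int((~valid).sum())
        if not valid.any():
            zone_col.append(UNASSIGNED)
            continue
        zone_col.append(_majority_zone(ts_cat[valid], zones[valid]))
    if unknown_pings:
        warnings.warn(
            f"ignored {unknown_pings} ping(s) referencing unknown beacons",
            stacklevel=2,
        )
    out["zone_id"] = zone_col
    return out


def assign_zone(
    interaction: pd.Series, beacon: pd.DataFrame, zone_map: ZoneMap
) -> str:
    """Zone of a single interaction (see :func:`assign_zones`)."""
    df = assign_zones(interaction.to_frame().T, beacon, zone_map)
    return df["zone_id"].iloc[0]


@dataclass
class ZoneOccupancy:
    """Cumulative active interaction pair-minutes per zone for one day."""

    day: str
    zone_minutes: pd.Series
    unassigned_min: float

    @property
    def total_min(self) -> float:
        return float(self.zone_minutes.sum()) + self.unassigned_min


def daily_occupancy(
    active: pd.DataFrame,
    zone_map: ZoneMap,
    day: str,
    day_start_offset_min: float = 0.0,
) -> ZoneOccupancy:
    """Sum active interaction durations per zone for one calendar day.

    An interaction belongs to the day its start falls in (after shifting the
    day boundary by ``day_start_offset_min``); durations are not split.
    """
    zones = zone_map.zone_ids()
    minutes = pd.Series(0.0, index=pd.Index(zones, name="zone_id"))
    unassigned = 0.0
    if not active.empty:
        shifted = active["start"] - pd.Timedelta(minutes=day_start_offset_min)
        mask = shifted.dt.strftime("%Y-%m-%d") == day
        sel = active[mask]
        for zid, dur in zip(sel.get("zone_id", pd.Series(dtype=object)),
                            sel["duration_min"]):
            if zid in minutes.index:
                minutes[zid] += dur
            else:
                unassigned += dur
    return ZoneOccupancy(day=day, zone_minutes=minutes, unassigned_min=unassigned)


def hotspots(occupancy: ZoneOccupancy, k: int) -> list[tuple[str, float]]:
    """Top-k zones by minutes, descending; ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    items = sorted(
        occupancy.zone_minutes.items(), key=lambda kv: (-kv[1], kv[0])
    )
    return items[: min(k, len(items))]
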