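"""CSV readers and writers for every pipeline artifact.

All files are comma-separated UTF-8 with a header row; timestamps are
ISO 8601 with an explicit UTC offset. Readers tolerate malformed rows by
dropping and counting them (a warning reports the count), so a single bad
sensor line never kills a run.
"""
from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import pandas as pd

from ._util import format_times, parse_times
from .synthgen import (
    EventStreams,
    Member,
    Roster,
    ShiftSchedule,
    ShiftTemplate,
    Zone,
    ZoneMap,
)

STREAM_FILES = {"ir": "ir.csv", "accel": "accel.csv", "beacon": "beacon.csv"}


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_roster(roster: Roster, path: Path) -> None:
    roster.to_frame().to_csv(path, index=False)


def write_zone_map(zone_map: ZoneMap, path: Path) -> None:
    zone_map.to_frame().to_csv(path, index=False)


def write_schedule(schedule: ShiftSchedule, path: Path) -> None:
    df = schedule.to_frame()
    out = pd.DataFrame(
        {
            "badge_id": df["badge_id"],
            "start_iso": format_times(df["start"]),
            "end_iso": format_times(df["end"]),
        }
    )
    out.to_csv(path, index=False)


def write_streams(streams: EventStreams, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ir = pd.DataFrame(
        {
            "timestamp_iso": format_times(streams.ir["timestamp"])
            if not streams.ir.empty else pd.Series(dtype=str),
            "observer_badge": streams.ir.get("observer_badge", pd.Series(dtype=str)),
            "observed_badge": streams.ir.get("observed_badge", pd.Series(dtype=str)),
        }
    )
    ir.to_csv(out_dir / "ir.csv", index=False)
    accel = pd.DataFrame(
        {
            "timestamp_iso": format_times(streams.accel["timestamp"])
            if not streams.accel.empty else pd.Series(dtype=str),
            "badge_id": streams.accel.get("badge_id", pd.Series(dtype=str)),
            "motion_hz": streams.accel.get("motion_hz", pd.Series(dtype=float)),
        }
    )
    accel.to_csv(out_dir / "accel.csv", index=False)
    beacon = pd.DataFrame(
        {
            "timestamp_iso": format_times(streams.beacon["timestamp"])
            if not streams.beacon.empty else pd.Series(dtype=str),
            "badge_id": streams.beacon.get("badge_id", pd.Series(dtype=str)),
            "beacon_id": streams.beacon.get("beacon_id", pd.Series(dtype=str)),
        }
    )
    beacon.to_csv(out_dir / "beacon.csv", index=False)


INTERACTION_COLUMNS = [
    "pair_a", "pair_b", "start_iso", "end_iso", "duration_min",
    "motion_a_hz", "motion_b_hz", "active", "zone_id",
]


def write_interactions(episodes: pd.DataFrame, active: pd.Series, path: Path) -> None:
    """Episode listing with the active flag and zone (if assigned)."""
    if episodes.empty:
        pd.DataFrame(columns=INTERACTION_COLUMNS).to_csv(path, index=False)
        return
    out = pd.DataFrame(
        {
            "pair_a": episodes["badge_a"],
            "pair_b": episodes["badge_b"],
            "start_iso": format_times(episodes["start"]),
            "end_iso": format_times(episodes["end"]),
            "duration_min": episodes["duration_min"],
            "motion_a_hz": episodes["motion_a_hz"],
            "motion_b_hz": episodes["motion_b_hz"],
            "active": active.astype(int).values,
            "zone_id": episodes.get("zone_id", pd.Series("", index=episodes.index)),
        }
    )
    out.to_csv(path, index=False)


def write_occupancy(occupancy, zone_map: ZoneMap, path: Path) -> None:
    cats = zone_map.zone_category()
    df = pd.DataFrame(
        {
            "zone_id": occupancy.zone_minutes.index,
            "category": [cats[z] for z in occupancy.zone_minutes.index],
            "minutes": occupancy.zone_minutes.values,
        }
    )
    df.loc[len(df)] = ["unassigned", "", occupancy.unassigned_min]
    df.to_csv(path, index=False)


def write_contact_matrix(cm, path: Path) -> None:
    cm.matrix.to_csv(path, index=True, index_label="badge_id")


def write_heatmap(pm, path: Path) -> None:
    """9 × 9 display matrix (log10 minutes + 1); N/A cells are left empty."""
    pm.display.to_csv(path, index=True, index_label="profession")


def write_edges_tsv(g, path: Path) -> None:
    rows = sorted((a, b, w) for (a, b), w in g.edges.items())
    pd.DataFrame(rows, columns=["source", "target", "minutes"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_csv_checked(path: Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing input file: {path}")
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {missing}")
    return df


def read_roster(path: Path) -> Roster:
    df = _read_csv_checked(path, ["badge_id", "profession"])
    return Roster(tuple(Member(r.badge_id, r.profession) for r in df.itertuples()))


def read_zone_map(path: Path) -> ZoneMap:
    df = _read_csv_checked(path, ["beacon_id", "zone_id", "category"])
    zones = []
    for (zid, cat), g in df.groupby(["zone_id", "category"], sort=True):
        zones.append(Zone(zid, cat, tuple(g["beacon_id"])))
    return ZoneMap(tuple(zones))


def read_schedule(path: Path, template: ShiftTemplate | None = None) -> ShiftSchedule:
    df = _read_csv_checked(path, ["badge_id", "start_iso", "end_iso"])
    intervals: dict[str, list] = {}
    starts = parse_times(df["start_iso"])
    ends = parse_times(df["end_iso"])
    for badge, s, e in zip(df["badge_id"], starts, ends):
        intervals.setdefault(badge, []).append((s, e))
    return ShiftSchedule(intervals, template=template or ShiftTemplate())


def read_streams(dir_path: Path) -> EventStreams:
    """Parse the three raw stream CSVs from a directory.

    Records are timestamp-sorted per stream; rows with unparseable fields
    are dropped, counted in ``streams.malformed`` and reported with a
    warning.
    """
    dir_path = Path(dir_path)
    malformed: dict[str, int] = {}

    ir_raw = _read_csv_checked(
        dir_path / STREAM_FILES["ir"],
        ["timestamp_iso", "observer_badge", "observed_badge"],
    )
    ir = pd.DataFrame(
        {
            "timestamp": parse_times(ir_raw["timestamp_iso"]),
            "observer_badge": ir_raw["observer_badge"],
            "observed_badge": ir_raw["observed_badge"],
        }
    )
    bad = ir["timestamp"].isna() | ir["observer_badge"].isna() | ir["observed_badge"].isna()
    malformed["ir"] = int(bad.sum())
    ir = ir[~bad].sort_values(
        ["timestamp", "observer_badge"], kind="stable"
    ).reset_index(drop=True)

    acc_raw = _read_csv_checked(
        dir_path / STREAM_FILES["accel"], ["timestamp_iso", "badge_id", "motion_hz"]
    )
    accel = pd.DataFrame(
        {
            "timestamp": parse_times(acc_raw["timestamp_iso"]),
            "badge_id": acc_raw["badge_id"],
            "motion_hz": pd.to_numeric(acc_raw["motion_hz"], errors="coerce"),
        }
    )
    bad = (
        accel["timestamp"].isna()
        | accel["badge_id"].isna()
        | accel["motion_hz"].isna()
        | (accel["motion_hz"] < 0)
    )
    malformed["accel"] = int(bad.sum())
    accel = accel[~bad].sort_values(
        ["timestamp", "badge_id"], kind="stable"
    ).reset_index(drop=True)

    bc_raw = _read_csv_checked(
        dir_path / STREAM_FILES["beacon"], ["timestamp_iso", "badge_id", "beacon_id"]
    )
    beacon = pd.DataFrame(
        {
            "timestamp": parse_times(bc_raw["timestamp_iso"]),
            "badge_id": bc_raw["badge_id"],
            "beacon_id": bc_raw["beacon_id"],
        }
    )
    bad = beacon["timestamp"].isna() | beacon["badge_id"].isna() | beacon["beacon_id"].isna()
    malformed["beacon"] = int(bad.sum())
    beacon = beacon[~bad].sort_values(
        ["timestamp", "badge_id"], kind="stable"
    ).reset_index(drop=True)

    total_bad = sum(malformed.values())
    if total_bad:
        warnings.warn(f"dropped {total_bad} malformed stream row(s)", stacklevel=2)
    return EventStreams(ir=ir, accel=accel, beacon=beacon, malformed=malformed)


def read_streams_beacon_only(path: Path) -> pd.DataFrame:
    """Read a standalone beacon ping CSV (for the map subcommand)."""
    raw = _read_csv_checked(path, ["timestamp_iso", "badge_id", "beacon_id"])
    beacon = pd.DataFrame(
        {
            "timestamp": parse_times(raw["timestamp_iso"]),
            "badge_id": raw["badge_id"],
            "beacon_id": raw["beacon_id"],
        }
    )
    bad = beacon.isna().any(axis=1)
    if bad.any():
        warnings.warn(f"dropped {int(bad.sum())} malformed beacon row(s)", stacklevel=2)
    return beacon[~bad].sort_values(
        ["timestamp", "badge_id"], kind="stable"
    ).reset_index(drop=True)


def read_interactions(path: Path) -> pd.DataFrame:
    """Read an interactions listing back into the episode frame schema."""
    df = _read_csv_checked(
        path,
        ["pair_a", "pair_b", "start_iso", "end_iso", "duration_min",
         "motion_a_hz", "motion_b_hz", "active"],
    )
    out = pd.DataFrame(
        {
            "badge_a": df["pair_a"],
            "badge_b": df["pair_b"],
            "start": parse_times(df["start_iso"]),
            "end": parse_times(df["end_iso"]),
            "duration_min": pd.to_numeric(df["duration_min"], errors="coerce"),
            "motion_a_hz": pd.to_numeric(df["motion_a_hz"], errors="coerce"),
            "motion_b_hz": pd.to_numeric(df["motion_b_hz"], errors="coerce"),
            "active": pd.to_numeric(df["active"], errors="coerce").astype("Int64"),
        }
    )
    if "zone_id" in df.columns:
        out["zone_id"] = df["zone_id"].fillna("")
    bad = out["start"].isna() | out["duration_min"].isna() | out["active"].isna()
    if bad.any():
        warnings.warn(f"dropped {int(bad.sum())} malformed interaction row(s)",
                      stacklevel=2)
        out = out[~bad]
    out["active"] = out["active"].astype(bool)
    return out.reset_index(drop=True)


def file_digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
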