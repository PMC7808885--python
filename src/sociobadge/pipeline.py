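"""End-to-end orchestration: simulate → detect → map → network.

Every run writes a machine-readable manifest (config snapshot, input
digests, per-stage record counts, warnings) next to its outputs; a stage
failure aborts the run, names the stage, and removes partial outputs.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as sio
from .config import PipelineConfig
from .detect import (
    active_mask,
    attach_motion,
    classify_active,
    intensity_series,
    segment_episodes,
)
from .network import (
    centrality_report,
    contact_matrix,
    core_periphery_fit,
    export_sociogram_graphml,
    profession_heatmap,
    threshold_graph,
)
from .spatial import assign_zones, daily_occupancy
from .synthgen import (
    MixingModel,
    ShiftTemplate,
    make_roster,
    make_schedule,
    make_zone_map,
    simulate_streams,
)

log = logging.getLogger("sociobadge")


@dataclass
class RunManifest:
    """Audit record of one pipeline run."""

    config: dict
    tool_version: str
    input_digests: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    generated_at: str = ""

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("[%s] starting", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # re-raise with the stage name attached
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(
    config: PipelineConfig,
    out_dir: Path,
    in_dir: Path | None = None,
) -> RunManifest:
    """Execute the full pipeline and write every artifact under ``out_dir``.

    With ``in_dir`` unset, the simulate stage generates the six raw CSVs
    into ``out_dir`` first; otherwise the raw files are read from
    ``in_dir``. On any stage failure the partially written outputs of this
    run are removed before the error propagates.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest = RunManifest(config=config.to_dict(), tool_version=__version__)
    manifest.generated_at = pd.Timestamp.now(tz="UTC").isoformat()

    def track(path: Path) -> Path:
        written.append(Path(path))
        return Path(path)

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            _run_stages(config, out_dir, in_dir, manifest, track)
        manifest.warnings = sorted({str(w.message) for w in caught})
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    manifest_path = out_dir / "run_manifest.json"
    manifest_path.write_text(manifest.to_json())
    return manifest


def _run_stages(config, out_dir, in_dir, manifest, track) -> None:
    @_stage("simulate")
    def simulate() -> Path:
        roster = make_roster(config.roster_counts)
        zone_map = make_zone_map()
        schedule = make_schedule(
            roster,
            start_date=config.start_date,
            n_days=config.n_days,
            template=ShiftTemplate(),
            target_hours_per_person=config.target_hours_per_person,
            handover_min=config.handover_min,
        )
        mixing = MixingModel(
            handover_multiplier=config.handover_multiplier,
            ir_tick_s=config.ir_tick_s,
        )
        streams = simulate_streams(
            roster, schedule, zone_map, mixing, seed=config.seed
        )
        sio.write_roster(roster, track(out_dir / "roster.csv"))
        sio.write_zone_map(zone_map, track(out_dir / "zones.csv"))
        sio.write_schedule(schedule, track(out_dir / "schedule.csv"))
        for name in ("ir.csv", "accel.csv", "beacon.csv"):
            track(out_dir / name)
        sio.write_streams(streams, out_dir)
        manifest.counts["ir_records"] = int(len(streams.ir))
        manifest.counts["accel_records"] = int(len(streams.accel))
        manifest.counts["beacon_records"] = int(len(streams.beacon))
        return out_dir

    raw_dir = simulate() if in_dir is None else Path(in_dir)

    for name in ("roster.csv", "zones.csv", "schedule.csv",
                 "ir.csv", "accel.csv", "beacon.csv"):
        path = raw_dir / name
        if not path.exists():
            raise RuntimeError(f"pipeline stage 'detect' failed: missing input {path}")
        manifest.input_digests[name] = sio.file_digest(path)

    @_stage("detect")
    def detect():
        roster = sio.read_roster(raw_dir / "roster.csv")
        zone_map = sio.read_zone_map(raw_dir / "zones.csv")
        streams = sio.read_streams(raw_dir)
        det = config.detection()
        episodes = segment_episodes(streams.ir, det)
        episodes = attach_motion(episodes, streams.accel)
        mask = (
            active_mask(episodes, det)
            if not episodes.empty
            else pd.Series(dtype=bool)
        )
        episodes = assign_zones(episodes, streams.beacon, zone_map)
        sio.write_interactions(
            episodes, mask, track(out_dir / "interactions.csv")
        )
        active = episodes[mask.values].copy() if not episodes.empty else episodes
        manifest.counts["episodes"] = int(len(episodes))
        manifest.counts["active_interactions"] = int(len(active))
        return roster, zone_map, active

    roster, zone_map, active = detect()

    @_stage("map")
    def spatial_stage():
        if active.empty:
            days: list[str] = []
        else:
            days = sorted(
                (active["start"] - pd.Timedelta(minutes=config.day_start_offset_min))
                .dt.strftime("%Y-%m-%d")
                .unique()
            )
        for day in days:
            occ = daily_occupancy(
                active, zone_map, day, config.day_start_offset_min
            )
            sio.write_occupancy(occ, zone_map, track(out_dir / f"occupancy_{day}.csv"))
        manifest.counts["days_mapped"] = len(days)

    spatial_stage()

    @_stage("network")
    def network_stage():
        cm = contact_matrix(active, roster)
        sio.write_contact_matrix(cm, track(out_dir / "contact_matrix.csv"))
        pm = profession_heatmap(cm, roster, unit=config.heatmap_unit)
        sio.write_heatmap(pm, track(out_dir / "heatmap.csv"))
        edges_per_threshold = {}
        tables = []
        for t in config.thresholds:
            g = threshold_graph(cm, t)
            edges_per_threshold[str(t)] = len(g.edges)
            report = centrality_report(g, roster)
            cp = None
            if g.edges and g.n >= 3:
                cp = core_periphery_fit(g, seed=config.seed)
            label = f"{t:g}"
            export_sociogram_graphml(
                g, report, cp, track(out_dir / f"sociogram_t{label}.graphml")
            )
            sio.write_edges_tsv(g, track(out_dir / f"edges_t{label}.tsv"))
            table = report.table.copy()
            table.insert(0, "threshold_min", t)
            table.insert(0, "badge_id", table.index)
            if cp is not None:
                table["core"] = cp.core.values
            else:
                table["core"] = False
            tables.append(table)
        pd.concat(tables).to_csv(track(out_dir / "centrality.csv"), index=False)
        manifest.counts["edges_per_threshold"] = edges_per_threshold

    network_stage()

    # overall intensity bookkeeping (handy for the manifest and diagnostics)
    if not active.empty:
        series = intensity_series(active, 60.0)
        manifest.counts["total_active_minutes"] = float(series.values.sum())
    else:
        manifest.counts["total_active_minutes"] = 0.0
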