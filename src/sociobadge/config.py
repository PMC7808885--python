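"""Pipeline configuration: defaults, YAML parsing, validation.

The defaults reproduce the study settings the analysis assumes: a 2 Hz
motion gate over episodes longer than 1 minute, sociogram thresholds of
1, 3, 4, 30, 150 and 180 cumulative minutes, a 4-week three-shift schedule
averaging 160 on-duty hours per person.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .detect import MOTION_RULES, DetectionConfig
from .synthgen import DEFAULT_PROFESSION_COUNTS, PROFESSIONS

DEFAULT_THRESHOLDS = (1.0, 3.0, 4.0, 30.0, 150.0, 180.0)

HEATMAP_UNITS = ("pair_minutes", "person_minutes")


@dataclass
class PipelineConfig:
    """Everything a full simulate → detect → map → network run needs."""

    # detection gates
    motion_threshold_hz: float = 2.0
    min_duration_min: float = 1.0
    gap_tolerance_s: float = 60.0
    motion_rule: str = "either"
    ir_tick_s: float = 10.0
    # network stage
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    heatmap_unit: str = "pair_minutes"
    # day bookkeeping
    day_start_offset_min: float = 0.0
    # simulation stage
    seed: int = 0
    n_days: int = 28
    start_date: str = "2024-01-01"
    target_hours_per_person: float | None = None
    handover_min: float = 30.0
    handover_multiplier: float = 4.0
    roster_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PROFESSION_COUNTS)
    )

    def __post_init__(self) -> None:
        self.detection()  # range checks on the detection fields
        if self.motion_rule not in MOTION_RULES:
            raise ValueError(f"motion_rule must be one of {MOTION_RULES}")
        if self.heatmap_unit not in HEATMAP_UNITS:
            raise ValueError(f"heatmap_unit must be one of {HEATMAP_UNITS}")
        self.thresholds = tuple(float(t) for t in self.thresholds)
        if any(t < 0 for t in self.thresholds):
            raise ValueError("thresholds must be >= 0")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.handover_min < 0 or self.handover_multiplier <= 0:
            raise ValueError("handover parameters out of range")
        unknown = set(self.roster_counts) - set(PROFESSIONS)
        if unknown:
            raise ValueError(f"unknown professions in roster_counts: {sorted(unknown)}")

    def detection(self) -> DetectionConfig:
        return DetectionConfig(
            motion_threshold_hz=self.motion_threshold_hz,
            min_duration_min=self.min_duration_min,
            gap_tolerance_s=self.gap_tolerance_s,
            motion_rule=self.motion_rule,
            ir_tick_s=self.ir_tick_s,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d


def validate_config(raw_config_text: str) -> PipelineConfig:
    """Parse structured config text, fill defaults, reject unknown keys.

    Unknown keys are an error (listed by name) rather than silently ignored;
    out-of-range values raise with the offending field name.
    """
    data = yaml.safe_load(raw_config_text) if raw_config_text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping of option names to values")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**data)
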