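"""From raw badge streams to active face-to-face interactions.

Two people "actively communicated" when a face-to-face episode lasted more
than a minimum duration (default 1 minute) with body-motion frequency
exceeding a threshold (default 2 Hz) — the gesture-aided-conversation rule.
This module segments dyadic IR detections into episodes, attaches per-episode
motion statistics, applies the two strict gates, and bins active interaction
minutes into intensity time series.

Episodes are handled as a pandas DataFrame with one row per episode:
``badge_a`` < ``badge_b`` (unordered pair, lexicographically ordered),
``start``/``end`` (tz-aware), ``duration_min``, ``motion_a_hz``/
``motion_b_hz`` episode-mean motion, ``motion_a_missing``/
``motion_b_missing`` flags, and (after classification/zone assignment)
``active`` and ``zone_id``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

EPISODE_COLUMNS = [
    "badge_a", "badge_b", "start", "end", "duration_min",
    "motion_a_hz", "motion_b_hz", "motion_a_missing", "motion_b_missing",
]

MOTION_RULES = ("either", "both", "mean")


@dataclass(frozen=True)
class DetectionConfig:
    """Gates and tolerances of the active-interaction rule.

    motion_threshold_hz:
        body-motion frequency a participant must exceed (strict), in Hz.
    min_duration_min:
        episode duration the pair must exceed (strict), in minutes.
    gap_tolerance_s:
        largest gap between consecutive IR detections of the same pair that
        still counts as one episode; bridges brief occlusions.
    motion_rule:
        whose motion must clear the threshold: ``either`` participant
        (max of the two episode means), ``both`` (min), or ``mean``.
    ir_tick_s:
        the badges' IR sampling tick; an episode extends one tick past its
        last detection.
    """

    motion_threshold_hz: float = 2.0
    min_duration_min: float = 1.0
    gap_tolerance_s: float = 60.0
    motion_rule: str = "either"
    ir_tick_s: float = 10.0

    def __post_init__(self) -> None:
        if self.motion_threshold_hz <= 0:
            raise ValueError("motion_threshold_hz must be > 0")
        if self.min_duration_min <= 0:
            raise ValueError("min_duration_min must be > 0")
        if self.gap_tolerance_s < 0:
            raise ValueError("gap_tolerance_s must be >= 0")
        if self.motion_rule not in MOTION_RULES:
            raise ValueError(f"motion_rule must be one of {MOTION_RULES}")
        if self.ir_tick_s <= 0:
            raise ValueError("ir_tick_s must be > 0")


def _empty_episodes() -> pd.DataFrame:
    df = pd.DataFrame(columns=EPISODE_COLUMNS)
    return df.astype({"duration_min": float, "motion_a_hz": float,
                      "motion_b_hz": float, "motion_a_missing": bool,
                      "motion_b_missing": bool})


def segment_episodes(ir: pd.DataFrame, config: DetectionConfig | None = None) -> pd.DataFrame:
    """Group dyadic IR detections into maximal per-pair episodes.

    Detections are symmetrized (observer/observed order discarded); for each
    unordered pair, a run of detections with gaps no larger than
    ``gap_tolerance_s`` becomes one episode ending one IR tick after its last
    detection. Self-detections are skipped with a warning.
    """
    if config is None:
        config = DetectionConfig()
    if ir.empty:
        return _empty_episodes()
    df = ir[["timestamp", "observer_badge", "observed_badge"]].copy()
    selfies = df["observer_badge"] == df["observed_badge"]
    if selfies.any():
        warnings.warn(
            f"skipped {int(selfies.sum())} self-detection IR record(s)",
            stacklevel=2,
        )
        df = df[~selfies]
    if df.empty:
        return _empty_episodes()
    obs = df["observer_badge"].astype(str).values
    seen = df["observed_badge"].astype(str).values
    sym = pd.DataFrame(
        {"badge_a": np.minimum(obs, seen), "badge_b": np.maximum(obs, seen)},
        index=df.index,
    )
    sym["timestamp"] = df["timestamp"]  # keeps tz-awareness
    sym = sym.drop_duplicates().sort_values(
        ["badge_a", "badge_b", "timestamp"], kind="stable"
    )
    new_pair = (sym["badge_a"] != sym["badge_a"].shift()) | (
        sym["badge_b"] != sym["badge_b"].shift()
    )
    gap_s = sym["timestamp"].diff().dt.total_seconds()
    breaks = new_pair | (gap_s > config.gap_tolerance_s)
    sym["episode"] = breaks.cumsum()
    agg = sym.groupby("episode", sort=True).agg(
        badge_a=("badge_a", "first"),
        badge_b=("badge_b", "first"),
        start=("timestamp", "first"),
        end=("timestamp", "last"),
    )
    agg["end"] = agg["end"] + pd.Timedelta(seconds=config.ir_tick_s)
    agg["duration_min"] = (agg["end"] - agg["start"]).dt.total_seconds() / 60.0
    agg["motion_a_hz"] = np.nan
    agg["motion_b_hz"] = np.nan
    agg["motion_a_missing"] = False
    agg["motion_b_missing"] = False
    return agg.sort_values(["start", "badge_a", "badge_b"], kind="stable").reset_index(
        drop=True
    )


def attach_motion(episodes: pd.DataFrame, accel: pd.DataFrame) -> pd.DataFrame:
    """Fill each participant's mean motion over the episode window.

    The mean is over motion samples of that badge with timestamps in
    ``[start, end)``; a participant with no samples in the window gets mean
    0 and a missing flag instead of NaN.
    """
    out = episodes.copy()
    if out.empty:
        return out
    groups: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if not accel.empty:
        acc = accel.sort_values("timestamp", kind="stable")
        for badge, g in acc.groupby("badge_id", sort=False):
            ts = g["timestamp"].values.astype("datetime64[ns]").astype(np.int64)
            cum = np.concatenate([[0.0], np.cumsum(g["motion_hz"].values)])
            groups[badge] = (ts, cum)
    start_ns = out["start"].values.astype("datetime64[ns]").astype(np.int64)
    end_ns = out["end"].values.astype("datetime64[ns]").astype(np.int64)
    for side in ("a", "b"):
        means = np.zeros(len(out))
        missing = np.ones(len(out), dtype=bool)
        badges = out[f"badge_{side}"].values
        for badge in pd.unique(badges):
            sel = np.where(badges == badge)[0]
            if badge not in groups:
                continue
            ts, cum = groups[badge]
            i0 = np.searchsorted(ts, start_ns[sel], side="left")
            i1 = np.searchsorted(ts, end_ns[sel], side="left")
            n = i1 - i0
            has = n > 0
            means[sel[has]] = (cum[i1[has]] - cum[i0[has]]) / n[has]
            missing[sel[has]] = False
        out[f"motion_{side}_hz"] = means
        out[f"motion_{side}_missing"] = missing
    return out


def active_mask(episodes: pd.DataFrame, config: DetectionConfig | None = None) -> pd.Series:
    """Boolean mask of episodes passing both strict gates."""
    if config is None:
        config = DetectionConfig()
    if episodes.empty:
        return pd.Series(dtype=bool)
    ma = episodes["motion_a_hz"].astype(float)
    mb = episodes["motion_b_hz"].astype(float)
    if config.motion_rule == "either":
        stat = np.maximum(ma, mb)
    elif config.motion_rule == "both":
        stat = np.minimum(ma, mb)
    else:
        stat = (ma + mb) / 2.0
    return (episodes["duration_min"] > config.min_duration_min) & (
        stat > config.motion_threshold_hz
    )


def classify_active(
    episodes: pd.DataFrame, config: DetectionConfig | None = None
) -> pd.DataFrame:
    """Episodes that qualify as active interactions (both gates strict)."""
    if episodes.empty:
        out = episodes.copy()
        out["active"] = pd.Series(dtype=bool)
        return out
    mask = active_mask(episodes, config)
    out = episodes[mask].copy()
    out["active"] = True
    return out.reset_index(drop=True)


@dataclass
class IntensitySeries:
    """Active pair-minutes per time bin over an analysis window."""

    bin_starts: pd.DatetimeIndex
    bin_width_min: float
    values: np.ndarray

    def daily_profile(self) -> np.ndarray:
        """Mean across days of the within-day bin values (24 h of bins)."""
        per_day = int(round(24 * 60 / self.bin_width_min))
        if len(self.values) % per_day:
            raise ValueError("series does not cover whole days")
        return self.values.reshape(-1, per_day).mean(axis=0)


def intensity_series(
    active: pd.DataFrame,
    bin_width_min: float = 60.0,
    window: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> IntensitySeries:
    """Bin active interaction minutes by overlap apportionment.

    Each interaction contributes to every bin it overlaps, in proportion to
    the overlap, so the bin sum equals the total active minutes inside the
    window. The bin width must divide 24 hours.
    """
    if abs(1440.0 / bin_width_min - round(1440.0 / bin_width_min)) > 1e-9:
        raise ValueError("bin_width_min must divide 24 h (1440 min)")
    if window is None:
        if active.empty:
            raise ValueError("window required when there are no interactions")
        w0 = active["start"].min().normalize()
        w1 = (active["end"].max().normalize() + pd.Timedelta(days=1))
    else:
        w0, w1 = window
    width = pd.Timedelta(minutes=bin_width_min)
    n_bins = int(np.ceil((w1 - w0) / width))
    bins = pd.date_range(w0, periods=n_bins, freq=width)
    values = np.zeros(n_bins)
    if not active.empty:
        s = ((active["start"] - w0).dt.total_seconds() / 60.0).values
        e = ((active["end"] - w0).dt.total_seconds() / 60.0).values
        s = np.clip(s, 0.0, n_bins * bin_width_min)
        e = np.clip(e, 0.0, n_bins * bin_width_min)
        for si, ei in zip(s, e):
            b0 = int(si // bin_width_min)
            b1 = int(np.ceil(ei / bin_width_min))
            for b in range(b0, min(b1, n_bins)):
                lo = max(si, b * bin_width_min)
                hi = min(ei, (b + 1) * bin_width_min)
                if hi > lo:
                    values[b] += hi - lo
    return IntensitySeries(bins, bin_width_min, values)


def count_local_maxima(profile: np.ndarray, circular: bool = True) -> int:
    """Strict local maxima in a daily profile (periodic by default)."""
    p = np.asarray(profile, dtype=float)
    if p.size < 3:
        return 0
    if circular:
        left = np.roll(p, 1)
        right = np.roll(p, -1)
        return int(np.sum((p > left) & (p > right)))
    interior = p[1:-1]
    return int(np.sum((interior > p[:-2]) & (interior > p[2:])))
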