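"""Synthetic sociometric-badge data for an intensive-care ward.

No raw badge data from the original deployment are available, so this module
generates rosters, shift schedules, zone/beacon maps and raw badge event
streams with the statistical structure the downstream analysis assumes:

* a 76-member staff across 9 professions with a nurse-heavy skew,
* a 3-shift day (shift starts 8 hours apart) with handover bursts of
  face-to-face contact, producing the characteristic 3 daily intensity peaks,
* profession-pair mixing preferences with a nurse-centred core,
* 42 functional areas instrumented with 249 location beacons.

The emitted streams mimic what the badges record: dyadic infrared (IR)
detections while two people face each other, per-badge body-motion frequency
samples, and location-beacon pings.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import TZ, child_rng

# ---------------------------------------------------------------------------
# Professions and roster
# ---------------------------------------------------------------------------

PROFESSIONS: tuple[str, ...] = (
    "attending_physician",
    "nurse",
    "senior_resident",
    "resident",
    "nursing_assistant",
    "medical_technician",
    "receptionist",
    "pharmacist",
    "secretary",
)

#: Professions counted as "doctors" in top-k flags and rank comparisons.
DOCTOR_PROFESSIONS: tuple[str, ...] = (
    "attending_physician",
    "senior_resident",
    "resident",
)

PROFESSION_PREFIX = {
    "attending_physician": "AP",
    "nurse": "NU",
    "senior_resident": "SR",
    "resident": "RE",
    "nursing_assistant": "NA",
    "medical_technician": "MT",
    "receptionist": "RC",
    "pharmacist": "PH",
    "secretary": "SC",
}

#: Default per-profession head counts of the emulated 76-member ICU staff.
DEFAULT_PROFESSION_COUNTS = {
    "attending_physician": 15,
    "nurse": 39,
    "senior_resident": 4,
    "resident": 1,
    "nursing_assistant": 4,
    "medical_technician": 8,
    "receptionist": 2,
    "pharmacist": 1,
    "secretary": 2,
}


@dataclass(frozen=True)
class Member:
    badge_id: str
    profession: str


@dataclass(frozen=True)
class Roster:
    """Badge identities with profession labels; the node universe of every network."""

    members: tuple[Member, ...]

    def __post_init__(self) -> None:
        ids = [m.badge_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate badge_id in roster")
        for m in self.members:
            if m.profession not in PROFESSIONS:
                raise ValueError(f"unknown profession {m.profession!r}")

    def __len__(self) -> int:
        return len(self.members)

    def badge_ids(self) -> list[str]:
        return [m.badge_id for m in self.members]

    def profession_of(self) -> dict[str, str]:
        return {m.badge_id: m.profession for m in self.members}

    def counts(self) -> dict[str, int]:
        out = {p: 0 for p in PROFESSIONS}
        for m in self.members:
            out[m.profession] += 1
        return out

    def by_profession(self, profession: str) -> list[str]:
        return [m.badge_id for m in self.members if m.profession == profession]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"badge_id": self.badge_ids(),
             "profession": [m.profession for m in self.members]}
        )


def make_roster(counts: dict[str, int] | None = None) -> Roster:
    """Build a roster from per-profession head counts.

    Badge ids are deterministic: a two-letter profession prefix plus a
    1-based index (``NU01`` … ``NU39``). Missing professions mean zero.
    """
    if counts is None:
        counts = DEFAULT_PROFESSION_COUNTS
    unknown = set(counts) - set(PROFESSIONS)
    if unknown:
        raise ValueError(f"unknown professions in counts: {sorted(unknown)}")
    members: list[Member] = []
    for prof in PROFESSIONS:
        n = int(counts.get(prof, 0))
        if n < 0:
            raise ValueError(f"negative count for profession {prof!r}")
        prefix = PROFESSION_PREFIX[prof]
        members.extend(Member(f"{prefix}{i:02d}", prof) for i in range(1, n + 1))
    return Roster(tuple(members))


# ---------------------------------------------------------------------------
# Zones and beacons
# ---------------------------------------------------------------------------

ZONE_CATEGORIES: tuple[str, ...] = (
    "bed",
    "central_nurses_station",
    "conference_room",
    "consultation_room",
    "ct_control_room",
    "examination_procedure_room",
    "family_room",
    "laboratory",
    "nurses_lounge",
    "physicians_lounge",
    "physician_station",
    "reception",
    "satellite_pharmacy",
    "shower_room",
    "utility_room",
    "storage_room",
)

#: (category, number of areas, beacons per area). 42 areas, 249 beacons total.
#: The area list is the ward's itemized functional-area inventory; the
#: per-area beacon allocation is a synthetic choice summing to the installed
#: beacon total (corridors carry no beacons by construction).
DEFAULT_AREA_SPEC: list[tuple[str, int, int]] = [
    ("bed", 14, 8),
    ("central_nurses_station", 1, 15),
    ("conference_room", 1, 8),
    ("consultation_room", 1, 4),
    ("ct_control_room", 1, 4),
    ("examination_procedure_room", 4, 6),
    ("family_room", 1, 3),
    ("laboratory", 3, 5),
    ("nurses_lounge", 1, 5),
    ("physicians_lounge", 1, 5),
    ("physician_station", 2, 6),
    ("reception", 1, 5),
    ("satellite_pharmacy", 1, 5),
    ("shower_room", 1, 2),
    ("utility_room", 4, 5),
    ("storage_room", 5, 2),
]


@dataclass(frozen=True)
class Zone:
    zone_id: str
    category: str
    beacon_ids: tuple[str, ...]


@dataclass(frozen=True)
class ZoneMap:
    """Functional areas and the beacons installed in each (beacons are unique)."""

    zones: tuple[Zone, ...]

    def __post_init__(self) -> None:
        zids = [z.zone_id for z in self.zones]
        if len(set(zids)) != len(zids):
            raise ValueError("duplicate zone_id in zone map")
        beacons = [b for z in self.zones for b in z.beacon_ids]
        if len(set(beacons)) != len(beacons):
            raise ValueError("a beacon belongs to more than one zone")

    def __len__(self) -> int:
        return len(self.zones)

    @property
    def n_beacons(self) -> int:
        return sum(len(z.beacon_ids) for z in self.zones)

    def zone_ids(self) -> list[str]:
        return [z.zone_id for z in self.zones]

    def beacon_to_zone(self) -> dict[str, str]:
        return {b: z.zone_id for z in self.zones for b in z.beacon_ids}

    def zone_category(self) -> dict[str, str]:
        return {z.zone_id: z.category for z in self.zones}

    def zones_by_category(self) -> dict[str, list[Zone]]:
        out: dict[str, list[Zone]] = {}
        for z in self.zones:
            out.setdefault(z.category, []).append(z)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [(b, z.zone_id, z.category) for z in self.zones for b in z.beacon_ids]
        return pd.DataFrame(rows, columns=["beacon_id", "zone_id", "category"])


def make_zone_map(area_spec: list[tuple[str, int, int]] | None = None) -> ZoneMap:
    """Build a zone map from ``(category, area count, beacons per area)`` rows.

    Zone ids are ``<category>_<index>`` (1-based within category); beacon ids
    are ``B001`` … sequential across the whole map.
    """
    if area_spec is None:
        area_spec = DEFAULT_AREA_SPEC
    zones: list[Zone] = []
    seen: set[str] = set()
    beacon_counter = itertools.count(1)
    for category, count, per_area in area_spec:
        count = int(count)
        per_area = int(per_area)
        if count <= 0 or per_area <= 0:
            raise ValueError(
                f"area count and beacons per area must be positive ({category!r})"
            )
        for i in range(1, count + 1):
            zone_id = f"{category}_{i:02d}"
            if zone_id in seen:
                raise ValueError(f"zone id collision: {zone_id!r}")
            seen.add(zone_id)
            beacons = tuple(f"B{next(beacon_counter):03d}" for _ in range(per_area))
            zones.append(Zone(zone_id, category, beacons))
    return ZoneMap(tuple(zones))


# ---------------------------------------------------------------------------
# Shift schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShiftTemplate:
    """Three daily shift starts, 8 hours apart, each shift 8 hours long."""

    start_hours: tuple[float, ...] = (0.0, 8.0, 16.0)
    shift_length_h: float = 8.0

    def __post_init__(self) -> None:
        starts = sorted(self.start_hours)
        if len(starts) != 3:
            raise ValueError("template must have 3 daily shift starts")
        gaps = [starts[1] - starts[0], starts[2] - starts[1], 24.0 - starts[2] + starts[0]]
        if any(abs(g - 8.0) > 1e-9 for g in gaps):
            raise ValueError("consecutive shift starts must be exactly 8 h apart")


@dataclass
class ShiftSchedule:
    """Per-badge on-duty intervals plus the shift template that produced them."""

    intervals: dict[str, list[tuple[pd.Timestamp, pd.Timestamp]]]
    template: ShiftTemplate = field(default_factory=ShiftTemplate)
    handover_min: float = 30.0

    def __post_init__(self) -> None:
        for badge, ivs in self.intervals.items():
            ivs.sort(key=lambda iv: iv[0])
            for (s, e) in ivs:
                if not s < e:
                    raise ValueError(f"empty or inverted interval for {badge}")
            for (_, e0), (s1, _) in zip(ivs, ivs[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping intervals for {badge}")

    def badges(self) -> list[str]:
        return list(self.intervals)

    def total_hours(self, badge: str) -> float:
        return sum((e - s).total_seconds() for s, e in self.intervals[badge]) / 3600.0

    def mean_hours(self) -> float:
        if not self.intervals:
            return 0.0
        return float(np.mean([self.total_hours(b) for b in self.intervals]))

    def window(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        starts = [s for ivs in self.intervals.values() for s, _ in ivs]
        ends = [e for ivs in self.intervals.values() for _, e in ivs]
        return min(starts), max(ends)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (badge, s, e)
            for badge, ivs in self.intervals.items()
            for s, e in ivs
        ]
        return pd.DataFrame(rows, columns=["badge_id", "start", "end"])


def make_schedule(
    roster: Roster,
    start_date: str = "2024-01-01",
    n_days: int = 28,
    template: ShiftTemplate | None = None,
    target_hours_per_person: float | None = None,
    handover_min: float = 30.0,
) -> ShiftSchedule:
    """Deterministic rotating schedule hitting a mean on-duty target.

    Each badge works ``round(target / shift_length)`` shifts, spread evenly
    over the study days with a per-badge day rotation, cycling through the
    three shift slots so staffing is balanced across day/evening/night.
    The default target scales the 4-week 160-hour average to ``n_days``.
    """
    if template is None:
        template = ShiftTemplate()
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if target_hours_per_person is None:
        target_hours_per_person = 160.0 * n_days / 28.0
    shift_h = template.shift_length_h
    n_shifts = int(round(target_hours_per_person / shift_h))
    if n_shifts > n_days:
        raise ValueError(
            f"target of {target_hours_per_person} h needs {n_shifts} shifts "
            f"but only {n_days} days are available"
        )
    if target_hours_per_person > 0 and (
        abs(n_shifts * shift_h - target_hours_per_person) / target_hours_per_person > 0.02
    ):
        raise ValueError(
            "target hours not achievable within 2% by whole 8-h shifts"
        )
    t0 = pd.Timestamp(start_date, tz=TZ).normalize()
    starts_sorted = sorted(template.start_hours)
    intervals: dict[str, list[tuple[pd.Timestamp, pd.Timestamp]]] = {}
    for b_idx, member in enumerate(roster.members):
        ivs: list[tuple[pd.Timestamp, pd.Timestamp]] = []
        for k in range(n_shifts):
            day = (k * n_days // n_shifts + b_idx) % n_days
            slot = (b_idx + k) % 3
            s = t0 + pd.Timedelta(days=day, hours=starts_sorted[slot])
            ivs.append((s, s + pd.Timedelta(hours=shift_h)))
        intervals[member.badge_id] = ivs
    return ShiftSchedule(intervals, template=template, handover_min=handover_min)


# ---------------------------------------------------------------------------
# Mixing model
# ---------------------------------------------------------------------------


def default_rate_matrix() -> pd.DataFrame:
    """Profession-pair encounter rates (encounters per co-on-duty pair-hour).

    Nurse–nurse contact dominates, nurses mix broadly, nursing assistants
    talk to nurses and each other but rarely to doctors — the nurse-centred
    mixing structure the downstream network analysis should recover.
    """
    base = 0.17
    m = pd.DataFrame(base, index=PROFESSIONS, columns=PROFESSIONS, dtype=float)

    def set_pair(p: str, q: str, v: float) -> None:
        m.loc[p, q] = v
        m.loc[q, p] = v

    set_pair("nurse", "nurse", 1.55)
    set_pair("nurse", "nursing_assistant", 1.05)
    set_pair("nursing_assistant", "nursing_assistant", 1.10)
    set_pair("nurse", "attending_physician", 0.63)
    set_pair("nurse", "senior_resident", 0.63)
    set_pair("nurse", "resident", 0.63)
    set_pair("attending_physician", "attending_physician", 0.56)
    set_pair("attending_physician", "senior_resident", 0.56)
    set_pair("attending_physician", "resident", 0.56)
    set_pair("senior_resident", "senior_resident", 0.49)
    set_pair("senior_resident", "resident", 0.49)
    set_pair("resident", "resident", 0.49)
    set_pair("nurse", "medical_technician", 0.42)
    set_pair("nurse", "pharmacist", 0.49)
    set_pair("nurse", "receptionist", 0.28)
    set_pair("nurse", "secretary", 0.21)
    set_pair("nursing_assistant", "attending_physician", 0.11)
    set_pair("nursing_assistant", "senior_resident", 0.11)
    set_pair("nursing_assistant", "resident", 0.11)
    set_pair("medical_technician", "medical_technician", 0.42)
    set_pair("receptionist", "receptionist", 0.42)
    set_pair("secretary", "secretary", 0.42)
    set_pair("receptionist", "secretary", 0.35)
    return m


def default_zone_propensity() -> pd.DataFrame:
    """Per-profession distribution over zone categories (rows sum to 1).

    Mass concentrates on patient beds and the central nurses' station so the
    generated ward reproduces bedside/station interaction hot spots.
    """
    w = pd.DataFrame(0.0, index=PROFESSIONS, columns=ZONE_CATEGORIES, dtype=float)

    def row(prof: str, **weights: float) -> None:
        for cat, v in weights.items():
            w.loc[prof, cat] = v

    row("nurse", bed=0.56, central_nurses_station=0.30, nurses_lounge=0.03,
        utility_room=0.03, storage_room=0.02, examination_procedure_room=0.03,
        conference_room=0.015, consultation_room=0.015)
    row("attending_physician", bed=0.36, physician_station=0.22,
        central_nurses_station=0.14, conference_room=0.10, physicians_lounge=0.08,
        examination_procedure_room=0.06, ct_control_room=0.04)
    row("senior_resident", bed=0.38, physician_station=0.22,
        central_nurses_station=0.14, conference_room=0.10, physicians_lounge=0.06,
        examination_procedure_room=0.06, ct_control_room=0.04)
    row("resident", bed=0.40, physician_station=0.20,
        central_nurses_station=0.14, conference_room=0.10, physicians_lounge=0.06,
        examination_procedure_room=0.06, ct_control_room=0.04)
    row("nursing_assistant", bed=0.46, central_nurses_station=0.18,
        utility_room=0.18, storage_room=0.10, shower_room=0.04, family_room=0.04)
    row("medical_technician", laboratory=0.40, bed=0.28, ct_control_room=0.12,
        examination_procedure_room=0.10, central_nurses_station=0.06,
        storage_room=0.04)
    row("receptionist", reception=0.70, central_nurses_station=0.12,
        family_room=0.10, conference_room=0.08)
    row("pharmacist", satellite_pharmacy=0.55, central_nurses_station=0.20,
        bed=0.17, storage_room=0.08)
    row("secretary", reception=0.35, conference_room=0.30,
        central_nurses_station=0.15, physician_station=0.10, family_room=0.10)
    return w.div(w.sum(axis=1), axis=0)


@dataclass
class MixingModel:
    """Statistical model of who meets whom, for how long, where, and how briskly.

    Encounters between a co-on-duty pair arise from a Poisson process at
    ``rate[p, q]`` per pair-hour, modulated over the shift: a
    ``handover_multiplier`` burst during the handover window after each shift
    start, then a log-linear dip to ``shift_trough`` at mid-shift and back.
    Episode durations are log-normal (median ``duration_median_min`` minutes,
    log-sd ``duration_sigma``). Body-motion samples are drawn once per minute
    from a truncated normal whose mean depends on whether the badge wearer is
    conversing; location pings follow profession zone propensities, or the
    encounter's zone while conversing.
    """

    rate: pd.DataFrame = field(default_factory=default_rate_matrix)
    duration_median_min: float | pd.DataFrame = 2.0
    duration_sigma: float | pd.DataFrame = 0.8
    conversing_motion_hz: float = 2.5
    idle_motion_hz: float = 1.0
    motion_sd_hz: float = 0.5
    handover_multiplier: float = 4.0
    shift_trough: float = 0.20
    zone_propensity: pd.DataFrame = field(default_factory=default_zone_propensity)
    ir_tick_s: float = 10.0
    sample_period_s: float = 60.0

    def __post_init__(self) -> None:
        r = self.rate
        if not np.allclose(r.values, r.values.T):
            raise ValueError("rate matrix must be symmetric")
        if (r.values < 0).any():
            raise ValueError("rate matrix must be non-negative")
        if np.any(np.asarray(self.duration_median_min) <= 0):
            raise ValueError("duration median must be positive")
        if np.any(np.asarray(self.duration_sigma) <= 0):
            raise ValueError("duration sigma must be positive")
        if self.shift_trough <= 0 or self.handover_multiplier <= 0:
            raise ValueError("shift modulation parameters must be positive")

    def pair_duration_params(self, p: str, q: str) -> tuple[float, float]:
        med = self.duration_median_min
        sig = self.duration_sigma
        if isinstance(med, pd.DataFrame):
            med = float(med.loc[p, q])
        if isinstance(sig, pd.DataFrame):
            sig = float(sig.loc[p, q])
        return float(med), float(sig)

    def rate_factor(
        self,
        phase_h: np.ndarray | float,
        handover_h: float,
        shift_length_h: float = 8.0,
    ) -> np.ndarray:
        """Within-shift rate modifier at ``phase_h`` hours after shift start.

        ``handover_multiplier`` inside the handover window, then a symmetric
        log-linear V from 1 down to ``shift_trough`` at mid-shift and back
        to 1 at shift end, so expected contact intensity is unimodal at each
        handover and monotone between handovers.
        """
        phase = np.asarray(phase_h, dtype=float)
        out = np.empty_like(phase)
        in_handover = phase < handover_h
        out[in_handover] = self.handover_multiplier
        rest = ~in_handover
        span = shift_length_h - handover_h
        # position in [0, 1] across the post-handover stretch; V in log space
        x = (phase[rest] - handover_h) / span
        depth = abs(math.log(self.shift_trough))
        out[rest] = np.exp(-depth * (1.0 - np.abs(2.0 * x - 1.0)))
        return out

    def mean_rate_factor(self, handover_h: float, shift_length_h: float = 8.0) -> float:
        """Shift-averaged rate modifier (numeric quadrature)."""
        g = np.linspace(0.0, shift_length_h, 16001)
        f = self.rate_factor(g, handover_h, shift_length_h)
        return float(np.trapezoid(f, g) / shift_length_h)


# ---------------------------------------------------------------------------
# Event streams
# ---------------------------------------------------------------------------

IR_COLUMNS = ["timestamp", "observer_badge", "observed_badge"]
ACCEL_COLUMNS = ["timestamp", "badge_id", "motion_hz"]
BEACON_COLUMNS = ["timestamp", "badge_id", "beacon_id"]


@dataclass
class EventStreams:
    """The three raw badge streams (IR dyads, motion samples, beacon pings)."""

    ir: pd.DataFrame
    accel: pd.DataFrame
    beacon: pd.DataFrame
    #: Ground-truth encounter table (diagnostics; not part of the raw streams).
    encounters: pd.DataFrame | None = None
    #: Malformed-row counts per stream, populated by the CSV reader.
    malformed: dict[str, int] = field(default_factory=dict)


def _intersect(
    a: list[tuple[float, float]], b: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Intersection of two sorted disjoint interval lists (two-pointer)."""
    out: list[tuple[float, float]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _sample_categories(
    probs: np.ndarray, row_idx: np.ndarray, u: np.ndarray
) -> np.ndarray:
    """Vectorized categorical draw: ``probs[row_idx[k]]`` row for sample k."""
    cum = np.cumsum(probs[row_idx], axis=1)
    return (u[:, None] > cum).sum(axis=1).clip(0, probs.shape[1] - 1)


def simulate_streams(
    roster: Roster,
    schedule: ShiftSchedule,
    zone_map: ZoneMap,
    mixing: MixingModel | None = None,
    seed: int = 0,
) -> EventStreams:
    """Generate raw badge event streams for a scheduled roster.

    For every pair of badges that are simultaneously on duty, encounters are
    drawn from a thinned Poisson process at the profession-pair mixing rate
    modulated by the within-shift profile. Each encounter emits paired IR
    records every ``ir_tick_s`` for its duration (truncated at shift end),
    minute-by-minute "conversing" motion samples and beacon pings from its
    zone; the remaining on-duty minutes emit "idle" motion samples and
    propensity-driven pings. Fully reproducible given ``seed``.
    """
    if mixing is None:
        mixing = MixingModel()
    badge_ids = roster.badge_ids()
    unknown = set(schedule.intervals) - set(badge_ids)
    if unknown:
        raise ValueError(f"scheduled badges absent from roster: {sorted(unknown)}")

    empty = EventStreams(
        ir=pd.DataFrame(columns=IR_COLUMNS),
        accel=pd.DataFrame(columns=ACCEL_COLUMNS),
        beacon=pd.DataFrame(columns=BEACON_COLUMNS),
        encounters=pd.DataFrame(
            columns=["badge_a", "badge_b", "start", "end", "zone_id"]
        ),
    )
    if not schedule.intervals or not any(schedule.intervals.values()):
        return empty

    prof = roster.profession_of()
    t0 = schedule.window()[0].normalize()
    shift_h = schedule.template.shift_length_h
    handover_h = schedule.handover_min / 60.0
    starts_sorted = np.asarray(sorted(schedule.template.start_hours), dtype=float)

    def phase_of(times_h: np.ndarray) -> np.ndarray:
        hod = np.mod(times_h, 24.0)
        k = np.searchsorted(starts_sorted, hod, side="right") - 1
        base = np.where(k >= 0, starts_sorted[k], starts_sorted[-1] - 24.0)
        return hod - base

    # Per-badge on-duty intervals in hours since t0.
    ivh: dict[str, list[tuple[float, float]]] = {}
    for badge in badge_ids:
        ivh[badge] = [
            ((s - t0).total_seconds() / 3600.0, (e - t0).total_seconds() / 3600.0)
            for s, e in schedule.intervals.get(badge, [])
        ]

    rng_enc = child_rng(seed, "encounters")
    rng_dur = child_rng(seed, "durations")
    rng_zone = child_rng(seed, "zones")
    rng_motion = child_rng(seed, "motion")
    rng_beacon = child_rng(seed, "beacon")

    cat_index = {c: i for i, c in enumerate(ZONE_CATEGORIES)}
    prop = mixing.zone_propensity.loc[list(PROFESSIONS), list(ZONE_CATEGORIES)].values
    prof_index = {p: i for i, p in enumerate(PROFESSIONS)}
    zones_by_cat = zone_map.zones_by_category()
    m_max = max(mixing.handover_multiplier, 1.0)

    # ---- encounters ------------------------------------------------------
    enc_a: list[str] = []
    enc_b: list[str] = []
    enc_t: list[np.ndarray] = []
    enc_med: list[np.ndarray] = []
    enc_sig: list[np.ndarray] = []
    enc_cap: list[np.ndarray] = []
    enc_pp: list[np.ndarray] = []
    for ia, ib in itertools.combinations(range(len(badge_ids)), 2):
        a, b = badge_ids[ia], badge_ids[ib]
        r = float(mixing.rate.loc[prof[a], prof[b]])
        if r <= 0:
            continue
        segs = _intersect(ivh[a], ivh[b])
        if not segs:
            continue
        med, sig = mixing.pair_duration_params(prof[a], prof[b])
        for s, e in segs:
            n = rng_enc.poisson(r * m_max * (e - s))
            if n == 0:
                continue
            t = np.sort(s + rng_enc.uniform(0.0, e - s, size=n))
            keep = (
                rng_enc.uniform(size=n)
                < mixing.rate_factor(phase_of(t), handover_h, shift_h) / m_max
            )
            t = t[keep]
            if t.size == 0:
                continue
            enc_a.extend([a] * t.size)
            enc_b.extend([b] * t.size)
            enc_t.append(t)
            enc_med.append(np.full(t.size, med))
            enc_sig.append(np.full(t.size, sig))
            enc_cap.append(np.full(t.size, e))
            mix_row = (prop[prof_index[prof[a]]] + prop[prof_index[prof[b]]]) / 2.0
            enc_pp.append(np.tile(mix_row, (t.size, 1)))

    if not enc_t:
        return empty

    t_h = np.concatenate(enc_t)
    med = np.concatenate(enc_med)
    sig = np.concatenate(enc_sig)
    cap_h = np.concatenate(enc_cap)
    pair_prop = np.concatenate(enc_pp, axis=0)
    a_arr = np.asarray(enc_a)
    b_arr = np.asarray(enc_b)
    n_enc = t_h.size

    dur_min = med * np.exp(sig * rng_dur.standard_normal(n_enc))
    start_s = np.floor(t_h * 3600.0).astype(np.int64)
    end_s = np.minimum(start_s + np.round(dur_min * 60.0), (cap_h * 3600.0)).astype(
        np.int64
    )
    end_s = np.maximum(end_s, start_s + 1)

    # encounter zone: category from the pair-averaged propensity, then a
    # uniform zone within the category, skipping categories absent from the map
    present = np.array([c in zones_by_cat for c in ZONE_CATEGORIES], dtype=float)
    pair_prop = pair_prop * present
    rs = pair_prop.sum(axis=1, keepdims=True)
    if np.any(rs == 0):
        raise ValueError("zone map has no zones for any category with propensity mass")
    pair_prop = pair_prop / rs
    cum = np.cumsum(pair_prop, axis=1)
    cat_idx = (rng_zone.uniform(size=n_enc)[:, None] > cum).sum(axis=1).clip(
        0, len(ZONE_CATEGORIES) - 1
    )
    zone_ids = np.empty(n_enc, dtype=object)
    u_zone = rng_zone.uniform(size=n_enc)
    for c, idx in cat_index.items():
        mask = cat_idx == idx
        if not mask.any():
            continue
        zl = zones_by_cat[c]
        zone_ids[mask] = [zl[int(k)].zone_id for k in
                          np.floor(u_zone[mask] * len(zl)).clip(0, len(zl) - 1)]

    # ---- IR records ------------------------------------------------------
    tick = int(round(mixing.ir_tick_s))
    n_ticks = np.maximum(1, np.ceil((end_s - start_s) / tick)).astype(np.int64)
    total = int(n_ticks.sum())
    offsets = np.arange(total) - np.repeat(np.cumsum(n_ticks) - n_ticks, n_ticks)
    ir_ts = np.repeat(start_s, n_ticks) + tick * offsets
    ir_obs = np.repeat(a_arr, n_ticks)
    ir_seen = np.repeat(b_arr, n_ticks)
    ir = pd.DataFrame(
        {
            "timestamp": np.concatenate([ir_ts, ir_ts]),
            "observer_badge": np.concatenate([ir_obs, ir_seen]),
            "observed_badge": np.concatenate([ir_seen, ir_obs]),
        }
    )

    # ---- per-badge minute grid: motion + beacon --------------------------
    period = int(round(mixing.sample_period_s))
    grid_badge: list[np.ndarray] = []
    grid_ts: list[np.ndarray] = []
    for badge in badge_ids:
        for s, e in ivh[badge]:
            s_s = int(round(s * 3600.0))
            e_s = int(round(e * 3600.0))
            ts = np.arange(s_s, e_s, period, dtype=np.int64)
            grid_ts.append(ts)
            grid_badge.append(np.repeat(badge, ts.size))
    g_ts = np.concatenate(grid_ts) if grid_ts else np.empty(0, dtype=np.int64)
    g_badge = (
        np.concatenate(grid_badge) if grid_badge else np.empty(0, dtype=object)
    )

    conversing = np.zeros(g_ts.size, dtype=bool)
    g_zone = np.empty(g_ts.size, dtype=object)
    # encounter intervals per badge, sorted by start; a sample is conversing if
    # it falls inside any of the last 3 encounters starting at or before it
    # (bounded back-scan; concurrent overlaps beyond that are vanishingly rare)
    by_badge: dict[str, list[int]] = {}
    for k in range(n_enc):
        by_badge.setdefault(str(a_arr[k]), []).append(k)
        by_badge.setdefault(str(b_arr[k]), []).append(k)
    for badge, enc_idx in by_badge.items():
        sel = np.where(g_badge == badge)[0]
        if sel.size == 0:
            continue
        ek = np.asarray(enc_idx)
        order = np.argsort(start_s[ek], kind="stable")
        ek = ek[order]
        es, ee = start_s[ek], end_s[ek]
        pos = np.searchsorted(es, g_ts[sel], side="right") - 1
        hit = np.full(sel.size, -1)
        for back in range(3):
            cand = pos - back
            ok = (cand >= 0) & (hit < 0)
            ok[ok] = g_ts[sel[ok]] < ee[cand[ok]]
            hit[ok] = cand[ok]
        found = hit >= 0
        conversing[sel[found]] = True
        g_zone[sel[found]] = zone_ids[ek[hit[found]]]

    # idle pings: zone from the badge's own profession propensity
    idle = ~conversing
    if idle.any():
        prof_rows = np.array([prof_index[prof[b]] for b in g_badge[idle]])
        iprop = prop * present
        iprop = iprop / iprop.sum(axis=1, keepdims=True)
        icat = _sample_categories(iprop, prof_rows, rng_beacon.uniform(size=idle.sum()))
        izone = np.empty(icat.size, dtype=object)
        u = rng_beacon.uniform(size=icat.size)
        for c, idx in cat_index.items():
            mask = icat == idx
            if not mask.any():
                continue
            zl = zones_by_cat[c]
            izone[mask] = [zl[int(k)].zone_id for k in
                           np.floor(u[mask] * len(zl)).clip(0, len(zl) - 1)]
        g_zone[idle] = izone

    motion = np.where(
        conversing, mixing.conversing_motion_hz, mixing.idle_motion_hz
    ) + mixing.motion_sd_hz * rng_motion.standard_normal(g_ts.size)
    motion = np.clip(motion, 0.0, None)

    zone_beacons = {z.zone_id: z.beacon_ids for z in zone_map.zones}
    u_b = rng_beacon.uniform(size=g_ts.size)
    beacon_ids_col = np.empty(g_ts.size, dtype=object)
    for zid, beacons in zone_beacons.items():
        mask = g_zone == zid
        if not mask.any():
            continue
        nb = len(beacons)
        beacon_ids_col[mask] = [
            beacons[int(k)] for k in np.floor(u_b[mask] * nb).clip(0, nb - 1)
        ]

    accel = pd.DataFrame(
        {"timestamp": g_ts, "badge_id": g_badge, "motion_hz": motion}
    )
    beacon = pd.DataFrame(
        {"timestamp": g_ts, "badge_id": g_badge, "beacon_id": beacon_ids_col}
    )

    def finalize(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
        df = df.copy()
        df["timestamp"] = t0 + pd.to_timedelta(df["timestamp"], unit="s")
        return df.sort_values(keys, kind="stable").reset_index(drop=True)

    encounters = pd.DataFrame(
        {
            "badge_a": a_arr,
            "badge_b": b_arr,
            "start": t0 + pd.to_timedelta(start_s, unit="s"),
            "end": t0 + pd.to_timedelta(end_s, unit="s"),
            "zone_id": zone_ids,
        }
    ).sort_values(["start", "badge_a", "badge_b"], kind="stable").reset_index(drop=True)

    return EventStreams(
        ir=finalize(ir, ["timestamp", "observer_badge"]),
        accel=finalize(accel, ["timestamp", "badge_id"]),
        beacon=finalize(beacon, ["timestamp", "badge_id"]),
        encounters=encounters,
    )
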