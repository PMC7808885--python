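"""Shared fixtures: small synthetic wards for unit tests and a cached
desk-scale (76-staff, 7-day) simulation for the heavier end-to-end checks."""
from __future__ import annotations

from types import SimpleNamespace

import pandas as pd
import pytest

from sociobadge import (
    attach_motion,
    classify_active,
    make_roster,
    make_schedule,
    make_zone_map,
    segment_episodes,
    simulate_streams,
)


@pytest.fixture(scope="session")
def default_roster():
    return make_roster()


@pytest.fixture(scope="session")
def zone_map():
    return make_zone_map()


@pytest.fixture(scope="session")
def week_schedule(default_roster):
    return make_schedule(default_roster, n_days=7)


@pytest.fixture(scope="session")
def desk_sim(default_roster, zone_map, week_schedule):
    """Factory returning (streams, episodes, active) for a seed, cached."""
    cache: dict[int, SimpleNamespace] = {}

    def get(seed: int) -> SimpleNamespace:
        if seed not in cache:
            streams = simulate_streams(
                default_roster, week_schedule, zone_map, seed=seed
            )
            episodes = attach_motion(segment_episodes(streams.ir), streams.accel)
            active = classify_active(episodes)
            cache[seed] = SimpleNamespace(
                streams=streams, episodes=episodes, active=active
            )
        return cache[seed]

    return get


@pytest.fixture(scope="session")
def small_sim(zone_map):
    """A 16-badge, 2-day ward: fast enough for per-module unit tests."""
    roster = make_roster(
        {
            "nurse": 8,
            "attending_physician": 4,
            "nursing_assistant": 2,
            "medical_technician": 2,
        }
    )
    schedule = make_schedule(roster, n_days=2, target_hours_per_person=16)
    streams = simulate_streams(roster, schedule, zone_map, seed=11)
    episodes = attach_motion(segment_episodes(streams.ir), streams.accel)
    active = classify_active(episodes)
    return SimpleNamespace(
        roster=roster,
        schedule=schedule,
        streams=streams,
        episodes=episodes,
        active=active,
    )


@pytest.fixture()
def ts():
    """Shorthand tz-aware timestamp constructor used across tests."""
    from sociobadge._util import TZ

    def make(text: str) -> pd.Timestamp:
        return pd.Timestamp(text, tz=TZ)

    return make
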