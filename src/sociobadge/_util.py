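"""Shared helpers: fixed ward timezone, seed derivation, timestamp I/O."""
from __future__ import annotations

import hashlib
from datetime import timedelta, timezone

import numpy as np
import pandas as pd

#: Fixed UTC offset for all timestamps (+09:00). Day boundaries fall at local midnight.
TZ = timezone(timedelta(hours=9))

#: Timestamp format written to CSV (ISO 8601 with numeric offset).
ISO_FMT = "%Y-%m-%dT%H:%M:%S%z"


def child_seed(master_seed: int, label: str) -> int:
    """Derive a deterministic 31-bit child seed from a master seed and a label.

    Labelled hashing gives each simulator component its own reproducible
    random stream while the caller passes a single master seed.
    """
    digest = hashlib.sha256(f"{int(master_seed)}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def child_rng(master_seed: int, label: str) -> np.random.Generator:
    """A numpy Generator seeded from ``child_seed(master_seed, label)``."""
    return np.random.default_rng(child_seed(master_seed, label))


def format_times(ts: pd.Series) -> pd.Series:
    """Render a tz-aware datetime series as ISO 8601 strings."""
    if len(ts) == 0:
        return pd.Series(dtype=str)
    return ts.dt.strftime(ISO_FMT)


def parse_times(raw: pd.Series) -> pd.Series:
    """Parse ISO 8601 strings; unparseable entries become NaT."""
    out = pd.to_datetime(raw, errors="coerce", utc=True, format="ISO8601")
    return out.dt.tz_convert(TZ)
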