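"""CSV input/output for epoch streams and participant tables.

The epoch format is long-form with header
``participant_id,day_index,minute_of_day,cpm``; reading and writing are
gzip-transparent (a ``.gz`` suffix is handled automatically by pandas).
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .actigraphy import CountStream

EPOCH_COLUMNS = ("participant_id", "day_index", "minute_of_day", "cpm")


def read_epoch_csv(path: str | Path) -> list[CountStream]:
    """Read an epoch CSV (optionally gzipped) into per-participant streams."""
    df = pd.read_csv(path)
    missing = set(EPOCH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"epoch CSV missing columns: {sorted(missing)}")
    streams = []
    for pid, grp in df.groupby("participant_id", sort=True):
        streams.append(
            CountStream.from_epochs(
                participant_id=str(pid),
                day_index=grp["day_index"].to_numpy(),
                minute_of_day=grp["minute_of_day"].to_numpy(),
                cpm=grp["cpm"].to_numpy(),
            )
        )
    return streams


def write_epoch_csv(streams: Sequence[CountStream], path: str | Path) -> None:
    """Write streams to a long-form epoch CSV (gzipped if path ends .gz)."""
    frames = [s.to_epochs_frame() for s in streams]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=EPOCH_COLUMNS)
    )
    df.to_csv(path, index=False)


def read_participants_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "participant_id" not in df.columns:
        raise ValueError("participant CSV must have a participant_id column")
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def write_participants_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
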