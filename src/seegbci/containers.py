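"""Shared in-memory containers for sEEG recordings and task schedules.

A :class:`Recording` is the package's canonical signal container: a
channels-by-samples voltage matrix in microvolts with a sampling rate and a
channel-metadata table.  Task structure travels as a *trial table*, a pandas
DataFrame with one row per movement or rest interval (half-open sample
intervals, 0-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MODALITIES = ("hand", "tongue", "foot")
REST = "rest"

#: centre-to-centre contact spacing along a lead: 2 mm contact + 1.5 mm gap
CONTACT_PITCH_MM = 3.5

TRIAL_COLUMNS = [
    "trial_id",
    "modality",
    "onset_sample",
    "offset_sample",
    "preceding_modality",
]


@dataclass(frozen=True)
class ChannelMeta:
    """One physical depth-electrode contact (or surface EMG electrode).

    ``contact_index`` is 1-based along the lead; ``segment_index`` groups
    contacts of segmented leads (bipolar pairs never cross segments).
    ``somatotopy`` marks which movement modality modulates the local
    population ('none' for unmodulated sites).
    """

    channel_id: str
    lead_id: str
    contact_index: int
    segment_index: int = 1
    position_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tissue: str = "gray"  # gray | white | gray-white
    somatotopy: str = "none"  # hand | tongue | foot | none


@dataclass
class Recording:
    """Multichannel voltage time series (µV) with channel metadata.

    ``channels`` has one row per row of ``data`` and at least the columns
    ``channel_id`` and ``type`` ('seeg', 'emg' or 'bipolar'); sEEG rows carry
    lead/contact/segment indices and x/y/z positions in mm.
    """

    data: np.ndarray
    fs: float
    channels: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"channel table has {len(self.channels)} rows for "
                f"{self.data.shape[0]} data rows"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.channels = self.channels.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_ids(self) -> list[str]:
        return list(self.channels["channel_id"])

    def get(self, channel_id: str) -> np.ndarray:
        """Return the voltage trace of one channel by id."""
        idx = np.flatnonzero(self.channels["channel_id"].to_numpy() == channel_id)
        if idx.size == 0:
            raise KeyError(f"channel {channel_id!r} not in recording")
        return self.data[idx[0]]

    def pick(self, channel_ids: Sequence[str]) -> "Recording":
        """Sub-recording restricted to the given channels, in the given order."""
        rows = [self.channels.index[self.channels["channel_id"] == c] for c in channel_ids]
        for c, r in zip(channel_ids, rows):
            if len(r) == 0:
                raise KeyError(f"channel {c!r} not in recording")
        sel = [int(r[0]) for r in rows]
        return Recording(self.data[sel], self.fs, self.channels.iloc[sel].copy())


def channel_frame(metas: Sequence[ChannelMeta], type_: str = "seeg") -> pd.DataFrame:
    """Tabulate ChannelMeta records into a Recording channel table."""
    return pd.DataFrame(
        {
            "channel_id": [m.channel_id for m in metas],
            "type": type_,
            "lead_id": [m.lead_id for m in metas],
            "contact_index": [m.contact_index for m in metas],
            "segment_index": [m.segment_index for m in metas],
            "x": [m.position_mm[0] for m in metas],
            "y": [m.position_mm[1] for m in metas],
            "z": [m.position_mm[2] for m in metas],
            "tissue": [m.tissue for m in metas],
            "somatotopy": [m.somatotopy for m in metas],
        }
    )


def validate_trial_table(trials: pd.DataFrame) -> None:
    """Check ordering, non-overlap and rest annotation of a trial table."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns {missing}")
    on = trials["onset_sample"].to_numpy()
    off = trials["offset_sample"].to_numpy()
    if np.any(off <= on):
        raise ValueError("trial table has empty or inverted intervals")
    if np.any(np.diff(on) < 0):
        raise ValueError("trial table not ordered by onset")
    if np.any(on[1:] < off[:-1]):
        raise ValueError("trial table has overlapping intervals")
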