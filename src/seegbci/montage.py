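"""Bipolar re-referencing and EMG-based trial epoching.

Depth-electrode voltages are re-referenced to a bipolar montage: every pair of
contacts that are adjacent on the same lead and within the same lead segment
forms one analysis channel (anode minus cathode), positioned at the midpoint
of the two contacts.  Movement onsets/offsets are refined from the rectified
EMG envelope with a robust threshold, replacing manual demarcation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .containers import REST, ChannelMeta, Recording, validate_trial_table

__all__ = [
    "BipolarMontage",
    "EmgEnvelope",
    "build_bipolar_montage",
    "apply_montage",
    "process_emg",
    "detect_movement_epochs",
]


@dataclass
class BipolarMontage:
    """Table of bipolar pairs: channel_id, anode, cathode, midpoint x/y/z (mm)."""

    pairs: pd.DataFrame

    def __len__(self) -> int:
        return len(self.pairs)

    def channel_ids(self) -> list[str]:
        return list(self.pairs["channel_id"])


@dataclass
class EmgEnvelope:
    """Rectified band-passed EMG (all values >= 0) with its sampling rate."""

    samples: np.ndarray
    fs: float
    muscle: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if np.any(self.samples < 0):
            raise ValueError("envelope must be nonnegative")


def build_bipolar_montage(channels: list[ChannelMeta]) -> BipolarMontage:
    """Enumerate all and only adjacent same-lead, same-segment contact pairs.

    Adjacency means consecutive 1-based contact indices along a lead; pairs
    never cross lead segments.  The derived channel's position is the
    arithmetic midpoint of the two contact centres.
    """
    rows = []
    by_lead: dict[str, list[ChannelMeta]] = {}
    for m in channels:
        by_lead.setdefault(m.lead_id, []).append(m)
    for lead_id in sorted(by_lead):
        metas = sorted(by_lead[lead_id], key=lambda m: m.contact_index)
        idx = [m.contact_index for m in metas]
        if len(set(idx)) != len(idx):
            dupes = sorted({i for i in idx if idx.count(i) > 1})
            raise ValueError(
                f"lead {lead_id!r} has duplicate contact indices {dupes}"
            )
        for a, b in zip(metas[:-1], metas[1:]):
            if b.contact_index != a.contact_index + 1:
                continue  # non-consecutive contacts are not adjacent
            if a.segment_index != b.segment_index:
                continue  # pairs never span a segment boundary
            mid = (np.asarray(a.position_mm) + np.asarray(b.position_mm)) / 2.0
            rows.append(
                (f"{a.channel_id}-{b.channel_id}", a.channel_id, b.channel_id,
                 mid[0], mid[1], mid[2])
            )
    return BipolarMontage(
        pd.DataFrame(rows, columns=["channel_id", "anode", "cathode", "x", "y", "z"])
    )


def apply_montage(rec: Recording, montage: BipolarMontage) -> Recording:
    """Re-reference a recording: each output trace = anode - cathode.

    Common-mode components (e.g. line noise shared by both contacts) cancel
    exactly.  Output channel metadata carries the pair midpoints.
    """
    id_to_row = {c: i for i, c in enumerate(rec.channels["channel_id"])}
    out = np.empty((len(montage), rec.n_samples))
    for j, row in enumerate(montage.pairs.itertuples(index=False)):
        for contact in (row.anode, row.cathode):
            if contact not in id_to_row:
                raise KeyError(f"montage contact {contact!r} missing from recording")
        out[j] = rec.data[id_to_row[row.anode]] - rec.data[id_to_row[row.cathode]]
    table = montage.pairs.copy()
    table.insert(1, "type", "bipolar")
    return Recording(out, rec.fs, table)


def process_emg(
    trace: np.ndarray,
    fs: float,
    muscle: str = "",
    smooth_s: float = 0.0,
) -> EmgEnvelope:
    """Band-pass 25-400 Hz (zero-phase) and rectify a surface-EMG trace.

    Forward-backward filtering keeps envelope timing unbiased, which matters
    for onset detection.  ``smooth_s`` optionally applies a moving-average of
    that length after rectification (default off).
    """
    if fs <= 800:
        raise ValueError(
            f"fs={fs} Hz cannot represent the 25-400 Hz passband (need fs > 800)"
        )
    trace = np.asarray(trace, dtype=float)
    if np.allclose(trace, 0.0):
        env = np.zeros_like(trace)
    else:
        sos = butter(4, [25.0, 400.0], btype="bandpass", fs=fs, output="sos")
        env = np.abs(sosfiltfilt(sos, trace))
    if smooth_s > 0:
        w = max(int(round(smooth_s * fs)), 1)
        kernel = np.ones(w) / w
        env = np.convolve(env, kernel, mode="same")
    return EmgEnvelope(env, fs, muscle)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True in a boolean mask."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        stops = stops + [mask.size]
    return list(zip(starts, stops))


def detect_movement_epochs(
    env: EmgEnvelope,
    schedule: pd.DataFrame,
    k_mad: float = 5.0,
    min_dur_s: float = 0.2,
    pre_s: float = 0.5,
    smooth_s: float = 0.05,
) -> pd.DataFrame:
    """Refine cued movement intervals from the EMG envelope.

    The envelope is smoothed with a ``smooth_s`` moving average (a rectified
    carrier dips through zero every half-cycle, so raw samples never stay
    above threshold); the threshold is the rest-period smoothed-envelope
    median plus ``k_mad`` median absolute deviations.  Within each cued
    movement window (extended ``pre_s`` before the cue), the refined
    onset/offset are the first/last samples of supra-threshold runs lasting
    at least ``min_dur_s``.  Trials with no such run are flagged
    (``flag=True``) and excluded downstream; rest rows are re-derived between
    refined movements, keeping their preceding modality.
    """
    validate_trial_table(schedule)
    x = env.samples
    if smooth_s > 0:
        w = max(int(round(smooth_s * env.fs)), 1)
        x = np.convolve(x, np.ones(w) / w, mode="same")
    if int(schedule["offset_sample"].max()) > x.size:
        raise ValueError("envelope does not cover the schedule span")
    fs = env.fs
    rest_rows = schedule[schedule["modality"] == REST]
    rest_samples = np.concatenate(
        [x[int(r.onset_sample):int(r.offset_sample)] for r in rest_rows.itertuples()]
    ) if len(rest_rows) else x
    med = np.median(rest_samples)
    mad = np.median(np.abs(rest_samples - med))
    thresh = med + k_mad * mad
    min_len = max(int(round(min_dur_s * fs)), 1)
    pre = int(round(pre_s * fs))

    moves = schedule[schedule["modality"] != REST]
    refined = []
    for r in moves.itertuples():
        lo = max(int(r.onset_sample) - pre, 0)
        hi = int(r.offset_sample)
        runs = [(a + lo, b + lo) for a, b in _runs_above(x[lo:hi] > thresh)
                if b - a >= min_len]
        if not runs:
            refined.append((r.trial_id, r.modality, int(r.onset_sample),
                            int(r.offset_sample), None, True))
        else:
            refined.append((r.trial_id, r.modality, runs[0][0], runs[-1][1],
                            None, False))

    # rebuild rest rows between consecutive refined movements
    rows = []
    for i, mv in enumerate(refined):
        rows.append(mv)
        orig_rest = schedule[
            (schedule["modality"] == REST)
            & (schedule["preceding_modality"] == mv[1])
            & (schedule["onset_sample"] >= moves.iloc[i]["onset_sample"])
        ]
        if len(orig_rest) == 0:
            continue
        rest = orig_rest.iloc[0]
        rest_on = max(mv[3], int(rest["onset_sample"]))
        next_on = (refined[i + 1][2] if i + 1 < len(refined)
                   else int(rest["offset_sample"]))
        rest_off = min(int(rest["offset_sample"]), next_on)
        if rest_off > rest_on:
            rows.append((int(rest["trial_id"]), REST, rest_on, rest_off,
                         mv[1], False))
    out = pd.DataFrame(
        rows,
        columns=["trial_id", "modality", "onset_sample", "offset_sample",
                 "preceding_modality", "flag"],
    )
    return out.sort_values("onset_sample").reset_index(drop=True)
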