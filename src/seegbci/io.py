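"""Readers and writers: BIDS-style events/electrodes tables, recordings, run logs.

Events and electrodes follow the iEEG-BIDS tsv column conventions (``onset``/
``duration``/``trial_type``; ``name``/``x``/``y``/``z``/``group``) so real
BIDS exports can be swapped in.  Recordings are stored as a raw array with a
JSON sidecar plus the channel table; sessions serialize to a single JSON
document with a config echo.  All writers round-trip through their readers.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .closed_loop import FeedbackConfig, NormalizerParams, RunLog, TrialOutcome
from .containers import Recording
from .montage import BipolarMontage

__all__ = [
    "write_events",
    "read_events",
    "write_electrodes",
    "save_recording",
    "load_recording",
    "write_montage",
    "write_screening_map",
    "read_screening_map",
    "save_session",
    "load_session",
    "read_edf",
]


def write_events(trials: pd.DataFrame, fs: float, path: str | Path) -> None:
    """Write a trial table as a BIDS-style events.tsv (onsets in seconds)."""
    out = pd.DataFrame(
        {
            "onset": trials["onset_sample"] / fs,
            "duration": (trials["offset_sample"] - trials["onset_sample"]) / fs,
            "trial_type": trials["modality"],
            "trial_id": trials["trial_id"],
            "preceding_modality": trials["preceding_modality"].fillna("n/a"),
        }
    )
    if "flag" in trials.columns:
        out["flag"] = trials["flag"].astype(bool)
    out.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events(path: str | Path, fs: float) -> pd.DataFrame:
    """Read an events.tsv back into a sample-indexed trial table."""
    t = pd.read_csv(path, sep="\t", na_values=["n/a"])
    trials = pd.DataFrame(
        {
            "trial_id": t["trial_id"].astype(int),
            "modality": t["trial_type"],
            "onset_sample": np.round(t["onset"] * fs).astype(int),
            "offset_sample": np.round((t["onset"] + t["duration"]) * fs).astype(int),
            "preceding_modality": t["preceding_modality"],
        }
    )
    if "flag" in t.columns:
        trials["flag"] = t["flag"].astype(bool)
    return trials


def write_electrodes(channels: pd.DataFrame, path: str | Path) -> None:
    """Write sEEG contact positions as a BIDS-style electrodes.tsv."""
    seeg = channels[channels["type"] == "seeg"] if "type" in channels.columns else channels
    out = pd.DataFrame(
        {
            "name": seeg["channel_id"],
            "x": seeg["x"],
            "y": seeg["y"],
            "z": seeg["z"],
            "group": seeg["lead_id"],
        }
    )
    out.to_csv(path, sep="\t", index=False, na_rep="n/a")


def save_recording(rec: Recording, outdir: str | Path, stem: str = "recording") -> None:
    """Store a recording: <stem>.npy array, <stem>.json sidecar, <stem>_channels.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.save(outdir / f"{stem}.npy", rec.data)
    (outdir / f"{stem}.json").write_text(
        json.dumps({"fs": rec.fs, "units": "uV", "n_channels": rec.data.shape[0],
                    "n_samples": rec.data.shape[1]}, indent=1)
    )
    rec.channels.to_csv(outdir / f"{stem}_channels.tsv", sep="\t", index=False)


def load_recording(outdir: str | Path, stem: str = "recording") -> Recording:
    outdir = Path(outdir)
    meta = json.loads((outdir / f"{stem}.json").read_text())
    data = np.load(outdir / f"{stem}.npy")
    channels = pd.read_csv(outdir / f"{stem}_channels.tsv", sep="\t",
                           keep_default_na=False, na_values=[""])
    return Recording(data, meta["fs"], channels)


def write_montage(montage: BipolarMontage, path: str | Path) -> None:
    """Export bipolar pairs as tsv (channel_id, anode, cathode, x, y, z)."""
    montage.pairs.to_csv(path, sep="\t", index=False)


def write_screening_map(screening_map: pd.DataFrame, path: str | Path) -> None:
    screening_map.to_csv(path, index=False)


def read_screening_map(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_session(
    logs: list[RunLog], cfg: FeedbackConfig, path: str | Path,
    extra: dict | None = None
) -> None:
    """Serialize a feedback session (config echo + per-trial records) to JSON."""
    doc = {
        "config": asdict(cfg),
        "extra": extra or {},
        "runs": [
            {
                "run_index": lg.run_index,
                "adaptive": lg.adaptive,
                "normalizer": {"P0": lg.params.P0, "g": lg.params.g},
                "trials": [
                    {
                        "target": t.target,
                        "result": t.result,
                        "trajectory": [round(float(v), 6) for v in t.trajectory],
                        "powers": [float(v) for v in t.powers],
                    }
                    for t in lg.trials
                ],
            }
            for lg in logs
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_session(path: str | Path) -> tuple[list[RunLog], FeedbackConfig, dict]:
    doc = json.loads(Path(path).read_text())
    cfg = FeedbackConfig(**{**doc["config"],
                            "band": tuple(doc["config"]["band"])})
    logs = [
        RunLog(
            run_index=r["run_index"],
            adaptive=r["adaptive"],
            params=NormalizerParams(**r["normalizer"]),
            trials=[
                TrialOutcome(
                    target=t["target"],
                    result=t["result"],
                    trajectory=np.asarray(t["trajectory"], dtype=float),
                    powers=np.asarray(t["powers"], dtype=float),
                )
                for t in r["trials"]
            ],
        )
        for r in doc["runs"]
    ]
    return logs, cfg, doc.get("extra", {})


def read_edf(path: str | Path) -> Recording:
    """Import an EDF recording (optional; requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF import requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    channels = pd.DataFrame(
        {
            "channel_id": raw.ch_names,
            "type": "seeg",
            "lead_id": "",
            "contact_index": 0,
            "segment_index": 0,
            "x": np.nan, "y": np.nan, "z": np.nan,
            "tissue": "", "somatotopy": "none",
        }
    )
    return Recording(data, raw.info["sfreq"], channels)
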