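"""Synthetic sEEG/EMG generator, task schedules, subject models and the cohort table.

The generator emulates the statistical structure that broadband motor mapping
assumes: 1/f-distributed background local field potentials, a movement-locked
multiplicative increase of broadband (>= 65 Hz) power on somatotopically tuned
channels, suppression of a low-frequency oscillation during movement, 60/120 Hz
line noise, and burst-like surface EMG that rectifies cleanly.  Everything is
seeded and bit-reproducible.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    CONTACT_PITCH_MM,
    MODALITIES,
    REST,
    ChannelMeta,
    Recording,
    channel_frame,
    validate_trial_table,
)

__all__ = [
    "SignalModelParams",
    "SubjectModel",
    "make_lead",
    "make_task_schedule",
    "simulate_recording",
    "make_cohort_fixture",
    "sample_band_power",
]


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass
class SignalModelParams:
    """Generative parameters of one synthetic sEEG recording.

    Broadband modulation multiplies the *power* of the shaped-noise component
    above ``broadband_split_hz`` by ``broadband_gain_active`` on a channel
    during that channel's somatotopic movement trials (gain 1 elsewhere and
    on untuned channels).  Amplitudes are in µV; the background is scaled to
    ``background_scale_uv`` RMS.
    """

    onef_exponent: float = 2.0
    broadband_gain_active: float = 3.0
    broadband_split_hz: float = 65.0
    ramp_s: float = 0.1
    osc_freq_hz: float = 20.0
    osc_amp: float = 5.0
    osc_suppression: float = 0.5  # amplitude factor during movement
    line_noise_amp: float = 0.5
    background_scale_uv: float = 10.0
    emg_burst_rate: float = 1.0  # movement repetitions per second
    emg_lead_in_s: float = 0.15  # EMG burst lag after cue onset
    emg_burst_amp: float = 50.0
    emg_baseline_amp: float = 1.0
    noise_seed: int = 0

    def validate(self) -> None:
        if self.broadband_gain_active < 1:
            raise ValueError("broadband_gain_active must be >= 1")
        for name in ("osc_amp", "line_noise_amp", "background_scale_uv",
                     "emg_burst_amp", "emg_baseline_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SubjectModel:
    """Lognormal band-power model of one BCI subject.

    Log band power in the control channel is normal with state-dependent
    mean: ``rest_log_mean`` at rest, ``active_log_mean`` during engagement.
    ``learning_rate`` adds to the active mean per completed run, growing the
    standardized separation d' = (active - rest) / pooled sd across a session,
    the signature of feedback learning.
    """

    rest_log_mean: float = 0.0
    rest_log_sd: float = 0.5
    active_log_mean: float = 1.0
    active_log_sd: float = 0.5
    reaction_latency_s: float = 0.3
    learning_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rest_log_sd <= 0 or self.active_log_sd <= 0:
            raise ValueError("log-power standard deviations must be positive")

    @property
    def pooled_sd(self) -> float:
        return float(np.sqrt((self.rest_log_sd**2 + self.active_log_sd**2) / 2.0))

    def dprime(self, run_index: int = 0) -> float:
        """Standardized active/rest separation at a given run."""
        sep = self.active_log_mean + self.learning_rate * run_index - self.rest_log_mean
        return float(sep / self.pooled_sd)

    @classmethod
    def from_dprime(
        cls,
        dprime: float,
        log_sd: float = 0.5,
        learning_rate: float = 0.0,
        seed: int = 0,
        reaction_latency_s: float = 0.3,
    ) -> "SubjectModel":
        return cls(
            rest_log_mean=0.0,
            rest_log_sd=log_sd,
            active_log_mean=dprime * log_sd,
            active_log_sd=log_sd,
            learning_rate=learning_rate,
            seed=seed,
            reaction_latency_s=reaction_latency_s,
        )


# --------------------------------------------------------------------------
# electrode layouts
# --------------------------------------------------------------------------

def make_lead(
    lead_id: str,
    n_contacts: int = 10,
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0),
    segment_breaks: tuple[int, ...] = (),
    somatotopy_map: dict[int, str] | None = None,
    tissue: str = "gray",
) -> list[ChannelMeta]:
    """Build ChannelMeta for one depth lead.

    Contacts are laid at the standard pitch along ``direction`` from
    ``origin_mm``.  ``segment_breaks`` lists the last 1-based contact index of
    each segment but the final one (e.g. ``(5,)`` splits 10 contacts into
    1-5 / 6-10).  ``somatotopy_map`` assigns a modality to chosen contact
    indices; unlisted contacts are 'none'.
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    somatotopy_map = somatotopy_map or {}
    breaks = sorted(segment_breaks)
    metas = []
    for i in range(1, n_contacts + 1):
        seg = 1 + sum(i > b for b in breaks)
        pos = np.asarray(origin_mm, dtype=float) + (i - 1) * CONTACT_PITCH_MM * d
        metas.append(
            ChannelMeta(
                channel_id=f"{lead_id}{i}",
                lead_id=lead_id,
                contact_index=i,
                segment_index=seg,
                position_mm=tuple(pos),
                tissue=tissue,
                somatotopy=somatotopy_map.get(i, "none"),
            )
        )
    return metas


# --------------------------------------------------------------------------
# task schedule
# --------------------------------------------------------------------------

def make_task_schedule(
    n_per_modality: int = 20,
    trial_s: float = 3.0,
    rest_s: float = 3.0,
    fs: float = 1200.0,
    seed: int = 0,
    modalities: tuple[str, ...] = MODALITIES,
) -> pd.DataFrame:
    """Shuffled block design: each movement trial followed by a rest interval.

    Movement trials of every modality are shuffled into random order by
    ``seed``; a rest row follows each movement row and is annotated with the
    movement type it follows (``preceding_modality``), which downstream
    screening uses to control post-movement rebound effects.
    """
    if n_per_modality < 1:
        raise ValueError("n_per_modality must be >= 1")
    if trial_s <= 0 or rest_s <= 0:
        raise ValueError("trial_s and rest_s must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    rng = np.random.default_rng(seed)
    movements = np.repeat(list(modalities), n_per_modality)
    movements = movements[rng.permutation(movements.size)]

    trial_len = int(round(trial_s * fs))
    rest_len = int(round(rest_s * fs))
    rows = []
    t = 0
    tid = 0
    for mod in movements:
        rows.append((tid, str(mod), t, t + trial_len, None))
        tid += 1
        t += trial_len
        rows.append((tid, REST, t, t + rest_len, str(mod)))
        tid += 1
        t += rest_len
    trials = pd.DataFrame(
        rows,
        columns=["trial_id", "modality", "onset_sample", "offset_sample",
                 "preceding_modality"],
    )
    validate_trial_table(trials)
    return trials


# --------------------------------------------------------------------------
# signal synthesis
# --------------------------------------------------------------------------

def _raised_cosine_gate(n: int, intervals: list[tuple[int, int]],
                        ramp: int) -> np.ndarray:
    """0/1 gate over ``n`` samples, 1 inside intervals, raised-cosine edges."""
    gate = np.zeros(n)
    for on, off in intervals:
        on, off = max(on, 0), min(off, n)
        if off <= on:
            continue
        gate[on:off] = 1.0
        r = min(ramp, (off - on) // 2)
        if r > 0:
            edge = 0.5 * (1 - np.cos(np.pi * np.arange(r) / r))
            gate[on:on + r] = np.minimum(gate[on:on + r], edge)
            gate[off - r:off] = np.minimum(gate[off - r:off], edge[::-1])
    return gate


def _shaped_noise(rng: np.random.Generator, n: int, fs: float,
                  exponent: float, split_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """1/f^exponent noise split into below/at-or-above ``split_hz`` components.

    Shaping is done in the frequency domain (|H(f)| proportional to
    f**(-exponent/2)), which gives direct control of the power-law slope.
    The two returned components sum to the full background; each has the
    correct spectrum restricted to its band.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    spec = spec * shape
    hi_mask = freqs >= split_hz
    low = np.fft.irfft(spec * ~hi_mask, n=n)
    high = np.fft.irfft(spec * hi_mask, n=n)
    return low, high


def simulate_recording(
    layout: list[ChannelMeta],
    schedule: pd.DataFrame,
    params: SignalModelParams,
    fs: float = 1200.0,
    duration_s: float | None = None,
    include_emg: bool = True,
    emg_modalities: tuple[str, ...] | None = None,
) -> Recording:
    """Synthesize a motor-screening recording for an electrode layout.

    Each sEEG channel is 1/f background noise; channels with a somatotopy
    label get their >= 65 Hz component multiplied (in power) by
    ``broadband_gain_active`` during that modality's movement trials, with
    100 ms raised-cosine ramps at trial edges, and their low-frequency
    oscillation suppressed during the same trials.  One surface-EMG channel
    per movement modality carries rectifiable 25-400 Hz bursts aligned to
    that modality's trials (onset lagging the cue by ``emg_lead_in_s``).
    """
    if not layout:
        raise ValueError("layout must be non-empty")
    params.validate()
    validate_trial_table(schedule)
    sched_end = int(schedule["offset_sample"].max())
    if duration_s is None:
        n = sched_end
        duration_s = n / fs
    else:
        n = int(round(duration_s * fs))
        if sched_end > n:
            raise ValueError(
                f"schedule ends at sample {sched_end} but recording has only {n}"
            )
    rng = np.random.default_rng(params.noise_seed)
    ramp = int(round(params.ramp_s * fs))
    t = np.arange(n) / fs

    mod_intervals: dict[str, list[tuple[int, int]]] = {}
    for mod in set(schedule["modality"]) - {REST}:
        sub = schedule[schedule["modality"] == mod]
        mod_intervals[mod] = list(
            zip(sub["onset_sample"].astype(int), sub["offset_sample"].astype(int))
        )

    traces = []
    for meta in layout:
        low, high = _shaped_noise(rng, n, fs, params.onef_exponent,
                                  params.broadband_split_hz)
        # scale the full background to the target RMS
        bg = low + high
        scale = params.background_scale_uv / max(np.std(bg), 1e-30)
        low, high = low * scale, high * scale

        if meta.somatotopy != "none" and meta.somatotopy in mod_intervals:
            gate = _raised_cosine_gate(n, mod_intervals[meta.somatotopy], ramp)
            amp_gain = np.sqrt(params.broadband_gain_active)
            env = 1.0 + (amp_gain - 1.0) * gate
            osc_env = 1.0 - (1.0 - params.osc_suppression) * gate
        else:
            env = 1.0
            osc_env = 1.0

        sig = low + env * high
        if params.osc_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            sig = sig + params.osc_amp * osc_env * np.sin(
                2 * np.pi * params.osc_freq_hz * t + phase
            )
        if params.line_noise_amp > 0:
            sig = sig + params.line_noise_amp * np.sin(2 * np.pi * 60.0 * t)
            sig = sig + 0.5 * params.line_noise_amp * np.sin(2 * np.pi * 120.0 * t)
        traces.append(sig)

    table = channel_frame(layout, type_="seeg")

    if include_emg:
        if emg_modalities is None:
            emg_modalities = tuple(m for m in MODALITIES if m in mod_intervals)
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, [25.0, min(400.0, 0.45 * fs)], btype="bandpass",
                     fs=fs, output="sos")
        lead_in = int(round(params.emg_lead_in_s * fs))
        emg_rows = []
        for mod in emg_modalities:
            carrier = sosfiltfilt(sos, rng.standard_normal(n))
            carrier /= max(np.std(carrier), 1e-30)
            env = np.full(n, params.emg_baseline_amp)
            for on, off in mod_intervals.get(mod, []):
                b0, b1 = min(on + lead_in, off), off
                if b1 <= b0:
                    continue
                tt = np.arange(b1 - b0) / fs
                # paced repetitions: amplitude dips between movement cycles
                cyc = 0.3 + 0.7 * np.abs(np.sin(np.pi * params.emg_burst_rate * tt))
                env[b0:b1] = params.emg_burst_amp * cyc
            traces.append(carrier * env)
            emg_rows.append(mod)
        emg_table = pd.DataFrame(
            {
                "channel_id": [f"EMG_{m}" for m in emg_rows],
                "type": "emg",
                "lead_id": "",
                "contact_index": 0,
                "segment_index": 0,
                "x": np.nan, "y": np.nan, "z": np.nan,
                "tissue": "none",
                "somatotopy": emg_rows,
            }
        )
        table = pd.concat([table, emg_table], ignore_index=True)

    return Recording(np.vstack(traces), fs, table)


# --------------------------------------------------------------------------
# cohort fixture
# --------------------------------------------------------------------------

def make_cohort_fixture() -> pd.DataFrame:
    """Load the transcribed cohort table (one row per BCI condition).

    The table records, per subject and feedback condition: demographics,
    implant extent, BCI modality code, control-channel anatomy, overt and
    imagery accuracies over the final two runs (percent, null when the task
    was not performed) and the number of learning trials before those runs.
    ``anatomy_is_pcg_exact`` is True only for a bare precentral-gyrus label,
    excluding composite ('PCG/CIN') and boundary ('PCG*') codes.
    """
    ref = importlib.resources.files("seegbci").joinpath("data/cohort_table.csv")
    with importlib.resources.as_file(ref) as path:
        table = pd.read_csv(
            path,
            dtype={"modality_code": "string", "anatomy_code": "string"},
        )
    table["anatomy_is_pcg_exact"] = table["anatomy_is_pcg_exact"].astype(bool)
    return table


# --------------------------------------------------------------------------
# subject band-power draws
# --------------------------------------------------------------------------

def sample_band_power(
    model: SubjectModel,
    state: str,
    run_index: int = 0,
    rng: np.random.Generator | None = None,
    size: int | None = None,
):
    """Draw control-channel band power from the subject's state distribution.

    Lognormal draw: log power is normal with the state's mean/sd, the active
    mean shifted up by ``learning_rate * run_index``.  ``state`` is 'active'
    or 'passive'.
    """
    if run_index < 0:
        raise ValueError("run_index must be >= 0")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    if state == "active":
        mu = model.active_log_mean + model.learning_rate * run_index
        sd = model.active_log_sd
    elif state == "passive":
        mu = model.rest_log_mean
        sd = model.rest_log_sd
    else:
        raise ValueError("state must be 'active' or 'passive'")
    draw = np.exp(mu + sd * rng.standard_normal(size))
    return draw if size is not None else float(draw)
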