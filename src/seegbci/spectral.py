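"""Trial spectra, global-mean normalization, band power, and the online AR estimator.

Per-trial spectra are Welch averaged periodograms (1 s Hann windows, 0.5 s
overlap) on a 1-300 Hz grid at 1 Hz.  Because local field potentials follow a
1/f power law, each trial's spectrum is normalized by the arithmetic-mean
spectrum over all trials so that low frequencies do not dominate statistics.
The online estimator mirrors the real-time pathway: a Burg autoregressive fit
per sliding window, integrated over the feedback band at the 10 Hz update rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import welch as _scipy_welch
from statsmodels.regression.linear_model import burg as _burg

from .containers import REST, Recording, validate_trial_table

__all__ = [
    "FREQ_LO_HZ",
    "FREQ_HI_HZ",
    "SpectraSet",
    "ArEstimatorConfig",
    "welch_psd",
    "trial_spectra",
    "normalize_psds",
    "band_power",
    "ar_band_power",
    "stream_band_power",
]

FREQ_LO_HZ = 1.0
FREQ_HI_HZ = 300.0
WELCH_WINDOW_S = 1.0
WELCH_OVERLAP = 0.5


@dataclass
class SpectraSet:
    """Per-trial PSDs on the 1-300 Hz grid with modality labels."""

    psd: np.ndarray  # trials x frequencies
    freqs: np.ndarray
    trial_labels: np.ndarray
    normalized: bool = False
    trial_ids: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.psd.shape[0]


@dataclass
class ArEstimatorConfig:
    """Autoregressive band-power estimator settings.

    Order-16 Burg fits on 0.5 s windows, integrated over the feedback band,
    updated at 10 Hz — the conventional real-time BCI configuration scale.
    """

    order: int = 16
    window_s: float = 0.5
    band: tuple[float, float] = (90.0, 130.0)
    update_rate: float = 10.0

    def validate(self, fs: float) -> None:
        if self.order < 2:
            raise ValueError("AR order must be >= 2")
        if self.window_s * fs <= 2 * self.order:
            raise ValueError(
                f"window of {self.window_s} s at fs={fs} is too short for "
                f"order {self.order} (need window_s * fs > 2 * order)"
            )
        lo, hi = self.band
        if not (FREQ_LO_HZ <= lo < hi <= FREQ_HI_HZ):
            raise ValueError(f"band {self.band} outside the {FREQ_LO_HZ}-{FREQ_HI_HZ} Hz grid")


def welch_psd(segment: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD on the 1-300 Hz grid at 1 Hz resolution.

    1 s Hann windows with 0.5 s overlap give exactly 1 Hz bin spacing; only
    full windows are used, so a segment must be at least 1 s long.  Returns
    ``(freqs, psd)`` with inclusive endpoints 1 and 300 Hz.
    """
    segment = np.asarray(segment, dtype=float)
    nperseg = int(round(WELCH_WINDOW_S * fs))
    if segment.size < nperseg:
        raise ValueError(
            f"segment of {segment.size} samples shorter than one "
            f"{WELCH_WINDOW_S} s window ({nperseg} samples)"
        )
    freqs, psd = _scipy_welch(
        segment,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(WELCH_OVERLAP * fs)),
        detrend=False,
        scaling="density",
    )
    keep = (freqs >= FREQ_LO_HZ - 1e-9) & (freqs <= FREQ_HI_HZ + 1e-9)
    return freqs[keep], psd[keep]


def trial_spectra(
    trace: np.ndarray,
    fs: float,
    trials: pd.DataFrame,
    drop_flagged: bool = True,
) -> SpectraSet:
    """Per-trial Welch spectra for one channel.

    Trials shorter than one Welch window (or flagged by epoching) are dropped.
    """
    validate_trial_table(trials)
    if drop_flagged and "flag" in trials.columns:
        trials = trials[~trials["flag"].astype(bool)]
    nperseg = int(round(WELCH_WINDOW_S * fs))
    psds, labels, ids = [], [], []
    freqs = None
    for r in trials.itertuples():
        seg = trace[int(r.onset_sample):int(r.offset_sample)]
        if seg.size < nperseg:
            continue  # trial shorter than one window: dropped
        freqs, p = welch_psd(seg, fs)
        psds.append(p)
        labels.append(r.modality)
        ids.append(r.trial_id)
    if not psds:
        raise ValueError("no trial long enough for one Welch window")
    return SpectraSet(
        psd=np.vstack(psds),
        freqs=freqs,
        trial_labels=np.asarray(labels),
        trial_ids=np.asarray(ids),
    )


def normalize_psds(s: SpectraSet) -> SpectraSet:
    """Divide every trial's PSD by the arithmetic mean PSD over all trials.

    Movement and rest trials are pooled in the mean; after normalization the
    column means are exactly 1, removing the 1/f dominance of low frequencies.
    """
    if s.n_trials < 2:
        raise ValueError("need >= 2 trials to normalize")
    mean = s.psd.mean(axis=0)
    if np.any(mean == 0):
        raise ValueError("global mean PSD has zero bins; cannot normalize")
    return replace(s, psd=s.psd / mean, normalized=True)


def band_power(psd: np.ndarray, freqs: np.ndarray, lo: float, hi: float) -> float:
    """Mean PSD over the closed band [lo, hi] (inclusive endpoints).

    With the 1 Hz grid, [65, 115] averages 51 bins.  Works on raw or
    normalized spectra; accepts a 1-D PSD.
    """
    if lo > hi:
        raise ValueError("band lo must be <= hi")
    if lo < freqs[0] - 1e-9 or hi > freqs[-1] + 1e-9:
        raise ValueError(f"band [{lo}, {hi}] outside grid "
                         f"[{freqs[0]}, {freqs[-1]}] Hz")
    keep = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    return float(np.mean(np.asarray(psd)[..., keep], axis=-1))


def trial_band_powers(
    s: SpectraSet, lo: float, hi: float, log: bool = True
) -> np.ndarray:
    """Per-trial mean power over [lo, hi], natural-log-transformed by default.

    The log transform stabilizes the multiplicative variance of band power;
    downstream statistics (signed r², d') consume these values.
    """
    keep = (s.freqs >= lo - 1e-9) & (s.freqs <= hi + 1e-9)
    if not keep.any():
        raise ValueError(f"band [{lo}, {hi}] has no bins on the grid")
    vals = s.psd[:, keep].mean(axis=1)
    return np.log(vals) if log else vals


def ar_band_power(
    window: np.ndarray, fs: float, cfg: ArEstimatorConfig | None = None
) -> float:
    """Band power from a Burg autoregressive fit of one window.

    The AR(order) model spectrum — a parametric stand-in for the FFT with a
    limited number of coefficients — is evaluated on the 1 Hz grid and
    averaged over ``cfg.band``.  Returns 0 for an (all-zero) degenerate
    window.
    """
    cfg = cfg or ArEstimatorConfig()
    cfg.validate(fs)
    x = np.asarray(window, dtype=float)
    expected = int(round(cfg.window_s * fs))
    if x.size != expected:
        raise ValueError(f"window has {x.size} samples, expected {expected}")
    if np.allclose(x, 0.0):
        return 0.0
    ar_coefs, sigma2 = _burg(x - x.mean(), order=cfg.order, demean=False)
    lo, hi = cfg.band
    f = np.arange(lo, hi + 0.5, 1.0)
    # one-sided model PSD: 2*sigma2 / (fs * |1 - sum a_k z^-k|^2)
    k = np.arange(1, cfg.order + 1)
    z = np.exp(-2j * np.pi * np.outer(f / fs, k))
    denom = np.abs(1.0 - z @ ar_coefs) ** 2
    psd = 2.0 * sigma2 / (fs * denom)
    return float(psd.mean())


def stream_band_power(
    rec: Recording,
    channels: list[str],
    cfg: ArEstimatorConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window AR band power at the update rate, averaged over channels.

    Windows of ``cfg.window_s`` advance by ``1/cfg.update_rate``; if several
    control channels are given their band powers are arithmetic-mean combined,
    as when multiple channels drive the cursor.  Returns ``(times, powers)``
    with times marking window ends.
    """
    cfg = cfg or ArEstimatorConfig()
    cfg.validate(rec.fs)
    if not channels:
        raise ValueError("need at least one channel")
    hop = int(round(rec.fs / cfg.update_rate))
    wlen = int(round(cfg.window_s * rec.fs))
    starts = np.arange(0, rec.n_samples - wlen + 1, hop)
    traces = [rec.get(c) for c in channels]
    powers = np.empty(starts.size)
    for i, s0 in enumerate(starts):
        vals = [ar_band_power(tr[s0:s0 + wlen], rec.fs, cfg) for tr in traces]
        powers[i] = float(np.mean(vals))
    times = (starts + wlen) / rec.fs
    return times, powers
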