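"""Signed-r² motor screening: channel-by-modality maps and control-channel choice.

For every bipolar channel and movement modality, the per-trial normalized
broadband (65-115 Hz) powers of movement trials are compared with those of
rest trials that *followed the same movement type* (controlling post-movement
beta-rebound cross-effects).  The statistic is the signed point-biserial r²:
the squared correlation between trial-wise band power and class membership,
carrying the sign of the movement-minus-rest mean difference.  Channels with
the highest values become feedback control channels.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import REST, Recording, validate_trial_table
from .spectral import normalize_psds, trial_band_powers, trial_spectra

__all__ = [
    "signed_r2",
    "pair_rest_trials",
    "screen_channels",
    "select_control_channels",
    "permutation_null",
]

logger = logging.getLogger(__name__)

BROADBAND_HZ = (65.0, 115.0)


def signed_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Signed squared point-biserial correlation between two sample groups.

    Pools the samples, correlates them with group membership, squares, and
    applies the sign of ``mean(a) - mean(b)`` — positive when group ``a``
    (movement) sits above group ``b`` (rest).  Returns 0 for degenerate input
    (zero pooled variance).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need >= 2 samples")
    x = np.concatenate([a, b])
    y = np.concatenate([np.ones(a.size), np.zeros(b.size)])
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        logger.debug("signed_r2: zero pooled variance; returning 0")
        return 0.0
    r = float((xc * yc).sum() / denom)
    return float(np.sign(a.mean() - b.mean()) * r**2)


def pair_rest_trials(
    trials: pd.DataFrame, modality: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Movement trials of a modality and the rest trials that follow that type.

    Rest rows whose ``preceding_modality`` differs (or is undefined, e.g. a
    run-initial rest) are excluded, so post-movement rebound from *other*
    movement types never contaminates the comparison.
    """
    validate_trial_table(trials)
    if "flag" in trials.columns:
        trials = trials[~trials["flag"].astype(bool)]
    moves = trials[trials["modality"] == modality]
    rests = trials[
        (trials["modality"] == REST)
        & (trials["preceding_modality"] == modality)
    ]
    if len(rests) == 0:
        raise ValueError(
            f"no rest trials follow {modality!r} movements; "
            "record more trials or check the schedule"
        )
    return moves, rests


def screen_channels(
    rec: Recording,
    trials: pd.DataFrame,
    band: tuple[float, float] = BROADBAND_HZ,
    log: bool = True,
) -> pd.DataFrame:
    """Signed-r² map over (bipolar channel, modality).

    Per channel: Welch spectra of every trial, global-mean normalization
    (movement and rest pooled), band power per trial (natural-log scale by
    default), then the signed r² over the rebound-controlled pairing.
    Returns a tidy frame (channel_id, modality, signed_r2, n_move, n_rest).
    """
    modalities = sorted(set(trials["modality"]) - {REST})
    rows = []
    for cid in rec.channel_ids():
        spectra = trial_spectra(rec.get(cid), rec.fs, trials)
        spectra = normalize_psds(spectra)
        powers = trial_band_powers(spectra, band[0], band[1], log=log)
        kept = set(spectra.trial_ids)
        n_dropped = len(trials) - len(kept)
        if n_dropped:
            logger.info("channel %s: dropped %d short/flagged trials", cid, n_dropped)
        for mod in modalities:
            moves, rests = pair_rest_trials(trials, mod)
            mi = np.isin(spectra.trial_ids, moves["trial_id"])
            ri = np.isin(spectra.trial_ids, rests["trial_id"])
            rows.append(
                (cid, mod, signed_r2(powers[mi], powers[ri]),
                 int(mi.sum()), int(ri.sum()))
            )
    return pd.DataFrame(
        rows, columns=["channel_id", "modality", "signed_r2", "n_move", "n_rest"]
    )


def select_control_channels(
    screening_map: pd.DataFrame, modality: str, k: int = 1
) -> list[str]:
    """Top-k channels by signed r² for one modality.

    Ranked by signed value descending (largest positive first); ties broken
    by channel id in lexicographic order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = screening_map[screening_map["modality"] == modality]
    if k > len(sub):
        raise ValueError(f"k={k} exceeds the {len(sub)} screened channels")
    ranked = sub.sort_values(
        ["signed_r2", "channel_id"], ascending=[False, True], kind="mergesort"
    )
    return list(ranked["channel_id"].head(k))


def permutation_null(
    rec: Recording,
    trials: pd.DataFrame,
    band: tuple[float, float] = BROADBAND_HZ,
    n_perm: int = 200,
    seed: int = 0,
    log: bool = True,
) -> np.ndarray:
    """Null distribution of the map-wide max |signed r²| under label shuffles.

    Diagnostic only (channel selection applies no multiple-testing
    correction): per permutation, movement/rest labels are shuffled within
    each modality's pairing and the maximum |r²| across channels and
    modalities recorded.
    """
    rng = np.random.default_rng(seed)
    modalities = sorted(set(trials["modality"]) - {REST})
    per_channel = {}
    for cid in rec.channel_ids():
        spectra = normalize_psds(trial_spectra(rec.get(cid), rec.fs, trials))
        powers = trial_band_powers(spectra, band[0], band[1], log=log)
        per_channel[cid] = (spectra.trial_ids, powers)
    maxima = np.empty(n_perm)
    for p in range(n_perm):
        best = 0.0
        for mod in modalities:
            moves, rests = pair_rest_trials(trials, mod)
            for cid, (tids, powers) in per_channel.items():
                mi = np.isin(tids, moves["trial_id"])
                ri = np.isin(tids, rests["trial_id"])
                pooled = np.concatenate([powers[mi], powers[ri]])
                n_a = int(mi.sum())
                perm = rng.permutation(pooled.size)
                best = max(best, abs(signed_r2(pooled[perm[:n_a]],
                                               pooled[perm[n_a:]])))
        maxima[p] = best
    return maxima
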