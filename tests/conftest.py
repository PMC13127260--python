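import numpy as np
import pytest

from seegbci import (
    SignalModelParams,
    apply_montage,
    build_bipolar_montage,
    make_lead,
    make_task_schedule,
    simulate_recording,
)

FS = 1200.0


@pytest.fixture(scope="session")
def hand_schedule():
    """20 hand trials (3 s) interleaved with 3 s rests at 1200 Hz."""
    return make_task_schedule(n_per_modality=20, fs=FS, seed=3, modalities=("hand",))


@pytest.fixture(scope="session")
def planted_layout():
    """Two 8-contact leads; contact L1-3 is a hand-modulated site."""
    return make_lead("L1", 8, somatotopy_map={3: "hand"}) + make_lead(
        "L2", 8, origin_mm=(0.0, 10.0, 0.0)
    )


@pytest.fixture(scope="session")
def planted_recording(hand_schedule, planted_layout):
    """Screening recording with one gain-3 broadband channel planted."""
    params = SignalModelParams(broadband_gain_active=3.0, noise_seed=3)
    return simulate_recording(planted_layout, hand_schedule, params, fs=FS)


@pytest.fixture(scope="session")
def planted_bipolar(planted_recording, planted_layout):
    montage = build_bipolar_montage(planted_layout)
    seeg_ids = [m.channel_id for m in planted_layout]
    return apply_montage(planted_recording.pick(seeg_ids), montage)


def brute_force_pairs(metas):
    """Independent enumeration of bipolar pairs straight from the rule."""
    pairs = set()
    for a in metas:
        for b in metas:
            if (
                a.lead_id == b.lead_id
                and a.segment_index == b.segment_index
                and b.contact_index == a.contact_index + 1
            ):
                pairs.add((a.channel_id, b.channel_id))
    return pairs


def oracle_welch(segment, fs):
    """Brute-force Welch: explicit Hann-windowed periodogram averaging.

    Written independently of the implementation: manual segmentation at a
    0.5 s hop, periodic Hann window, one-sided density scaling, mean over
    windows, restricted to 1-300 Hz.
    """
    segment = np.asarray(segment, float)
    nper = int(fs)
    hop = nper // 2
    w = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(nper) / nper)
    n_win = (segment.size - nper) // hop + 1
    psds = []
    for k in range(n_win):
        seg = segment[k * hop:k * hop + nper] * w
        spec = np.abs(np.fft.rfft(seg)) ** 2
        psd = 2.0 * spec / (fs * np.sum(w**2))
        psd[0] /= 2.0
        psd[-1] /= 2.0
        psds.append(psd)
    mean_psd = np.mean(psds, axis=0)
    freqs = np.fft.rfftfreq(nper, 1 / fs)
    keep = (freqs >= 1.0) & (freqs <= 300.0)
    return freqs[keep], mean_psd[keep], n_win


def oracle_pearson(x, y):
    """Explicit-sum Pearson correlation (no library call)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    num = n * sxy - sx * sy
    den = np.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den


def oracle_signed_r2(a, b):
    """Explicit-sum signed point-biserial r-squared."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    x = np.concatenate([a, b])
    y = np.concatenate([np.ones(a.size), np.zeros(b.size)])
    r = oracle_pearson(x, y)
    sign = 1.0 if a.sum() / a.size >= b.sum() / b.size else -1.0
    return sign * r * r
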