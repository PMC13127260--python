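"""Closed-loop 1-D cursor BCI: normalizer calibration, control law, trial logic.

Cursor velocity is a linear function of instantaneous control-channel band
power: v = kappa * g * (P - P0), where the threshold P0 is the mean and the
gain g the inverse standard deviation of a 30 s calibration buffer, both
adapted continuously during run 0 and frozen afterwards.  Power above P0
drives the cursor toward the top (active) target, power below toward the
bottom (passive) target.  A trial ends with a hit (cued target region
entered), a miss (opposite region entered) or a timeout (5 s elapsed;
excluded from accuracy).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .synthetic import SubjectModel

__all__ = [
    "NormalizerParams",
    "FeedbackConfig",
    "TrialOutcome",
    "RunLog",
    "calibrate_normalizer",
    "control_velocity",
    "run_trial",
    "run_session",
    "learning_curve",
]

ACTIVE_TARGET = "active_top"
PASSIVE_TARGET = "passive_bottom"

#: lag-1 autocorrelation of successive online band-power estimates; 0.5 s
#: windows advancing at 10 Hz share 80% of their samples
STREAM_RHO = 0.8

DPRIME_CAP = 50.0


@dataclass
class NormalizerParams:
    """Control-law threshold (P0) and gain (g, inverse power units)."""

    P0: float
    g: float


@dataclass
class FeedbackConfig:
    """Timing and geometry of the feedback task.

    Defaults: 90-130 Hz feedback band, 10 Hz cursor updates, 2 s target
    display, 5 s trial timeout, 3 s inter-trial interval, 2 min runs, a 30 s
    normalizer buffer, and top/bottom target bands each occupying 10% of the
    screen.  ``kappa`` scales velocity so one standard deviation above P0
    moves the cursor 0.1 screen units per second.
    """

    band: tuple[float, float] = (90.0, 130.0)
    update_rate: float = 10.0
    target_display_s: float = 2.0
    trial_timeout_s: float = 5.0
    iti_s: float = 3.0
    run_length_s: float = 120.0
    target_fraction: float = 0.1
    buffer_s: float = 30.0
    kappa: float = 0.1

    def validate(self) -> None:
        for name in ("update_rate", "target_display_s", "trial_timeout_s",
                     "iti_s", "run_length_s", "buffer_s", "kappa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.target_fraction < 0.5):
            raise ValueError("target_fraction must be in (0, 0.5)")


@dataclass
class TrialOutcome:
    """One feedback trial: cued target, result, and the recorded traces."""

    target: str
    result: str  # hit | miss | timeout
    trajectory: np.ndarray  # cursor positions after each update, in [0, 1]
    powers: np.ndarray  # control power at each update

    @property
    def n_steps(self) -> int:
        return self.powers.size

    def mean_power(self) -> float:
        return float(self.powers.mean())


@dataclass
class RunLog:
    """One 2-minute run: its trials and the normalizer that produced them."""

    run_index: int
    trials: list[TrialOutcome]
    params: NormalizerParams
    adaptive: bool = False

    def count(self, result: str) -> int:
        return sum(t.result == result for t in self.trials)


def calibrate_normalizer(buffer: np.ndarray, ddof: int = 0) -> NormalizerParams:
    """P0 = buffer mean, g = 1 / sqrt(buffer variance).

    Population variance (``ddof=0``) by default, the usual convention for
    streaming moment estimates; switchable.
    """
    x = np.asarray(buffer, dtype=float)
    if x.size == 0:
        raise ValueError("calibration buffer is empty")
    if x.size <= ddof or np.ptp(x) == 0:
        raise ValueError("calibration buffer has zero variance")
    var = float(x.var(ddof=ddof))
    if var <= 0 or not np.isfinite(var):
        raise ValueError("calibration buffer has zero variance")
    return NormalizerParams(P0=float(x.mean()), g=1.0 / np.sqrt(var))


def control_velocity(P: float, params: NormalizerParams, kappa: float = 0.1) -> float:
    """Linear control law: v = kappa * g * (P - P0), screen units per second."""
    return kappa * params.g * (P - params.P0)


def run_trial(
    power_source: Callable[[], float],
    params: NormalizerParams,
    cfg: FeedbackConfig,
    target: str,
) -> TrialOutcome:
    """Run one trial: integrate the cursor at the update rate until decision.

    The cursor starts at screen centre (0.5), moves by v / update_rate each
    step (clipped to [0, 1]), and the trial ends when it enters the cued
    region (hit), the opposite region (miss) or the timeout elapses.
    ``params`` is read every step, so an adapting normalizer mutated by the
    power source takes effect immediately.
    """
    if target not in (ACTIVE_TARGET, PASSIVE_TARGET):
        raise ValueError(f"unknown target {target!r}")
    cfg.validate()
    dt = 1.0 / cfg.update_rate
    n_max = int(round(cfg.trial_timeout_s * cfg.update_rate))
    top_edge = 1.0 - cfg.target_fraction
    bottom_edge = cfg.target_fraction
    pos = 0.5
    traj = np.empty(n_max)
    powers = np.empty(n_max)
    result = "timeout"
    steps = n_max
    for i in range(n_max):
        P = power_source()
        pos = float(np.clip(pos + control_velocity(P, params, cfg.kappa) * dt,
                            0.0, 1.0))
        traj[i] = pos
        powers[i] = P
        in_top = pos >= top_edge - 1e-9
        in_bottom = pos <= bottom_edge + 1e-9
        if in_top or in_bottom:
            reached = ACTIVE_TARGET if in_top else PASSIVE_TARGET
            result = "hit" if reached == target else "miss"
            steps = i + 1
            break
    return TrialOutcome(target, result, traj[:steps].copy(), powers[:steps].copy())


class _PowerStream:
    """Simulated control-channel band power with estimator-window memory.

    Log power is normal around the subject's state mean; the unit-variance
    innovation follows an AR(1) process with lag-1 correlation
    ``STREAM_RHO``, reflecting the sample overlap of successive sliding
    estimator windows.  State changes take effect after the subject's
    reaction latency.
    """

    def __init__(self, model: SubjectModel, rng: np.random.Generator,
                 update_rate: float, rho: float = STREAM_RHO):
        self.model = model
        self.rng = rng
        self.rho = rho
        self.u = rng.standard_normal()
        lat = max(int(round(model.reaction_latency_s * update_rate)), 0)
        self._pending = deque(["passive"] * lat, maxlen=lat) if lat else None
        self.run_index = 0

    def step(self, state: str) -> float:
        if self._pending is not None:
            self._pending.append(state)
            state = self._pending[0]
        self.u = self.rho * self.u + np.sqrt(1 - self.rho**2) * self.rng.standard_normal()
        if state == "active":
            mu = self.model.active_log_mean + self.model.learning_rate * self.run_index
            sd = self.model.active_log_sd
        else:
            mu = self.model.rest_log_mean
            sd = self.model.rest_log_sd
        return float(np.exp(mu + sd * self.u))


def _balanced_targets(n: int, rng: np.random.Generator) -> list[str]:
    """Pseudo-random target order balanced within consecutive pairs.

    Randomizing the order inside each active/passive pair keeps every prefix
    balanced to +-1, so a run that ends mid-list still has equal counts.
    """
    seq = []
    for _ in range((n + 1) // 2):
        pair = [ACTIVE_TARGET, PASSIVE_TARGET]
        if rng.random() < 0.5:
            pair.reverse()
        seq += pair
    return seq[:n]


def run_session(
    model: SubjectModel,
    cfg: FeedbackConfig | None = None,
    n_runs: int = 5,
    seed: int | None = None,
) -> list[RunLog]:
    """Simulate a full feedback session: one adaptive run, then scoring runs.

    Run 0 alternates active/passive targets while the normalizer is
    recomputed every update from the trailing 30 s of power samples; its
    final state is frozen and reused for all later runs, whose targets are
    pseudo-randomized with balanced counts.  Each run packs as many trials
    (2 s target display + up-to-5 s trial + 3 s ITI) as fit in 2 minutes.
    """
    cfg = cfg or FeedbackConfig()
    cfg.validate()
    if n_runs < 2:
        raise ValueError("need n_runs >= 2 (one adaptive run plus scoring runs)")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    stream = _PowerStream(model, rng, cfg.update_rate)
    buffer: deque = deque(maxlen=int(round(cfg.buffer_s * cfg.update_rate)))
    params = NormalizerParams(P0=0.0, g=0.0)  # inert until the buffer fills

    def adapt_step(state: str) -> float:
        P = stream.step(state)
        buffer.append(P)
        if len(buffer) >= 2:
            arr = np.asarray(buffer)
            var = arr.var()
            if var > 0:
                params.P0 = float(arr.mean())
                params.g = float(1.0 / np.sqrt(var))
        return P

    logs: list[RunLog] = []
    n_disp = int(round(cfg.target_display_s * cfg.update_rate))
    n_iti = int(round(cfg.iti_s * cfg.update_rate))
    max_trials = int(np.ceil(cfg.run_length_s /
                             (cfg.target_display_s + cfg.iti_s))) + 1

    for run_index in range(n_runs):
        adaptive = run_index == 0
        stream.run_index = run_index
        step_fn = adapt_step if adaptive else stream.step
        if adaptive:
            targets = [(ACTIVE_TARGET, PASSIVE_TARGET)[i % 2]
                       for i in range(max_trials)]
        else:
            targets = _balanced_targets(max_trials, rng)
        elapsed = 0.0
        trials: list[TrialOutcome] = []
        for target in targets:
            if elapsed >= cfg.run_length_s:
                break
            for _ in range(n_disp):  # target display: subject still at rest
                step_fn("passive")
            state = "active" if target == ACTIVE_TARGET else "passive"
            outcome = run_trial(lambda: step_fn(state), params, cfg, target)
            for _ in range(n_iti):
                step_fn("passive")
            trials.append(outcome)
            elapsed += (cfg.target_display_s + outcome.n_steps / cfg.update_rate
                        + cfg.iti_s)
        logs.append(RunLog(run_index, trials, replace(params), adaptive))
    return logs


def learning_curve(
    logs: list[RunLog],
    per_run_sd: bool = False,
    dprime_cap: float = DPRIME_CAP,
) -> "pd.DataFrame":
    """Per-run target-class separation (d') and accuracy across a session.

    For each non-adaptive run: mean log trial power per target class, the
    class-mean separation standardized to d', and hit accuracy.  By default
    the within-class standard deviation is pooled across all scoring runs of
    the session (trial-power variance is stationary; a per-run sd from a
    handful of trials is estimation-noise-dominated and would swamp the
    learning signal) — ``per_run_sd=True`` switches to run-local pooling.
    d' is capped at ``dprime_cap`` when the spread degenerates; runs with
    fewer than two trials of either class get a null d'.
    """
    import pandas as pd

    scoring = [lg for lg in logs if not lg.adaptive]
    if len(scoring) < 2:
        raise ValueError("need >= 2 non-adaptive runs for a learning curve")

    groups = []  # (run, class) -> log trial powers
    for lg in scoring:
        a = np.array([np.log(t.mean_power()) for t in lg.trials
                      if t.target == ACTIVE_TARGET])
        p = np.array([np.log(t.mean_power()) for t in lg.trials
                      if t.target == PASSIVE_TARGET])
        groups.append((lg, a, p))

    if not per_run_sd:
        ss = sum(float(((x - x.mean()) ** 2).sum())
                 for _, a, p in groups for x in (a, p) if x.size >= 2)
        dof = sum(x.size - 1 for _, a, p in groups for x in (a, p) if x.size >= 2)
        session_sd = np.sqrt(ss / dof) if dof > 0 else 0.0

    rows = []
    for lg, a, p in groups:
        if a.size >= 2 and p.size >= 2:
            sd = (np.sqrt((a.var(ddof=1) + p.var(ddof=1)) / 2.0)
                  if per_run_sd else session_sd)
            if sd < 1e-12:
                d = float(np.sign(a.mean() - p.mean()) * dprime_cap)
            else:
                d = float(np.clip((a.mean() - p.mean()) / sd,
                                  -dprime_cap, dprime_cap))
        else:
            d = None
        hits, misses = lg.count("hit"), lg.count("miss")
        acc = 100.0 * hits / (hits + misses) if hits + misses else None
        rows.append(
            (lg.run_index, a.size, p.size,
             a.mean() if a.size else None, p.mean() if p.size else None,
             d, acc)
        )
    return pd.DataFrame(
        rows,
        columns=["run_index", "n_active", "n_passive", "mean_log_active",
                 "mean_log_passive", "dprime", "accuracy_pct"],
    )
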