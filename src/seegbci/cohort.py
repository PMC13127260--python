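"""Accuracy metrics, cohort success tallies, and the trials-accuracy correlation.

Accuracy counts hits over decided trials only — timeouts never enter the
denominator — and a feedback condition is *successful* when the mean accuracy
of its final two runs exceeds 80%.  Cohort analytics run over the shipped
condition table (one row per subject x BCI condition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .closed_loop import RunLog

__all__ = [
    "SUCCESS_THRESHOLD_PCT",
    "CohortSummary",
    "run_accuracy",
    "final_two_run_accuracy",
    "cohort_counts",
    "trials_accuracy_correlation",
    "separation_report",
]

SUCCESS_THRESHOLD_PCT = 80.0

CORRELATION_INTERPRETATIONS = (
    "per_condition",
    "per_subject_peak",
    "per_subject_peak_summed_trials",
)


@dataclass
class CohortSummary:
    """Countable facts of the cohort condition table."""

    n_conditions: int
    n_overt_success_conditions: int
    n_subjects: int
    n_subjects_overt_success: int
    pct_subjects_overt_success: float
    n_imagery_conditions: int
    n_imagery_success_conditions: int
    anatomy_pcg_exact: int
    anatomy_pcg_any: int


def run_accuracy(log: RunLog) -> float | None:
    """Hit percentage of one scoring run: 100 * hits / (hits + misses).

    Timed-out trials are excluded from the denominator.  Returns None when no
    trial was decided.  The adaptive calibration run is never scored.
    """
    if log.adaptive:
        raise ValueError("run 0 is the adaptive calibration run and is not scored")
    hits, misses = log.count("hit"), log.count("miss")
    if hits + misses == 0:
        return None
    return 100.0 * hits / (hits + misses)


def final_two_run_accuracy(logs: list[RunLog]) -> float:
    """Mean accuracy of the last two scorable (non-adaptive) runs."""
    accs = [a for lg in logs if not lg.adaptive
            if (a := run_accuracy(lg)) is not None]
    if len(accs) < 2:
        raise ValueError("need at least 2 scorable runs")
    return float(np.mean(accs[-2:]))


def cohort_counts(
    table: pd.DataFrame, threshold: float = SUCCESS_THRESHOLD_PCT
) -> CohortSummary:
    """Tally conditions and subjects meeting the success criterion.

    Success is strict: accuracy > ``threshold`` percent.  A subject counts as
    overt-successful when any of their conditions succeeds.  Anatomy is
    tallied both as exact precentral-gyrus labels and as any label containing
    'PCG' (composite and boundary codes included).
    """
    required = {"subject_id", "overt_accuracy_pct", "imagery_accuracy_pct",
                "anatomy_code", "anatomy_is_pcg_exact", "learning_trials"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    bad = table[table["overt_accuracy_pct"].notna()
                & ~table["overt_accuracy_pct"].between(0, 100)]
    if len(bad):
        raise ValueError(f"accuracy outside [0, 100] in rows {list(bad.index)}")

    overt = table[table["overt_accuracy_pct"].notna()]
    imagery = table[table["imagery_accuracy_pct"].notna()]
    success = overt[overt["overt_accuracy_pct"] > threshold]
    subjects = overt["subject_id"].unique()
    success_subjects = success["subject_id"].unique()
    anatomy = overt["anatomy_code"].fillna("")
    return CohortSummary(
        n_conditions=len(overt),
        n_overt_success_conditions=len(success),
        n_subjects=len(subjects),
        n_subjects_overt_success=len(success_subjects),
        pct_subjects_overt_success=100.0 * len(success_subjects) / len(subjects)
        if len(subjects) else 0.0,
        n_imagery_conditions=len(imagery),
        n_imagery_success_conditions=int(
            (imagery["imagery_accuracy_pct"] > threshold).sum()
        ),
        anatomy_pcg_exact=int(overt["anatomy_is_pcg_exact"].sum()),
        anatomy_pcg_any=int(anatomy.str.contains("PCG").sum()),
    )


def trials_accuracy_correlation(
    table: pd.DataFrame, interpretation: str = "per_condition"
) -> tuple[float, float]:
    """Pearson correlation of learning-trial counts with imagery accuracy.

    The pairing of the two columns is ambiguous at the cohort level, so three
    interpretations are supported and none privileged:

    - ``per_condition``: every condition with both values is one pair;
    - ``per_subject_peak``: one pair per subject — peak imagery accuracy and
      the learning trials of that peak condition;
    - ``per_subject_peak_summed_trials``: peak imagery accuracy vs the
      subject's learning trials summed over conditions.

    Returns ``(r, p)``; degenerate input (constant column) gives (nan, nan).
    """
    if interpretation not in CORRELATION_INTERPRETATIONS:
        raise ValueError(f"interpretation must be one of {CORRELATION_INTERPRETATIONS}")
    sub = table[table["imagery_accuracy_pct"].notna()
                & table["learning_trials"].notna()]
    if interpretation == "per_condition":
        x = sub["learning_trials"].to_numpy(float)
        y = sub["imagery_accuracy_pct"].to_numpy(float)
    else:
        rows = sub.loc[sub.groupby("subject_id")["imagery_accuracy_pct"].idxmax()]
        y = rows["imagery_accuracy_pct"].to_numpy(float)
        if interpretation == "per_subject_peak":
            x = rows["learning_trials"].to_numpy(float)
        else:
            x = sub.groupby("subject_id")["learning_trials"].sum().loc[
                rows["subject_id"]].to_numpy(float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def separation_report(logs: list[RunLog]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trial raster and per-run summary of a feedback session.

    Returns ``(trials, runs)``: a tidy per-trial table (run, trial, target,
    mean control power, outcome) suitable for a learning raster, and the
    per-run d'/accuracy table.  The d' is computed from trial powers even in
    runs where no trial was decided.
    """
    from .closed_loop import learning_curve

    scoring = [lg for lg in logs if not lg.adaptive]
    if not scoring:
        raise ValueError("no scorable runs to report")
    rows = []
    for lg in scoring:
        for i, t in enumerate(lg.trials):
            rows.append((lg.run_index, i, t.target, t.mean_power(), t.result))
    trials = pd.DataFrame(
        rows, columns=["run_index", "trial", "target", "mean_power", "outcome"]
    )
    if len(scoring) >= 2:
        runs = learning_curve(logs)
    else:
        lg = scoring[0]
        runs = learning_curve([lg, lg]).iloc[:1]
    return trials, runs
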