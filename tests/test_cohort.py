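"""Accuracy rules, cohort tallies over the condition table, correlations."""

import numpy as np
import pandas as pd
import pytest

from seegbci import (
    NormalizerParams,
    RunLog,
    SubjectModel,
    TrialOutcome,
    cohort_counts,
    final_two_run_accuracy,
    make_cohort_fixture,
    run_accuracy,
    run_session,
    separation_report,
    trials_accuracy_correlation,
)
from seegbci.closed_loop import ACTIVE_TARGET, PASSIVE_TARGET

from .conftest import oracle_pearson


def make_log(hits=0, misses=0, timeouts=0, run_index=1, adaptive=False):
    trials = (
        [TrialOutcome(ACTIVE_TARGET, "hit", np.array([1.0]), np.array([2.0]))] * hits
        + [TrialOutcome(ACTIVE_TARGET, "miss", np.array([0.0]), np.array([1.0]))] * misses
        + [TrialOutcome(PASSIVE_TARGET, "timeout", np.array([0.5]), np.array([1.5]))] * timeouts
    )
    return RunLog(run_index, trials, NormalizerParams(1.0, 1.0), adaptive)


class TestRunAccuracy:
    def test_timeouts_excluded(self):
        assert run_accuracy(make_log(8, 2, 2)) == 80.0

    def test_all_timeouts_null(self):
        assert run_accuracy(make_log(0, 0, 5)) is None

    def test_all_hits(self):
        assert run_accuracy(make_log(12)) == 100.0

    def test_adaptive_run_rejected(self):
        with pytest.raises(ValueError, match="adaptive"):
            run_accuracy(make_log(5, adaptive=True))


class TestFinalTwoRuns:
    def test_mean_of_last_two(self):
        logs = [make_log(5, adaptive=True, run_index=0),
                make_log(19, 1, run_index=1),   # 95%
                make_log(10, 0, run_index=2)]   # 100%
        assert final_two_run_accuracy(logs) == 97.5

    def test_only_last_two_count(self):
        logs = [make_log(0, adaptive=True, run_index=0),
                make_log(1, 1, run_index=1),    # 50%
                make_log(9, 1, run_index=2),    # 90%
                make_log(10, 0, run_index=3)]   # 100%
        assert final_two_run_accuracy(logs) == 95.0

    def test_unscorable_runs_skipped(self):
        logs = [make_log(10, 0, run_index=1),
                make_log(0, 0, 5, run_index=2),
                make_log(8, 2, run_index=3)]
        assert final_two_run_accuracy(logs) == 90.0

    def test_too_few_runs(self):
        with pytest.raises(ValueError):
            final_two_run_accuracy([make_log(10)])


class TestCohortCounts:
    def test_fixture_golden_tallies(self):
        """Hand-verified counts of the shipped condition table."""
        s = cohort_counts(make_cohort_fixture())
        assert s.n_conditions == 31
        assert s.n_overt_success_conditions == 29
        assert s.n_subjects == 26
        assert s.n_subjects_overt_success == 25
        assert s.pct_subjects_overt_success == pytest.approx(96.15, abs=0.01)
        assert s.n_imagery_conditions == 24
        assert s.n_imagery_success_conditions == 11
        assert s.anatomy_pcg_exact == 19
        assert s.anatomy_pcg_any == 23  # 19 exact + 3 PCG/CIN + 1 PCG*

    def test_empty_table(self):
        empty = make_cohort_fixture().iloc[0:0]
        s = cohort_counts(empty)
        assert s.n_conditions == 0 and s.n_subjects == 0

    def test_malformed_rows_rejected(self):
        t = make_cohort_fixture().copy()
        t.loc[t.index[1], "overt_accuracy_pct"] = 150.0
        with pytest.raises(ValueError, match="0, 100"):
            cohort_counts(t)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            cohort_counts(pd.DataFrame({"subject_id": [1]}))


class TestCorrelation:
    def test_linear_pair(self):
        t = pd.DataFrame({
            "subject_id": range(10),
            "learning_trials": np.arange(10.0),
            "imagery_accuracy_pct": 50 + 5 * np.arange(10.0),
        })
        r, p = trials_accuracy_correlation(t)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_constant_column_degenerate(self):
        t = pd.DataFrame({
            "subject_id": range(5),
            "learning_trials": np.full(5, 3.0),
            "imagery_accuracy_pct": np.arange(5.0),
        })
        r, p = trials_accuracy_correlation(t)
        assert np.isnan(r) and np.isnan(p)

    @pytest.mark.parametrize(
        "interp", ["per_condition", "per_subject_peak", "per_subject_peak_summed_trials"]
    )
    def test_fixture_matches_explicit_sum_oracle(self, interp):
        """Every pairing interpretation agrees with the hand-rolled Pearson."""
        t = make_cohort_fixture()
        r, _ = trials_accuracy_correlation(t, interp)
        sub = t[t["imagery_accuracy_pct"].notna() & t["learning_trials"].notna()]
        if interp == "per_condition":
            x = sub["learning_trials"].to_numpy(float)
            y = sub["imagery_accuracy_pct"].to_numpy(float)
        else:
            rows = sub.loc[sub.groupby("subject_id")["imagery_accuracy_pct"].idxmax()]
            y = rows["imagery_accuracy_pct"].to_numpy(float)
            if interp == "per_subject_peak":
                x = rows["learning_trials"].to_numpy(float)
            else:
                x = sub.groupby("subject_id")["learning_trials"].sum().loc[
                    rows["subject_id"]].to_numpy(float)
        assert r == pytest.approx(oracle_pearson(x, y), abs=1e-12)

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(4, 30)
            t = pd.DataFrame({
                "subject_id": np.arange(n),
                "learning_trials": rng.integers(0, 150, n).astype(float),
                "imagery_accuracy_pct": rng.uniform(30, 100, n),
            })
            r, _ = trials_accuracy_correlation(t)
            assert r == pytest.approx(
                oracle_pearson(t["learning_trials"], t["imagery_accuracy_pct"]),
                abs=1e-12,
            )

    def test_too_few_pairs(self):
        t = pd.DataFrame({
            "subject_id": [1, 2],
            "learning_trials": [1.0, 2.0],
            "imagery_accuracy_pct": [50.0, 60.0],
        })
        with pytest.raises(ValueError):
            trials_accuracy_correlation(t)

    def test_unknown_interpretation(self):
        with pytest.raises(ValueError):
            trials_accuracy_correlation(make_cohort_fixture(), "per_run")


class TestSeparationReport:
    def test_session_raster_shape(self):
        logs = run_session(SubjectModel.from_dprime(2.0), n_runs=3, seed=0)
        trials, runs = separation_report(logs)
        assert set(trials.columns) == {"run_index", "trial", "target", "mean_power", "outcome"}
        assert len(trials) == sum(len(lg.trials) for lg in logs[1:])
        assert len(runs) == 2

    def test_single_run_log(self):
        logs = [make_log(0, adaptive=True, run_index=0), make_log(4, 1, run_index=1)]
        _, runs = separation_report(logs)
        assert len(runs) == 1

    def test_all_timeout_run_keeps_dprime(self):
        lg = RunLog(1, [
            TrialOutcome(ACTIVE_TARGET, "timeout", np.array([0.5]), np.array([4.0 + i]))
            for i in range(3)
        ] + [
            TrialOutcome(PASSIVE_TARGET, "timeout", np.array([0.5]), np.array([1.0 + 0.1 * i]))
            for i in range(3)
        ], NormalizerParams(1.0, 1.0))
        trials, runs = separation_report([lg])
        assert runs["accuracy_pct"].isna().all()
        assert np.isfinite(runs["dprime"]).all()

    def test_nothing_to_report(self):
        with pytest.raises(ValueError):
            separation_report([make_log(1, adaptive=True, run_index=0)])

    def test_learning_separation_strictly_ordered_most_seeds(self):
        """Feedback learning separates target-wise power run over run."""
        mono = 0
        for seed in range(20):
            m = SubjectModel.from_dprime(0.5, learning_rate=0.5)
            logs = run_session(m, n_runs=6, seed=seed)
            _, runs = separation_report(logs)
            d = runs["dprime"].to_numpy(float)
            mono += bool(np.all(np.isfinite(d)) and np.all(np.diff(d) > 0))
        assert mono >= 14  # >= 70% of 20 seeded sessions
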