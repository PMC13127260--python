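"""Normalizer calibration, control law, trial mechanics, and session dynamics."""

import numpy as np
import pytest

from seegbci import (
    FeedbackConfig,
    NormalizerParams,
    RunLog,
    SubjectModel,
    TrialOutcome,
    calibrate_normalizer,
    control_velocity,
    learning_curve,
    run_session,
    run_trial,
)
from seegbci.closed_loop import ACTIVE_TARGET, PASSIVE_TARGET


class TestCalibration:
    def test_two_point_closed_form(self):
        p = calibrate_normalizer([1.0, 3.0])
        assert p.P0 == 2.0
        assert p.g == 1.0  # population variance of {1,3} is 1

    def test_sample_variance_switch(self):
        p = calibrate_normalizer([1.0, 3.0], ddof=1)
        assert p.g == pytest.approx(1 / np.sqrt(2))

    def test_constant_buffer_errors(self):
        with pytest.raises(ValueError, match="variance"):
            calibrate_normalizer(np.full(10, 4.2))

    def test_lognormal_recovery(self):
        """P0 and g recover the generative mean and 1/sd from a 300-sample buffer."""
        mu, sigma = 0.5, 0.4
        rng = np.random.default_rng(0)
        buf = rng.lognormal(mu, sigma, size=300)
        dist_mean = np.exp(mu + sigma**2 / 2)
        dist_sd = dist_mean * np.sqrt(np.exp(sigma**2) - 1)
        p = calibrate_normalizer(buf)
        assert abs(p.P0 - dist_mean) < 3 * dist_sd / np.sqrt(300)
        assert p.g == pytest.approx(1 / dist_sd, rel=0.10)


class TestControlLaw:
    PARAMS = NormalizerParams(P0=5.0, g=2.0)

    def test_threshold_is_stationary(self):
        assert control_velocity(5.0, self.PARAMS) == 0.0

    def test_unit_z_gives_kappa(self):
        assert control_velocity(5.0 + 1 / 2.0, self.PARAMS, kappa=0.1) == pytest.approx(0.1)

    def test_linearity(self):
        d = 0.3
        assert control_velocity(5.0 + 2 * d, self.PARAMS) == pytest.approx(
            2 * control_velocity(5.0 + d, self.PARAMS)
        )


class TestRunTrial:
    CFG = FeedbackConfig()
    P = NormalizerParams(P0=10.0, g=0.5)

    def test_unit_z_hits_top_at_four_seconds(self):
        out = run_trial(lambda: 12.0, self.P, self.CFG, ACTIVE_TARGET)  # P0 + 1/g
        assert out.result == "hit"
        assert out.n_steps == 40  # 0.4 screen units at 0.1 units/s, 10 Hz
        assert out.trajectory[-1] >= 0.9 - 1e-9

    def test_threshold_power_times_out(self):
        out = run_trial(lambda: 10.0, self.P, self.CFG, ACTIVE_TARGET)
        assert out.result == "timeout"
        assert out.n_steps == 50
        np.testing.assert_allclose(out.trajectory, 0.5)

    def test_low_power_misses_top_target(self):
        out = run_trial(lambda: 4.0, self.P, self.CFG, ACTIVE_TARGET)
        assert out.result == "miss"

    @pytest.mark.parametrize("z", [1.0, 1.25, 2.5])
    def test_traversal_time_closed_form(self, z):
        """Time to hit matches (distance)/(kappa*g*(P-P0)) within one update step."""
        out = run_trial(lambda: 10.0 + z / 0.5, self.P, self.CFG, ACTIVE_TARGET)
        predicted = 0.4 / (0.1 * z)
        assert out.result == "hit"
        assert abs(out.n_steps / 10.0 - predicted) <= 0.1 + 1e-9

    def test_deterministic_source_bit_reproducible(self):
        rng = np.random.default_rng(3)
        powers = list(10.0 + rng.standard_normal(50))
        outs = [run_trial(iter(powers.copy()).__next__, self.P, self.CFG, ACTIVE_TARGET)
                for _ in range(2)]
        np.testing.assert_array_equal(outs[0].trajectory, outs[1].trajectory)
        assert outs[0].result == outs[1].result

    def test_unknown_target(self):
        with pytest.raises(ValueError):
            run_trial(lambda: 0.0, self.P, self.CFG, "left")


class TestRunSession:
    def test_needs_two_runs(self):
        with pytest.raises(ValueError):
            run_session(SubjectModel(), n_runs=1)

    def test_run_zero_is_adaptive_and_calibrated(self):
        logs = run_session(SubjectModel.from_dprime(2.0), n_runs=3, seed=0)
        assert logs[0].adaptive and not logs[1].adaptive
        assert logs[1].params.g > 0
        # frozen thereafter
        assert logs[1].params == logs[2].params

    def test_trial_budget_bound(self):
        logs = run_session(SubjectModel.from_dprime(6.0), n_runs=3, seed=1)
        for lg in logs:
            assert len(lg.trials) <= 24  # floor(120 / (2 s display + 3 s ITI))

    def test_targets_balanced(self):
        logs = run_session(SubjectModel.from_dprime(1.0), n_runs=3, seed=2)
        for lg in logs[1:]:
            n_a = sum(t.target == ACTIVE_TARGET for t in lg.trials)
            n_p = sum(t.target == PASSIVE_TARGET for t in lg.trials)
            assert abs(n_a - n_p) <= 1

    def test_session_determinism(self):
        a = run_session(SubjectModel.from_dprime(2.0), n_runs=3, seed=5)
        b = run_session(SubjectModel.from_dprime(2.0), n_runs=3, seed=5)
        for la, lb in zip(a, b):
            for ta, tb in zip(la.trials, lb.trials):
                np.testing.assert_array_equal(ta.powers, tb.powers)

    def test_ideal_subject_is_perfect(self):
        """d'=6 gives 100% accuracy on every scoring run across seeds."""
        from seegbci import run_accuracy

        for seed in (0, 1, 2):
            logs = run_session(SubjectModel.from_dprime(6.0), n_runs=4, seed=seed)
            for lg in logs[1:]:
                assert run_accuracy(lg) == 100.0

    def test_accuracy_monotone_in_dprime(self):
        """Pooled accuracy over 30 seeds is non-decreasing in model d'."""
        from seegbci import run_accuracy

        pooled = []
        for d in (0.0, 1.0, 2.0, 4.0):
            hits = misses = 0
            for seed in range(30):
                logs = run_session(SubjectModel.from_dprime(d), n_runs=3, seed=seed)
                for lg in logs[1:]:
                    hits += lg.count("hit")
                    misses += lg.count("miss")
            pooled.append(100 * hits / (hits + misses))
        assert all(b >= a for a, b in zip(pooled, pooled[1:]))


class TestLearningCurve:
    def _dummy_log(self, run_index, active_powers, passive_powers, adaptive=False):
        trials = [
            TrialOutcome(ACTIVE_TARGET, "hit", np.array([1.0]), np.array([p]))
            for p in active_powers
        ] + [
            TrialOutcome(PASSIVE_TARGET, "hit", np.array([0.0]), np.array([p]))
            for p in passive_powers
        ]
        return RunLog(run_index, trials, NormalizerParams(1.0, 1.0), adaptive)

    def test_learning_rate_gives_positive_dprime_slope(self):
        slopes = []
        for seed in range(10):
            m = SubjectModel.from_dprime(0.5, learning_rate=0.5)
            logs = run_session(m, n_runs=5, seed=seed)
            lc = learning_curve(logs)
            d = lc["dprime"].to_numpy(float)
            slopes.append(np.polyfit(np.arange(d.size), d, 1)[0])
        assert np.mean(slopes) > 0
        assert np.mean(np.array(slopes) > 0) >= 0.9

    def test_no_learning_flat_dprime(self):
        slopes = []
        for seed in range(10):
            logs = run_session(SubjectModel.from_dprime(1.5), n_runs=5, seed=seed)
            d = learning_curve(logs)["dprime"].to_numpy(float)
            slopes.append(np.polyfit(np.arange(d.size), d, 1)[0])
        t = np.mean(slopes) / (np.std(slopes, ddof=1) / np.sqrt(len(slopes)))
        assert abs(t) < 3.0

    def test_degenerate_sd_capped(self):
        logs = [
            self._dummy_log(0, [], [], adaptive=True),
            self._dummy_log(1, [np.e**2, np.e**2], [1.0, 1.0]),
            self._dummy_log(2, [np.e**2, np.e**2], [1.0, 1.0]),
        ]
        lc = learning_curve(logs)
        assert (lc["dprime"] == 50.0).all()

    def test_few_trials_gives_null_dprime(self):
        logs = [
            self._dummy_log(0, [], [], adaptive=True),
            self._dummy_log(1, [2.0], [1.0, 1.1]),
            self._dummy_log(2, [2.0, 2.1], [1.0, 1.1]),
        ]
        lc = learning_curve(logs)
        assert lc["dprime"].isna().iloc[0]
        assert np.isfinite(lc["dprime"].iloc[1])

    def test_needs_two_scoring_runs(self):
        with pytest.raises(ValueError):
            learning_curve([self._dummy_log(0, [1.0], [2.0], adaptive=True)])
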