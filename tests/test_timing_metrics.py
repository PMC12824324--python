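"""Per-trial metrics, peri-reward histogram analyses and splits."""

import numpy as np
import pytest

from chronobeh.config import LEVER_FS
from chronobeh import timing_metrics as tm
from chronobeh.lever_events import TrialRecord


def _trial(joint_onset=1.0, joint_end=2.0, reward=1.75, required=750.0, index=0, lag=0.0):
    return TrialRecord(
        trial_index=index,
        required_interval_ms=required,
        n_attempts=1,
        effort_s=joint_end - joint_onset,
        reward_time=reward,
        joint_onset=joint_onset,
        joint_end=joint_end,
        onset_lag_abs_s=lag,
    )


class TestOvershoot:
    def test_overshoot_is_release_minus_reward(self):
        t = _trial(joint_onset=1.0, reward=1.75, joint_end=1.9)
        assert tm.overshoot_ms(t) == pytest.approx(150.0)
        assert tm.overshoot_ms(_trial(joint_end=1.75)) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "over,req,frac", [(150.0, 750.0, 0.2), (150.0, 1250.0, 0.12), (0.0, 900.0, 0.0)]
    )
    def test_overshoot_fraction_examples(self, over, req, frac):
        assert tm.overshoot_fraction(over, req) == pytest.approx(frac)

    def test_overshoot_fraction_rejects_bad_input(self):
        with pytest.raises(ValueError):
            tm.overshoot_fraction(-1.0, 750.0)
        with pytest.raises(ValueError):
            tm.overshoot_fraction(10.0, 0.0)

    def test_median_overshoot_recovers_planned_margin(self, clean_two_interval):
        session, (left, right, attempts, rewards, trials) = clean_two_interval
        med = np.median([tm.overshoot_ms(t) for t in trials])
        assert med == pytest.approx(session.ground_truth["planned_margin_ms"], abs=2.0)


class TestInterlimbCorrelation:
    times = np.arange(0, 2, 1 / LEVER_FS)

    def test_perfect_and_inverted_correlation(self):
        x = np.interp(self.times, [0, 0.5, 1.5, 2.0], [0, 2.6, 2.6, 0])
        assert tm.interlimb_correlation(self.times, x, x, (0.0, 2.0)) == pytest.approx(1.0)
        assert tm.interlimb_correlation(self.times, x, -x + 3.0, (0.0, 2.0)) == pytest.approx(-1.0)

    def test_matches_direct_covariance_formula(self):
        rng = np.random.default_rng(8)
        x = np.interp(self.times, [0, 0.3, 1.7, 2.0], [0, 2.6, 2.6, 0])
        y = x + rng.normal(0, 0.1, x.size)
        r = tm.interlimb_correlation(self.times, x, y, (0.0, 2.0))
        # independent direct computation from sums
        n = x.size
        cov = (x * y).sum() / n - x.mean() * y.mean()
        oracle = cov / np.sqrt(
            ((x**2).sum() / n - x.mean() ** 2) * ((y**2).sum() / n - y.mean() ** 2)
        )
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_window_is_missing_not_zero(self):
        flat = np.ones_like(self.times)
        x = np.linspace(0, 1, self.times.size)
        assert np.isnan(tm.interlimb_correlation(self.times, flat, x, (0.0, 2.0)))


class TestBmov:
    def test_equal_lags_give_zero(self):
        assert tm.bmov([0.2, 0.2, 0.2]) == pytest.approx(0.0, abs=1e-12)

    def test_two_point_sample_variance(self):
        assert tm.bmov([0.1, 0.3]) == pytest.approx(0.02)

    def test_folded_normal_large_sample_variance(self):
        rng = np.random.default_rng(3)
        sigma = 0.05
        lags = np.abs(rng.normal(0, sigma, 20000))
        assert tm.bmov(lags) == pytest.approx(sigma**2 * (1 - 2 / np.pi), rel=0.05)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            tm.bmov([0.1])


class TestSpeed:
    def test_constant_trace_zero_speed(self):
        speed, mx = tm.movement_speed(np.ones(100))
        assert mx == 0.0 and np.all(speed == 0)

    def test_linear_ramp_uniform_speed(self):
        # 2.6 cm in 0.2 s -> 13 cm/s in every 4 ms bin
        ramp = np.linspace(0, 2.6, 51)
        speed, mx = tm.movement_speed(ramp)
        assert np.allclose(speed, 13.0)
        assert mx == pytest.approx(13.0)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            tm.movement_speed([1.0])


class TestTrajectoryVariability:
    def test_identical_traces_give_zero(self):
        traces = np.tile(np.linspace(0, 3, 50), (5, 1))
        assert tm.trajectory_variability(traces) == 0.0

    def test_gaussian_jitter_gives_normal_iqr(self):
        rng = np.random.default_rng(9)
        sigma = 0.2
        template = np.linspace(0, 2.6, 200)
        traces = template + rng.normal(0, sigma, (400, 200))
        assert tm.trajectory_variability(traces) == pytest.approx(1.349 * sigma, rel=0.05)

    def test_invariant_to_common_offset(self):
        rng = np.random.default_rng(10)
        traces = rng.normal(0, 1, (10, 50))
        assert tm.trajectory_variability(traces + 5.0) == pytest.approx(
            tm.trajectory_variability(traces)
        )


class TestEfficiency:
    def test_perfect_trials_timing(self):
        trials = [_trial(reward=10.0 * (k + 1), index=k) for k in range(100)]
        out = tm.efficiency_metrics(trials)
        assert out["time_to_100_trials_s"] == pytest.approx(1000.0)
        assert out["attempts_per_reward"] == 1.0

    def test_empty_session_reports_missing(self):
        out = tm.efficiency_metrics([])
        assert out["trials_per_session"] == 0
        assert np.isnan(out["time_to_100_trials_s"])

    def test_failed_attempts_raise_attempts_and_effort(self):
        t = _trial()
        t.n_attempts = 2
        t.effort_s = 0.5 + (0.75 + 0.15)
        out = tm.efficiency_metrics([t, t])
        assert out["attempts_per_reward"] == 2.0
        assert out["effort_per_reward_s"] == pytest.approx(1.4)


class TestPeriRewardHistogram:
    def test_presses_at_reward_fill_single_bin(self):
        h = tm.peri_reward_histogram([10.0], [10.0])
        occupied = np.flatnonzero(h.rate)
        assert occupied.size == 1
        assert h.bin_edges[occupied[0]] == pytest.approx(0.0)

    def test_uniform_pressing_gives_flat_histogram(self):
        rng = np.random.default_rng(5)
        lam = 2.0
        presses = np.sort(rng.uniform(0, 1000, int(lam * 1000)))
        h = tm.peri_reward_histogram(presses, np.arange(40.0, 960.0, 35.0))
        inner = h.rate[2:-2]
        assert inner.mean() == pytest.approx(lam * 1.0, rel=0.05)

    def test_normalization_recovers_total_count(self):
        rng = np.random.default_rng(6)
        rewards = np.arange(30.0, 300.0, 30.0)
        presses = rng.uniform(0, 300, 200)
        h = tm.peri_reward_histogram(presses, rewards)
        rel = (presses[None, :] - rewards[:, None]).ravel()
        expected = np.sum((rel >= -30.0) & (rel < 5.0))
        assert h.rate.sum() * h.n_trials == pytest.approx(expected, abs=1.0)

    def test_empty_press_list_gives_zero_histogram(self):
        h = tm.peri_reward_histogram([], [30.0])
        assert np.all(h.rate == 0)

    def test_auc_zero_and_flat_cases(self):
        h = tm.peri_reward_histogram([], [30.0])
        assert tm.histogram_auc(h) == 0.0
        h.rate = np.ones_like(h.rate) * 0.5
        # flat rate r over the 30 s pre-window integrates to ~30 r
        assert tm.histogram_auc(h) == pytest.approx(0.5 * 29.0, rel=0.01)

    def test_peak_interval_reads_relative_to_previous_reward(self):
        h = tm.peri_reward_histogram([29.5, 59.5], [30.0, 60.0])
        assert tm.peak_interval_s(h) == pytest.approx(29.5, abs=0.5)

    def test_peak_interval_single_spike_maps_to_own_bin(self):
        h = tm.peri_reward_histogram([20.2] * 5, [30.0])
        # bin [-10,-9) holds the spike; its centre is 30 - 9.5 = 20.5
        assert tm.peak_interval_s(h) == pytest.approx(20.5, abs=1e-9)

    def test_peak_interval_all_zero_raises(self):
        h = tm.peri_reward_histogram([], [30.0])
        with pytest.raises(ValueError):
            tm.peak_interval_s(h)


class TestSplits:
    def test_halves_even_and_odd(self):
        trials = [_trial(index=k) for k in range(100)]
        parts = tm.split_trials(trials, "halves")
        assert len(parts["first_half"]) == 50 and len(parts["second_half"]) == 50
        parts = tm.split_trials([_trial(index=k) for k in range(101)], "halves")
        assert len(parts["first_half"]) == 50 and len(parts["second_half"]) == 51

    def test_block_edges_10(self):
        trials = [_trial(index=k) for k in range(40)]
        parts = tm.split_trials(trials, "block_edges_10")
        assert len(parts["block_first10"]) == 20 and len(parts["block_last10"]) == 20
        idx = [t.trial_index for t in parts["block_first10"]]
        assert idx == list(range(10)) + list(range(20, 30))

    def test_splits_partition_disjointly(self):
        trials = [_trial(index=k) for k in range(200)]
        parts = tm.split_trials(trials, "first_last_100")
        ids = [t.trial_index for t in parts["first_100"]] + [
            t.trial_index for t in parts["last_100"]
        ]
        assert len(set(ids)) == 200

    def test_insufficient_trials_rejected(self):
        with pytest.raises(ValueError):
            tm.split_trials([_trial()], "first_last_100")


def test_planned_hold_location_inverts_zero_truncation():
    """Moment-matching recovers the location of a normal left-censored at
    zero (retried short holds)."""
    rng = np.random.default_rng(13)
    m, s = 200.0, 150.0
    x = rng.normal(m, s, 6000)
    x = x[x >= 0]  # censoring: failures are redrawn, never observed
    assert np.mean(x) > m + 10  # the raw mean is visibly biased
    assert tm.planned_hold_location(x) == pytest.approx(m, rel=0.05)
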