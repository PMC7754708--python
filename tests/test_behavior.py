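"""Behavior maps, deceleration events, deltas and the peak-progression test."""

import numpy as np
import pytest

from conftest import make_behavior
from placestim.behavior import (
    BEHAVIOR_BIN_WIDTH,
    BehaviorMap,
    WINDOW_REWARD,
    behavior_spatial_map,
    decel_peak_progression,
    deceleration_events,
    delta_map,
    outcome_delta_vs_control,
    peak_trend_test,
    window_summary,
)
from placestim.errors import AnalysisError
from placestim.session import EpochSet, TrialRecord, build_trial_table


def running_behavior(n_trials=3, speed=20.0, licks_at_cm=(), stop_cm=None):
    """Trials of constant-speed running with licks at given positions."""
    n_per = int(200.0 / speed * 100)
    pos_t = np.minimum((np.arange(n_per) + 0.5) * speed / 100, 199.9)
    pos = np.tile(pos_t, n_trials)
    tid = np.repeat(np.arange(n_trials), n_per)
    licks = []
    for t in range(n_trials):
        for cm in licks_at_cm:
            licks.append(t * n_per + int(np.searchsorted(pos_t, cm)))
    return make_behavior(pos, speed=np.full(pos.size, speed), licks=licks,
                         trial_ids=tid)


class TestBehaviorSpatialMap:
    def test_lick_rate_nonzero_only_where_licked(self):
        beh = running_behavior(licks_at_cm=(165.0, 170.0))
        trials = build_trial_table(beh)
        m = behavior_spatial_map(beh, trials, "lick_rate")
        nz = np.flatnonzero(np.nan_to_num(m.trial_avg) > 0)
        assert set(nz) <= {int(165.0 // BEHAVIOR_BIN_WIDTH),
                           int(170.0 // BEHAVIOR_BIN_WIDTH)}
        assert nz.size >= 1

    def test_occupancy_rows_sum_to_trial_duration(self):
        beh = running_behavior()
        trials = build_trial_table(beh)
        m = behavior_spatial_map(beh, trials, "occupancy")
        for k, t in enumerate(trials):
            dur = t.end_time - t.start_time
            assert np.nansum(m.per_trial[k]) == pytest.approx(dur, rel=0.01)

    def test_lick_counts_conserved_under_binning(self):
        beh = running_behavior(n_trials=4, licks_at_cm=(30.0, 90.0, 165.0))
        trials = build_trial_table(beh)
        m = behavior_spatial_map(beh, trials, "lick_rate")
        total = np.nansum(np.nan_to_num(m.per_trial) * m.occupancy_s)
        assert total == pytest.approx(beh.lick_flags.sum())

    def test_unknown_variable_raises(self):
        beh = running_behavior()
        trials = build_trial_table(beh)
        with pytest.raises(Exception, match="unknown"):
            behavior_spatial_map(beh, trials, "pupil")


class TestDecelerationEvents:
    def test_constant_speed_has_no_events(self):
        beh = make_behavior(np.linspace(0, 199, 3000),
                            speed=np.full(3000, 20.0))
        assert deceleration_events(beh).size == 0

    def test_single_sharp_stop_is_one_event_at_the_stop(self):
        speed = np.full(6000, 20.0)
        speed[3000:3050] = 0.0  # brief stop at t = 30 s
        beh = make_behavior(np.minimum(np.cumsum(speed) / 100, 199.0),
                            speed=speed)
        events = deceleration_events(beh)
        assert events.size == 1
        assert abs(events[0] - 3000) <= 10  # within one 0.1-s interval

    def test_speed_scaling_leaves_event_locations_unchanged(self):
        rng = np.random.default_rng(2)
        speed = 20.0 + np.repeat(rng.normal(0, 2, 60), 100)
        speed[2500:2600] = 0.0
        beh1 = make_behavior(np.full(6000, 50.0), speed=speed)
        beh2 = make_behavior(np.full(6000, 50.0), speed=2 * speed)
        assert np.array_equal(deceleration_events(beh1),
                              deceleration_events(beh2))

    def test_too_little_data_raises(self):
        beh = make_behavior(np.full(500, 50.0))
        with pytest.raises(AnalysisError):
            deceleration_events(beh)


class TestDeltaAndWindows:
    def test_delta_of_identical_maps_is_zero(self):
        a = np.arange(66, dtype=float)
        assert np.allclose(delta_map(a, a), 0.0)

    def test_delta_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=66), rng.normal(size=66)
        assert np.allclose(delta_map(a, b), -delta_map(b, a))

    def test_window_summary_of_constant_map(self):
        centers = (np.arange(66) + 0.5) * BEHAVIOR_BIN_WIDTH
        assert window_summary(np.full(66, 3.3), (50, 80), centers) == pytest.approx(3.3)

    def test_window_summary_averages_member_bins(self):
        centers = (np.arange(66) + 0.5) * BEHAVIOR_BIN_WIDTH
        vals = np.full(66, np.nan)
        sel = (centers >= 50) & (centers <= 60)
        vals[sel] = [1.0, 2.0, 3.0][: sel.sum()]
        assert window_summary(vals, (50, 60), centers) == pytest.approx(2.0)

    def test_reward_zone_window_spans_six_bins(self):
        centers = (np.arange(66) + 0.5) * BEHAVIOR_BIN_WIDTH
        inside = (centers >= WINDOW_REWARD[0]) & (centers <= WINDOW_REWARD[1])
        assert inside.sum() == 6


def _trials(outcomes, t0=0.0, spacing=10.0):
    out = []
    for k, o in enumerate(outcomes):
        start = t0 + k * spacing
        out.append(TrialRecord(trial_id=k + int(t0), start_time=start,
                               end_time=start + 5, outcome=o,
                               reached_stim_point=True, max_position=150.0,
                               n_licks_in_zone=3, n_licks_out_zone=0))
    return out


class TestOutcomeDelta:
    EP = EpochSet(baseline=(0, 100), pre=(100, 150), stim=(150, 250),
                  post=(250, 300))

    def test_identical_proportions_give_zero(self):
        trials = _trials(["correct"] * 10) + _trials(["correct"] * 10, t0=150.0)
        delta, controlled = outcome_delta_vs_control(trials, self.EP)
        assert not controlled
        assert delta["correct"] == pytest.approx(0.0)

    def test_control_day_subtraction(self):
        # stim day: fail_lick 0.4 -> 0.6; control day: 0.4 -> 0.45
        def day(p1, p2):
            n1 = int(p1 * 10)
            n2 = int(p2 * 20)
            return (_trials(["fail_lick"] * n1 + ["correct"] * (10 - n1))
                    + _trials(["fail_lick"] * n2 + ["correct"] * (20 - n2),
                              t0=150.0, spacing=5.0))

        delta, controlled = outcome_delta_vs_control(
            day(0.4, 0.6), self.EP, day(0.4, 0.45), self.EP)
        assert controlled
        assert delta["fail_lick"] == pytest.approx(0.15)

    def test_outcome_deltas_sum_to_zero(self):
        trials = (_trials(["correct"] * 6 + ["fail_lick"] * 4)
                  + _trials(["correct"] * 3 + ["fail_overshoot"] * 7, t0=150.0,
                            spacing=5.0))
        delta, _ = outcome_delta_vs_control(trials, self.EP)
        assert sum(delta.values()) == pytest.approx(0.0)


class TestPeakProgression:
    def test_constant_peaks_have_zero_slope_and_r2(self):
        out = peak_trend_test(np.full(8, 50.0), n_shuffles=200, seed=0)
        assert out["slope"] == 0.0
        assert out["r2"] == 0.0

    def test_noiseless_moving_peak_has_r2_one_and_extreme_p(self):
        peaks = 90.0 - 3.03 * np.arange(10)  # one bin earlier per block
        out = peak_trend_test(peaks, n_shuffles=1000, seed=1)
        assert out["r2"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(-3.03)
        # identity (and order-reversal, same r2) are the only permutations
        # matching the observed r2: p is at the resolution floor
        assert out["p_r2"] <= 5 / 1001
        assert out["p_slope"] <= 5 / 1001

    def test_progression_pipeline_on_constructed_maps(self):
        nb = 66
        centers = (np.arange(nb) + 0.5) * BEHAVIOR_BIN_WIDTH
        n_trials = 9
        per_trial = np.zeros((n_trials, nb))
        for t in range(n_trials):
            per_trial[t, 30 - t] = 5.0  # peak moves one bin earlier per trial
        stim_map = BehaviorMap("decel_events", per_trial, per_trial.mean(0),
                               np.ones((n_trials, nb)), np.arange(n_trials),
                               BEHAVIOR_BIN_WIDTH, centers)
        base = BehaviorMap("decel_events", np.zeros((3, nb)), np.zeros(nb),
                           np.ones((3, nb)), np.arange(3),
                           BEHAVIOR_BIN_WIDTH, centers)
        out = decel_peak_progression(stim_map, base, block_size=3,
                                     n_shuffles=500, seed=3)
        assert out["slope"] < 0
        assert out["r2"] > 0.95
        assert out["p_r2"] < 0.05

    def test_permutation_p_is_uniform_under_the_null(self):
        """Null calibration: iid block peaks give uniform p-values."""
        from scipy.stats import kstest

        rng = np.random.default_rng(7)
        ps = []
        for rep in range(200):
            peaks = rng.integers(0, 66, size=10) * BEHAVIOR_BIN_WIDTH
            ps.append(peak_trend_test(peaks, n_shuffles=500,
                                      seed=int(rng.integers(2**31)))["p_r2"])
        assert kstest(ps, "uniform").pvalue > 0.01
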