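"""Peri-stimulus extraction, response windows, responsive calling, efficacy."""

import numpy as np
import pytest

from placestim.errors import AnalysisError
from placestim.session import StimProtocol, UM_PER_PIXEL
from placestim.stim import (
    ResponseRecord,
    classify_responsive,
    detect_off_target,
    extract_peristim,
    preferred_window,
    response_stability_slope,
    response_windows,
    stimulation_efficacy,
)


def make_raw(n_neurons=1, t_len=2000, base=100.0):
    return np.full((n_neurons, t_len), base)


class TestResponseWindows:
    def test_formula_matches_schedule_walk_oracle(self):
        # illumination j ends at 105*(j+1) - 5 ms; window starts at the next
        # full frame and spans 3 frames
        windows = response_windows()
        for j, (lo, hi) in enumerate(windows):
            expected = int(np.ceil((105 * (j + 1) - 5) / 1000 * 30))
            assert lo == expected
            assert hi == lo + 3

    def test_ten_pairwise_disjoint_windows(self):
        windows = response_windows()
        assert len(windows) == 10
        for (a, b), (c, d) in zip(windows, windows[1:]):
            assert b <= c


class TestExtractPeristim:
    def test_constant_trace_normalizes_to_zero(self):
        tensor = extract_peristim(make_raw(), np.array([500, 900]))
        assert np.allclose(tensor.data, 0.0)

    def test_step_response_normalizes_to_half(self):
        raw = make_raw()
        raw[0, 540:560] = 150.0  # 10-29 frames after the onset at 500
        tensor = extract_peristim(raw, np.array([500]))
        assert np.allclose(tensor.data[0, 0, 70:90], 0.5)
        assert np.allclose(tensor.data[0, 0, :70], 0.0)

    def test_onset_too_close_to_edge_is_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            tensor = extract_peristim(make_raw(), np.array([10, 500]))
        assert tensor.n_trials == 1
        assert tensor.onsets[0] == 500


def planted_tensor(window_idx=3, amp=0.5, hit_trials=None, n_trials=10,
                   n_neurons=1):
    """Peri-stimulus tensor with an exact-amplitude transient planted in one
    response window on chosen trials (written into the normalized data so
    boundary amplitudes are exact)."""
    windows = response_windows()
    onsets = 400 + 600 * np.arange(n_trials)
    raw = make_raw(n_neurons, int(onsets[-1] + 400))
    tensor = extract_peristim(raw, onsets)
    hit_trials = range(n_trials) if hit_trials is None else hit_trials
    lo, hi = windows[window_idx]
    for t in hit_trials:
        tensor.data[:, t, 30 + lo : 30 + hi] = amp
    return tensor, windows


class TestPreferredWindow:
    def test_planted_response_in_window_three(self):
        tensor, windows = planted_tensor(window_idx=3)
        assert preferred_window(tensor, windows)[0] == 3

    def test_tie_breaks_to_earliest_window(self):
        tensor, windows = planted_tensor(window_idx=2)
        lo, hi = windows[7]
        for t, o in enumerate(tensor.onsets):
            tensor.data[0, t, 30 + lo : 30 + hi] = tensor.data[0, t, 30 + windows[2][0]]
        assert preferred_window(tensor, windows)[0] == 2


class TestClassifyResponsive:
    @pytest.mark.parametrize(
        "amp,hits,expected",
        [
            (0.5, 4, True),  # 0.5 > 0.40 on 40% > 30% of trials
            (0.5, 3, False),  # 30% is not > 30%
            (0.40, 10, False),  # 0.40 is not > 0.40
            (0.41, 4, True),
        ],
    )
    def test_strict_thresholds(self, amp, hits, expected):
        tensor, windows = planted_tensor(amp=amp, hit_trials=range(hits))
        (rec,) = classify_responsive(tensor, windows)
        assert rec.responsive is expected

    def test_invariant_to_trial_order_permutation(self):
        tensor, windows = planted_tensor(amp=0.6, hit_trials=[0, 3, 5, 6])
        (rec,) = classify_responsive(tensor, windows)
        rng = np.random.default_rng(1)
        perm = rng.permutation(tensor.n_trials)
        tensor.data = tensor.data[:, perm]
        tensor.artifact = tensor.artifact[perm]
        (rec_p,) = classify_responsive(tensor, windows)
        assert rec.responsive == rec_p.responsive
        assert rec.preferred_window == rec_p.preferred_window

    def test_too_few_trials_raise(self):
        tensor, windows = planted_tensor(n_trials=4)
        with pytest.raises(AnalysisError):
            classify_responsive(tensor, windows)


def _rec(nid, responsive, target=False, amp=0.5):
    return ResponseRecord(neuron_id=nid, preferred_window=0,
                          trial_amplitudes=np.full(10, amp),
                          responsive=responsive, mean_amplitude=amp,
                          is_target=target, cluster=-1)


class TestDetectOffTarget:
    def _setup(self, dist_um):
        centroids = np.zeros((2, 2))
        centroids[1] = [dist_um / UM_PER_PIXEL, 0.0]
        beamlets = np.array([[0.0, 0.0]])
        return centroids, beamlets

    def test_close_responsive_and_sham_silent_is_off_target(self):
        centroids, beamlets = self._setup(10.0)
        out = detect_off_target([_rec(1, True)], [_rec(1, False)], beamlets,
                                centroids)
        assert list(out) == [1]

    def test_beyond_thirty_micron_is_excluded(self):
        centroids, beamlets = self._setup(31.0)
        out = detect_off_target([_rec(1, True)], [_rec(1, False)], beamlets,
                                centroids)
        assert out.size == 0

    def test_sham_responsive_cells_are_excluded(self):
        centroids, beamlets = self._setup(10.0)
        out = detect_off_target([_rec(1, True)], [_rec(1, True)], beamlets,
                                centroids)
        assert out.size == 0

    def test_targets_are_never_off_target(self):
        centroids, beamlets = self._setup(0.0)
        out = detect_off_target([_rec(1, True, target=True)], [], beamlets,
                                centroids)
        assert out.size == 0


class TestStabilitySlope:
    def test_constant_amplitudes_have_zero_slope(self):
        assert response_stability_slope(np.full(10, 0.5)) == pytest.approx(0.0)

    def test_exact_line_recovers_its_slope(self):
        amps = 0.5 - 0.01 * np.arange(12)
        assert response_stability_slope(amps) == pytest.approx(-0.01)

    def test_stationary_noise_slope_is_centered_at_zero(self):
        rng = np.random.default_rng(8)
        slopes = [response_stability_slope(rng.normal(0.5, 0.05, 20))
                  for _ in range(100)]
        assert abs(np.mean(slopes)) < np.std(slopes) / np.sqrt(100) * 3


class TestEfficacy:
    def _records(self, n_reward, n_start, n_other, amp):
        cats, recs = {}, []
        nid = 0
        for cat, n in (("reward_pc", n_reward), ("start_pc", n_start),
                       ("other_pc", n_other)):
            for _ in range(n):
                recs.append(_rec(nid, True, amp=amp))
                cats[nid] = cat
                nid += 1
        return recs, cats

    def test_reward_dominated_session(self):
        recs, cats = self._records(10, 2, 0, 0.6)
        out = stimulation_efficacy(recs, cats)
        assert out["specificity"] == pytest.approx(8 / 12)
        assert out["efficacy"] == pytest.approx(4.8)

    def test_balanced_session_has_zero_efficacy(self):
        recs, cats = self._records(5, 5, 2, 0.6)
        assert stimulation_efficacy(recs, cats)["efficacy"] == pytest.approx(0.0)

    def test_start_dominated_session_is_negative(self):
        recs, cats = self._records(2, 10, 0, 0.6)
        assert stimulation_efficacy(recs, cats)["efficacy"] == pytest.approx(-4.8)

    def test_sign_flips_under_label_swap(self):
        recs, cats = self._records(7, 3, 1, 0.5)
        swapped = {k: {"reward_pc": "start_pc", "start_pc": "reward_pc"}.get(v, v)
                   for k, v in cats.items()}
        assert stimulation_efficacy(recs, cats)["efficacy"] == pytest.approx(
            -stimulation_efficacy(recs, swapped)["efficacy"]
        )

    def test_no_responsive_cells_is_undefined(self):
        out = stimulation_efficacy([_rec(0, False)], {0: "reward_pc"})
        assert np.isnan(out["efficacy"])
        assert out["n_responsive"] == 0


class TestRecoveryOnSyntheticSession:
    def test_targets_recovered_and_off_targets_found(self):
        from placestim.synth import SimConfig, make_session
        from conftest import SMALL_CFG

        cfg = SimConfig(**{**SMALL_CFG, "n_off_target": 6})
        session, truth = make_session(cfg, seed=23)
        windows = response_windows(session.protocol)
        tensor = extract_peristim(session.traces, session.protocol.trial_onsets)
        is_target = np.zeros(cfg.n_neurons, dtype=bool)
        is_target[session.protocol.target_ids] = True
        records = classify_responsive(tensor, windows, is_target=is_target)
        resp = np.array([r.responsive for r in records])
        assert resp[is_target].mean() >= 0.9
        # planted off-target responders near beamlets are recovered
        from placestim.synth import stim_onset_times

        sham_t = stim_onset_times(session.behavior, session.epochs,
                                  session.geometry, epoch="pre")
        sham = extract_peristim(session.traces,
                                np.floor(sham_t * 30).astype(int))
        sham_records = classify_responsive(sham, windows, is_target=is_target)
        found = detect_off_target(records, sham_records,
                                  session.protocol.beamlet_xy,
                                  session.traces.roi_centroids)
        planted = set(truth.off_target_ids.tolist())
        assert planted
        recall = len(planted & set(found.tolist())) / len(planted)
        assert recall >= 0.9
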