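"""Population matrix, factor model, divergence, perturbation deciles."""

import numpy as np
import pytest

from placestim.errors import AnalysisError
from placestim.latent import (
    PopulationMatrix,
    fit_latent_model,
    perturbation_scores,
    prepare_population_matrix,
    select_analysis_cells,
    stim_triggered_average,
    trajectory_divergence,
)
from placestim.session import build_trial_table
from placestim import traces as tr

BIN_W = 2.27
NB = 88
CENTERS = (np.arange(NB) + 0.5) * BIN_W


def make_pm(X, row_epoch, row_trial, row_bin, n_cells=None):
    n_cells = X.shape[1] if n_cells is None else n_cells
    cov = {}
    for e in np.unique(row_epoch):
        n_tr = np.zeros(NB, dtype=int)
        for t in np.unique(row_trial[row_epoch == e]):
            n_tr[row_bin[(row_epoch == e) & (row_trial == t)]] += 1
        cov[str(e)] = (n_tr, n_tr)
    return PopulationMatrix(
        X=X, cell_ids=np.arange(n_cells), row_epoch=np.asarray(row_epoch),
        row_trial=np.asarray(row_trial), row_bin=np.asarray(row_bin),
        bin_centers=CENTERS, kept_bins=np.arange(NB), coverage=cov,
    )


def grid_pm(n_trials_a=8, n_trials_b=8, n_cells=12, noise=0.3, seed=0,
            shift=None):
    """Both epochs visit every bin once per trial; optional mean shift on
    chosen cells over chosen bins in epoch 'stim'."""
    rng = np.random.default_rng(seed)
    rows, re, rt, rb = [], [], [], []
    base = rng.normal(0, 1, (NB, n_cells))  # shared spatial profile
    for epoch, n_tr in (("pre", n_trials_b), ("stim", n_trials_a)):
        for t in range(n_tr):
            for b in range(NB):
                x = base[b] + rng.normal(0, noise, n_cells)
                if shift is not None and epoch == "stim":
                    cells, bins_, delta = shift
                    if b in bins_:
                        x = x.copy()
                        x[cells] += delta
                rows.append(x)
                re.append(epoch)
                rt.append(t + (1000 if epoch == "stim" else 0))
                rb.append(b)
    return make_pm(np.array(rows), np.array(re), np.array(rt), np.array(rb))


class TestPreparePopulationMatrix:
    def _session_inputs(self, small_session, small_trials):
        session, truth = small_session
        cells = np.flatnonzero(truth.is_place_cell)
        dff = tr.compute_dff(session.traces.fluorescence[cells],
                             frame_rate=30.0)
        tbe = {}
        for e in ("pre", "stim"):
            lo, hi = session.epochs.interval(e)
            tbe[e] = [t for t in small_trials
                      if lo <= t.start_time < hi and t.reached_stim_point]
        return session, cells, dff, tbe

    def test_rows_match_direct_recomputation_oracle(self, small_session,
                                                    small_trials):
        """Recompute a sample of rows from the raw inputs independently."""
        session, cells, dff, tbe = self._session_inputs(small_session,
                                                        small_trials)
        pm = prepare_population_matrix(
            dff, session.traces.frame_time, session.behavior, session.epochs,
            session.traces.artifact_mask, tbe, cell_ids=cells,
            geometry=session.geometry)
        ft = session.traces.frame_time
        pos = np.interp(ft, session.behavior.time, session.behavior.position)
        idx = np.clip(np.searchsorted(session.behavior.time, ft), 0,
                      session.behavior.time.size - 1)
        f_tid = session.behavior.trial_id[idx]
        art = session.traces.artifact_mask
        art_pos = pos[art & (f_tid >= 0)]
        band = (pos >= art_pos.min()) & (pos <= art_pos.max())
        rng = np.random.default_rng(0)
        for r in rng.choice(pm.X.shape[0], 10, replace=False):
            epoch = pm.row_epoch[r]
            lo, hi = session.epochs.interval(epoch)
            wanted = np.array([t.trial_id for t in tbe[epoch]])
            in_ep = (ft >= lo) & (ft < hi) & np.isin(f_tid, wanted) & ~art
            stats = in_ep & ~band
            keep = np.isin(cells, pm.cell_ids)
            mu = dff[keep][:, stats].mean(axis=1)
            sd = dff[keep][:, stats].std(axis=1)
            bins = np.minimum((pos / BIN_W).astype(int), NB - 1)
            sel = in_ep & (f_tid == pm.row_trial[r]) & (bins == pm.row_bin[r])
            oracle = ((dff[keep][:, sel].mean(axis=1) - mu) / sd)
            assert np.allclose(pm.X[r], oracle, atol=1e-10)

    def test_constant_cell_is_dropped(self, small_session, small_trials):
        session, cells, dff, tbe = self._session_inputs(small_session,
                                                        small_trials)
        dff = dff.copy()
        dff[3] = 1.0  # constant-activity cell
        with pytest.warns(UserWarning, match="zero-variance"):
            pm = prepare_population_matrix(
                dff, session.traces.frame_time, session.behavior,
                session.epochs, session.traces.artifact_mask, tbe,
                cell_ids=cells, geometry=session.geometry)
        assert cells[3] not in pm.cell_ids

    def test_stimulated_bins_vanish_from_the_stim_epoch(self, small_session,
                                                        small_trials):
        session, cells, dff, tbe = self._session_inputs(small_session,
                                                        small_trials)
        pm = prepare_population_matrix(
            dff, session.traces.frame_time, session.behavior, session.epochs,
            session.traces.artifact_mask, tbe, cell_ids=cells,
            geometry=session.geometry)
        n_clean, n_trav = pm.coverage["stim"]
        # bins fully inside the bout's minimum spatial extent (the slowest
        # allowed run still covers 105 + 6 cm/s * 1.045 s ~ 111 cm)
        bins_in_bout = (CENTERS >= 108) & (CENTERS <= 110.5)
        assert (n_clean[bins_in_bout] == 0).all()
        assert (n_trav[bins_in_bout] > 0).all()


class TestFitLatentModel:
    def test_two_planted_factors_are_recovered(self):
        rng = np.random.default_rng(0)
        n_rows, n_cells = 1500, 40
        z = rng.normal(size=(n_rows, 2))
        w = rng.normal(size=(2, n_cells))
        X = z @ w + rng.normal(0, 0.5, (n_rows, n_cells))
        pm = make_pm(X, np.array(["pre"] * n_rows), np.zeros(n_rows, int),
                     np.zeros(n_rows, int))
        model = fit_latent_model(pm, n_factors=10)
        # canonical correlation between planted scores and fitted scores
        from numpy.linalg import lstsq

        pred, *_ = lstsq(model.scores, z, rcond=None)
        resid = z - model.scores @ pred
        frac = 1 - resid.var(axis=0) / z.var(axis=0)
        assert frac.min() >= 0.9

    def test_ten_factor_model_fits_better_than_one_factor(self):
        rng = np.random.default_rng(1)
        n_rows, n_cells = 1200, 30
        z = rng.normal(size=(n_rows, 4))
        w = rng.normal(size=(4, n_cells))
        X = z @ w + rng.normal(0, 0.7, (n_rows, n_cells))
        pm = make_pm(X, np.array(["pre"] * n_rows), np.zeros(n_rows, int),
                     np.zeros(n_rows, int))

        def rms_resid(k):
            m = fit_latent_model(pm, n_factors=k)
            Xs = (X - X.mean(0)) / X.std(0)
            sample = np.corrcoef(Xs.T)
            lam = m.loadings
            implied = lam @ lam.T + np.diag(m.uniquenesses)
            off = ~np.eye(n_cells, dtype=bool)
            return np.sqrt(np.mean((sample - implied)[off] ** 2))

        assert rms_resid(10) < rms_resid(1)

    def test_white_noise_has_low_communalities(self):
        # on independent noise the common-factor model explains little
        # variance; individual cells can still capture a chance factor, so
        # the null property is distributional, not per-cell
        rng = np.random.default_rng(2)
        X = rng.normal(size=(2000, 30))
        pm = make_pm(X, np.array(["pre"] * 2000), np.zeros(2000, int),
                     np.zeros(2000, int))
        model = fit_latent_model(pm, n_factors=10)
        assert model.communalities.mean() < 0.15
        assert np.median(model.communalities) < 0.1

    def test_determinism(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(600, 20))
        pm = make_pm(X, np.array(["pre"] * 600), np.zeros(600, int),
                     np.zeros(600, int))
        m1 = fit_latent_model(pm, 5)
        m2 = fit_latent_model(pm, 5)
        assert np.array_equal(m1.loadings, m2.loadings)
        assert np.array_equal(m1.scores, m2.scores)

    def test_too_few_rows_raise(self):
        X = np.random.default_rng(0).normal(size=(10, 30))
        pm = make_pm(X, np.array(["pre"] * 10), np.zeros(10, int),
                     np.zeros(10, int))
        with pytest.raises(AnalysisError, match="too few rows"):
            fit_latent_model(pm)


class TestTrajectoryDivergence:
    def test_same_trials_give_zero_distance(self):
        pm = grid_pm(seed=4)
        scores = np.random.default_rng(4).normal(size=(pm.X.shape[0], 10))
        # epoch_a = epoch_b: distance must vanish identically
        div = trajectory_divergence(scores, pm, epoch_a="pre", epoch_b="pre")
        assert np.allclose(div.distance[np.isfinite(div.distance)], 0.0)

    def test_planted_constant_offset_appears_as_its_norm(self):
        pm = grid_pm(seed=5, noise=1e-4)
        rng = np.random.default_rng(5)
        scores = rng.normal(size=(pm.X.shape[0], 10)) * 1e-4
        delta = 0.7
        scores[pm.row_epoch == "stim", 2] += delta
        div = trajectory_divergence(scores, pm)
        d = div.distance[np.isfinite(div.distance)]
        assert np.allclose(d, delta, atol=0.01)

    def test_strong_post_zone_shift_is_detected_and_null_is_not(self):
        sig_bins = set(range(48, 56))  # just after the stimulation zone
        pm_sig = grid_pm(seed=6, shift=(list(range(6)), sig_bins, 1.0))
        pm_null = grid_pm(seed=7)
        model_sig = fit_latent_model(pm_sig, 6)
        model_null = fit_latent_model(pm_null, 6)
        div_sig = trajectory_divergence(model_sig.scores, pm_sig,
                                        n_perm=300, perm_seed=0)
        div_null = trajectory_divergence(model_null.scores, pm_null,
                                         n_perm=300, perm_seed=0)
        assert div_sig.detected
        assert not div_null.detected


class TestCellSelectionAndScores:
    def test_selection_rules(self):
        pm = grid_pm(seed=8, noise=0.05)
        n_cells = pm.X.shape[1]
        loadings = np.full((n_cells, 10), 0.5)
        loadings[0] = 0.1  # all loadings below 0.2 -> excluded
        model_like = type("M", (), {"loadings": loadings})()
        pm.X = pm.X.copy()
        # cell 1: large pre-zone stim-pre difference -> excluded
        pre_zone_rows = (pm.row_epoch == "stim") & np.isin(
            pm.row_bin, np.arange(36, 46))
        pm.X[pre_zone_rows, 1] += 1.0
        keep = select_analysis_cells(model_like, pm)
        assert not keep[0]
        assert not keep[1]
        assert keep[2:].all()

    def test_decile_arithmetic_on_known_scores(self):
        # 100 cells whose stim-pre difference ranks 1..100 in the score bins
        rows, re, rt, rb = [], [], [], []
        zone_bins = [58, 59, 60]
        scores = np.arange(1.0, 101.0)
        for epoch in ("pre", "stim"):
            for b in zone_bins + [10, 11]:
                if epoch == "stim" and b in zone_bins:
                    x = scores.copy()
                else:
                    x = np.zeros(100)
                rows.append(x)
                re.append(epoch)
                rt.append(0 if epoch == "pre" else 1)
                rb.append(b)
        pm = make_pm(np.array(rows), np.array(re), np.array(rt), np.array(rb))
        out = perturbation_scores(pm, np.ones(100, dtype=bool))
        sup = sorted(s.cell_id for s in out if s.klass == "suppressed")
        enh = sorted(s.cell_id for s in out if s.klass == "enhanced")
        # 10th pct of 1..100 is 10.9, 90th is 90.1 (strict inequalities)
        assert sup == list(range(0, 10))  # scores 1..10
        assert enh == list(range(90, 100))  # scores 91..100

    def test_too_few_eligible_cells_raise(self):
        pm = grid_pm(seed=9)
        with pytest.raises(AnalysisError, match="decile"):
            perturbation_scores(pm, np.arange(pm.X.shape[1]) < 5)


class TestStimTriggeredAverage:
    def test_constant_trace_gives_flat_zero(self):
        dff = np.full((1, 2000), 0.3)
        out = stim_triggered_average(dff, np.array([500, 900, 1300]))
        assert np.allclose(out, 0.0)

    def test_planted_transient_peaks_near_its_frame(self):
        rng = np.random.default_rng(1)
        dff = rng.normal(0, 0.02, (1, 4000))
        onsets = np.array([500, 1500, 2500, 3500])
        for o in onsets:
            dff[0, o + 5] += 0.5
        out = stim_triggered_average(dff, onsets)
        peak = np.argmax(out[0]) - 30  # frames relative to onset
        assert abs(peak - 5) <= 2

    def test_trial_permutation_invariance(self):
        rng = np.random.default_rng(2)
        dff = rng.normal(0, 0.1, (2, 3000))
        onsets = np.array([400, 900, 1400, 1900])
        a = stim_triggered_average(dff, onsets)
        b = stim_triggered_average(dff, onsets[::-1])
        assert np.allclose(a, b)
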