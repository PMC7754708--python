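"""Latent-factor analysis of place-cell population activity.

Activity of the place-cell population is z-scored per cell within each
epoch (after removing frames acquired during stimulation bouts), averaged
into 2.27-cm spatial bins per trial, and decomposed into 10 common factors
by maximum-likelihood factor analysis with regression-method factor scores.
Stimulation effects appear as a divergence of the stimulation-epoch latent
trajectory from the pre-epoch trajectory in the bins following the
stimulation zone, and as per-cell activity differences whose within-session
first/last deciles define suppressed and enhanced subpopulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import wilcoxon
from sklearn.decomposition import FactorAnalysis

from .errors import AnalysisError
from .session import BehaviorTimeseries, EpochSet, TrackGeometry, TrialRecord
from .traces import DEFAULT_BIN_WIDTH, frame_positions, frame_trial_ids, n_bins_for


@dataclass
class PopulationMatrix:
    """Rows = (epoch, trial, spatial bin); columns = cells; values = binned z-scores."""

    X: np.ndarray
    cell_ids: np.ndarray
    row_epoch: np.ndarray  # epoch label per row
    row_trial: np.ndarray
    row_bin: np.ndarray  # bin index on the full track grid
    bin_centers: np.ndarray  # full grid
    kept_bins: np.ndarray  # bins retaining any clean data
    # per epoch: (trials with clean frames per bin, trials traversing per bin)
    coverage: dict[str, tuple[np.ndarray, np.ndarray]]

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]


@dataclass
class LatentModel:
    loadings: np.ndarray  # cells x k
    scores: np.ndarray  # rows x k
    uniquenesses: np.ndarray  # per cell
    n_iter: int

    @property
    def communalities(self) -> np.ndarray:
        return 1.0 - self.uniquenesses


@dataclass
class PerturbationScore:
    cell_id: int
    score: float  # stim - pre activity difference, SD units
    klass: str  # suppressed | enhanced | neither


def prepare_population_matrix(
    dff: np.ndarray,
    frame_time: np.ndarray,
    behavior: BehaviorTimeseries,
    epochs: EpochSet,
    artifact_mask: np.ndarray,
    trials_by_epoch: dict[str, Sequence[TrialRecord]],
    cell_ids: Optional[np.ndarray] = None,
    geometry: TrackGeometry | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    epochs_used: tuple[str, ...] = ("pre", "stim"),
) -> PopulationMatrix:
    """Z-score per cell within epoch, drop stimulation frames, bin per trial.

    ``dff`` holds only the analyzed cell subset (rows follow ``cell_ids``).
    Frames acquired during stimulation bouts are removed before binning, so
    a (trial, bin) pair contributes a row only when it retains clean frames;
    bins the bout covered on every trial drop out of the stimulation epoch
    entirely. So that both epochs are normalized over comparable data, the
    per-cell z statistics of every epoch exclude frames from the position
    band the bouts censor (otherwise cells tuned to the stimulation zone
    would carry a spurious between-epoch z offset at every bin).
    Near-zero-variance cells are dropped with a warning.
    """
    geometry = geometry or TrackGeometry()
    dff = np.atleast_2d(dff)
    n_cells = dff.shape[0]
    ids = np.arange(n_cells) if cell_ids is None else np.asarray(cell_ids)
    nb = n_bins_for(geometry.track_length, bin_width)
    pos = frame_positions(behavior, frame_time)
    tid = frame_trial_ids(behavior, frame_time)
    bins = np.minimum((pos / bin_width).astype(np.int64), nb - 1)
    art = np.asarray(artifact_mask, dtype=bool)

    kept_bins = np.arange(nb)

    # position band censored by the bouts (for symmetric z statistics)
    if art.any():
        art_pos = pos[art & (tid >= 0)]
        band = (art_pos.min(), art_pos.max()) if art_pos.size else None
    else:
        band = None
    in_band = (
        (pos >= band[0]) & (pos <= band[1])
        if band is not None
        else np.zeros(pos.size, dtype=bool)
    )

    rows = []
    row_epoch, row_trial, row_bin = [], [], []
    drop_sd = np.zeros(n_cells, dtype=bool)
    z_by_epoch = {}
    coverage: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for epoch in epochs_used:
        trials = trials_by_epoch.get(epoch, [])
        wanted = np.array([t.trial_id for t in trials], dtype=np.int64)
        in_epoch = epochs.mask(frame_time, epoch)
        traversed = in_epoch & np.isin(tid, wanted)
        frame_ok = traversed & ~art
        if not frame_ok.any():
            raise AnalysisError(f"epoch {epoch!r} has zero clean frames")
        n_clean = np.zeros(nb, dtype=np.int64)
        n_trav = np.zeros(nb, dtype=np.int64)
        for t in wanted:
            n_trav[np.unique(bins[traversed & (tid == t)])] += 1
            n_clean[np.unique(bins[frame_ok & (tid == t)])] += 1
        coverage[epoch] = (n_clean, n_trav)
        stats_ok = frame_ok & ~in_band
        if not stats_ok.any():
            stats_ok = frame_ok
        sub = dff[:, frame_ok]
        ref = dff[:, stats_ok]
        mu = ref.mean(axis=1, keepdims=True)
        sd = ref.std(axis=1, keepdims=True)
        drop_sd |= (sd < 1e-12).ravel()
        sd = np.where(sd < 1e-12, 1.0, sd)
        z = (sub - mu) / sd
        z_by_epoch[epoch] = (z, tid[frame_ok], bins[frame_ok], wanted)

    if drop_sd.any():
        warnings.warn(f"dropping {drop_sd.sum()} near-zero-variance cell(s)")

    keep_cells = ~drop_sd
    for epoch in epochs_used:
        z, f_tid, f_bin, wanted = z_by_epoch[epoch]
        z = z[keep_cells]
        for t in wanted:
            sel_t = f_tid == t
            if not sel_t.any():
                continue
            b_t = f_bin[sel_t]
            for b in np.unique(b_t):
                rows.append(z[:, sel_t][:, b_t == b].mean(axis=1))
                row_epoch.append(epoch)
                row_trial.append(int(t))
                row_bin.append(int(b))

    if not rows:
        raise AnalysisError("population matrix is empty")
    return PopulationMatrix(
        X=np.vstack([r[None, :] for r in rows]),
        cell_ids=ids[keep_cells],
        row_epoch=np.array(row_epoch),
        row_trial=np.array(row_trial),
        row_bin=np.array(row_bin),
        bin_centers=(np.arange(nb) + 0.5) * bin_width,
        kept_bins=kept_bins,
        coverage=coverage,
    )


def fit_latent_model(pm: PopulationMatrix, n_factors: int = 10) -> LatentModel:
    """Maximum-likelihood common-factor model with regression-method scores.

    Columns are standardized before fitting (the decomposition acts on the
    correlation matrix); the deterministic LAPACK SVD path is used so that
    repeated fits are bit-identical. Heywood cases are floored at a
    uniqueness of 0.005 with a warning.
    """
    X = pm.X
    n_rows, n_cells = X.shape
    if n_rows <= n_cells / 2:
        raise AnalysisError(f"too few rows ({n_rows}) for {n_cells} cells")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd < 1e-12):
        raise AnalysisError("degenerate (constant) column in population matrix")
    Xs = (X - mu) / sd
    fa = FactorAnalysis(
        n_components=n_factors, svd_method="lapack", max_iter=2000, tol=1e-3
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fa.fit(Xs)
    if fa.n_iter_ >= 2000:
        raise AnalysisError(
            f"factor analysis did not converge after {fa.n_iter_} iterations "
            f"(loglik {fa.loglike_[-1]:.3f})"
        )
    uniq = fa.noise_variance_.copy()
    if np.any(uniq < 0.005):
        warnings.warn("Heywood case: flooring uniqueness at 0.005")
        uniq = np.maximum(uniq, 0.005)
    scores = fa.transform(Xs)  # posterior-mean = regression-method estimator
    return LatentModel(
        loadings=fa.components_.T.copy(),
        scores=scores,
        uniquenesses=uniq,
        n_iter=int(fa.n_iter_),
    )


def _trial_bin_scores(scores, pm, epoch):
    """scores regrouped as trials x bins x k for one epoch (NaN missing)."""
    sel = pm.row_epoch == epoch
    trials = np.unique(pm.row_trial[sel])
    nb = pm.bin_centers.size
    k = scores.shape[1]
    out = np.full((trials.size, nb, k), np.nan)
    t_index = {int(t): i for i, t in enumerate(trials)}
    for r in np.flatnonzero(sel):
        out[t_index[int(pm.row_trial[r])], pm.row_bin[r]] = scores[r]
    return trials, out


def _cell_epoch_activity(pm: PopulationMatrix, epoch: str) -> np.ndarray:
    """Per-cell trial-averaged binned activity for one epoch: cells x bins."""
    sel = pm.row_epoch == epoch
    nb = pm.bin_centers.size
    sums = np.zeros((nb, pm.n_cells))
    counts = np.zeros(nb)
    for r in np.flatnonzero(sel):
        sums[pm.row_bin[r]] += pm.X[r]
        counts[pm.row_bin[r]] += 1
    with np.errstate(invalid="ignore"):
        avg = sums / counts[:, None]
    avg[counts == 0] = np.nan
    return avg.T


@dataclass
class DivergenceResult:
    bin_centers: np.ndarray
    distance: np.ndarray  # per bin, NaN where undefined
    per_bin_p: np.ndarray  # two-sided sign-rank p per bin (NaN off post-zone)
    significant_runs: list[tuple[int, int]]  # [start, stop) bin-index runs
    post_zone_p: float  # one-sided session-level sign-rank p
    detected: bool


COVER_THR = 0.8


def trajectory_divergence(
    scores: np.ndarray,
    pm: PopulationMatrix,
    geometry: TrackGeometry | None = None,
    epoch_a: str = "stim",
    epoch_b: str = "pre",
    n_pre_zone_bins: int = 10,
    n_post_zone_bins: int = 8,
    alpha: float = 0.05,
    n_perm: int = 1000,
    perm_seed: int = 0,
) -> DivergenceResult:
    """Latent-trajectory divergence between two epochs across space.

    The divergence per bin is the Euclidean distance between the
    trial-averaged 10-D trajectories. Per-trial distances of ``epoch_a``
    trials from the ``epoch_b`` mean trajectory are compared, at every bin
    after the stimulation zone, to each trial's average over the ten bins
    preceding the zone (two-sided sign-rank; contiguous significant runs are
    reported).

    The session-level detection is an epoch-label permutation test on the
    trial-averaged post-zone distance: trials are exchangeable between the
    two epochs under the no-perturbation null, so reassigning trials to
    epochs at random and recomputing the mean post-zone distance between the
    group-average trajectories yields an exact null for the observed value.
    This is unbiased even though raw distances are noise-inflated in
    high-activity bins, because the inflation affects every permutation
    equally.
    """
    geometry = geometry or TrackGeometry()
    trials_a, Sa = _trial_bin_scores(scores, pm, epoch_a)
    trials_b, Sb = _trial_bin_scores(scores, pm, epoch_b)
    if trials_a.size < 3 or trials_b.size < 3:
        raise AnalysisError("trajectory divergence needs >= 3 trials per epoch")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_a = np.nanmean(Sa, axis=0)  # bins x k
        mean_b = np.nanmean(Sb, axis=0)
    distance = np.linalg.norm(mean_a - mean_b, axis=1)
    distance[~np.isfinite(mean_a).all(axis=1) | ~np.isfinite(mean_b).all(axis=1)] = np.nan

    # per-trial distance of epoch_a trials from the epoch_b mean trajectory
    d_t = np.linalg.norm(Sa - mean_b[None, :, :], axis=2)  # trials x bins

    centers = pm.bin_centers
    kept = np.zeros(centers.size, dtype=bool)
    kept[pm.kept_bins] = True
    defined = kept & np.isfinite(distance)
    # detection bins must not be artifact-censored on a substantial share of
    # the trials that traversed them: bins the bout still covers on slower
    # trials would otherwise be compared between a speed-selected subset of
    # stimulation trials and all reference trials, and traversal speed
    # shapes the spatial calcium profile
    covered = np.ones(centers.size, dtype=bool)
    for epoch in (epoch_a, epoch_b):
        if epoch in pm.coverage:
            n_clean, n_trav = pm.coverage[epoch]
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(n_trav > 0, n_clean / np.maximum(n_trav, 1), 0.0)
            covered &= frac >= COVER_THR
    pre_candidates = np.flatnonzero(defined & (centers <= geometry.stim_point))
    post_bins = np.flatnonzero(
        defined & covered & (centers > geometry.stim_point)
    )
    if pre_candidates.size < 3 or post_bins.size == 0:
        raise AnalysisError("not enough occupied bins around the stimulation zone")
    pre_bins = pre_candidates[-n_pre_zone_bins:]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        ref = np.nanmean(d_t[:, pre_bins], axis=1)  # per trial

    per_bin_p = np.full(centers.size, np.nan)
    for b in post_bins:
        diff = d_t[:, b] - ref
        diff = diff[np.isfinite(diff)]
        if diff.size >= 5 and np.any(diff != 0):
            per_bin_p[b] = wilcoxon(diff).pvalue
    sig = np.zeros(centers.size, dtype=bool)
    sig[post_bins] = per_bin_p[post_bins] < alpha
    runs = _runs(sig)

    # epoch-label permutation null for the noise-corrected squared distance
    # between the trial-averaged trajectories, over the first
    # n_post_zone_bins covered bins after the zone (mirroring the pre-zone
    # reference span; the perturbation is expected immediately after the
    # stimulation zone)
    detect_bins = post_bins[:n_post_zone_bins]
    pooled = np.concatenate([Sa, Sb], axis=0)[:, detect_bins, :]
    n_a = Sa.shape[0]
    n_pool = pooled.shape[0]

    def _stat(order: np.ndarray) -> float:
        A, B = pooled[order[:n_a]], pooled[order[n_a:]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            ma = np.nanmean(A, axis=0)
            mb = np.nanmean(B, axis=0)
            na = np.isfinite(A[:, :, 0]).sum(axis=0).astype(float)
            nb = np.isfinite(B[:, :, 0]).sum(axis=0).astype(float)
            va = np.nanvar(A, axis=0, ddof=1)
            vb = np.nanvar(B, axis=0, ddof=1)
            d2 = np.nansum((ma - mb) ** 2, axis=1)
            # subtract the squared distance expected from trial noise alone
            bias = np.nansum(va, axis=1) / na + np.nansum(vb, axis=1) / nb
            ok = (na >= 2) & (nb >= 2)
            if not ok.any():
                return 0.0
            return float(np.nansum((d2 - bias)[ok]))

    t_obs = _stat(np.arange(n_pool))
    rng = np.random.default_rng(perm_seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _stat(rng.permutation(n_pool))
    post_zone_p = float((1 + np.count_nonzero(null >= t_obs)) / (n_perm + 1))
    return DivergenceResult(
        bin_centers=centers,
        distance=distance,
        per_bin_p=per_bin_p,
        significant_runs=runs,
        post_zone_p=post_zone_p,
        detected=bool(post_zone_p < alpha),
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def select_analysis_cells(
    model: LatentModel,
    pm: PopulationMatrix,
    geometry: TrackGeometry | None = None,
    loading_min: float = 0.2,
    pre_zone_diff_max: float = 0.2,
    n_pre_zone_bins: int = 10,
    epoch_a: str = "stim",
    epoch_b: str = "pre",
) -> np.ndarray:
    """Eligible-cell flags for the perturbation analysis.

    A cell is kept when some factor loads on it with |loading| >= 0.2 and its
    average stimulation-minus-pre activity difference over the ten bins
    preceding the stimulation zone stays within 0.2 SD.
    """
    geometry = geometry or TrackGeometry()
    act_a = _cell_epoch_activity(pm, epoch_a)
    act_b = _cell_epoch_activity(pm, epoch_b)
    centers = pm.bin_centers
    kept = np.zeros(centers.size, dtype=bool)
    kept[pm.kept_bins] = True
    pre = np.flatnonzero(kept & (centers <= geometry.stim_point))[-n_pre_zone_bins:]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        diff = np.nanmean(act_a[:, pre] - act_b[:, pre], axis=1)
    loaded = np.abs(model.loadings).max(axis=1) >= loading_min
    return loaded & (np.abs(diff) <= pre_zone_diff_max)


def perturbation_scores(
    pm: PopulationMatrix,
    eligible: np.ndarray,
    geometry: TrackGeometry | None = None,
    center_cm: float = 136.0,
    n_zone_bins: int = 3,
    epoch_a: str = "stim",
    epoch_b: str = "pre",
) -> list[PerturbationScore]:
    """Per-cell stimulation-minus-pre activity scores and decile classes.

    The score averages the trial-averaged activity difference over the
    ``n_zone_bins`` uncontaminated bins centered at ``center_cm`` (just after
    the stimulation zone). Suppressed cells fall below the within-session
    10th percentile of eligible scores, enhanced cells above the 90th.
    """
    geometry = geometry or TrackGeometry()
    eligible = np.asarray(eligible, dtype=bool)
    if eligible.sum() < 10:
        raise AnalysisError("deciles undefined with < 10 eligible cells")
    act_a = _cell_epoch_activity(pm, epoch_a)
    act_b = _cell_epoch_activity(pm, epoch_b)
    centers = pm.bin_centers
    kept_ok = np.zeros(centers.size, dtype=bool)
    kept_ok[pm.kept_bins] = True
    order = np.argsort(np.abs(centers - center_cm), kind="stable")
    zone_bins = np.sort([b for b in order if kept_ok[b]][:n_zone_bins])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        diff = np.nanmean(act_a[:, zone_bins] - act_b[:, zone_bins], axis=1)
    scores = diff[eligible]
    lo = np.percentile(scores, 10)
    hi = np.percentile(scores, 90)
    out = []
    for idx, cell in zip(np.flatnonzero(eligible), pm.cell_ids[eligible]):
        s = diff[idx]
        klass = "suppressed" if s < lo else ("enhanced" if s > hi else "neither")
        out.append(PerturbationScore(cell_id=int(cell), score=float(s), klass=klass))
    return out


def stim_triggered_average(
    dff: np.ndarray,
    onsets: np.ndarray,
    pre: int = 30,
    post: int = 120,
    smooth_sd_frames: float = 5.0,
) -> np.ndarray:
    """Standardized, Gaussian-smoothed, trial-averaged peri-onset traces.

    Traces are z-scored per cell over the whole recording, aligned to each
    onset, smoothed along time with an SD of ``smooth_sd_frames`` imaging
    frames, then averaged over onsets. Onsets too close to a recording edge
    are dropped.
    """
    dff = np.atleast_2d(dff)
    onsets = np.asarray(onsets, dtype=np.int64)
    if onsets.size < 3:
        raise AnalysisError("stim_triggered_average needs >= 3 onsets")
    ok = (onsets >= pre) & (onsets + post <= dff.shape[1])
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} onset(s) near a recording edge; dropped")
    kept = onsets[ok]
    mu = dff.mean(axis=1, keepdims=True)
    sd = dff.std(axis=1, keepdims=True)
    sd = np.where(sd < 1e-12, 1.0, sd)
    z = (dff - mu) / sd
    idx = kept[:, None] + np.arange(-pre, post)[None, :]
    cut = z[:, idx]  # cells x trials x frames
    cut = gaussian_filter1d(cut, smooth_sd_frames, axis=2, mode="nearest")
    return cut.mean(axis=1)
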