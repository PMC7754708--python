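"""Spatial behavior maps, deceleration events and epoch-delta statistics.

Behavior is binned into 3.03-cm bins (66 bins over the 200-cm track) per
trial: lick rate (licks per second of bin occupancy), occupancy-weighted
running speed, occupancy time, and deceleration-event counts. Stimulation
effects are quantified as bin-wise stimulation-minus-baseline deltas
summarized over task windows (the 21.21 cm after the trigger point, the
reward zone, or the 15.15 cm before the trigger for decelerations), and the
trial-block progression of the deceleration peak is tested against a
block-order permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import AnalysisError, ConfigError
from .session import BEHAVIOR_RATE, BehaviorTimeseries, TrackGeometry, TrialRecord

BEHAVIOR_BIN_WIDTH = 3.03  # cm
VARIABLES = ("lick_rate", "speed", "occupancy", "decel_events")

# summary windows, cm
WINDOW_POST_STIM = (105.0, 126.21)  # 21.21 cm after the trigger
WINDOW_REWARD = (160.0, 178.6)
WINDOW_PRE_STIM_DECEL = (89.85, 105.0)  # 15.15 cm before the trigger


@dataclass
class BehaviorMap:
    variable: str
    per_trial: np.ndarray  # trials x bins, NaN where unoccupied
    trial_avg: np.ndarray  # bins
    occupancy_s: np.ndarray  # trials x bins, seconds
    trial_ids: np.ndarray
    bin_width: float
    bin_centers: np.ndarray


def deceleration_events(
    behavior: BehaviorTimeseries,
    interval_s: float = 0.1,
    k_sd: float = 2.0,
) -> np.ndarray:
    """Sample indices of deceleration events.

    Acceleration is the speed change across consecutive ``interval_s``
    intervals; an event is a maximal run of intervals whose acceleration
    falls below mean - ``k_sd`` * SD (statistics over the session's in-world
    intervals). Returns the behavior-grid sample index of each event start.
    """
    step = int(round(interval_s * BEHAVIOR_RATE))
    v = behavior.speed[::step]
    inw = behavior.in_world[::step]
    if inw.sum() * interval_s < 10.0:
        raise AnalysisError("deceleration_events needs >= 10 s of in-world data")
    a = np.diff(v) / interval_s
    valid = inw[:-1] & inw[1:]
    mu = a[valid].mean()
    sd = a[valid].std()
    below = valid & (a < mu - k_sd * sd)
    starts = np.flatnonzero(below & ~np.concatenate([[False], below[:-1]]))
    return starts * step


def behavior_spatial_map(
    behavior: BehaviorTimeseries,
    trials: Sequence[TrialRecord],
    variable: str,
    geometry: TrackGeometry | None = None,
    bin_width: float = BEHAVIOR_BIN_WIDTH,
    decel_samples: Optional[np.ndarray] = None,
) -> BehaviorMap:
    """Per-trial spatial map of one behavioral variable."""
    if variable not in VARIABLES:
        raise ConfigError(f"unknown behavior variable {variable!r}")
    geometry = geometry or TrackGeometry()
    if not trials:
        raise AnalysisError("behavior_spatial_map needs at least one trial")
    nb = int(np.floor(geometry.track_length / bin_width))
    dt = behavior.dt
    bins = np.minimum((behavior.position / bin_width).astype(np.int64), nb - 1)
    if variable == "decel_events" and decel_samples is None:
        decel_samples = deceleration_events(behavior)

    ids = np.array([t.trial_id for t in trials], dtype=np.int64)
    per_trial = np.full((ids.size, nb), np.nan)
    occ = np.zeros((ids.size, nb))
    for k, t in enumerate(ids):
        sel = behavior.trial_id == t
        b = bins[sel]
        cnt = np.bincount(b, minlength=nb).astype(np.float64)
        occ[k] = cnt * dt
        occupied = cnt > 0
        if variable == "occupancy":
            per_trial[k] = occ[k]
            per_trial[k, ~occupied] = np.nan
        elif variable == "lick_rate":
            licks = np.bincount(b[behavior.lick_flags[sel]], minlength=nb)
            with np.errstate(invalid="ignore", divide="ignore"):
                per_trial[k] = licks / occ[k]
            per_trial[k, ~occupied] = np.nan
        elif variable == "speed":
            s = np.bincount(b, weights=behavior.speed[sel], minlength=nb)
            with np.errstate(invalid="ignore", divide="ignore"):
                per_trial[k] = s / cnt
            per_trial[k, ~occupied] = np.nan
        else:  # decel_events
            ev = decel_samples[np.isin(decel_samples, np.flatnonzero(sel))]
            per_trial[k] = np.bincount(bins[ev], minlength=nb).astype(np.float64)
            per_trial[k, ~occupied] = np.nan
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore", category=RuntimeWarning)
        trial_avg = np.nanmean(per_trial, axis=0)
    centers = (np.arange(nb) + 0.5) * bin_width
    return BehaviorMap(
        variable=variable,
        per_trial=per_trial,
        trial_avg=trial_avg,
        occupancy_s=occ,
        trial_ids=ids,
        bin_width=bin_width,
        bin_centers=centers,
    )


def delta_map(map_a: np.ndarray, map_b: np.ndarray) -> np.ndarray:
    """Bin-wise a - b over mutually occupied bins (NaN elsewhere)."""
    a = np.asarray(map_a, dtype=np.float64)
    b = np.asarray(map_b, dtype=np.float64)
    if a.shape != b.shape:
        raise AnalysisError("delta_map requires identical binning")
    out = a - b
    return out


def window_summary(
    values: np.ndarray,
    window: tuple[float, float],
    bin_centers: np.ndarray,
) -> float:
    """Mean of the bins whose centers lie inside the window; NaN if none."""
    lo, hi = window
    sel = (bin_centers >= lo) & (bin_centers <= hi)
    vals = np.asarray(values, dtype=np.float64)[sel]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def outcome_proportions(trials: Sequence[TrialRecord], lo: float, hi: float) -> dict[str, float]:
    """Per-outcome proportion among trials starting within [lo, hi)."""
    sel = [t for t in trials if lo <= t.start_time < hi]
    n = len(sel)
    out = {}
    for outcome in ("correct", "fail_lick", "fail_overshoot"):
        out[outcome] = sum(1 for t in sel if t.outcome == outcome) / n if n else float("nan")
    return out


def outcome_delta_vs_control(
    stim_trials: Sequence[TrialRecord],
    stim_epochs,
    control_trials: Optional[Sequence[TrialRecord]] = None,
    control_epochs=None,
    epoch_a: str = "stim",
    epoch_b: str = "baseline",
) -> tuple[dict[str, float], bool]:
    """Per-outcome proportion change, stimulation day minus control day.

    Returns (deltas, controlled). Without a control session the raw
    stimulation-day delta is returned flagged ``controlled=False``.
    """
    pa = outcome_proportions(stim_trials, *stim_epochs.interval(epoch_a))
    pb = outcome_proportions(stim_trials, *stim_epochs.interval(epoch_b))
    delta = {k: pa[k] - pb[k] for k in pa}
    if control_trials is None:
        return delta, False
    ca = outcome_proportions(control_trials, *control_epochs.interval(epoch_a))
    cb = outcome_proportions(control_trials, *control_epochs.interval(epoch_b))
    return {k: delta[k] - (ca[k] - cb[k]) for k in delta}, True


def peak_trend_test(
    peaks_cm: np.ndarray,
    n_shuffles: int = 100_000,
    seed: int = 0,
) -> dict[str, float]:
    """Trend of peak location across trial blocks vs a block-order permutation null.

    Fits peak location against block index (OLS); the null permutes block
    order. p_r2 is the fraction of permutations with R^2 at least as large;
    p_slope the fraction with a slope at least as negative (an earlier-moving
    peak). Both use the add-one permutation convention.
    """
    y = np.asarray(peaks_cm, dtype=np.float64)
    m = y.size
    if m < 3:
        raise AnalysisError("peak trend test needs >= 3 blocks")
    x = np.arange(m, dtype=np.float64)
    xc = x - x.mean()
    yc = y - y.mean()
    var_x = (xc**2).sum()
    var_y = (yc**2).sum()
    cov = (xc * yc).sum()
    slope = cov / var_x
    r2 = 0.0 if var_y == 0 else (cov**2) / (var_x * var_y)

    rng = np.random.default_rng(seed)
    perm = rng.random((n_shuffles, m)).argsort(axis=1)
    yp = yc[perm]  # centered values permuted
    cov_p = yp @ xc
    slope_p = cov_p / var_x
    r2_p = np.zeros(n_shuffles) if var_y == 0 else (cov_p**2) / (var_x * var_y)
    p_r2 = (1 + np.count_nonzero(r2_p >= r2)) / (n_shuffles + 1)
    p_slope = (1 + np.count_nonzero(slope_p <= slope)) / (n_shuffles + 1)
    return {"slope": float(slope), "r2": float(r2),
            "p_r2": float(p_r2), "p_slope": float(p_slope)}


def decel_peak_progression(
    stim_map: BehaviorMap,
    baseline_map: BehaviorMap,
    block_size: int = 3,
    step: int = 1,
    n_shuffles: int = 100_000,
    seed: int = 0,
    peak_window: Optional[tuple[float, float]] = None,
) -> dict:
    """Sliding-block deceleration-peak progression with a permutation trend test.

    For each sliding block of ``block_size`` stimulation trials, the
    deceleration-count map averaged over the block minus the baseline
    trial-average is computed and its peak bin located (optionally within
    ``peak_window``). The peak-location trend across blocks is then tested
    with :func:`peak_trend_test`.
    """
    if stim_map.per_trial.shape[0] < 5:
        raise AnalysisError("peak progression needs >= 5 stimulation trials")
    n_blocks = (stim_map.per_trial.shape[0] - block_size) // step + 1
    if n_blocks < 3:
        raise AnalysisError("fewer than 3 trial blocks")
    centers = stim_map.bin_centers
    if peak_window is not None:
        in_win = (centers >= peak_window[0]) & (centers <= peak_window[1])
    else:
        in_win = np.ones(centers.size, dtype=bool)
    base = baseline_map.trial_avg
    peaks = np.empty(n_blocks)
    import warnings as _w

    for b in range(n_blocks):
        rows = stim_map.per_trial[b * step : b * step + block_size]
        with _w.catch_warnings():
            _w.simplefilter("ignore", category=RuntimeWarning)
            block_avg = np.nanmean(rows, axis=0)
        delta = block_avg - base
        delta = np.where(in_win, delta, np.nan)
        if not np.isfinite(delta).any():
            raise AnalysisError(f"block {b} has no occupied bins in the peak window")
        peaks[b] = centers[np.nanargmax(delta)]
    trend = peak_trend_test(peaks, n_shuffles=n_shuffles, seed=seed)
    trend["peaks_cm"] = peaks
    trend["n_blocks"] = n_blocks
    return trend
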