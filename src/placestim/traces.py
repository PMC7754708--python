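"""Fluorescence preprocessing and spatial tuning maps.

Raw traces are converted to dF/F against a slow running baseline (the 8th
percentile of a 10-s window centered on each frame), restricted to frames
where the animal runs above 5 cm/s, and binned into 2.27-cm spatial bins
smoothed with a 3-bin-SD Gaussian. Bins never occupied under the velocity
filter are carried as NaN rather than zero-filled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d

from ._rolling import rolling_percentile_matrix
from .errors import AlignmentError, AnalysisError, ConfigError
from .session import BehaviorTimeseries, TraceMatrix, TrackGeometry, TrialRecord

DEFAULT_BIN_WIDTH = 2.27  # cm
DEFAULT_SMOOTH_SD = 3.0  # bins
SPEED_THRESHOLD = 5.0  # cm/s


def n_bins_for(track_length: float, bin_width: float) -> int:
    return int(np.floor(track_length / bin_width))


def compute_dff(
    traces: TraceMatrix | np.ndarray,
    window_s: float = 10.0,
    percentile: float = 8.0,
    frame_rate: float | None = None,
) -> np.ndarray:
    """dF/F with a sliding-percentile baseline.

    F0(t) is the ``percentile``-th percentile of the raw trace in a
    ``window_s`` window centered on frame t (truncated at the recording
    edges); dF/F = (F - F0) / F0.
    """
    if isinstance(traces, TraceMatrix):
        raw = traces.fluorescence
        frame_rate = frame_rate or traces.frame_rate
    else:
        raw = np.atleast_2d(np.asarray(traces, dtype=np.float64))
        if frame_rate is None:
            raise ConfigError("frame_rate required when passing a bare array")
    window = int(round(window_s * frame_rate))
    if window < 1:
        raise ConfigError("baseline window must cover at least one frame")
    f0 = rolling_percentile_matrix(raw, window, percentile)
    bad = f0 <= 0
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise AnalysisError(f"non-positive baseline F0 at neuron {i}, frame {j}")
    return (raw - f0) / f0


def velocity_mask(
    behavior: BehaviorTimeseries,
    frame_time: np.ndarray,
    threshold: float = SPEED_THRESHOLD,
) -> np.ndarray:
    """Frame-aligned running mask: speed strictly above threshold and in-world.

    Behavior samples are interpolated onto the imaging clock; the two clocks
    must overlap to within one frame.
    """
    frame_time = np.asarray(frame_time)
    if frame_time.size:
        skew = max(behavior.time[0] - frame_time[0], frame_time[-1] - behavior.time[-1])
        if skew > 1.0 / 30.0 + 1e-9:
            raise AlignmentError(
                f"behavior and imaging clocks misaligned by {skew:.3f} s"
            )
    speed = np.interp(frame_time, behavior.time, behavior.speed)
    in_world = _nearest_bool(behavior.time, behavior.in_world, frame_time)
    return (speed > threshold) & in_world


def _nearest_bool(t_src: np.ndarray, values: np.ndarray, t_dst: np.ndarray) -> np.ndarray:
    idx = np.clip(np.searchsorted(t_src, t_dst), 0, t_src.size - 1)
    left = np.clip(idx - 1, 0, t_src.size - 1)
    use_left = np.abs(t_src[left] - t_dst) <= np.abs(t_src[idx] - t_dst)
    idx = np.where(use_left, left, idx)
    return values.astype(bool)[idx]


def frame_trial_ids(behavior: BehaviorTimeseries, frame_time: np.ndarray) -> np.ndarray:
    """Nearest-sample trial id per imaging frame (-1 in inter-trial intervals)."""
    idx = np.clip(np.searchsorted(behavior.time, frame_time), 0, behavior.time.size - 1)
    return behavior.trial_id[idx]


def frame_positions(behavior: BehaviorTimeseries, frame_time: np.ndarray) -> np.ndarray:
    return np.interp(frame_time, behavior.time, behavior.position)


@dataclass
class PlaceMap:
    """Per-trial and trial-averaged spatial dF/F maps.

    ``per_trial`` is neurons x trials x bins with NaN marking bins without
    velocity-filtered occupancy on that trial; ``trial_avg`` averages over
    the trials that occupied each bin.
    """

    per_trial: np.ndarray
    trial_avg: np.ndarray
    occupancy: np.ndarray  # trials x bins, velocity-filtered frame counts
    trial_ids: np.ndarray
    bin_width: float
    bin_centers: np.ndarray
    smoothing_sd_bins: float

    @property
    def n_bins(self) -> int:
        return self.per_trial.shape[2]


def _smooth_kernel(sd_bins: float) -> np.ndarray:
    radius = int(np.ceil(4 * sd_bins))
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sd_bins) ** 2)
    return k / k.sum()


def smooth_map(values: np.ndarray, sd_bins: float) -> np.ndarray:
    """NaN-aware Gaussian smoothing along the last axis.

    Uses normalized (truncated-kernel) convolution: missing bins do not
    contribute and the kernel is renormalized over the bins present, so the
    track edges are not wrapped.
    """
    if sd_bins <= 0:
        return values
    k = _smooth_kernel(sd_bins)
    filled = np.nan_to_num(values, nan=0.0)
    weight = np.isfinite(values).astype(np.float64)
    num = convolve1d(filled * weight, k, axis=-1, mode="constant", cval=0.0)
    den = convolve1d(weight, k, axis=-1, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[weight == 0] = np.nan
    return out


def spatial_tuning_map(
    dff: np.ndarray,
    behavior: BehaviorTimeseries,
    mask: np.ndarray,
    trials: list[TrialRecord],
    geometry: TrackGeometry | None = None,
    frame_time: np.ndarray | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    smooth_sd_bins: float = DEFAULT_SMOOTH_SD,
) -> PlaceMap:
    """Trial-resolved spatial dF/F maps for a set of trials.

    Per trial, each bin holds the mean dF/F of the velocity-masked frames the
    animal spent in that bin, Gaussian-smoothed along the track. Trials with
    zero occupied bins are excluded with a warning.
    """
    geometry = geometry or TrackGeometry()
    dff = np.atleast_2d(dff)
    n_neurons, n_frames = dff.shape
    if frame_time is None:
        frame_time = np.arange(n_frames) / 30.0
    nb = n_bins_for(geometry.track_length, bin_width)
    pos = frame_positions(behavior, frame_time)
    tid = frame_trial_ids(behavior, frame_time)
    bins = np.minimum((pos / bin_width).astype(np.int64), nb - 1)

    wanted = np.array([t.trial_id for t in trials], dtype=np.int64)
    if wanted.size == 0:
        raise AnalysisError("spatial_tuning_map needs at least one trial")
    trial_index = {t: i for i, t in enumerate(wanted)}

    sel = mask & np.isin(tid, wanted)
    counts = np.zeros((wanted.size, nb), dtype=np.int64)
    sums = np.zeros((n_neurons, wanted.size, nb), dtype=np.float64)
    if sel.any():
        rows = np.array([trial_index[t] for t in tid[sel]], dtype=np.int64)
        keys = rows * nb + bins[sel]
        order = np.argsort(keys, kind="stable")
        keys_sorted = keys[order]
        uniq, seg_starts = np.unique(keys_sorted, return_index=True)
        vals = dff[:, np.flatnonzero(sel)[order]]
        seg_sums = np.add.reduceat(vals, seg_starts, axis=1)
        seg_counts = np.add.reduceat(np.ones(keys_sorted.size), seg_starts)
        counts.reshape(-1)[uniq] = seg_counts.astype(np.int64)
        sums.reshape(n_neurons, -1)[:, uniq] = seg_sums

    empty_trials = np.flatnonzero(counts.sum(axis=1) == 0)
    if empty_trials.size:
        warnings.warn(
            f"{empty_trials.size} trial(s) had no velocity-filtered occupancy "
            "and were excluded from the place map"
        )
        keep = np.setdiff1d(np.arange(wanted.size), empty_trials)
        counts = counts[keep]
        sums = sums[:, keep]
        wanted = wanted[keep]

    with np.errstate(invalid="ignore", divide="ignore"):
        per_trial = sums / counts[None, :, :]
    per_trial[:, counts == 0] = np.nan
    per_trial = smooth_map(per_trial, smooth_sd_bins)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        trial_avg = np.nanmean(per_trial, axis=1)
    centers = (np.arange(nb) + 0.5) * bin_width
    return PlaceMap(
        per_trial=per_trial,
        trial_avg=trial_avg,
        occupancy=counts,
        trial_ids=wanted,
        bin_width=bin_width,
        bin_centers=centers,
        smoothing_sd_bins=smooth_sd_bins,
    )


def event_rate(
    dff: np.ndarray,
    mask: np.ndarray,
    frame_rate: float = 30.0,
    threshold_sd: float = 3.0,
) -> np.ndarray:
    """Transient events per second within the masked samples.

    An event is an upward crossing of mean + ``threshold_sd`` * SD, with both
    statistics computed on the masked samples themselves (i.e. per epoch when
    the mask selects one epoch). Zero-variance traces yield rate 0.
    """
    dff = np.atleast_2d(dff)
    sel = np.flatnonzero(mask)
    if sel.size < frame_rate:
        raise AnalysisError("event_rate needs at least 1 s of masked data")
    x = dff[:, sel]
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(f"{flat.sum()} zero-variance trace(s); event rate set to 0")
        sd = np.where(sd == 0, np.inf, sd)
    above = x >= mu + threshold_sd * sd
    crossings = above[:, 1:] & ~above[:, :-1]
    counts = crossings.sum(axis=1) + above[:, 0]
    duration = sel.size / frame_rate
    return counts / duration


def match_rois(
    centroids_a: np.ndarray,
    centroids_b: np.ndarray,
    tol_px: float = 4.0,
) -> np.ndarray:
    """Greedy one-to-one nearest-neighbor pairing of ROI centroids.

    Candidate pairs are taken in order of increasing distance; a pair is kept
    when both members are still free and the distance is within ``tol_px``.
    Returns an (n_pairs, 2) array of (index_a, index_b).
    """
    a = np.atleast_2d(np.asarray(centroids_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(centroids_b, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    order = np.argsort(d, axis=None, kind="stable")
    used_a = np.zeros(a.shape[0], dtype=bool)
    used_b = np.zeros(b.shape[0], dtype=bool)
    pairs = []
    for flat in order:
        i, j = divmod(int(flat), b.shape[0])
        if d[i, j] > tol_px:
            break
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        pairs.append((i, j))
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    return np.array(sorted(pairs), dtype=np.int64)
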