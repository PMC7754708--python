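"""Photostimulation response analysis.

Per stimulation trial, each neuron's raw trace is cut 30 frames before to
120 frames after bout onset and normalized by its own mean baseline from
frames 5-29 of the cut. Responses are scored in the ten ~100-ms (3-frame)
windows that follow each of the ten cluster illuminations; a cell is
responsive when its dF/F exceeds 0.40 on more than 30% of trials in its
preferred window (the window with the largest trial-averaged response,
earliest on ties). Off-target responders are non-targets that are
responsive, silent under sham (no-stimulation) onsets, and within 30 um of
a stimulation beamlet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import linregress

from .errors import AnalysisError, ProtocolError
from .session import (
    FRAME_RATE,
    N_CLUSTERS,
    N_CYCLES,
    UM_PER_PIXEL,
    StimProtocol,
    TraceMatrix,
)

PRE_FRAMES = 30
POST_FRAMES = 120
BASELINE_FRAMES = slice(5, 30)  # within the pre-onset span
WINDOW_FRAMES = 3  # ~100 ms at 30 Hz


@dataclass
class PeristimTensor:
    """Baseline-normalized peri-stimulus traces: neurons x trials x frames.

    Frame 0 is 30 frames before onset; onset sits at frame index 30.
    ``artifact`` flags frames to exclude from window statistics (all False
    when the traces carry no artifact).
    """

    data: np.ndarray
    artifact: np.ndarray  # trials x frames
    onsets: np.ndarray  # kept onset frame indices

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def onset_index(self) -> int:
        return PRE_FRAMES


@dataclass
class ResponseRecord:
    neuron_id: int
    preferred_window: int  # 0-9; -1 when undefined
    trial_amplitudes: np.ndarray  # dF/F per trial in the preferred window
    responsive: bool
    mean_amplitude: float
    is_target: bool
    cluster: int  # -1 for non-targets


def extract_peristim(
    traces: TraceMatrix | np.ndarray,
    onsets: np.ndarray,
    pre: int = PRE_FRAMES,
    post: int = POST_FRAMES,
    artifact_mask: Optional[np.ndarray] = None,
) -> PeristimTensor:
    """Cut and normalize per-trial peri-stimulus traces from raw fluorescence.

    Each trial is normalized by subtracting and dividing its own mean
    baseline from frames 5-29 of the cut. Onsets too close to a recording
    edge are dropped with a warning.
    """
    raw = traces.fluorescence if isinstance(traces, TraceMatrix) else np.atleast_2d(traces)
    t_total = raw.shape[1]
    onsets = np.asarray(onsets, dtype=np.int64)
    ok = (onsets >= pre) & (onsets + post <= t_total)
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} onset(s) too close to a recording edge; dropped")
    kept = onsets[ok]
    if kept.size == 0:
        raise AnalysisError("no usable stimulation onsets")
    idx = kept[:, None] + np.arange(-pre, post)[None, :]
    cut = raw[:, idx]  # neurons x trials x frames
    base = cut[:, :, BASELINE_FRAMES].mean(axis=2, keepdims=True)
    if np.any(base <= 0):
        raise AnalysisError("non-positive peri-stimulus baseline")
    data = (cut - base) / base
    if artifact_mask is not None:
        artifact = np.asarray(artifact_mask, dtype=bool)[idx]
    else:
        artifact = np.zeros(idx.shape, dtype=bool)
    return PeristimTensor(data=data, artifact=artifact, onsets=kept)


def response_windows(
    protocol: StimProtocol | None = None,
    frame_rate: float = FRAME_RATE,
    window_frames: int = WINDOW_FRAMES,
) -> list[tuple[int, int]]:
    """Frame ranges (relative to onset) of the 10 post-illumination windows.

    Window j starts at the first full frame after illumination j completes
    (at 105*(j+1) - 5 ms) and spans ~100 ms.
    """
    protocol = protocol or StimProtocol.empty()
    sched = protocol.schedule_ms()
    if len(sched) != N_CLUSTERS * N_CYCLES:
        raise ProtocolError(f"schedule has {len(sched)} illuminations, expected 10")
    out = []
    for _, _, off_ms in sched:
        start = int(np.ceil(off_ms / 1000.0 * frame_rate))
        out.append((start, start + window_frames))
    return out


def _window_trial_means(tensor: PeristimTensor, windows) -> np.ndarray:
    """Per-window per-trial mean dF/F over clean frames: neurons x trials x 10."""
    n, tr, _ = tensor.data.shape
    onset = tensor.onset_index
    out = np.full((n, tr, len(windows)), np.nan)
    for w, (lo, hi) in enumerate(windows):
        cols = np.arange(onset + lo, onset + hi)
        clean = ~tensor.artifact[:, cols]  # trials x frames
        vals = tensor.data[:, :, cols]
        cnt = clean.sum(axis=1)
        with np.errstate(invalid="ignore"):
            means = np.where(clean[None, :, :], vals, 0.0).sum(axis=2) / cnt[None, :]
        means[:, cnt == 0] = np.nan
        out[:, :, w] = means
    return out


def preferred_window(tensor: PeristimTensor, windows) -> np.ndarray:
    """Per-neuron index of the window with the maximal trial-averaged response.

    Ties break to the earliest window; a neuron whose windows are all
    artifact-masked gets -1.
    """
    wm = _window_trial_means(tensor, windows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        avg = np.nanmean(wm, axis=1)  # neurons x windows
    pref = np.full(avg.shape[0], -1, dtype=np.int64)
    for i in range(avg.shape[0]):
        if np.isfinite(avg[i]).any():
            pref[i] = int(np.nanargmax(avg[i]))  # argmax returns the first maximum
    return pref


def classify_responsive(
    tensor: PeristimTensor,
    windows,
    amp: float = 0.40,
    frac: float = 0.30,
    is_target: Optional[np.ndarray] = None,
    cluster: Optional[np.ndarray] = None,
    neuron_ids: Optional[np.ndarray] = None,
) -> list[ResponseRecord]:
    """Responsive-cell classification with strict > thresholds on both criteria."""
    if tensor.n_trials < 5:
        raise AnalysisError("responsive classification needs >= 5 stimulation trials")
    wm = _window_trial_means(tensor, windows)
    pref = preferred_window(tensor, windows)
    n = wm.shape[0]
    ids = np.arange(n) if neuron_ids is None else np.asarray(neuron_ids)
    tgt = np.zeros(n, dtype=bool) if is_target is None else np.asarray(is_target)
    clu = np.full(n, -1, dtype=np.int64) if cluster is None else np.asarray(cluster)
    records = []
    for i in range(n):
        if pref[i] < 0:
            records.append(
                ResponseRecord(int(ids[i]), -1, np.empty(0), False, float("nan"),
                               bool(tgt[i]), int(clu[i]))
            )
            continue
        amps = wm[i, :, pref[i]]
        valid = np.isfinite(amps)
        # strict > with an epsilon so a window mean of exactly the threshold
        # never passes through float summation error
        hit_frac = np.count_nonzero(amps[valid] > amp + 1e-9) / max(1, valid.sum())
        responsive = bool(hit_frac > frac + 1e-12)
        records.append(
            ResponseRecord(
                neuron_id=int(ids[i]),
                preferred_window=int(pref[i]),
                trial_amplitudes=amps,
                responsive=responsive,
                mean_amplitude=float(np.nanmean(amps)) if valid.any() else float("nan"),
                is_target=bool(tgt[i]),
                cluster=int(clu[i]),
            )
        )
    return records


def detect_off_target(
    records: list[ResponseRecord],
    no_stim_records: list[ResponseRecord],
    beamlet_xy: np.ndarray,
    roi_centroids_px: np.ndarray,
    um_per_px: float = UM_PER_PIXEL,
    radius_um: float = 30.0,
) -> np.ndarray:
    """Off-target responder ids: responsive non-targets, silent under sham
    onsets, within ``radius_um`` of a stimulation beamlet."""
    if um_per_px is None or um_per_px <= 0:
        raise AnalysisError("missing um-per-pixel calibration")
    beamlet_xy = np.atleast_2d(beamlet_xy)
    sham = {r.neuron_id: r.responsive for r in no_stim_records}
    out = []
    for r in records:
        if r.is_target or not r.responsive:
            continue
        if sham.get(r.neuron_id, False):
            continue
        xy_um = roi_centroids_px[r.neuron_id] * um_per_px
        d = np.linalg.norm(beamlet_xy - xy_um[None, :], axis=1)
        if d.size and d.min() <= radius_um:
            out.append(r.neuron_id)
    return np.asarray(out, dtype=np.int64)


def response_stability_slope(trial_amplitudes: np.ndarray) -> float:
    """OLS slope of the responsive population's mean amplitude across trials.

    ``trial_amplitudes`` is trials-long (already population-averaged) or
    neurons x trials, in which case the population mean is taken first.
    """
    a = np.asarray(trial_amplitudes, dtype=np.float64)
    if a.ndim == 2:
        a = np.nanmean(a, axis=0)
    ok = np.isfinite(a)
    if ok.sum() < 5:
        raise AnalysisError("stability slope needs >= 5 trials")
    x = np.flatnonzero(ok).astype(np.float64)
    return float(linregress(x, a[ok]).slope)


def stimulation_efficacy(
    records: list[ResponseRecord],
    categories: dict[int, str],
) -> dict[str, float]:
    """Specificity and efficacy of a stimulation session.

    specificity = (n responsive Reward-PCs - n responsive Start-PCs) / n
    responsive; efficacy = specificity * n responsive * mean response
    amplitude. Undefined (NaN) without any responsive neuron.
    """
    resp = [r for r in records if r.responsive]
    n_total = len(resp)
    if n_total == 0:
        return {"specificity": float("nan"), "efficacy": float("nan"),
                "n_responsive": 0, "mean_amplitude": float("nan")}
    n_reward = sum(1 for r in resp if categories.get(r.neuron_id) == "reward_pc")
    n_start = sum(1 for r in resp if categories.get(r.neuron_id) == "start_pc")
    mean_amp = float(np.nanmean([r.mean_amplitude for r in resp]))
    specificity = (n_reward - n_start) / n_total
    return {
        "specificity": specificity,
        "efficacy": specificity * n_total * mean_amp,
        "n_responsive": n_total,
        "mean_amplitude": mean_amp,
    }
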