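"""Pre/post remapping analysis.

Lasting changes in spatial tuning are quantified by (i) the Pearson
correlation of each stable cell's trial-averaged maps between the pre- and
post-stimulation epochs, (ii) the shift of its activity center of mass
(COM), (iii) the mode of a normal-kernel fit to the population COM
histogram, and (iv) a shuffle null for the number of cells whose map peak
falls in the reward zone, built by random circular translation of every
cell's average map along the track.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde, pearsonr

from .errors import AnalysisError
from .placecells import place_field_com
from .session import TrackGeometry
from .traces import PlaceMap


@dataclass
class ComRecord:
    neuron_id: int
    category: str
    com_pre: float
    com_post: float
    shift: float  # com_post - com_pre, cm
    prepost_r: float


def prepost_map_correlation(pre_map: PlaceMap, post_map: PlaceMap,
                            min_bins: int = 3) -> np.ndarray:
    """Per-cell Pearson r between pre and post trial-averaged maps.

    NaN where fewer than ``min_bins`` mutually occupied bins exist or a map
    is constant.
    """
    a, b = pre_map.trial_avg, post_map.trial_avg
    if a.shape != b.shape:
        raise AnalysisError("pre/post maps must share binning")
    out = np.full(a.shape[0], np.nan)
    for i in range(a.shape[0]):
        ok = np.isfinite(a[i]) & np.isfinite(b[i])
        if ok.sum() < min_bins:
            continue
        x, y = a[i, ok], b[i, ok]
        if x.std() == 0 or y.std() == 0:
            continue
        out[i] = pearsonr(x, y).statistic
    return out


def _baseline_subtracted(trial_avg: np.ndarray, frac_of_peak: float = 0.25) -> np.ndarray:
    """Map preprocessed for a noise-robust COM.

    Subtracts the floor used by field detection (baseline + 25% of the
    baseline-to-peak range). Without it, the flat dF/F offset left by the
    running-percentile baseline plus clipped noise mass drags every COM
    toward the track center; with it the COM tracks the field itself and is
    translation-equivariant.
    """
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore", category=RuntimeWarning)
        base = np.nanmin(trial_avg)
        peak = np.nanmax(trial_avg)
        return trial_avg - (base + frac_of_peak * (peak - base))


def build_com_records(
    pre_map: PlaceMap,
    post_map: PlaceMap,
    categories: dict[int, str],
    keep: np.ndarray,
    neuron_ids: np.ndarray | None = None,
) -> list[ComRecord]:
    """COM records for the cells passing the baseline/pre stability filter."""
    ids = np.arange(pre_map.trial_avg.shape[0]) if neuron_ids is None else np.asarray(neuron_ids)
    rs = prepost_map_correlation(pre_map, post_map)
    records = []
    for k in np.flatnonzero(np.asarray(keep, dtype=bool)):
        c_pre = place_field_com(_baseline_subtracted(pre_map.trial_avg[k]),
                                pre_map.bin_centers)
        c_post = place_field_com(_baseline_subtracted(post_map.trial_avg[k]),
                                 post_map.bin_centers)
        records.append(
            ComRecord(
                neuron_id=int(ids[k]),
                category=categories.get(int(ids[k]), "non_pc"),
                com_pre=c_pre,
                com_post=c_post,
                shift=c_post - c_pre,
                prepost_r=float(rs[k]),
            )
        )
    return records


def com_distribution_peak(
    coms: np.ndarray,
    track_length: float = 200.0,
    grid_step: float = 0.5,
) -> float:
    """Mode of a normal-kernel density fit to a COM sample, in cm.

    Uses the rule-of-thumb (Scott) bandwidth and an evaluation grid of
    ``grid_step`` cm over the track. Needs at least 10 COMs.
    """
    coms = np.asarray(coms, dtype=np.float64)
    coms = coms[np.isfinite(coms)]
    if coms.size < 10:
        warnings.warn("fewer than 10 COMs; distribution peak undefined")
        return float("nan")
    grid = np.arange(0.0, track_length + grid_step / 2, grid_step)
    if np.std(coms) < 1e-12:
        return float(coms[0])
    dens = gaussian_kde(coms)(grid)
    return float(grid[np.argmax(dens)])


def com_shift_summary(records: list[ComRecord]) -> dict[str, dict[str, float]]:
    """Signed and absolute COM shifts aggregated per category."""
    if not records:
        raise AnalysisError("no COM records")
    out: dict[str, dict[str, float]] = {}
    cats = sorted({r.category for r in records})
    for cat in cats + ["all"]:
        sel = [r for r in records if cat == "all" or r.category == cat]
        shifts = np.array([r.shift for r in sel if np.isfinite(r.shift)])
        if shifts.size == 0:
            continue
        out[cat] = {
            "n": int(shifts.size),
            "median_shift": float(np.median(shifts)),
            "median_abs_shift": float(np.median(np.abs(shifts))),
            "mean_shift": float(np.mean(shifts)),
        }
    return out


def translate_map(trial_avg: np.ndarray, shift_bins: int) -> np.ndarray:
    """Circular translation of a map along the track (mass-preserving)."""
    return np.roll(trial_avg, shift_bins)


def reward_zone_peak_shuffle(
    trial_avg: np.ndarray,
    bin_centers: np.ndarray,
    zone: tuple[float, float] | None = None,
    n_shuffles: int = 10_000,
    seed: int = 0,
) -> dict:
    """Observed reward-zone peak count vs a circular-translation null.

    Each cell's map peak is its argmax bin; the null randomly circularly
    translates every map by an independent uniform offset and recounts peaks
    inside the zone. Translation moves the argmax deterministically, so the
    null is evaluated on shifted peak indices (equivalent to rolling every
    map; see :func:`translate_map`).
    """
    geometry = TrackGeometry()
    zone = zone or geometry.reward_zone
    maps = np.atleast_2d(trial_avg)
    n_cells, nb = maps.shape
    filled = np.where(np.isfinite(maps), maps, -np.inf)
    peaks = np.argmax(filled, axis=1)
    in_zone = (bin_centers >= zone[0]) & (bin_centers <= zone[1])
    observed = int(np.count_nonzero(in_zone[peaks]))

    rng = np.random.default_rng(seed)
    shifts = rng.integers(0, nb, size=(n_shuffles, n_cells))
    shifted = (peaks[None, :] + shifts) % nb
    null_counts = in_zone[shifted].sum(axis=1)
    p = (1 + np.count_nonzero(null_counts >= observed)) / (n_shuffles + 1)
    return {
        "observed": observed,
        "null_mean": float(null_counts.mean()),
        "null_quantiles": {
            "q025": float(np.quantile(null_counts, 0.025)),
            "q500": float(np.quantile(null_counts, 0.5)),
            "q975": float(np.quantile(null_counts, 0.975)),
        },
        "p": float(p),
        "n_shuffles": int(n_shuffles),
    }
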