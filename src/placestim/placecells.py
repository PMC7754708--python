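"""Place-field detection and zone classification.

A candidate field is a maximal contiguous run of bins whose trial-averaged
dF/F exceeds baseline + 25% of (peak - baseline). A candidate is accepted
when (i) its width lies within [9, 120] cm, (ii) its in-field mean is at
least 3x the out-field mean, (iii) it carries significant in-field activity
on at least 25% of trials, and (iv) its peak dF/F reaches 0.20. No bootstrap
is applied. Cells are then classified by which task zone their fields cover:
a field overlapping more than half of the start zone (21.4-48.8 cm) makes a
Start-PC, more than half of the reward zone (160-178.6 cm) a Reward-PC, and
analogously for the configurable stimulation zone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import pearsonr

from .errors import AnalysisError, ConfigError
from .session import TrackGeometry
from .traces import PlaceMap


@dataclass
class FieldCriteria:
    """Acceptance thresholds for candidate place fields."""

    frac_of_peak: float = 0.25
    width_bounds_cm: tuple[float, float] = (9.0, 120.0)
    in_out_ratio_min: float = 3.0
    active_trial_frac_min: float = 0.25
    peak_min_dff: float = 0.20
    active_sd: float = 2.0  # per-trial activity threshold, SDs of out-field values

    def validate(self) -> None:
        lo, hi = self.width_bounds_cm
        if lo >= hi:
            raise ConfigError("field width bounds must satisfy lo < hi")


@dataclass
class PlaceFieldRecord:
    neuron_id: int
    field_interval: tuple[float, float]  # cm, [lo, hi)
    peak_dff: float
    peak_bin: int
    in_out_ratio: float
    active_trial_fraction: float
    com: float


@dataclass
class CellCategory:
    neuron_id: int
    category: str  # start_pc | reward_pc | stim_zone_pc | other_pc | non_pc


def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_place_fields(
    place_map: PlaceMap,
    criteria: FieldCriteria | None = None,
    neuron_ids: Optional[np.ndarray] = None,
) -> dict[int, list[PlaceFieldRecord]]:
    """Detect accepted place fields per neuron from a trial-resolved map."""
    criteria = criteria or FieldCriteria()
    criteria.validate()
    n_neurons, n_trials, n_bins = place_map.per_trial.shape
    if n_trials < 5:
        raise AnalysisError("place-field detection needs at least 5 trials")
    ids = np.arange(n_neurons) if neuron_ids is None else np.asarray(neuron_ids)
    w = place_map.bin_width
    out: dict[int, list[PlaceFieldRecord]] = {}
    for k, nid in enumerate(ids):
        avg = place_map.trial_avg[k]
        occupied = np.isfinite(avg)
        records: list[PlaceFieldRecord] = []
        if occupied.sum() >= 2:
            base = np.nanmin(avg)
            peak = np.nanmax(avg)
            thr = base + criteria.frac_of_peak * (peak - base)
            above = occupied & (avg >= thr) & (peak > base)
            for lo, hi in _contiguous_runs(above):
                records.extend(
                    _evaluate_candidate(place_map, k, int(nid), lo, hi, criteria)
                )
        out[int(nid)] = records
    return out


def _evaluate_candidate(place_map, k, nid, lo, hi, criteria):
    avg = place_map.trial_avg[k]
    w = place_map.bin_width
    width = (hi - lo) * w
    lo_w, hi_w = criteria.width_bounds_cm
    if not (lo_w <= width <= hi_w):
        return []
    in_field = np.zeros(avg.size, dtype=bool)
    in_field[lo:hi] = True
    occupied = np.isfinite(avg)
    peak_rel = np.nanargmax(np.where(in_field, avg, -np.inf))
    peak_dff = avg[peak_rel]
    if peak_dff < criteria.peak_min_dff:
        return []
    out_vals = avg[occupied & ~in_field]
    out_mean = out_vals.mean() if out_vals.size else 0.0
    in_mean = np.nanmean(avg[lo:hi])
    ratio = np.inf if out_mean <= 0 else in_mean / out_mean
    if ratio < criteria.in_out_ratio_min:
        return []
    # per-trial significant in-field activity: in-field mean above
    # mean + active_sd * SD of that trial's out-of-field values
    per_trial = place_map.per_trial[k]
    active = 0
    counted = 0
    for t in range(per_trial.shape[0]):
        row = per_trial[t]
        if not np.isfinite(row[lo:hi]).any():
            counted += 1
            continue
        out_row = row[~in_field]
        out_row = out_row[np.isfinite(out_row)]
        if out_row.size < 2:
            continue
        thr_t = out_row.mean() + criteria.active_sd * out_row.std()
        counted += 1
        if np.nanmean(row[lo:hi]) > thr_t:
            active += 1
    frac = active / counted if counted else 0.0
    if frac < criteria.active_trial_frac_min:
        return []
    com = place_field_com(np.where(in_field, avg, np.nan), place_map.bin_centers)
    return [
        PlaceFieldRecord(
            neuron_id=nid,
            field_interval=(lo * w, hi * w),
            peak_dff=float(peak_dff),
            peak_bin=int(peak_rel),
            in_out_ratio=float(ratio),
            active_trial_fraction=float(frac),
            com=float(com),
        )
    ]


def place_field_com(trial_avg: np.ndarray, bin_centers: np.ndarray) -> float:
    """Center of mass of the non-negative part of a trial-averaged map, in cm.

    Unoccupied bins (NaN) are excluded; an all-zero map has no COM (NaN).
    """
    vals = np.asarray(trial_avg, dtype=np.float64)
    ok = np.isfinite(vals)
    w = np.clip(vals[ok], 0.0, None)
    total = w.sum()
    if total <= 0:
        return float("nan")
    return float((bin_centers[ok] * w).sum() / total)


def _overlap_fraction(interval: tuple[float, float], zone: tuple[float, float]) -> float:
    lo = max(interval[0], zone[0])
    hi = min(interval[1], zone[1])
    return max(0.0, hi - lo) / (zone[1] - zone[0])


def classify_zone(
    fields: list[PlaceFieldRecord],
    geometry: TrackGeometry | None = None,
    neuron_id: int | None = None,
) -> CellCategory:
    """Zone category of one cell from its accepted fields.

    A field must cover strictly more than 50% of a zone to claim it. The
    start and reward zones take precedence over the stimulation zone; if
    fields claim both start and reward, the larger coverage wins.
    """
    geometry = geometry or TrackGeometry()
    nid = neuron_id if neuron_id is not None else (fields[0].neuron_id if fields else -1)
    if not fields:
        return CellCategory(neuron_id=nid, category="non_pc")
    start_cov = max(_overlap_fraction(f.field_interval, geometry.start_zone) for f in fields)
    reward_cov = max(_overlap_fraction(f.field_interval, geometry.reward_zone) for f in fields)
    stim_cov = max(_overlap_fraction(f.field_interval, geometry.stim_zone) for f in fields)
    # strictly more than half the zone; epsilon guards the exact-50% boundary
    thr = 0.5 + 1e-9
    if start_cov > thr or reward_cov > thr:
        category = "start_pc" if start_cov >= reward_cov else "reward_pc"
    elif stim_cov > thr:
        category = "stim_zone_pc"
    else:
        category = "other_pc"
    return CellCategory(neuron_id=nid, category=category)


def classify_cells(
    fields_by_neuron: dict[int, list[PlaceFieldRecord]],
    geometry: TrackGeometry | None = None,
) -> dict[int, str]:
    return {
        nid: classify_zone(fields, geometry, neuron_id=nid).category
        for nid, fields in fields_by_neuron.items()
    }


def stability_filter(
    map_epoch1: PlaceMap,
    map_epoch2: PlaceMap,
    r_min: float = 0.3,
    min_bins: int = 3,
) -> np.ndarray:
    """Keep flag per neuron: Pearson r between the two trial-averaged maps >= r_min.

    Computed over mutually occupied bins; cells with fewer than ``min_bins``
    such bins are excluded with a warning.
    """
    a = map_epoch1.trial_avg
    b = map_epoch2.trial_avg
    if a.shape != b.shape:
        raise AnalysisError("stability_filter requires maps on identical bins")
    keep = np.zeros(a.shape[0], dtype=bool)
    short = 0
    for i in range(a.shape[0]):
        ok = np.isfinite(a[i]) & np.isfinite(b[i])
        if ok.sum() < min_bins:
            short += 1
            continue
        x, y = a[i, ok], b[i, ok]
        if x.std() == 0 or y.std() == 0:
            continue
        keep[i] = pearsonr(x, y).statistic >= r_min
    if short:
        warnings.warn(f"{short} cell(s) had < {min_bins} mutually occupied bins")
    return keep
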