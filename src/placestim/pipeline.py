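"""Session-level orchestration: simulate -> analyze -> report.

``analyze_session`` runs every analysis family on one session and returns a
machine-readable summary plus tabular outputs; ``cross_session_stats``
aggregates per-session summaries with standard nonparametric tests
(delegated to scipy). Every threshold used is logged into the summary so
each reported number is traceable to a module operation and its settings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import behavior as beh
from . import latent as lat
from . import placecells as pc
from . import remap as rm
from . import stim as st
from . import traces as tr
from .errors import AnalysisError
from .session import EPOCH_NAMES, SessionData, build_trial_table, trial_table_frame
from .synth import stim_onset_times


@dataclass
class RunConfig:
    """Analysis settings for one session run."""

    session_type: str = "reward_pc"  # start_pc | reward_pc | non_pc | no_stim
    seed: int = 0
    run_latent: bool = True
    run_remapping: bool = True
    run_response: bool = True
    n_factors: int = 10
    n_peak_shuffles: int = 10_000
    n_block_shuffles: int = 10_000
    field_criteria: pc.FieldCriteria = field(default_factory=pc.FieldCriteria)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def _epoch_trials(trials, epochs, epoch, good_only=False):
    lo, hi = epochs.interval(epoch)
    out = [t for t in trials if lo <= t.start_time < hi]
    if good_only:
        out = [t for t in out if t.reached_stim_point]
    return out


def analyze_session(
    session: SessionData,
    config: Optional[RunConfig] = None,
) -> tuple[dict, dict[str, pd.DataFrame]]:
    """Run the full quantification stack on one session.

    Returns (summary, tables); sections whose preconditions fail are marked
    unavailable with the reason instead of aborting the remaining stages.
    """
    config = config or RunConfig()
    geometry = session.geometry
    epochs = session.epochs
    behavior = session.behavior
    traces = session.traces

    summary: dict = {
        "session_type": config.session_type,
        "seed": config.seed,
        "thresholds": {
            "speed_cm_s": tr.SPEED_THRESHOLD,
            "bin_cm": tr.DEFAULT_BIN_WIDTH,
            "smooth_sd_bins": tr.DEFAULT_SMOOTH_SD,
            "behavior_bin_cm": beh.BEHAVIOR_BIN_WIDTH,
            "peak_min_dff": config.field_criteria.peak_min_dff,
            "responsive_amp": 0.40,
            "responsive_frac": 0.30,
            "stability_r": 0.3,
            "off_target_um": 30.0,
        },
    }
    tables: dict[str, pd.DataFrame] = {}

    # --- trials and behavior ------------------------------------------------
    trials = build_trial_table(behavior, geometry)
    tables["trials"] = trial_table_frame(trials)
    outcome_counts = {
        o: sum(1 for t in trials if t.outcome == o)
        for o in ("correct", "fail_lick", "fail_overshoot")
    }
    base_trials = _epoch_trials(trials, epochs, "baseline")
    summary["behavior"] = {
        "n_trials": len(trials),
        "outcome_counts": outcome_counts,
        "baseline_pct_correct": (
            100.0
            * sum(1 for t in base_trials if t.outcome == "correct")
            / max(1, len(base_trials))
        ),
        "good_trials_stim_epoch": len(_epoch_trials(trials, epochs, "stim", True)),
    }

    decel = beh.deceleration_events(behavior)
    good_stim = _epoch_trials(trials, epochs, "stim", good_only=True)
    good_base = _epoch_trials(trials, epochs, "baseline", good_only=True)
    deltas = {}
    if good_stim and good_base:
        for var, window in (
            ("lick_rate", beh.WINDOW_POST_STIM),
            ("decel_events", beh.WINDOW_PRE_STIM_DECEL),
            ("occupancy", beh.WINDOW_REWARD),
        ):
            m_stim = beh.behavior_spatial_map(
                behavior, good_stim, var, geometry, decel_samples=decel
            )
            m_base = beh.behavior_spatial_map(
                behavior, good_base, var, geometry, decel_samples=decel
            )
            d = beh.delta_map(m_stim.trial_avg, m_base.trial_avg)
            deltas[f"{var}_delta"] = beh.window_summary(d, window, m_stim.bin_centers)
    summary["behavior"]["stim_vs_baseline"] = deltas
    outcome_delta, controlled = beh.outcome_delta_vs_control(trials, epochs)
    summary["behavior"]["outcome_delta_raw"] = outcome_delta
    summary["behavior"]["outcome_delta_controlled"] = controlled

    # --- traces, maps and place cells ---------------------------------------
    dff = tr.compute_dff(traces)
    vmask = tr.velocity_mask(behavior, traces.frame_time)
    epoch_masks = {e: epochs.mask(traces.frame_time, e) for e in EPOCH_NAMES}

    maps = {}
    for epoch in EPOCH_NAMES:
        etr = _epoch_trials(trials, epochs, epoch)
        if len(etr) >= 2:
            maps[epoch] = tr.spatial_tuning_map(
                dff, behavior, vmask & epoch_masks[epoch], etr, geometry,
                frame_time=traces.frame_time,
            )

    categories: dict[int, str] = {}
    if "baseline" in maps and maps["baseline"].per_trial.shape[1] >= 5:
        fields = pc.detect_place_fields(maps["baseline"], config.field_criteria)
        categories = pc.classify_cells(fields, geometry)
        from .synth import CATEGORIES as CATS

        cat_counts = {c: sum(1 for v in categories.values() if v == c) for c in CATS}
        n_pc = sum(v for c, v in cat_counts.items() if c != "non_pc")
        summary["place_cells"] = {
            "available": True,
            "n_neurons": traces.n_neurons,
            "n_place_cells": n_pc,
            "pct_place_cells": 100.0 * n_pc / traces.n_neurons,
            "category_counts": cat_counts,
        }
        tables["classification"] = pd.DataFrame(
            [
                {
                    "neuron_id": nid,
                    "category": categories[nid],
                    "n_fields": len(fields[nid]),
                    "field_lo": fields[nid][0].field_interval[0] if fields[nid] else np.nan,
                    "field_hi": fields[nid][0].field_interval[1] if fields[nid] else np.nan,
                    "peak_dff": fields[nid][0].peak_dff if fields[nid] else np.nan,
                    "com": fields[nid][0].com if fields[nid] else np.nan,
                }
                for nid in sorted(fields)
            ]
        )
    else:
        summary["place_cells"] = {"available": False, "reason": "too few baseline trials"}

    # --- stimulation response ------------------------------------------------
    protocol = session.protocol
    if config.run_response and not protocol.is_empty and protocol.trial_onsets.size >= 5:
        try:
            windows = st.response_windows(protocol)
            tensor = st.extract_peristim(traces, protocol.trial_onsets)
            is_target = np.zeros(traces.n_neurons, dtype=bool)
            is_target[protocol.target_ids] = True
            cluster = np.full(traces.n_neurons, -1, dtype=np.int64)
            cluster[protocol.target_ids] = protocol.cluster_assignment
            records = st.classify_responsive(tensor, windows, is_target=is_target,
                                             cluster=cluster)
            sham_t = stim_onset_times(behavior, epochs, geometry, epoch="pre")
            off_target = np.empty(0, dtype=np.int64)
            if sham_t.size >= 5:
                sham_onsets = np.floor(sham_t * traces.frame_rate).astype(np.int64)
                sham_tensor = st.extract_peristim(traces, sham_onsets)
                sham_records = st.classify_responsive(sham_tensor, windows,
                                                      is_target=is_target)
                off_target = st.detect_off_target(
                    records, sham_records, protocol.beamlet_xy, traces.roi_centroids
                )
            resp_targets = [r for r in records if r.is_target and r.responsive]
            slope = float("nan")
            if resp_targets:
                amps = np.vstack([r.trial_amplitudes for r in resp_targets])
                slope = st.response_stability_slope(amps)
            eff = st.stimulation_efficacy(records, categories)
            resp_nt_pc = [
                r
                for r in records
                if r.responsive
                and not r.is_target
                and categories.get(r.neuron_id, "non_pc") != "non_pc"
            ]
            summary["response"] = {
                "available": True,
                "n_stim_trials": int(tensor.n_trials),
                "n_responsive_targets": len(resp_targets),
                "n_responsive_nontarget_pcs": len(resp_nt_pc),
                "n_off_target": int(off_target.size),
                "stability_slope": slope,
                **eff,
            }
            tables["responses"] = pd.DataFrame(
                [
                    {
                        "neuron_id": r.neuron_id,
                        "is_target": r.is_target,
                        "cluster": r.cluster,
                        "preferred_window": r.preferred_window,
                        "responsive": r.responsive,
                        "mean_amplitude": r.mean_amplitude,
                    }
                    for r in records
                ]
            )
        except AnalysisError as e:
            summary["response"] = {"available": False, "reason": str(e)}
    else:
        summary["response"] = {"available": False, "reason": "no stimulation protocol"}

    # --- latent analysis -----------------------------------------------------
    if config.run_latent and categories:
        try:
            cells = np.array(sorted(
                nid for nid, c in categories.items() if c != "non_pc"
            ))
            if config.session_type == "non_pc":
                cells = cells[~np.isin(cells, protocol.target_ids)]
            trials_by_epoch = {
                e: _epoch_trials(trials, epochs, e, good_only=True)
                for e in ("pre", "stim")
            }
            pm = lat.prepare_population_matrix(
                dff[cells], traces.frame_time, behavior, epochs,
                traces.artifact_mask, trials_by_epoch, cell_ids=cells,
                geometry=geometry,
            )
            model = lat.fit_latent_model(pm, n_factors=min(config.n_factors,
                                                           max(1, pm.n_cells - 2)))
            div = lat.trajectory_divergence(
                model.scores, pm, geometry, perm_seed=config.seed
            )
            eligible = lat.select_analysis_cells(model, pm, geometry)
            scores = []
            if eligible.sum() >= 10:
                scores = lat.perturbation_scores(pm, eligible, geometry)
            summary["latent"] = {
                "available": True,
                "n_cells": int(pm.n_cells),
                "n_eligible": int(eligible.sum()),
                "post_zone_p": div.post_zone_p,
                "divergence_detected": div.detected,
                "n_significant_runs": len(div.significant_runs),
                "n_suppressed": sum(1 for s in scores if s.klass == "suppressed"),
                "n_enhanced": sum(1 for s in scores if s.klass == "enhanced"),
            }
            if scores:
                tables["perturbation"] = pd.DataFrame(
                    [{"cell_id": s.cell_id, "score": s.score, "class": s.klass}
                     for s in scores]
                )
        except AnalysisError as e:
            summary["latent"] = {"available": False, "reason": str(e)}
    else:
        summary["latent"] = {"available": False, "reason": "disabled or no place cells"}
    if config.session_type == "no_stim":
        summary["response"]["applicable"] = False
        summary["latent"].setdefault("applicable", True)
        summary["latent"]["applicable"] = False

    # --- remapping -----------------------------------------------------------
    if config.run_remapping and categories and all(e in maps for e in ("pre", "post")):
        try:
            keep = pc.stability_filter(maps["baseline"], maps["pre"])
            records = rm.build_com_records(maps["pre"], maps["post"], categories, keep)
            pc_records = [r for r in records if r.category != "non_pc"]
            coms_pre = np.array([r.com_pre for r in pc_records])
            coms_post = np.array([r.com_post for r in pc_records])
            pc_ids = np.array(sorted(
                nid for nid, c in categories.items() if c != "non_pc"
            ))
            shuffle = rm.reward_zone_peak_shuffle(
                maps["baseline"].trial_avg[pc_ids],
                maps["baseline"].bin_centers,
                geometry.reward_zone,
                n_shuffles=config.n_peak_shuffles,
                seed=config.seed,
            )
            summary["remapping"] = {
                "available": True,
                "n_stable_cells": int(np.sum(keep)),
                "mean_prepost_r": float(np.nanmean([r.prepost_r for r in pc_records]))
                if pc_records else float("nan"),
                "com_peak_pre": rm.com_distribution_peak(coms_pre),
                "com_peak_post": rm.com_distribution_peak(coms_post),
                "shift_summary": rm.com_shift_summary(records) if records else {},
                "reward_zone_peaks": shuffle,
            }
            tables["com_records"] = pd.DataFrame(
                [
                    {
                        "neuron_id": r.neuron_id,
                        "category": r.category,
                        "com_pre": r.com_pre,
                        "com_post": r.com_post,
                        "shift": r.shift,
                        "prepost_r": r.prepost_r,
                    }
                    for r in records
                ]
            )
        except AnalysisError as e:
            summary["remapping"] = {"available": False, "reason": str(e)}
    else:
        summary["remapping"] = {"available": False,
                                "reason": "missing pre/post maps or place cells"}

    summary = _jsonable(summary)
    payload = json.dumps(summary, sort_keys=True).encode()
    summary["config_hash"] = hashlib.sha256(payload).hexdigest()[:16]
    return summary, tables


def run_pipeline(session: SessionData, config: Optional[RunConfig] = None) -> dict:
    """Summary-only wrapper of :func:`analyze_session`."""
    summary, _ = analyze_session(session, config)
    return summary


def summary_json(summary: dict) -> str:
    """Canonical JSON serialization (byte-stable for identical runs)."""
    return json.dumps(summary, sort_keys=True, indent=2)


def cross_session_stats(
    sessions: pd.DataFrame,
    tests: Sequence[dict],
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Standard cross-session tests over per-session metrics.

    ``sessions`` holds one row per session; each test spec is a dict with
    ``name``, ``kind`` (wilcoxon | ranksums | kruskal | pearson), ``metric``
    and, depending on kind, ``metric2`` (paired/correlate) or ``group_by`` /
    ``groups``. All machinery is delegated to scipy.
    """
    if len(sessions) < 2:
        raise AnalysisError("cross_session_stats needs >= 2 sessions")
    rows = []
    for spec in tests:
        kind = spec["kind"]
        name = spec.get("name", f"{kind}:{spec.get('metric')}")
        try:
            if kind == "wilcoxon":
                x = sessions[spec["metric"]].dropna()
                if "metric2" in spec:
                    y = sessions[spec["metric2"]].dropna()
                    res = sps.wilcoxon(x, y)
                else:
                    res = sps.wilcoxon(x)
                stat, p, extra = res.statistic, res.pvalue, {}
            elif kind == "ranksums":
                ga, gb = spec["groups"]
                col = sessions[spec["group_by"]]
                a = sessions.loc[col == ga, spec["metric"]].dropna()
                b = sessions.loc[col == gb, spec["metric"]].dropna()
                res = sps.ranksums(a, b)
                stat, p, extra = res.statistic, res.pvalue, {}
            elif kind == "kruskal":
                groups = [
                    g[spec["metric"]].dropna().to_numpy()
                    for _, g in sessions.groupby(spec["group_by"])
                ]
                res = sps.kruskal(*groups)
                stat, p, extra = res.statistic, res.pvalue, {}
            elif kind == "pearson":
                sub = sessions[[spec["metric"], spec["metric2"]]].dropna()
                res = sps.pearsonr(sub[spec["metric"]], sub[spec["metric2"]])
                stat, p = res.statistic, res.pvalue
                extra = {"r2": float(stat) ** 2}
            else:
                raise AnalysisError(f"unknown test kind {kind!r}")
            rows.append({"name": name, "kind": kind, "stat": float(stat),
                         "p": float(p), "skipped": False, **extra})
        except (ValueError, KeyError) as e:
            rows.append({"name": name, "kind": kind, "stat": np.nan, "p": np.nan,
                         "skipped": True, "note": str(e)})
    out = pd.DataFrame(rows)
    if bonferroni:
        m = (~out["skipped"]).sum()
        out["p_bonferroni"] = np.minimum(1.0, out["p"] * m)
    return out
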