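"""Synthetic session generator with planted ground truth.

Emulates one all-optical experiment end to end: task-rule-obeying running
and licking on the 200-cm virtual track, place-tuned calcium transients for
a configurable fraction of neurons, photostimulation-evoked transients in
targeted cells, planted suppression/enhancement of non-targeted cells after
stimulus onset, and planted post-epoch remapping. Every planted label is
returned as ground truth so downstream recovery can be verified by
construction.

Task rules enforced by the generator (and re-checked by an independent
replay oracle in the test suite):

* reward only after >= 3 s in the reward zone and >= 3 in-zone licks,
* the 11th lick outside the reward zone instantly ends the trial,
* running into the back wall ends the trial,
* correct trials are followed by >= 5 s dark timeout, failures by >= 10 s
  white timeout, and no licks occur within 3 s of the next trial start.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.signal import lfilter

from .errors import ConfigError, ProtocolError
from .session import (
    BEHAVIOR_RATE,
    FRAME_RATE,
    UM_PER_PIXEL,
    BOUT_MS,
    N_CLUSTERS,
    BehaviorTimeseries,
    EpochSet,
    SessionData,
    StimProtocol,
    TraceMatrix,
    TrackGeometry,
    build_trial_table,
)

CATEGORIES = ("start_pc", "reward_pc", "stim_zone_pc", "other_pc", "non_pc")


@dataclass
class NeuronSpec:
    """Generative parameters and planted labels for one simulated neuron."""

    is_place_cell: bool
    field_center: float  # cm
    field_width: float  # cm (Gaussian SD of the event-rate modulation)
    field_amplitude: float  # peak dF/F of a single transient
    baseline_rate: float  # transients/s outside the field
    is_target: bool = False
    response_prob: float = 0.0  # per-trial probability of an evoked transient
    response_amp: float = 0.0  # dF/F of the evoked transient
    perturbation: str = "none"  # none | suppressed | enhanced
    perturbation_magnitude: float = 0.0
    post_shift: float = 0.0  # cm added to the field center in the post epoch
    pre_center: Optional[float] = None  # full remap from the pre epoch onward
    category: str = "non_pc"  # planted zone label

    def validate(self) -> None:
        if not 0.0 <= self.field_center <= 200.0:
            raise ConfigError("field_center outside [0, 200] cm")
        for p in (self.response_prob,):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        for a in (self.field_amplitude, self.response_amp, self.baseline_rate):
            if a < 0:
                raise ConfigError("amplitudes and rates must be >= 0")
        if self.perturbation not in ("none", "suppressed", "enhanced"):
            raise ConfigError(f"unknown perturbation {self.perturbation!r}")


@dataclass
class SimConfig:
    """Study conditions of a simulated session.

    Defaults reproduce the recorded cohort: ~600 neurons of which 27% carry
    place fields, ~44 start-zone and ~49 reward-zone cells, 15/5/10/5-minute
    epochs, and a trial economy tuned to ~19 completed trials per 10-minute
    stimulation epoch.
    """

    # population
    n_neurons: int = 600
    place_cell_fraction: float = 0.27
    n_start_pc: int = 44
    n_reward_pc: int = 49
    # epoch durations, s
    epoch_baseline: float = 900.0
    epoch_pre: float = 300.0
    epoch_stim: float = 600.0
    epoch_post: float = 300.0
    # behavior
    mean_speed: float = 15.0  # cm/s
    speed_sd: float = 3.0
    speed_segment_s: float = 2.0
    start_latency_mean: float = 10.0  # s, pause at the trial start
    in_zone_lick_rate: float = 4.0  # Hz while waiting in the reward zone
    out_zone_lick_rate: float = 0.15  # Hz background licking elsewhere
    stim_zone_lick_boost: float = 0.0  # extra Hz in the stim zone on stim trials
    success_prob: float = 0.61
    fail_lick_frac: float = 0.6  # lick failures among intended failures
    timeout_correct_s: float = 5.0
    timeout_fail_s: float = 10.0
    post_reward_delay_s: float = 1.0
    slowdown_positions: Optional[list[float]] = None  # planted stop per stim trial
    # calcium traces
    calcium_tau_s: float = 0.4
    noise_sd: float = 0.05
    f0_range: tuple[float, float] = (80.0, 120.0)
    in_field_event_rate: float = 2.5  # transients/s at the field center
    baseline_event_rate: float = 0.05
    baseline_event_amp: float = 0.5
    field_width_range: tuple[float, float] = (6.0, 12.0)
    field_amp_range: tuple[float, float] = (0.6, 1.5)
    # stimulation
    stim_targets: str = "reward_pc"  # start_pc | reward_pc | non_pc | none
    n_targets: Optional[int] = None  # None = every cell of the targeted category
    response_prob: float = 0.8
    response_amp: float = 0.6
    # planted perturbations of non-targeted cells
    n_suppressed: int = 0
    n_enhanced: int = 0
    suppression_magnitude: float = 0.5
    enhancement_magnitude: float = 0.5
    perturbed_center_range: tuple[float, float] = (129.0, 150.0)
    n_off_target: int = 0
    off_target_radius_um: float = 15.0
    # planted remapping
    post_shift_cm: float = 0.0
    post_shift_category: str = "start_pc"
    remap_fraction: float = 0.0  # PCs fully remapped between baseline and pre

    def validate(self) -> None:
        n_pc = round(self.n_neurons * self.place_cell_fraction)
        if self.n_start_pc + self.n_reward_pc > n_pc:
            raise ConfigError("zone place-cell counts exceed the place-cell budget")
        if n_pc > self.n_neurons:
            raise ConfigError("place cells exceed n_neurons")
        if self.stim_targets not in ("start_pc", "reward_pc", "non_pc", "none"):
            raise ConfigError(f"unknown stim_targets {self.stim_targets!r}")
        min_trial = 200.0 / max(self.mean_speed, 1e-9) + self.timeout_fail_s
        for name in ("epoch_baseline", "epoch_pre", "epoch_stim", "epoch_post"):
            if getattr(self, name) < min_trial:
                raise ConfigError(f"{name} shorter than one feasible trial")

    def epochs(self) -> EpochSet:
        b = self.epoch_baseline
        p = b + self.epoch_pre
        s = p + self.epoch_stim
        q = s + self.epoch_post
        return EpochSet(baseline=(0.0, b), pre=(b, p), stim=(p, s), post=(s, q))

    @property
    def total_duration(self) -> float:
        return (
            self.epoch_baseline + self.epoch_pre + self.epoch_stim + self.epoch_post
        )


@dataclass
class GroundTruth:
    """Planted labels of a simulated session, for recovery tests."""

    specs: list[NeuronSpec]
    category: np.ndarray  # planted zone label per neuron
    is_place_cell: np.ndarray
    is_target: np.ndarray
    perturbation: np.ndarray  # 'none' | 'suppressed' | 'enhanced'
    post_shift: np.ndarray
    off_target_ids: np.ndarray
    field_center: np.ndarray


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

def _segment_speeds(rng: np.random.Generator, cfg: SimConfig, n_samples: int) -> np.ndarray:
    """Piecewise-constant running speed, clipped well above the 5 cm/s filter."""
    seg = max(1, int(round(cfg.speed_segment_s * BEHAVIOR_RATE)))
    n_seg = int(np.ceil(n_samples / seg))
    v = np.clip(rng.normal(cfg.mean_speed, cfg.speed_sd, n_seg), 6.0, 35.0)
    return np.repeat(v, seg)[:n_samples]


def simulate_behavior(
    config: SimConfig,
    seed: int,
    geometry: TrackGeometry | None = None,
) -> BehaviorTimeseries:
    """Generate a rule-obeying 100-Hz behavior log spanning all four epochs."""
    config.validate()
    geometry = geometry or TrackGeometry()
    rng = np.random.default_rng(seed)
    dt = 1.0 / BEHAVIOR_RATE
    n_total = int(round(config.total_duration * BEHAVIOR_RATE))
    stim_lo, stim_hi = config.epochs().interval("stim")
    zone_lo, zone_hi = geometry.reward_zone

    pos = np.zeros(n_total)
    speed = np.zeros(n_total)
    lick = np.zeros(n_total, dtype=bool)
    reward = np.zeros(n_total, dtype=bool)
    tid = np.full(n_total, -1, dtype=np.int64)
    inw = np.zeros(n_total, dtype=bool)

    cursor = 0
    trial = 0
    stim_trial_counter = 0
    while True:
        p_pos, p_speed, lick_samples, reward_time, iti = _plan_trial(
            rng, config, geometry, cursor * dt, stim_lo, stim_hi, stim_trial_counter
        )
        n_trial = p_pos.size
        if cursor + n_trial >= n_total:
            break  # drop the in-progress trial; the session ends in an ITI
        sl = slice(cursor, cursor + n_trial)
        pos[sl] = p_pos
        speed[sl] = p_speed
        tid[sl] = trial
        inw[sl] = True
        for ls in lick_samples:
            lick[cursor + ls] = True
        if reward_time is not None:
            idx = cursor + min(n_trial - 1, int(round(reward_time * BEHAVIOR_RATE)))
            reward[idx] = True
        t_start = cursor * dt
        if stim_lo <= t_start < stim_hi:
            stim_trial_counter += 1
        cursor += n_trial + int(round(iti * BEHAVIOR_RATE))
        trial += 1
        if cursor >= n_total:
            break

    time = np.arange(n_total) * dt
    behavior = BehaviorTimeseries(
        time=time,
        position=pos,
        speed=speed,
        lick_flags=lick,
        reward_flags=reward,
        trial_id=tid,
        in_world=inw,
    )
    behavior.validate(geometry.track_length)
    return behavior


def _plan_trial(rng, cfg, geometry, t_start, stim_lo, stim_hi, stim_trial_idx):
    """Build per-sample arrays for one trial; returns (pos, speed, licks, reward_t, iti).

    Times in the returned lick/reward values are relative to the trial start.
    The 11-out-zone-lick rule is enforced by a final scan that truncates the
    trial at the violating lick, so no trial can continue past its 11th
    out-of-zone lick regardless of the intended outcome.
    """
    dt = 1.0 / BEHAVIOR_RATE
    zone_lo, zone_hi = geometry.reward_zone
    in_stim_epoch = stim_lo <= t_start < stim_hi

    u = rng.random()
    if u < cfg.success_prob:
        intended = "correct"
        x_stop = rng.uniform(zone_lo + 6.0, zone_hi - 2.0)
    elif rng.random() < cfg.fail_lick_frac:
        intended = "fail_lick"
        x_stop = rng.uniform(geometry.stim_point + 1.0, zone_lo - 5.0)
    else:
        intended = "overshoot"
        x_stop = geometry.track_length

    # phase 1: latency at the track start
    latency = min(30.0, rng.exponential(cfg.start_latency_mean))
    n_lat = int(round(latency * BEHAVIOR_RATE))

    # phase 2: run to x_stop
    max_run = int(np.ceil(geometry.track_length / 6.0 * BEHAVIOR_RATE)) + 10
    v_run = _segment_speeds(rng, cfg, max_run)
    x_run = np.cumsum(v_run) * dt
    n_run = int(np.searchsorted(x_run, min(x_stop, geometry.track_length)) + 1)
    n_run = min(n_run, max_run)
    v_run = v_run[:n_run]
    x_run = np.minimum(x_run[:n_run], geometry.track_length)

    # optional planted slowdown (a brief stop) on stimulation-epoch trials
    if cfg.slowdown_positions is not None and in_stim_epoch:
        if stim_trial_idx < len(cfg.slowdown_positions):
            sp = cfg.slowdown_positions[stim_trial_idx]
            k = int(np.searchsorted(x_run, sp))
            if 0 < k < n_run:
                n_slow = int(round(0.7 * BEHAVIOR_RATE))
                v_run = np.concatenate([v_run[:k], np.zeros(n_slow), v_run[k:]])
                x_run = np.concatenate(
                    [x_run[:k], np.full(n_slow, x_run[k - 1]), x_run[k:]]
                )
                n_run += n_slow

    pos = np.concatenate([np.zeros(n_lat), x_run])
    speed = np.concatenate([np.zeros(n_lat), v_run])
    t_run_end = pos.size * dt

    lick_times: list[float] = []
    reward_time: float | None = None

    # background out-of-zone licking during latency + run
    n_bg = rng.poisson(cfg.out_zone_lick_rate * t_run_end)
    lick_times.extend(rng.uniform(0.0, t_run_end, n_bg))

    # planted stimulation-zone lick surge
    if in_stim_epoch and cfg.stim_zone_lick_boost > 0:
        sz_lo, sz_hi = geometry.stim_zone
        in_sz = (pos >= sz_lo) & (pos <= sz_hi) & (speed > 0)
        dur = in_sz.sum() * dt
        if dur > 0:
            n_extra = rng.poisson(cfg.stim_zone_lick_boost * dur)
            sz_times = np.flatnonzero(in_sz) * dt
            if n_extra and sz_times.size:
                lick_times.extend(rng.choice(sz_times, n_extra))

    if intended == "correct":
        # zone entry is the crossing of the reward-zone boundary while running
        entry_idx = int(np.searchsorted(x_run, zone_lo))
        t_entry = (n_lat + entry_idx) * dt
        reward_time = t_entry + 3.05 + rng.exponential(0.3)
        dwell_end = reward_time + cfg.post_reward_delay_s
        # three anchor licks guarantee the >= 3 in-zone licks precondition
        # even if random licks collide on the sample grid (the animal is in
        # the zone from t_entry onward)
        lick_times.extend([reward_time - 0.7, reward_time - 0.4,
                           reward_time - 0.1])
        n_in = rng.poisson(cfg.in_zone_lick_rate * (reward_time - t_run_end))
        lick_times.extend(rng.uniform(t_run_end + 0.05, reward_time - 0.03, n_in))
        # post-reward: 1 s delay then the 3 licks that end the trial
        end_licks = dwell_end + 0.05 + np.arange(3) * 0.3
        lick_times.extend(end_licks)
        t_end = end_licks[-1] + 0.1
    elif intended == "fail_lick":
        # false stop mid-track with a lick burst; the 11th lick ends the trial
        burst = t_run_end + 0.1 + np.arange(11) / cfg.in_zone_lick_rate
        lick_times.extend(burst)
        t_end = burst[-1] + 0.01
    else:  # overshoot into the back wall
        t_end = t_run_end + 0.2

    n_tail = int(round(t_end * BEHAVIOR_RATE)) - pos.size
    if n_tail > 0:
        pos = np.concatenate([pos, np.full(n_tail, pos[-1])])
        speed = np.concatenate([speed, np.zeros(n_tail)])

    # snap licks to the 100-Hz grid (collapsing coincident licks), then
    # rule-scan: the trial is truncated at its 11th out-of-zone lick
    lick_samples = sorted(
        {
            int(round(t * BEHAVIOR_RATE))
            for t in lick_times
            if 0 <= int(round(t * BEHAVIOR_RATE)) < pos.size
        }
    )
    n_out = 0
    cut: int | None = None
    for ls in lick_samples:
        p = pos[ls]
        if not (zone_lo <= p <= zone_hi):
            n_out += 1
            if n_out > 10:
                cut = ls
                break
    if cut is not None:
        pos = pos[: cut + 1]
        speed = speed[: cut + 1]
        lick_samples = [s for s in lick_samples if s <= cut]
        if reward_time is not None and reward_time * BEHAVIOR_RATE > cut:
            reward_time = None
        intended = "fail_lick"

    iti = cfg.timeout_correct_s if reward_time is not None else cfg.timeout_fail_s
    return pos, speed, lick_samples, reward_time, iti


def stim_onset_times(
    behavior: BehaviorTimeseries,
    epochs: EpochSet,
    geometry: TrackGeometry | None = None,
    epoch: str = "stim",
) -> np.ndarray:
    """Times at which a trial starting in ``epoch`` first crosses the trigger point.

    With ``epoch='pre'`` or ``'post'`` this yields sham onsets for
    no-stimulation response analyses.
    """
    geometry = geometry or TrackGeometry()
    lo, hi = epochs.interval(epoch)
    times = []
    for rec in build_trial_table(behavior, geometry):
        if not (lo <= rec.start_time < hi) or not rec.reached_stim_point:
            continue
        sl = (behavior.time >= rec.start_time) & (behavior.time < rec.end_time)
        idx = np.flatnonzero(sl & (behavior.position >= geometry.stim_point))
        if idx.size and behavior.time[idx[0]] < hi:
            times.append(behavior.time[idx[0]])
    return np.asarray(times)


# ---------------------------------------------------------------------------
# Neuron specs
# ---------------------------------------------------------------------------

def make_neuron_specs(config: SimConfig, seed: int) -> list[NeuronSpec]:
    """Draw the per-neuron generative parameters and planted labels."""
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_neurons
    n_pc = int(round(n * config.place_cell_fraction))
    n_start = min(config.n_start_pc, n_pc)
    n_reward = min(config.n_reward_pc, n_pc - n_start)
    n_other = n_pc - n_start - n_reward

    specs: list[NeuronSpec] = []
    geometry = TrackGeometry()

    def _nominal_category(center: float, width: float) -> tuple[str, bool]:
        """Planted zone label from the field's nominal extent.

        The detectable field of a Gaussian rate bump extends to where the
        bump falls to 25% of its peak, i.e. +/- 1.665 SD of the map-level
        width. The map widens the planted bump by the 3-bin smoothing kernel
        (6.8 cm SD added in quadrature) and drags a calcium-decay tail of
        roughly speed * tau (~6 cm) in the running direction. The label then
        follows the same >50% zone-coverage rule as the classifier; draws
        whose coverage is ambiguous (40-60%) are flagged for redraw so
        planted labels are unambiguous by construction.
        """
        sd_map = float(np.hypot(width, 3.0 * 2.27))
        half = 1.665 * sd_map
        tail = config.mean_speed * config.calcium_tau_s
        lo, hi = center - half, center + half + tail

        def cov(zone):
            o = max(0.0, min(hi, zone[1]) - max(lo, zone[0]))
            return o / (zone[1] - zone[0])

        covs = {
            "start_pc": cov(geometry.start_zone),
            "reward_pc": cov(geometry.reward_zone),
            "stim_zone_pc": cov(geometry.stim_zone),
        }
        ambiguous = any(0.4 < c <= 0.6 for c in covs.values())
        if covs["start_pc"] > 0.5 or covs["reward_pc"] > 0.5:
            cat = "start_pc" if covs["start_pc"] >= covs["reward_pc"] else "reward_pc"
        elif covs["stim_zone_pc"] > 0.5:
            cat = "stim_zone_pc"
        else:
            cat = "other_pc"
        return cat, ambiguous

    def _pc(center: float, width: float) -> NeuronSpec:
        cat, _ = _nominal_category(center, width)
        return NeuronSpec(
            is_place_cell=True,
            field_center=float(np.clip(center, 2.0, 198.0)),
            field_width=width,
            field_amplitude=float(rng.uniform(*config.field_amp_range)),
            baseline_rate=config.baseline_event_rate,
            category=cat,
        )

    def _draw(lo_c, hi_c, want=None, width_lo=None):
        w_lo, w_hi = config.field_width_range
        if width_lo is not None:
            w_lo = max(w_lo, width_lo)
        for _ in range(100):
            c = rng.uniform(lo_c, hi_c)
            w = rng.uniform(w_lo, w_hi)
            cat, ambiguous = _nominal_category(c, w)
            if ambiguous:
                continue
            if want is None or cat == want:
                return c, w
        return c, w  # pragma: no cover - accept the last draw

    # centers stay within the part of the track the task reliably samples:
    # correct trials end at the in-zone stop, so bins past ~176 cm are
    # occupied only on overshoot trials and fields there are undetectable
    for _ in range(n_start):
        specs.append(_pc(*_draw(29.0, 41.0, want="start_pc", width_lo=8.0)))
    for _ in range(n_reward):
        specs.append(_pc(*_draw(163.5, 173.5, want="reward_pc", width_lo=8.0)))
    n_perturb = min(config.n_suppressed + config.n_enhanced, n_other)
    for i in range(n_other):
        if i < n_perturb:
            specs.append(_pc(*_draw(*config.perturbed_center_range)))
        else:
            specs.append(_pc(*_draw(5.0, 172.0)))
    for _ in range(n - n_pc):
        specs.append(
            NeuronSpec(
                is_place_cell=False,
                field_center=float(rng.uniform(0.0, 200.0)),
                field_width=10.0,
                field_amplitude=0.0,
                baseline_rate=config.baseline_event_rate,
                category="non_pc",
            )
        )

    # planted suppression / enhancement among the re-centered other-PCs
    k = 0
    for i in range(n_start + n_reward, n_start + n_reward + n_perturb):
        if k < config.n_suppressed:
            specs[i] = replace(
                specs[i],
                perturbation="suppressed",
                perturbation_magnitude=config.suppression_magnitude,
            )
        else:
            specs[i] = replace(
                specs[i],
                perturbation="enhanced",
                perturbation_magnitude=config.enhancement_magnitude,
            )
        k += 1

    # planted post-epoch remapping
    if config.post_shift_cm:
        for i, s in enumerate(specs):
            if s.category == config.post_shift_category:
                specs[i] = replace(s, post_shift=config.post_shift_cm)
    if config.remap_fraction > 0:
        pcs = [i for i, s in enumerate(specs) if s.is_place_cell]
        n_remap = int(round(config.remap_fraction * len(pcs)))
        for i in rng.choice(pcs, n_remap, replace=False):
            specs[i] = replace(specs[i], pre_center=float(rng.uniform(5.0, 195.0)))

    # shuffle neuron order so indices carry no category information
    order = rng.permutation(n)
    specs = [specs[i] for i in order]
    for s in specs:
        s.validate()
    return specs


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------

def _epoch_center(spec: NeuronSpec, epoch_labels: np.ndarray) -> np.ndarray:
    """Field center per frame, honoring planted remapping and post shifts."""
    base = spec.field_center
    later = spec.pre_center if spec.pre_center is not None else base
    centers = np.full(epoch_labels.size, base)
    centers[np.isin(epoch_labels, ("pre", "stim"))] = later
    centers[epoch_labels == "post"] = np.clip(later + spec.post_shift, 1.0, 199.0)
    return centers


def simulate_traces(
    behavior: BehaviorTimeseries,
    specs: list[NeuronSpec],
    config: SimConfig,
    seed: int,
    geometry: TrackGeometry | None = None,
) -> TraceMatrix:
    """Simulate raw somatic fluorescence from behavior and neuron specs.

    Transient events are drawn as an inhomogeneous Poisson process whose rate
    is a Gaussian bump over position (while the animal moves in-world),
    convolved with a single-exponential calcium kernel; raw fluorescence is
    F0 * (1 + dF/F + noise).
    """
    geometry = geometry or TrackGeometry()
    rng = np.random.default_rng(seed)
    epochs = config.epochs()
    n = len(specs)
    t_total = int(round(config.total_duration * FRAME_RATE))
    frame_time = np.arange(t_total) / FRAME_RATE

    pos = np.interp(frame_time, behavior.time, behavior.position)
    spd = np.interp(frame_time, behavior.time, behavior.speed)
    idx = np.clip(np.searchsorted(behavior.time, frame_time), 0, behavior.time.size - 1)
    inw = behavior.in_world[idx]
    f_tid = behavior.trial_id[idx]
    labels = epochs.label(frame_time)
    moving = inw & (spd > 2.0)

    impulses = np.zeros((n, t_total), dtype=np.float32)
    noise_seed = int(rng.integers(2**31))
    event_rng = np.random.default_rng(int(rng.integers(2**31)))
    dt = 1.0 / FRAME_RATE
    for i, s in enumerate(specs):
        lam = np.full(t_total, s.baseline_rate)
        if s.is_place_cell:
            c = _epoch_center(s, labels)
            bump = np.exp(-0.5 * ((pos - c) / s.field_width) ** 2)
            lam = lam + (config.in_field_event_rate - s.baseline_rate) * bump * moving
        counts = event_rng.poisson(lam * dt)
        amp = s.field_amplitude if s.is_place_cell else config.baseline_event_amp
        impulses[i] = counts * amp

    f0 = rng.uniform(*config.f0_range, n)
    centroids = rng.uniform(0.0, 512.0, (n, 2))
    sim_state = {
        "impulses": impulses,
        "f0": f0,
        "noise_seed": noise_seed,
        "noise_sd": config.noise_sd,
        "tau": config.calcium_tau_s,
        "frame_trial_id": f_tid,
        "epochs": epochs,
        "geometry": geometry,
        "specs": specs,
    }
    fluo = _compose_fluorescence(sim_state, t_total)
    return TraceMatrix(
        fluorescence=fluo,
        frame_time=frame_time,
        roi_centroids=centroids,
        artifact_mask=np.zeros(t_total, dtype=bool),
        frame_rate=FRAME_RATE,
        sim_state=sim_state,
    )


def _compose_fluorescence(sim_state: dict, t_total: int) -> np.ndarray:
    a = np.exp(-1.0 / (sim_state["tau"] * FRAME_RATE))
    signal = lfilter([1.0], [1.0, -a], sim_state["impulses"].astype(np.float64), axis=1)
    noise = np.random.default_rng(sim_state["noise_seed"]).normal(
        0.0, sim_state["noise_sd"], signal.shape
    )
    return sim_state["f0"][:, None] * (1.0 + signal + noise)


def apply_stimulation(
    traces: TraceMatrix,
    protocol: StimProtocol,
    specs: list[NeuronSpec],
    seed: int,
) -> TraceMatrix:
    """Plant photostimulation effects into simulator-produced traces.

    Per stimulation trial each target (and any planted off-target responder)
    emits a transient of its ``response_amp`` with probability
    ``response_prob``, time-locked to the end of each of its cluster's two
    illumination intervals. Cells marked suppressed/enhanced have their
    transient amplitudes scaled down/up from the bout onset to the end of
    that trial. All frames overlapping the 1045-ms bout are flagged in the
    artifact mask.
    """
    if traces.sim_state is None:
        raise ConfigError("apply_stimulation requires simulator-produced traces")
    state = traces.sim_state
    epochs: EpochSet = state["epochs"]
    stim_lo, stim_hi = epochs.interval("stim")
    onset_times = traces.frame_time[protocol.trial_onsets]
    if np.any((onset_times < stim_lo) | (onset_times >= stim_hi)):
        raise ProtocolError("stimulation onset outside the stim epoch")

    rng = np.random.default_rng(seed)
    impulses = state["impulses"].copy()
    t_total = impulses.shape[1]
    f_tid = state["frame_trial_id"]
    mask = traces.artifact_mask.copy()

    # frames at which each of the 10 cluster illuminations ends
    sched = StimProtocol.empty().schedule_ms()
    end_frames = np.array(
        [int(round(off / 1000.0 * FRAME_RATE)) for _, _, off in sched]
    )
    clusters = np.array([c for c, _, _ in sched])

    responders = [
        i for i, s in enumerate(specs) if s.response_prob > 0 and s.response_amp > 0
    ]
    target_cluster = {
        int(t): int(c)
        for t, c in zip(protocol.target_ids, protocol.cluster_assignment)
    }
    # an off-target responder is driven by the nearest beamlet's cluster
    cluster_for: dict[int, int] = {}
    for i in responders:
        if i in target_cluster:
            cluster_for[i] = target_cluster[i]
        elif protocol.n_targets:
            d = np.linalg.norm(
                traces.roi_centroids[protocol.target_ids] - traces.roi_centroids[i],
                axis=1,
            )
            cluster_for[i] = int(protocol.cluster_assignment[np.argmin(d)])
    perturbed = [i for i, s in enumerate(specs) if s.perturbation != "none"]

    n_bout_frames = int(np.ceil(BOUT_MS / 1000.0 * FRAME_RATE))
    for o in protocol.trial_onsets:
        o = int(o)
        mask[o : min(t_total, o + n_bout_frames + 1)] = True
        trial = f_tid[o]
        for i in responders:
            s = specs[i]
            if rng.random() >= s.response_prob:
                continue
            c = cluster_for.get(i, 0)
            for f in end_frames[clusters == c]:
                j = o + int(f)
                if j < t_total:
                    impulses[i, j] += s.response_amp
        if trial >= 0:
            span = (f_tid == trial) & (np.arange(t_total) >= o)
            for i in perturbed:
                s = specs[i]
                factor = (
                    1.0 - s.perturbation_magnitude
                    if s.perturbation == "suppressed"
                    else 1.0 + s.perturbation_magnitude
                )
                impulses[i, span] *= factor

    new_state = dict(state)
    new_state["impulses"] = impulses
    fluo = _compose_fluorescence(new_state, t_total)
    return TraceMatrix(
        fluorescence=fluo,
        frame_time=traces.frame_time,
        roi_centroids=traces.roi_centroids,
        artifact_mask=mask,
        frame_rate=traces.frame_rate,
        sim_state=new_state,
    )


# ---------------------------------------------------------------------------
# Full session
# ---------------------------------------------------------------------------

def _build_protocol(
    config: SimConfig,
    specs: list[NeuronSpec],
    centroids: np.ndarray,
    behavior: BehaviorTimeseries,
    geometry: TrackGeometry,
    rng: np.random.Generator,
) -> tuple[StimProtocol, list[NeuronSpec]]:
    """Choose targets, cluster them spatially and schedule per-trial onsets."""
    if config.stim_targets == "none":
        return StimProtocol.empty(), specs
    pool = [i for i, s in enumerate(specs) if s.category == config.stim_targets]
    if config.n_targets is not None:
        pool = pool[: config.n_targets]
    elif config.stim_targets == "non_pc":
        pool = pool[:60]
    targets = np.array(sorted(pool), dtype=np.int64)
    if targets.size == 0:
        raise ConfigError(f"no neurons of category {config.stim_targets!r} to target")

    # five spatial clusters across the field of view (by centroid x)
    order = targets[np.argsort(centroids[targets, 0], kind="stable")]
    cluster_of = np.empty(targets.size, dtype=np.int64)
    split = np.array_split(np.arange(targets.size), N_CLUSTERS)
    rank = {int(t): r for r, t in enumerate(order)}
    bounds = np.cumsum([len(s) for s in split])
    for k, t in enumerate(targets):
        cluster_of[k] = int(np.searchsorted(bounds, rank[int(t)], side="right"))

    onset_t = stim_onset_times(behavior, config.epochs(), geometry, "stim")
    onsets = np.floor(onset_t * FRAME_RATE).astype(np.int64)
    beamlets = centroids[targets] * UM_PER_PIXEL

    new_specs = list(specs)
    for k, t in enumerate(targets):
        new_specs[t] = replace(
            new_specs[t],
            is_target=True,
            response_prob=config.response_prob,
            response_amp=config.response_amp,
        )

    # planted off-target responders near beamlets (non-targets)
    if config.n_off_target > 0:
        non_targets = [i for i in range(len(specs)) if i not in set(targets.tolist())]
        chosen = rng.choice(non_targets, config.n_off_target, replace=False)
        for j, i in enumerate(chosen):
            anchor = int(targets[j % targets.size])
            offset = rng.uniform(-1, 1, 2)
            offset *= config.off_target_radius_um / UM_PER_PIXEL / np.sqrt(2)
            centroids[i] = np.clip(centroids[anchor] + offset, 0.0, 511.99)
            new_specs[i] = replace(
                new_specs[i],
                response_prob=config.response_prob,
                response_amp=config.response_amp,
            )

    protocol = StimProtocol(
        target_ids=targets,
        cluster_assignment=cluster_of,
        trial_onsets=onsets,
        beamlet_xy=beamlets,
    )
    return protocol, new_specs


def make_session(
    config: SimConfig, seed: int, geometry: TrackGeometry | None = None
) -> tuple[SessionData, GroundTruth]:
    """Compose behavior, traces and stimulation into a four-epoch session."""
    config.validate()
    geometry = geometry or TrackGeometry()
    rng = np.random.default_rng(seed)
    s_beh, s_spec, s_tr, s_stim = (int(rng.integers(2**31)) for _ in range(4))

    behavior = simulate_behavior(config, s_beh, geometry)
    specs = make_neuron_specs(config, s_spec)
    traces = simulate_traces(behavior, specs, config, s_tr, geometry)
    protocol, specs = _build_protocol(
        config, specs, traces.roi_centroids, behavior, geometry, rng
    )
    traces.sim_state["specs"] = specs
    if not protocol.is_empty:
        traces = apply_stimulation(traces, protocol, specs, s_stim)

    off_target = np.array(
        [
            i
            for i, s in enumerate(specs)
            if s.response_prob > 0 and not s.is_target
        ],
        dtype=np.int64,
    )
    truth = GroundTruth(
        specs=specs,
        category=np.array([s.category for s in specs]),
        is_place_cell=np.array([s.is_place_cell for s in specs]),
        is_target=np.array([s.is_target for s in specs]),
        perturbation=np.array([s.perturbation for s in specs]),
        post_shift=np.array([s.post_shift for s in specs]),
        off_target_ids=off_target,
        field_center=np.array([s.field_center for s in specs]),
    )
    session = SessionData(
        behavior=behavior,
        traces=traces,
        epochs=config.epochs(),
        protocol=protocol,
        geometry=geometry,
        meta={"seed": seed, "stim_targets": config.stim_targets},
    )
    session.validate()
    return session, truth


def save_ground_truth(path: str, truth: GroundTruth) -> None:
    """Append planted labels to a session container under ``/truth``."""
    import h5py

    with h5py.File(path, "a") as f:
        if "truth" in f:
            del f["truth"]
        g = f.create_group("truth")
        g.create_dataset("category", data=truth.category.astype("S"))
        g.create_dataset("is_place_cell", data=truth.is_place_cell)
        g.create_dataset("is_target", data=truth.is_target)
        g.create_dataset("perturbation", data=truth.perturbation.astype("S"))
        g.create_dataset("post_shift", data=truth.post_shift)
        g.create_dataset("off_target_ids", data=truth.off_target_ids)
        g.create_dataset("field_center", data=truth.field_center)
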