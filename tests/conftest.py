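"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from placestim.session import (
    BehaviorTimeseries,
    TrackGeometry,
    build_trial_table,
)
from placestim.synth import SimConfig, make_session

# ---------------------------------------------------------------------------
# Independent oracles (deliberately simple, separate from the implementation)
# ---------------------------------------------------------------------------


def brute_force_dff(raw: np.ndarray, window: int = 300, q: float = 8.0) -> np.ndarray:
    """Per-frame recomputation of the sliding-percentile baseline."""
    raw = np.asarray(raw, dtype=np.float64)
    t_total = raw.size
    half = window // 2
    out = np.empty(t_total)
    for t in range(t_total):
        lo = max(0, t - half)
        hi = min(t_total, t - half + window)
        f0 = np.percentile(raw[lo:hi], q)
        out[t] = (raw[t] - f0) / f0
    return out


def replay_rule_violations(behavior: BehaviorTimeseries,
                           geometry: TrackGeometry | None = None) -> list[str]:
    """Re-check the task rules from the raw event log, trial by trial.

    Violations checked: a reward without >= 3 s of continuous reward-zone
    presence or without >= 3 in-zone licks since zone entry; a trial
    continuing more than 0.05 s past its 11th out-of-zone lick.
    """
    geometry = geometry or TrackGeometry()
    lo, hi = geometry.reward_zone
    dt = behavior.dt
    violations: list[str] = []
    tid = behavior.trial_id
    for t in np.unique(tid[tid >= 0]):
        idx = np.flatnonzero(tid == t)
        pos = behavior.position[idx]
        licks = behavior.lick_flags[idx]
        rewards = np.flatnonzero(behavior.reward_flags[idx])
        in_zone = (pos >= lo) & (pos <= hi)
        out_licks = np.flatnonzero(licks & ~in_zone)
        if out_licks.size > 10:
            k11 = out_licks[10]
            if idx.size - 1 - k11 > int(0.05 / dt):
                violations.append(f"trial {t}: continued past the 11th out-zone lick")
        for r in rewards:
            if not in_zone[r]:
                violations.append(f"trial {t}: reward outside the zone")
                continue
            entry = r
            while entry > 0 and in_zone[entry - 1]:
                entry -= 1
            dwell = (r - entry) * dt
            n_in_licks = np.count_nonzero(licks[entry : r + 1] & in_zone[entry : r + 1])
            if dwell < 3.0 - 2 * dt:
                violations.append(f"trial {t}: reward after only {dwell:.2f} s in zone")
            if n_in_licks < 3:
                violations.append(f"trial {t}: reward after {n_in_licks} in-zone licks")
    return violations


def make_behavior(position, speed=None, licks=(), rewards=(), trial_ids=None,
                  in_world=None, fs=100.0):
    """Hand-built behavior log from plain arrays (for rule/edge-case tests)."""
    position = np.asarray(position, dtype=np.float64)
    n = position.size
    time = np.arange(n) / fs
    speed = np.full(n, 10.0) if speed is None else np.asarray(speed, dtype=np.float64)
    lick = np.zeros(n, dtype=bool)
    lick[list(licks)] = True
    reward = np.zeros(n, dtype=bool)
    reward[list(rewards)] = True
    tid = np.zeros(n, dtype=np.int64) if trial_ids is None else np.asarray(trial_ids)
    inw = np.ones(n, dtype=bool) if in_world is None else np.asarray(in_world)
    return BehaviorTimeseries(
        time=time, position=position, speed=speed, lick_flags=lick,
        reward_flags=reward, trial_id=tid, in_world=inw,
    )


def uniform_track_behavior(n_trials=8, speed=20.0, fs=100.0, track=200.0):
    """Repeated constant-speed traversals: near-uniform occupancy per trial."""
    n_per = int(round(track / speed * fs))
    pos = np.tile((np.arange(n_per) + 0.5) * speed / fs, n_trials)
    pos = np.clip(pos, 0, track)
    tid = np.repeat(np.arange(n_trials), n_per)
    return make_behavior(pos, speed=np.full(pos.size, speed), trial_ids=tid, fs=fs)


# ---------------------------------------------------------------------------
# Session fixtures (session-scoped: simulated once per test run)
# ---------------------------------------------------------------------------

SMALL_CFG = dict(
    n_neurons=120,
    n_start_pc=10,
    n_reward_pc=11,
    epoch_baseline=300.0,
    epoch_pre=180.0,
    epoch_stim=300.0,
    epoch_post=120.0,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(**SMALL_CFG)


@pytest.fixture(scope="session")
def small_session(small_cfg):
    """A compact stimulation session with ground truth, shared across tests."""
    return make_session(small_cfg, seed=7)


@pytest.fixture(scope="session")
def small_trials(small_session):
    session, _ = small_session
    return build_trial_table(session.behavior, session.geometry)
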