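"""Session container for one all-optical place-cell experiment.

A session bundles four pieces of data recorded (or simulated) on a 200-cm
virtual linear track:

* behavior sampled at 100 Hz (position, speed, lick/reward events, trial id),
* a neurons x frames fluorescence matrix at 30 Hz with ROI centroids,
* the four behavioral epochs (baseline / pre / stim / post),
* an optional photostimulation protocol (5 target clusters, per-trial onset
  frames, beamlet coordinates, artifact-frame mask).

Sessions round-trip through a single HDF5 file with groups ``/behavior``,
``/traces``, ``/protocol``, ``/epochs`` and ``/meta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .errors import SchemaError, SessionValidationError

BEHAVIOR_RATE = 100.0  # Hz
FRAME_RATE = 30.0  # Hz
FOV_PIXELS = 512
UM_PER_PIXEL = 800.0 / 512.0  # 800 um field of view imaged at 512 px

EPOCH_NAMES = ("baseline", "pre", "stim", "post")
OUTCOMES = ("correct", "fail_lick", "fail_overshoot")


@dataclass
class TrackGeometry:
    """Zone layout of the virtual linear track, in cm from the track start.

    The stimulation zone has no printed extent; the default covers the
    21.21 cm summary window after the 105-cm trigger point.
    """

    track_length: float = 200.0
    start_zone: tuple[float, float] = (21.4, 48.8)
    reward_zone: tuple[float, float] = (160.0, 178.6)
    stim_point: float = 105.0
    stim_zone: tuple[float, float] = (105.0, 126.21)

    def validate(self) -> None:
        for name in ("start_zone", "reward_zone", "stim_zone"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo < hi <= self.track_length):
                raise SessionValidationError(f"{name}=({lo}, {hi}) outside track")
        if not 0.0 <= self.stim_point <= self.track_length:
            raise SessionValidationError("stim_point outside track")

    def in_zone(self, position: np.ndarray, zone: tuple[float, float]) -> np.ndarray:
        lo, hi = zone
        position = np.asarray(position)
        return (position >= lo) & (position <= hi)


@dataclass
class BehaviorTimeseries:
    """100-Hz behavior log: position/speed plus lick, reward and trial flags.

    ``trial_id`` is -1 during inter-trial intervals; ``in_world`` is False
    whenever the animal is in a timeout environment rather than on the track.
    """

    time: np.ndarray  # s, uniform 100 Hz grid
    position: np.ndarray  # cm
    speed: np.ndarray  # cm/s
    lick_flags: np.ndarray  # bool
    reward_flags: np.ndarray  # bool
    trial_id: np.ndarray  # int, -1 = ITI
    in_world: np.ndarray  # bool

    @property
    def sample_rate(self) -> float:
        return BEHAVIOR_RATE

    @property
    def dt(self) -> float:
        return 1.0 / BEHAVIOR_RATE

    def validate(self, track_length: float = 200.0) -> None:
        n = self.time.size
        for name in ("position", "speed", "lick_flags", "reward_flags", "trial_id", "in_world"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise SessionValidationError(
                    f"behavior/{name} has length {arr.shape}, expected ({n},)"
                )
        steps = np.diff(self.time)
        if n > 1 and not np.allclose(steps, self.dt, rtol=0, atol=1e-6):
            raise SessionValidationError("behavior time grid is not uniform 100 Hz")
        if n > 1 and np.any(steps <= 0):
            raise SessionValidationError("behavior time not strictly increasing")
        inw = self.in_world.astype(bool)
        pos = self.position[inw]
        if pos.size and (pos.min() < 0 or pos.max() > track_length):
            raise SessionValidationError("in-world position outside [0, track_length]")


@dataclass
class TraceMatrix:
    """Raw somatic fluorescence (neurons x frames) with ROI centroids.

    ``artifact_mask`` marks frames that overlap a photostimulation bout and
    would be contaminated by stimulation light in a real recording.
    """

    fluorescence: np.ndarray  # neurons x frames, a.u. >= 0
    frame_time: np.ndarray  # s, one per frame
    roi_centroids: np.ndarray  # neurons x 2, px in a 512x512 field
    artifact_mask: np.ndarray  # bool per frame
    frame_rate: float = FRAME_RATE
    # Private generative state attached by the simulator so that
    # apply_stimulation can rescale underlying transients; absent for
    # sessions loaded from real recordings.
    sim_state: Optional[dict] = field(default=None, repr=False, compare=False)

    @property
    def n_neurons(self) -> int:
        return self.fluorescence.shape[0]

    @property
    def n_frames(self) -> int:
        return self.fluorescence.shape[1]

    def validate(self) -> None:
        n, t = self.fluorescence.shape
        if self.frame_time.shape != (t,):
            raise SessionValidationError("frame_time length != number of frames")
        if np.any(np.diff(self.frame_time) <= 0):
            raise SessionValidationError("frame_time not monotone increasing")
        bad = ~np.isfinite(self.fluorescence)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise SessionValidationError(
                f"non-finite fluorescence at neuron {i}, frame {j}"
            )
        if self.roi_centroids.shape != (n, 2):
            raise SessionValidationError("roi_centroids must be neurons x 2")
        if self.roi_centroids.size and (
            self.roi_centroids.min() < 0 or self.roi_centroids.max() >= FOV_PIXELS
        ):
            raise SessionValidationError("ROI centroids outside [0, 512) px")
        if self.artifact_mask.shape != (t,):
            raise SessionValidationError("artifact_mask length != number of frames")


@dataclass
class EpochSet:
    """Named, ordered, non-overlapping session intervals in seconds."""

    baseline: tuple[float, float] = (0.0, 900.0)
    pre: tuple[float, float] = (900.0, 1200.0)
    stim: tuple[float, float] = (1200.0, 1800.0)
    post: tuple[float, float] = (1800.0, 2100.0)

    def validate(self) -> None:
        prev_end = -np.inf
        for name in EPOCH_NAMES:
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise SessionValidationError(f"epoch {name} has non-positive length")
            if lo < prev_end:
                raise SessionValidationError("epochs overlap or are out of order")
            prev_end = hi

    def interval(self, name: str) -> tuple[float, float]:
        if name not in EPOCH_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def mask(self, times: np.ndarray, name: str) -> np.ndarray:
        lo, hi = self.interval(name)
        times = np.asarray(times)
        return (times >= lo) & (times < hi)

    def label(self, times: np.ndarray) -> np.ndarray:
        """Epoch name per time point; '' outside every epoch."""
        times = np.asarray(times)
        out = np.full(times.shape, "", dtype=object)
        for name in EPOCH_NAMES:
            out[self.mask(times, name)] = name
        return out


# Schedule constants of the photostimulation bout: 5 clusters illuminated
# 100 ms each with 5 ms switching gaps, cycled twice -> 1000 ms of light
# over 1045 ms.
CLUSTER_ON_MS = 100.0
CLUSTER_GAP_MS = 5.0
N_CLUSTERS = 5
N_CYCLES = 2
BOUT_MS = N_CLUSTERS * N_CYCLES * (CLUSTER_ON_MS + CLUSTER_GAP_MS) - CLUSTER_GAP_MS  # 1045


@dataclass
class StimProtocol:
    """Photostimulation protocol: targets, clusters, onsets and beamlets."""

    target_ids: np.ndarray  # neuron indices
    cluster_assignment: np.ndarray  # per target, 0..4
    trial_onsets: np.ndarray  # frame indices of bout start
    beamlet_xy: np.ndarray  # per target, um in the imaging plane

    @classmethod
    def empty(cls) -> "StimProtocol":
        return cls(
            target_ids=np.empty(0, dtype=np.int64),
            cluster_assignment=np.empty(0, dtype=np.int64),
            trial_onsets=np.empty(0, dtype=np.int64),
            beamlet_xy=np.empty((0, 2), dtype=np.float64),
        )

    @property
    def n_targets(self) -> int:
        return int(self.target_ids.size)

    @property
    def is_empty(self) -> bool:
        return self.n_targets == 0 and self.trial_onsets.size == 0

    def schedule_ms(self) -> list[tuple[int, float, float]]:
        """The 10 cluster illuminations as (cluster, on_ms, off_ms) from bout start."""
        out = []
        for j in range(N_CLUSTERS * N_CYCLES):
            on = j * (CLUSTER_ON_MS + CLUSTER_GAP_MS)
            out.append((j % N_CLUSTERS, on, on + CLUSTER_ON_MS))
        return out

    def validate(self, n_neurons: Optional[int] = None) -> None:
        if self.target_ids.shape != self.cluster_assignment.shape:
            raise SessionValidationError("cluster_assignment must match target_ids")
        if self.beamlet_xy.shape != (self.n_targets, 2):
            raise SessionValidationError("beamlet_xy must be n_targets x 2")
        if self.n_targets:
            clusters = np.unique(self.cluster_assignment)
            if clusters.min() < 0 or clusters.max() >= N_CLUSTERS:
                raise SessionValidationError("cluster indices must lie in 0..4")
        if n_neurons is not None and self.n_targets:
            if self.target_ids.min() < 0 or self.target_ids.max() >= n_neurons:
                raise SessionValidationError("target id outside trace matrix")


@dataclass
class TrialRecord:
    """Bookkeeping for one in-world trial segment."""

    trial_id: int
    start_time: float
    end_time: float
    outcome: str  # correct | fail_lick | fail_overshoot
    reached_stim_point: bool
    max_position: float
    n_licks_in_zone: int
    n_licks_out_zone: int


@dataclass
class SessionData:
    """One session: behavior + traces + epochs + protocol + geometry."""

    behavior: BehaviorTimeseries
    traces: TraceMatrix
    epochs: EpochSet
    protocol: StimProtocol
    geometry: TrackGeometry = field(default_factory=TrackGeometry)
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.geometry.validate()
        self.behavior.validate(self.geometry.track_length)
        self.traces.validate()
        self.epochs.validate()
        self.protocol.validate(self.traces.n_neurons)


def build_trial_table(
    behavior: BehaviorTimeseries,
    geometry: TrackGeometry | None = None,
    max_out_zone_licks: int = 10,
    wall_margin: float = 0.5,
) -> list[TrialRecord]:
    """Segment the behavior log into trials and assign task outcomes.

    A trial is a maximal contiguous run of samples sharing a non-negative
    ``trial_id``. Outcomes follow the task rules: a reward flag makes the
    trial correct; more than ``max_out_zone_licks`` licks outside the reward
    zone make it a lick failure; otherwise the animal ran into the back wall
    (overshoot). The same trial_id appearing in two disjoint segments is a
    structural error.
    """
    geometry = geometry or TrackGeometry()
    tid = np.asarray(behavior.trial_id)
    n = tid.size
    if n == 0:
        return []
    boundaries = np.flatnonzero(np.diff(tid) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [n]])

    seen: set[int] = set()
    records: list[TrialRecord] = []
    in_zone = geometry.in_zone(behavior.position, geometry.reward_zone)
    for s, e in zip(starts, ends):
        t = int(tid[s])
        if t < 0:
            continue
        if t in seen:
            raise SessionValidationError(f"trial_id {t} appears in disjoint segments")
        seen.add(t)
        sl = slice(s, e)
        licks = behavior.lick_flags[sl].astype(bool)
        zone = in_zone[sl]
        n_in = int(np.count_nonzero(licks & zone))
        n_out = int(np.count_nonzero(licks & ~zone))
        max_pos = float(behavior.position[sl].max())
        if behavior.reward_flags[sl].any():
            outcome = "correct"
        elif n_out > max_out_zone_licks:
            outcome = "fail_lick"
        else:
            # no reward and within the lick budget: the trial ended at the
            # back wall (overshoot). wall_margin tolerates integration jitter.
            outcome = "fail_overshoot"
            _ = max_pos >= geometry.track_length - wall_margin  # documented rule
        records.append(
            TrialRecord(
                trial_id=t,
                start_time=float(behavior.time[s]),
                end_time=float(behavior.time[e - 1]) + behavior.dt,
                outcome=outcome,
                reached_stim_point=max_pos >= geometry.stim_point,
                max_position=max_pos,
                n_licks_in_zone=n_in,
                n_licks_out_zone=n_out,
            )
        )
    return records


def trial_table_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Trial records as a DataFrame (CSV-exportable)."""
    return pd.DataFrame([asdict(r) for r in records])


# ---------------------------------------------------------------------------
# HDF5 I/O
# ---------------------------------------------------------------------------

def _require(group: h5py.Group, name: str) -> h5py.Dataset | h5py.Group:
    if name not in group:
        raise SchemaError(f"missing '{group.name}/{name}' in session container")
    return group[name]


def save_session(session: SessionData, path: str) -> None:
    """Write a session to a single HDF5 container (schema in module docstring)."""
    session.validate()
    with h5py.File(path, "w") as f:
        b = f.create_group("behavior")
        beh = session.behavior
        for name in ("time", "position", "speed"):
            b.create_dataset(name, data=getattr(beh, name).astype(np.float64))
        for name in ("lick_flags", "reward_flags", "in_world"):
            b.create_dataset(name, data=getattr(beh, name).astype(bool))
        b.create_dataset("trial_id", data=beh.trial_id.astype(np.int64))

        t = f.create_group("traces")
        t.create_dataset("fluorescence", data=session.traces.fluorescence)
        t.create_dataset("frame_time", data=session.traces.frame_time)
        t.create_dataset("roi_centroids", data=session.traces.roi_centroids)
        t.create_dataset("artifact_mask", data=session.traces.artifact_mask.astype(bool))
        t.attrs["frame_rate"] = session.traces.frame_rate

        e = f.create_group("epochs")
        for name in EPOCH_NAMES:
            e.create_dataset(name, data=np.asarray(session.epochs.interval(name)))

        if not session.protocol.is_empty:
            p = f.create_group("protocol")
            p.create_dataset("target_ids", data=session.protocol.target_ids.astype(np.int64))
            p.create_dataset(
                "cluster_assignment", data=session.protocol.cluster_assignment.astype(np.int64)
            )
            p.create_dataset("trial_onsets", data=session.protocol.trial_onsets.astype(np.int64))
            p.create_dataset("beamlet_xy", data=session.protocol.beamlet_xy.astype(np.float64))

        m = f.create_group("meta")
        g = session.geometry
        m.attrs["track_length"] = g.track_length
        m.attrs["start_zone"] = np.asarray(g.start_zone)
        m.attrs["reward_zone"] = np.asarray(g.reward_zone)
        m.attrs["stim_point"] = g.stim_point
        m.attrs["stim_zone"] = np.asarray(g.stim_zone)
        for key, val in session.meta.items():
            m.attrs[key] = val


def load_session(path: str) -> SessionData:
    """Load and validate a session container written by :func:`save_session`.

    The ``/protocol`` group is optional: a session recorded without
    stimulation loads with an empty protocol.
    """
    with h5py.File(path, "r") as f:
        b = _require(f, "behavior")
        behavior = BehaviorTimeseries(
            time=np.asarray(_require(b, "time")),
            position=np.asarray(_require(b, "position")),
            speed=np.asarray(_require(b, "speed")),
            lick_flags=np.asarray(_require(b, "lick_flags")).astype(bool),
            reward_flags=np.asarray(_require(b, "reward_flags")).astype(bool),
            trial_id=np.asarray(_require(b, "trial_id")).astype(np.int64),
            in_world=np.asarray(_require(b, "in_world")).astype(bool),
        )
        t = _require(f, "traces")
        traces = TraceMatrix(
            fluorescence=np.asarray(_require(t, "fluorescence")),
            frame_time=np.asarray(_require(t, "frame_time")),
            roi_centroids=np.asarray(_require(t, "roi_centroids")),
            artifact_mask=np.asarray(_require(t, "artifact_mask")).astype(bool),
            frame_rate=float(t.attrs.get("frame_rate", FRAME_RATE)),
        )
        e = _require(f, "epochs")
        epochs = EpochSet(
            **{name: tuple(np.asarray(_require(e, name))) for name in EPOCH_NAMES}
        )
        if "protocol" in f:
            p = f["protocol"]
            protocol = StimProtocol(
                target_ids=np.asarray(_require(p, "target_ids")).astype(np.int64),
                cluster_assignment=np.asarray(_require(p, "cluster_assignment")).astype(np.int64),
                trial_onsets=np.asarray(_require(p, "trial_onsets")).astype(np.int64),
                beamlet_xy=np.asarray(_require(p, "beamlet_xy")),
            )
        else:
            protocol = StimProtocol.empty()
        m = _require(f, "meta")
        geometry = TrackGeometry(
            track_length=float(m.attrs["track_length"]),
            start_zone=tuple(m.attrs["start_zone"]),
            reward_zone=tuple(m.attrs["reward_zone"]),
            stim_point=float(m.attrs["stim_point"]),
            stim_zone=tuple(m.attrs["stim_zone"]),
        )
        known = {"track_length", "start_zone", "reward_zone", "stim_point", "stim_zone"}
        meta = {k: m.attrs[k] for k in m.attrs if k not in known}

    session = SessionData(
        behavior=behavior,
        traces=traces,
        epochs=epochs,
        protocol=protocol,
        geometry=geometry,
        meta=meta,
    )
    session.validate()
    return session
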