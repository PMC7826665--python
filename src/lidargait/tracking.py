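"""Inertia-based multi-object tracking of ankle snapshots (IOTA).

The tracker assumes that between fast consecutive scans a slowly moving
object changes velocity negligibly.  For every snapshot k in the current
frame and every live object m it forms the *candidate velocity* the
snapshot would imply if it were object m, and scores its similarity to
m's previous velocity:

    S(n, k, m) = 1 / (1 + d(v_m(n, k), v(n-1, m)))

with ``d`` the Euclidean distance between the two velocity vectors.
Snapshot identities are then resolved by a greedy one-to-one matching
over all (k, m) scores in descending order (the per-snapshot argmax rule
alone could give two snapshots the same identity).

Unmatched snapshots spawn new objects with zero initial velocity
(standing start); unmatched objects become *occluded*, coast along their
last velocity, and remain matchable so that an object reappearing on its
inertial path after a short occlusion resumes its old identity.  Objects
occluded longer than a timeout become *lost* and are never revived — an
object id, once lost, is never reissued within a run.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .detection import DetectionCriteria, ObjectSnapshot, detect_frame
from .scan_io import ScanFrame, SensorPose, TrajectorySample, WorldPoint

__all__ = [
    "TrackState",
    "TrackedObject",
    "ScoreEntry",
    "TrackerConfig",
    "TargetPair",
    "velocity_score",
    "candidate_velocity",
    "assign_ids",
    "step_tracker",
    "designate_targets",
    "Tracker",
    "track_frames",
]


class TrackState(enum.Enum):
    ACTIVE = "active"
    OCCLUDED = "occluded"
    LOST = "lost"


@dataclass
class TrackedObject:
    """A persistent identity with position, velocity, state, and history.

    ``position`` is the current best estimate: the matched snapshot
    position while active, and the coasted (position + velocity * dt)
    prediction while occluded.  ``anchor`` is the position at the last
    actual observation; velocity candidates are measured from the anchor
    over the full time gap since ``last_seen``, so that an object
    reappearing on its inertial path scores ~1 regardless of how many
    frames it was hidden.
    """

    object_id: int
    position: np.ndarray
    velocity: np.ndarray
    state: TrackState
    last_seen: tuple[int, float]  # (frame_index, timestamp)
    history: list[TrajectorySample] = field(default_factory=list)
    anchor: np.ndarray | None = None
    position_time: float | None = None  # instant `position` refers to

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(2)
        self.velocity = np.asarray(self.velocity, dtype=float).reshape(2)
        if self.anchor is None:
            self.anchor = self.position.copy()
        else:
            self.anchor = np.asarray(self.anchor, dtype=float).reshape(2)
        if self.position_time is None:
            self.position_time = self.last_seen[1]


@dataclass(frozen=True)
class ScoreEntry:
    """One (snapshot k, object m) hypothesis with its velocity score."""

    k: int
    m: int
    candidate_velocity: tuple[float, float]
    distance: float
    score: float


@dataclass(frozen=True)
class TrackerConfig:
    """Tracker thresholds (all config-exposed).

    score_min
        Minimum acceptable velocity score. The default 1e-4 corresponds
        to a velocity mismatch of ~10 m/s and acts purely as an absurdity
        bound: a swinging ankle legitimately changes its frame-averaged
        velocity by several m/s between 10-15 Hz scans, so identity
        discrimination is left to the relative greedy comparison rather
        than an absolute cut.
    occlusion_timeout
        Seconds an object may stay unseen before it is declared lost
        (default 1.0 s, above the ~0.5 s gaps typical of people crossing
        in front of each other).
    designation_displacement
        Net axial displacement (mm) after which a track qualifies as a
        walking ankle for automatic left/right target designation.
    """

    score_min: float = 1e-4
    occlusion_timeout: float = 1.0
    designation_displacement: float = 300.0

    def __post_init__(self) -> None:
        if not (0 < self.score_min < 1):
            raise ValueError("score_min must lie in (0, 1)")
        if self.occlusion_timeout <= 0:
            raise ValueError("occlusion_timeout must be positive")


@dataclass(frozen=True)
class TargetPair:
    """The automatically designated left/right ankle identities."""

    left_id: int
    right_id: int
    designated_at: float

    def __post_init__(self) -> None:
        if self.left_id == self.right_id:
            raise ValueError("left_id and right_id must differ")


def velocity_score(candidate_velocity, previous_velocity) -> float:
    """S = 1 / (1 + |v_candidate - v_previous|); symmetric, in (0, 1]."""
    v1 = np.asarray(candidate_velocity, dtype=float)
    v2 = np.asarray(previous_velocity, dtype=float)
    return 1.0 / (1.0 + float(np.linalg.norm(v1 - v2)))


def candidate_velocity(snapshot: ObjectSnapshot, obj: TrackedObject) -> np.ndarray:
    """Velocity the snapshot implies if it is object ``obj``: displacement
    from the object's last observed position over the full time gap."""
    dt = snapshot.timestamp - obj.last_seen[1]
    if dt <= 0:
        raise ValueError(
            f"snapshot at t={snapshot.timestamp} does not follow object last seen at t={obj.last_seen[1]}"
        )
    return (snapshot.xy - obj.anchor) / dt


def assign_ids(
    snapshots: list[ObjectSnapshot],
    objects: list[TrackedObject],
    config: TrackerConfig = TrackerConfig(),
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy one-to-one matching over the velocity-score matrix.

    Entries are visited in descending score (ties: smaller object id m,
    then smaller snapshot index k); a pair is accepted when both sides
    are still free and the score reaches ``score_min``.

    Returns ``(matches, new_ids, unseen)``: accepted ``(k, m)`` pairs,
    snapshot indices that start new objects, and object ids left unseen.
    """
    ids = [o.object_id for o in objects]
    if len(set(ids)) != len(ids):
        raise ValueError("objects must have distinct ids")
    entries: list[ScoreEntry] = []
    for snap in snapshots:
        for obj in objects:
            if obj.state is TrackState.LOST:
                continue
            if snap.timestamp <= obj.last_seen[1]:
                continue
            vc = candidate_velocity(snap, obj)
            d = float(np.linalg.norm(vc - obj.velocity))
            entries.append(
                ScoreEntry(snap.snapshot_index, obj.object_id, (vc[0], vc[1]), d, 1.0 / (1.0 + d))
            )
    entries.sort(key=lambda e: (-e.score, e.m, e.k))
    matched_k: set[int] = set()
    matched_m: set[int] = set()
    matches: list[tuple[int, int]] = []
    for e in entries:
        if e.score < config.score_min:
            break
        if e.k in matched_k or e.m in matched_m:
            continue
        matches.append((e.k, e.m))
        matched_k.add(e.k)
        matched_m.add(e.m)
    new_ids = [s.snapshot_index for s in snapshots if s.snapshot_index not in matched_k]
    unseen = [o.object_id for o in objects if o.object_id not in matched_m and o.state is not TrackState.LOST]
    return matches, new_ids, unseen


def step_tracker(
    frame_snapshots: list[ObjectSnapshot],
    objects: list[TrackedObject],
    config: TrackerConfig = TrackerConfig(),
    frame_index: int | None = None,
    timestamp: float | None = None,
) -> list[TrackedObject]:
    """Advance the tracker by one frame, mutating and returning ``objects``.

    ``frame_index``/``timestamp`` may be omitted when the frame has at
    least one snapshot.  Frames must be processed in time order.
    """
    if timestamp is None or frame_index is None:
        if not frame_snapshots:
            raise ValueError("empty frame requires explicit frame_index and timestamp")
        frame_index = frame_snapshots[0].frame_index
        timestamp = frame_snapshots[0].timestamp
    latest = max((o.position_time for o in objects), default=-math.inf)
    if objects and timestamp <= latest:
        raise ValueError(f"frame at t={timestamp} is out of order")

    snap_by_k = {s.snapshot_index: s for s in frame_snapshots}
    matches, new_ks, unseen = assign_ids(frame_snapshots, objects, config)
    obj_by_id = {o.object_id: o for o in objects}

    for k, m in matches:
        snap = snap_by_k[k]
        obj = obj_by_id[m]
        v = candidate_velocity(snap, obj)
        obj.velocity = v
        obj.position = snap.xy.copy()
        obj.anchor = snap.xy.copy()
        obj.state = TrackState.ACTIVE
        obj.last_seen = (frame_index, timestamp)
        obj.position_time = timestamp
        obj.history.append(TrajectorySample(timestamp, m, snap.position))

    next_id = max((o.object_id for o in objects), default=0) + 1
    for k in new_ks:
        snap = snap_by_k[k]
        obj = TrackedObject(
            object_id=next_id,
            position=snap.xy,
            velocity=np.zeros(2),
            state=TrackState.ACTIVE,
            last_seen=(frame_index, timestamp),
            history=[TrajectorySample(timestamp, next_id, snap.position)],
        )
        objects.append(obj)
        next_id += 1

    for m in unseen:
        obj = obj_by_id[m]
        if timestamp - obj.last_seen[1] > config.occlusion_timeout:
            obj.state = TrackState.LOST
        else:
            obj.state = TrackState.OCCLUDED
            dt = timestamp - obj.position_time
            if dt > 0:
                obj.position = obj.position + obj.velocity * dt
            obj.position_time = timestamp
    return objects


def _qualification(obj: TrackedObject, displacement: float) -> tuple[float, float, float] | None:
    """First time the track's net axial displacement reaches the threshold.

    Returns (timestamp, signed displacement, y at qualification) or None.
    """
    if len(obj.history) < 2:
        return None
    x0 = obj.history[0].position.x
    for s in obj.history[1:]:
        dx = s.position.x - x0
        if abs(dx) >= displacement:
            return (s.timestamp, dx, s.position.y)
    return None


def designate_targets(
    objects: list[TrackedObject], config: TrackerConfig = TrackerConfig()
) -> TargetPair | None:
    """Automatic target designation during the initial movement.

    The first two tracks whose net displacement along the walking axis
    exceeds ``designation_displacement`` (in the direction set by the
    first qualifier) become the target ankles; at designation time the
    track with the larger y is labelled *left*, the smaller y *right*.
    Returns ``None`` while fewer than two tracks qualify.
    """
    quals: list[tuple[float, TrackedObject, float, float]] = []
    for obj in objects:
        q = _qualification(obj, config.designation_displacement)
        if q is not None:
            quals.append((q[0], obj, q[1], q[2]))
    if not quals:
        return None
    quals.sort(key=lambda q: (q[0], q[1].object_id))
    direction = math.copysign(1.0, quals[0][2])
    same = [q for q in quals if math.copysign(1.0, q[2]) == direction]
    if len(same) < 2:
        return None
    (t1, o1, _, y1), (t2, o2, _, y2) = same[0], same[1]
    if y1 >= y2:
        left, right = o1, o2
    else:
        left, right = o2, o1
    return TargetPair(left_id=left.object_id, right_id=right.object_id, designated_at=max(t1, t2))


class Tracker:
    """Stateful frame-by-frame IOTA driver.

    Feeds detection snapshots through :func:`step_tracker`, maintains the
    object list, and performs automatic target designation once two
    tracks start walking.  Once designated, the target pair is remembered
    for the rest of the run.
    """

    def __init__(self, config: TrackerConfig = TrackerConfig()):
        self.config = config
        self.objects: list[TrackedObject] = []
        self.target_pair: TargetPair | None = None
        self._last_time = -math.inf

    def step(
        self, snapshots: list[ObjectSnapshot], frame_index: int, timestamp: float
    ) -> list[TrackedObject]:
        if timestamp <= self._last_time:
            raise ValueError(f"frame at t={timestamp} is out of order")
        step_tracker(snapshots, self.objects, self.config, frame_index, timestamp)
        self._last_time = timestamp
        if self.target_pair is None:
            self.target_pair = designate_targets(self.objects, self.config)
        return self.objects

    @property
    def trajectories(self) -> list[TrajectorySample]:
        """All observed samples of all objects, in time order."""
        out = [s for o in self.objects for s in o.history]
        out.sort(key=lambda s: (s.timestamp, s.object_id))
        return out

    def history_of(self, object_id: int) -> list[TrajectorySample]:
        for o in self.objects:
            if o.object_id == object_id:
                return list(o.history)
        raise KeyError(f"no object with id {object_id}")


def track_frames(
    frames,
    pose: SensorPose = SensorPose(),
    criteria: DetectionCriteria = DetectionCriteria(),
    config: TrackerConfig = TrackerConfig(),
) -> Tracker:
    """Run detection + tracking over a frame sequence; returns the Tracker."""
    tracker = Tracker(config)
    for frame in frames:
        snaps = detect_frame(frame, pose, criteria)
        tracker.step(snaps, frame.frame_index, frame.timestamp)
    return tracker
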