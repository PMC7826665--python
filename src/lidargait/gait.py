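"""Gait events and spatiotemporal gait parameters from ankle trajectories.

During stance the ankle's forward speed is near zero; during swing it
peaks at roughly twice the mean walking speed.  Foot-contact and foot-off
events are therefore detected by thresholding each ankle's forward speed
at a fraction of its own mean, and nine spatiotemporal parameters are
derived from the resulting contact sequence: step length, step width,
cadence, gait speed, stride length, stride time, step time, swing time,
and stance time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .scan_io import TrajectorySample, WorldPoint

__all__ = [
    "InsufficientDataError",
    "EventSequenceError",
    "GaitEvent",
    "ParameterStat",
    "GaitReport",
    "GaitConfig",
    "detect_events",
    "compute_parameters",
    "analyze_gait",
]


class InsufficientDataError(ValueError):
    """Trajectory too short/sparse, or no gait cycles found."""


class EventSequenceError(ValueError):
    """The detected contacts do not alternate between sides."""


@dataclass(frozen=True)
class GaitEvent:
    side: str  # "left" | "right"
    kind: str  # "contact" | "off"
    timestamp: float
    position: WorldPoint

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.kind not in ("contact", "off"):
            raise ValueError(f"kind must be 'contact' or 'off', got {self.kind!r}")


@dataclass(frozen=True)
class GaitConfig:
    """Event-detection tuning.

    v_stance_frac
        Stance threshold as a fraction of the ankle's mean forward speed
        (default 0.2: stance speed is near zero, swing peaks near twice
        the mean, so any fraction well below 1 separates the phases).
    min_swing_time
        Stance runs separated by a shorter gap are merged (default 0.3 s,
        below the ~0.35-0.45 s swing phase of any walking cadence), so
        that a brief speed spike — sensor noise, or samples interpolated
        across an occlusion — cannot split one true stance into two
        same-side contacts.
    """

    v_stance_frac: float = 0.2
    min_swing_time: float = 0.3


@dataclass(frozen=True)
class ParameterStat:
    """Mean, sample SD (n-1 denominator; 0 for a single value), and the
    per-step/per-cycle values a summary was computed from."""

    mean: float
    sd: float
    values: tuple[float, ...]

    @classmethod
    def of(cls, values) -> "ParameterStat":
        v = np.asarray(list(values), dtype=float)
        if v.size == 0:
            raise InsufficientDataError("no values for parameter statistic")
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        return cls(float(v.mean()), sd, tuple(float(x) for x in v))


@dataclass(frozen=True)
class GaitReport:
    """The nine spatiotemporal gait parameters of one walk."""

    step_length: ParameterStat  # mm
    step_width: ParameterStat  # mm
    cadence: float  # steps/min
    gait_speed: float  # m/s
    stride_length: ParameterStat | None  # mm; None with only two contacts
    stride_time: ParameterStat | None  # s
    step_time: ParameterStat  # s
    swing_time: ParameterStat | None  # s; None when no complete cycle has a foot-off
    stance_time: ParameterStat | None  # s
    n_steps: int
    events: tuple[GaitEvent, ...] = ()

    def to_dict(self) -> dict:
        def stat(s: ParameterStat | None) -> dict | None:
            if s is None:
                return None
            return {"mean": s.mean, "sd": s.sd, "values": list(s.values)}

        return {
            "step_length": stat(self.step_length),
            "step_width": stat(self.step_width),
            "cadence": self.cadence,
            "gait_speed": self.gait_speed,
            "stride_length": stat(self.stride_length),
            "stride_time": stat(self.stride_time),
            "step_time": stat(self.step_time),
            "swing_time": stat(self.swing_time),
            "stance_time": stat(self.stance_time),
            "n_steps": self.n_steps,
            "events": [
                {
                    "side": e.side,
                    "kind": e.kind,
                    "timestamp": e.timestamp,
                    "x_mm": e.position.x,
                    "y_mm": e.position.y,
                }
                for e in self.events
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "GaitReport":
        def stat(key: str) -> ParameterStat | None:
            s = d[key]
            if s is None:
                return None
            return ParameterStat(s["mean"], s["sd"], tuple(s["values"]))

        events = tuple(
            GaitEvent(e["side"], e["kind"], e["timestamp"], WorldPoint(e["x_mm"], e["y_mm"]))
            for e in d.get("events", ())
        )
        return cls(
            step_length=stat("step_length"),
            step_width=stat("step_width"),
            cadence=d["cadence"],
            gait_speed=d["gait_speed"],
            stride_length=stat("stride_length"),
            stride_time=stat("stride_time"),
            step_time=stat("step_time"),
            swing_time=stat("swing_time"),
            stance_time=stat("stance_time"),
            n_steps=d["n_steps"],
            events=events,
        )


def _side_events(
    traj: list[TrajectorySample], side: str, config: GaitConfig
) -> list[GaitEvent]:
    t = np.array([s.timestamp for s in traj])
    x = np.array([s.position.x for s in traj])
    y = np.array([s.position.y for s in traj])
    if t.size < 2 or t[-1] - t[0] < 1.0:
        raise InsufficientDataError(f"{side} trajectory shorter than 1 s")
    rate = (t.size - 1) / (t[-1] - t[0])
    if rate < 8.0:
        raise InsufficientDataError(f"{side} trajectory sampled below 8 Hz ({rate:.1f} Hz)")
    speed = np.abs(np.gradient(x, t))
    threshold = config.v_stance_frac * float(speed.mean())
    mask = speed < threshold

    # maximal runs of stance samples
    runs: list[tuple[int, int]] = []  # inclusive index ranges
    i = 0
    n = t.size
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    runs = [(a, b) for a, b in runs if b - a + 1 >= 2]
    # merge runs separated by an implausibly short "swing"
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and t[run[0]] - t[merged[-1][1]] < config.min_swing_time:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)

    def _crossing(i_fast: int, i_slow: int) -> float:
        """Sub-sample threshold crossing between an above- and a
        below-threshold sample (sample-rate timing alone lags by up to
        ~1.5 frames because the central-difference speed smears the
        transition)."""
        s_fast, s_slow = speed[i_fast], speed[i_slow]
        if s_fast <= s_slow or s_fast <= threshold:
            return float(t[i_slow])
        frac = (s_fast - threshold) / (s_fast - s_slow)
        frac = min(max(frac, 0.0), 1.0)
        return float(t[i_fast] + frac * (t[i_slow] - t[i_fast]))

    events: list[GaitEvent] = []
    for a, b in merged:
        pos = WorldPoint(float(x[a : b + 1].mean()), float(y[a : b + 1].mean()))
        if a > 0:  # a run starting at the first sample has no observed contact
            events.append(GaitEvent(side, "contact", _crossing(a - 1, a), pos))
        if b < n - 1:  # a run ending at the last sample has no observed foot-off
            events.append(GaitEvent(side, "off", _crossing(b + 1, b), pos))
    return events


def detect_events(
    left_traj: list[TrajectorySample],
    right_traj: list[TrajectorySample],
    v_stance_frac: float | None = None,
    config: GaitConfig = GaitConfig(),
) -> list[GaitEvent]:
    """Detect foot contacts and foot-offs for both ankles.

    Stance intervals are maximal runs where the ankle's forward speed is
    below ``v_stance_frac`` times its own mean forward speed; the contact
    is placed at the run start, the foot-off at the run end, and the
    event position is the mean ankle position over the run.  Runs shorter
    than 2 samples are discarded; runs touching the trajectory boundary
    emit only their interior event.

    Raises :class:`InsufficientDataError` when a trajectory is shorter
    than 1 s, sampled below 8 Hz, or yields fewer than two contacts in
    total (e.g. a constant-velocity trajectory with no stance at all).
    """
    if v_stance_frac is not None:
        config = GaitConfig(v_stance_frac=v_stance_frac, min_swing_time=config.min_swing_time)
    events = _side_events(left_traj, "left", config) + _side_events(right_traj, "right", config)
    events.sort(key=lambda e: (e.timestamp, e.side, e.kind))
    n_contacts = sum(1 for e in events if e.kind == "contact")
    if n_contacts < 2:
        raise InsufficientDataError(
            f"only {n_contacts} contacts detected; need at least one full gait cycle"
        )
    return events


def compute_parameters(events: list[GaitEvent]) -> GaitReport:
    """Derive the nine gait parameters from an alternating contact sequence.

    For contacts C1..CM ordered in time: step length / width / time are
    |dx| / |dy| / dt between consecutive (contralateral) contacts; stride
    quantities between consecutive same-side contacts; cadence is
    60 (M-1)/(tM - t1); gait speed |xM - x1| / (tM - t1) in m/s.  Stance
    time is foot-off minus contact within a cycle and swing time the
    remainder of the stride; only complete cycles contribute.
    """
    events = sorted(events, key=lambda e: e.timestamp)
    contacts = [e for e in events if e.kind == "contact"]
    if len(contacts) < 2:
        raise InsufficientDataError(f"need >= 2 contacts, got {len(contacts)}")
    for a, b in zip(contacts, contacts[1:]):
        if a.side == b.side:
            raise EventSequenceError(
                f"contacts do not alternate sides: consecutive {a.side} contacts at "
                f"t={a.timestamp:.3f} s and t={b.timestamp:.3f} s"
            )

    step_length = [abs(b.position.x - a.position.x) for a, b in zip(contacts, contacts[1:])]
    step_width = [abs(b.position.y - a.position.y) for a, b in zip(contacts, contacts[1:])]
    step_time = [b.timestamp - a.timestamp for a, b in zip(contacts, contacts[1:])]

    stride_length: list[float] = []
    stride_time: list[float] = []
    for a, b in zip(contacts, contacts[2:]):  # same side, alternation guaranteed
        stride_length.append(abs(b.position.x - a.position.x))
        stride_time.append(b.timestamp - a.timestamp)

    # stance/swing per complete cycle: contact -> off -> next same-side contact
    stance_time: list[float] = []
    swing_time: list[float] = []
    for side in ("left", "right"):
        side_ev = [e for e in events if e.side == side]
        for i, e in enumerate(side_ev):
            if e.kind != "contact":
                continue
            rest = side_ev[i + 1 :]
            if len(rest) >= 2 and rest[0].kind == "off" and rest[1].kind == "contact":
                stance_time.append(rest[0].timestamp - e.timestamp)
                swing_time.append(rest[1].timestamp - rest[0].timestamp)

    t1, tM = contacts[0].timestamp, contacts[-1].timestamp
    M = len(contacts)
    cadence = 60.0 * (M - 1) / (tM - t1)
    gait_speed = abs(contacts[-1].position.x - contacts[0].position.x) / (tM - t1) / 1000.0

    return GaitReport(
        step_length=ParameterStat.of(step_length),
        step_width=ParameterStat.of(step_width),
        cadence=cadence,
        gait_speed=gait_speed,
        stride_length=ParameterStat.of(stride_length) if stride_length else None,
        stride_time=ParameterStat.of(stride_time) if stride_time else None,
        step_time=ParameterStat.of(step_time),
        swing_time=ParameterStat.of(swing_time) if swing_time else None,
        stance_time=ParameterStat.of(stance_time) if stance_time else None,
        n_steps=M - 1,
        events=tuple(events),
    )


def analyze_gait(
    left_traj: list[TrajectorySample],
    right_traj: list[TrajectorySample],
    config: GaitConfig = GaitConfig(),
) -> GaitReport:
    """Events + parameters in one call."""
    return compute_parameters(detect_events(left_traj, right_traj, config=config))
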