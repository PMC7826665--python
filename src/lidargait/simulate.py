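"""Ray-casting gait-scene simulator.

Walkers are modelled as pairs of vertical leg cylinders, i.e. two 2-D
discs at ankle height whose centers follow an alternating stance/swing
gait: during stance the ankle is frozen on the ground; during swing it
advances one stride (twice the step length) with a sinusoidal forward
velocity profile (zero velocity at both contacts).  The two feet are
half a stride out of phase, the lateral offsets are +-step_width/2, and
the average forward speed equals the configured gait speed exactly.

The sensor model casts one ray per angular-resolution step per frame,
returns the range to the nearest leg-disc intersection (nearer discs
occlude farther ones along the same ray), clips at the maximum reliable
range, and adds seeded Gaussian range noise.  Rays that hit nothing are
omitted, like a real scanner facing open space.

Defaults mirror the validation geometry this package targets: sensor at
(-4000, 0) mm at one end of a 6000 x 2000 mm monitored area, scan rate
10-15 Hz, angular resolution 0.225 deg, ranges reliable to 10 m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import gait as gait_mod
from .gait import GaitEvent, GaitReport
from .scan_io import PolarPoint, ScanFrame, SensorPose, TrajectorySample, WorldPoint

__all__ = [
    "WalkerSpec",
    "SceneConfig",
    "WalkerTruth",
    "GroundTruth",
    "step_length_mm",
    "ankle_positions",
    "generate_gait",
    "render_frames",
    "make_scene",
    "single_walker_scene",
    "crossing_scene",
]


@dataclass(frozen=True)
class WalkerSpec:
    """Kinematic description of one simulated walker.

    Units: positions/lengths mm, speeds m/s, cadence steps/min, times s.
    ``axis`` is the walking axis ("x" for the monitored walkway, "y" for
    someone traversing it laterally) and ``direction`` +1 or -1 along it.
    ``duty_factor`` is the stance fraction of the stride (typically
    0.55-0.65 for walking).  ``start_delay`` keeps the walker standing
    before the first stride.
    """

    start_position: tuple[float, float] = (-2700.0, 0.0)
    direction: int = 1
    gait_speed: float = 1.2
    cadence: float = 110.0
    step_width: float = 160.0
    duty_factor: float = 0.62
    leg_radius: float = 60.0
    start_delay: float = 0.0
    axis: str = "x"

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")
        if self.axis not in ("x", "y"):
            raise ValueError("axis must be 'x' or 'y'")
        if self.gait_speed <= 0 or self.cadence <= 0 or self.leg_radius <= 0:
            raise ValueError("gait_speed, cadence and leg_radius must be positive")
        if not (0.0 < self.duty_factor < 1.0):
            raise ValueError("duty_factor must lie in (0, 1)")
        if self.step_width <= 0 or self.start_delay < 0:
            raise ValueError("step_width must be positive and start_delay non-negative")
        if step_length_mm(self.gait_speed, self.cadence) > 1200.0:
            raise ValueError(
                "inconsistent spec: gait_speed/cadence imply a step length above 1200 mm"
            )

    @property
    def stride_time(self) -> float:
        return 2.0 * 60.0 / self.cadence

    @property
    def step_length(self) -> float:
        return step_length_mm(self.gait_speed, self.cadence)


def step_length_mm(gait_speed: float, cadence: float) -> float:
    """Step length implied by speed (m/s) and cadence (steps/min), in mm."""
    return gait_speed * 60000.0 / cadence


@dataclass(frozen=True)
class SceneConfig:
    """Scene + sensor configuration; ``seed`` governs the range noise only
    (walker kinematics are deterministic)."""

    walkers: tuple[WalkerSpec, ...] = (WalkerSpec(),)
    sensor: SensorPose = SensorPose((-4000.0, 0.0), 0.0)
    scan_rate: float = 15.0  # Hz
    angular_resolution: float = 0.225  # degrees
    max_range: float = 10000.0  # mm
    range_noise_sd: float = 10.0  # mm
    duration: float = 5.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scan_rate <= 0 or self.angular_resolution <= 0 or self.max_range <= 0:
            raise ValueError("scan_rate, angular_resolution and max_range must be positive")
        if self.range_noise_sd < 0 or self.duration <= 0:
            raise ValueError("range_noise_sd must be >= 0 and duration > 0")
        object.__setattr__(self, "walkers", tuple(self.walkers))

    @property
    def timestamps(self) -> np.ndarray:
        n = int(math.floor(self.duration * self.scan_rate)) + 1
        return np.arange(n) / self.scan_rate


@dataclass
class WalkerTruth:
    """Ground truth for one walker: ankle trajectories at scan timestamps,
    the true event list, and the gait report they imply."""

    left: list[TrajectorySample]
    right: list[TrajectorySample]
    events: list[GaitEvent]
    report: GaitReport | None


@dataclass
class GroundTruth:
    walkers: list[WalkerTruth]
    timestamps: np.ndarray

    def all_samples(self) -> list[TrajectorySample]:
        out = [s for w in self.walkers for traj in (w.left, w.right) for s in traj]
        out.sort(key=lambda s: (s.timestamp, s.object_id))
        return out


def _foot_progress(phase_cycles: np.ndarray, duty: float) -> np.ndarray:
    """Completed strides + swing progress for a foot, given its phase in
    stride units.  Swing displacement follows (1 - cos)/2 of the swing
    phase, i.e. a sinusoidal velocity profile vanishing at both contacts."""
    cycles = np.floor(phase_cycles)
    phi = phase_cycles - cycles
    swing = np.where(phi < duty, 0.0, (1.0 - np.cos(np.pi * (phi - duty) / (1.0 - duty))) / 2.0)
    return cycles + swing


def _to_world(spec: WalkerSpec, forward: np.ndarray, lateral: float) -> np.ndarray:
    """Map (forward displacement, lateral offset) into world coordinates."""
    x0, y0 = spec.start_position
    if spec.axis == "x":
        return np.column_stack((x0 + forward, np.full_like(forward, y0 + lateral)))
    return np.column_stack((np.full_like(forward, x0 + lateral), y0 + forward))


def ankle_positions(spec: WalkerSpec, t) -> tuple[np.ndarray, np.ndarray]:
    """Analytic left/right ankle positions at times ``t`` -> two (n, 2) arrays."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    t_eff = np.maximum(t, spec.start_delay) - spec.start_delay
    T = spec.stride_time
    stride = 2.0 * spec.step_length
    left_prog = _foot_progress(t_eff / T, spec.duty_factor)
    right_prog = _foot_progress(t_eff / T - 0.5, spec.duty_factor)
    left_fwd = spec.direction * stride * left_prog
    # right foot's cycle-0 contact sits one step length ahead of the left's
    right_fwd = spec.direction * (spec.step_length + stride * right_prog)
    left = _to_world(spec, left_fwd, spec.step_width / 2.0)
    right = _to_world(spec, right_fwd, -spec.step_width / 2.0)
    return left, right


def _true_events(spec: WalkerSpec, duration: float) -> list[GaitEvent]:
    """Exact contact/foot-off events inside (start_delay, duration].

    The pseudo-contacts at the standing start (both feet already on the
    ground at t = start_delay) are not events and are excluded.
    """
    T = spec.stride_time
    stride = 2.0 * spec.step_length
    t0 = spec.start_delay
    duty = spec.duty_factor
    wl, wr = spec.step_width / 2.0, -spec.step_width / 2.0
    events: list[GaitEvent] = []

    def _pos(fwd: float, lateral: float) -> WorldPoint:
        p = _to_world(spec, np.array([fwd]), lateral)[0]
        return WorldPoint(float(p[0]), float(p[1]))

    # left foot: contact of cycle i at t0 + i*T (i >= 1), off at t0 + (i + duty)*T (i >= 0)
    i = 1
    while t0 + i * T <= duration:
        events.append(GaitEvent("left", "contact", t0 + i * T, _pos(spec.direction * stride * i, wl)))
        i += 1
    i = 0
    while t0 + (i + duty) * T <= duration:
        events.append(GaitEvent("left", "off", t0 + (i + duty) * T, _pos(spec.direction * stride * i, wl)))
        i += 1
    # right foot: contact of cycle i at t0 + (i + 0.5)*T (i >= 0),
    # off at t0 + (i + 0.5 + duty)*T (i >= -1; i = -1 is the standing foot's first lift)
    i = 0
    while t0 + (i + 0.5) * T <= duration:
        events.append(
            GaitEvent("right", "contact", t0 + (i + 0.5) * T, _pos(spec.direction * (spec.step_length + stride * i), wr))
        )
        i += 1
    i = -1
    while t0 + (i + 0.5 + duty) * T <= duration:
        t_off = t0 + (i + 0.5 + duty) * T
        if t_off > t0:
            events.append(
                GaitEvent("right", "off", t_off, _pos(spec.direction * (spec.step_length + stride * i), wr))
            )
        i += 1
    events.sort(key=lambda e: e.timestamp)
    return events


def generate_gait(
    spec: WalkerSpec, timestamps, object_ids: tuple[int, int] = (1, 2)
) -> tuple[list[TrajectorySample], list[TrajectorySample], list[GaitEvent]]:
    """Sample the walker's true ankle trajectories and list its true events."""
    t = np.asarray(timestamps, dtype=float)
    left_xy, right_xy = ankle_positions(spec, t)
    lid, rid = object_ids
    left = [TrajectorySample(float(tt), lid, WorldPoint(float(p[0]), float(p[1]))) for tt, p in zip(t, left_xy)]
    right = [TrajectorySample(float(tt), rid, WorldPoint(float(p[0]), float(p[1]))) for tt, p in zip(t, right_xy)]
    events = _true_events(spec, float(t[-1]))
    return left, right, events


def render_frames(
    config: SceneConfig, rng: np.random.Generator | None = None
) -> list[ScanFrame]:
    """Ray-cast all frames of the scene.

    For each ray (at integer multiples of the angular resolution) the
    returned range is the distance to the nearest leg-disc intersection,
    plus Gaussian noise; rays hitting nothing, or beyond ``max_range``,
    produce no point.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_rays = int(round(360.0 / config.angular_resolution))
    angles_deg = np.arange(n_rays) * config.angular_resolution
    theta = np.radians(config.sensor.heading + angles_deg)
    u = np.column_stack((np.cos(theta), np.sin(theta)))  # (R, 2)
    sensor = config.sensor.xy

    radii = np.concatenate([[w.leg_radius, w.leg_radius] for w in config.walkers])
    frames: list[ScanFrame] = []
    for idx, t in enumerate(config.timestamps):
        centers = []
        for w in config.walkers:
            lw, rw = ankle_positions(w, t)
            centers.append(lw[0])
            centers.append(rw[0])
        c = np.asarray(centers) - sensor  # (D, 2)
        tc = u @ c.T  # (R, D) distance along ray to foot of perpendicular
        perp2 = (c**2).sum(axis=1)[None, :] - tc**2
        r2 = radii[None, :] ** 2
        hit = (tc > 0) & (perp2 <= r2)
        dist = np.where(hit, tc - np.sqrt(np.maximum(r2 - perp2, 0.0)), np.inf)
        ranges = dist.min(axis=1)
        mask = np.isfinite(ranges)
        if config.range_noise_sd > 0:
            noise = rng.normal(0.0, config.range_noise_sd, size=int(mask.sum()))
            ranges = ranges.copy()
            ranges[mask] += noise
        keep = mask & (ranges > 0) & (ranges <= config.max_range)
        points = tuple(
            PolarPoint(float(a), float(r)) for a, r in zip(angles_deg[keep], ranges[keep])
        )
        frames.append(ScanFrame(idx, float(t), points))
    return frames


def make_scene(config: SceneConfig) -> tuple[list[ScanFrame], GroundTruth]:
    """Deterministic scene generation: frames + ground truth for a config."""
    t = config.timestamps
    truths: list[WalkerTruth] = []
    for i, w in enumerate(config.walkers):
        left, right, events = generate_gait(w, t, object_ids=(2 * i + 1, 2 * i + 2))
        try:
            # gait parameters assume forward = x; lateral crossers get none
            report = gait_mod.compute_parameters(events) if w.axis == "x" else None
        except (gait_mod.InsufficientDataError, gait_mod.EventSequenceError):
            report = None
        truths.append(WalkerTruth(left, right, events, report))
    rng = np.random.default_rng(config.seed)
    frames = render_frames(config, rng)
    return frames, GroundTruth(truths, t)


def single_walker_scene(
    gait_speed: float = 1.2,
    cadence: float = 110.0,
    range_noise_sd: float = 10.0,
    scan_rate: float = 15.0,
    duration: float = 5.0,
    seed: int = 0,
    start_delay: float = 0.0,
    **walker_kwargs,
) -> SceneConfig:
    """One walker crossing the monitored area along +x."""
    walker = WalkerSpec(
        start_position=(-2700.0, 0.0),
        direction=1,
        gait_speed=gait_speed,
        cadence=cadence,
        start_delay=start_delay,
        **walker_kwargs,
    )
    return SceneConfig(
        walkers=(walker,),
        scan_rate=scan_rate,
        range_noise_sd=range_noise_sd,
        duration=duration,
        seed=seed,
    )


def crossing_scene(
    seed: int = 0,
    range_noise_sd: float = 10.0,
    scan_rate: float = 15.0,
    duration: float = 6.0,
) -> SceneConfig:
    """Three walkers, six legs: a monitored subject who starts standing
    and then walks the corridor, plus two people traversing the area
    laterally between the sensor and the subject.  Each crosser's feet
    sweep through the sensor->subject bearing corridor during swing,
    hiding the subject's ankles for a few tenths of a second at a time;
    the crossers start moving only after the subject's ankles have been
    designated, the way a monitored walk in a busy corridor begins."""
    subject = WalkerSpec(
        start_position=(-1000.0, 0.0),
        direction=1,
        gait_speed=0.9,
        cadence=100.0,
        start_delay=0.5,
    )
    crosser_near = WalkerSpec(
        start_position=(-1200.0, -2200.0),
        direction=1,
        axis="y",
        gait_speed=1.1,
        cadence=115.0,
        start_delay=2.1,
    )
    crosser_far = WalkerSpec(
        start_position=(-2200.0, 2000.0),
        direction=-1,
        axis="y",
        gait_speed=1.2,
        cadence=115.0,
        start_delay=2.9,
    )
    return SceneConfig(
        walkers=(subject, crosser_near, crosser_far),
        scan_rate=scan_rate,
        range_noise_sd=range_noise_sd,
        duration=duration,
        seed=seed,
    )
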