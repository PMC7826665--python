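"""Data model and I/O for 2D-LiDAR scan frames and ankle trajectories.

A 2D-LiDAR sensor returns, once per revolution, a set of (angle, range)
pairs measured in a single horizontal plane.  This module defines the
in-memory types for those scans (:class:`PolarPoint`, :class:`ScanFrame`),
the world coordinate frame used throughout the package, and plain-text
readers/writers for the two on-disk formats.

Coordinate conventions
----------------------
* World frame: ``x`` along the walking axis, ``y`` lateral, origin at the
  center of the monitored region of interest.  Units are millimetres.
* Angles are degrees, normalized to ``[0, 360)``, increasing
  counter-clockwise viewed from above.  Radians appear only internally.
* The default sensor pose places the scanner at ``(-4000, 0)`` mm, at one
  end of a 6000 x 2000 mm walkway, with its 0-degree ray along ``+x``.

Frame file format (one frame per line, UTF-8, ``.`` decimal separator)::

    frame_index <TAB> timestamp_s <TAB> angle1:range1,angle2:range2,...

EBNF::

    file      = { comment | frame } ;
    comment   = "#" , { any } , newline ;
    frame     = integer , tab , float , tab , [ points ] , newline ;
    points    = point , { "," , point } ;
    point     = float , ":" , float ;       (* angle_deg : range_mm *)

Frames with zero points (total dropout) are legal: the third field is
empty.  Within a file, ``frame_index`` and ``timestamp_s`` must be
strictly increasing.

Trajectory file format: CSV with header ``timestamp_s,object_id,x_mm,y_mm``
(rows for different objects may interleave; per object the timestamps must
be strictly increasing).  Lines starting with ``#`` are metadata comments.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "ValidationError",
    "PolarPoint",
    "ScanFrame",
    "SensorPose",
    "WorldPoint",
    "TrajectorySample",
    "polar_to_world",
    "frame_to_world",
    "read_frames",
    "write_frames",
    "read_trajectory",
    "write_trajectory",
    "split_trajectory",
]


class FormatError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed data violates a structural invariant (ordering, sign, ...)."""


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class WorldPoint:
    """A point in the world frame (mm); x axial, y lateral."""

    x: float
    y: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", _require_finite("x", self.x))
        object.__setattr__(self, "y", _require_finite("y", self.y))

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class PolarPoint:
    """One laser return: beam angle (degrees) and measured range (mm)."""

    angle: float
    range: float

    def __post_init__(self) -> None:
        angle = _require_finite("angle", self.angle) % 360.0
        rng = _require_finite("range", self.range)
        if rng <= 0:
            raise ValidationError(f"range must be positive, got {rng!r}")
        object.__setattr__(self, "angle", angle)
        object.__setattr__(self, "range", rng)


@dataclass(frozen=True)
class SensorPose:
    """Sensor placement: position (mm) and heading of its 0-degree ray."""

    position: tuple[float, float] = (-4000.0, 0.0)
    heading: float = 0.0

    def __post_init__(self) -> None:
        x, y = self.position
        object.__setattr__(
            self, "position", (_require_finite("pose.x", x), _require_finite("pose.y", y))
        )
        object.__setattr__(self, "heading", _require_finite("heading", self.heading) % 360.0)

    @property
    def xy(self) -> np.ndarray:
        return np.array(self.position, dtype=float)


@dataclass(frozen=True)
class ScanFrame:
    """One full sensor revolution: index, timestamp, and its returns.

    Points are stored sorted by angle; an empty point tuple is legal and
    represents total occlusion or sensor dropout.
    """

    frame_index: int
    timestamp: float
    points: tuple[PolarPoint, ...] = ()

    def __post_init__(self) -> None:
        if int(self.frame_index) != self.frame_index or self.frame_index < 0:
            raise ValidationError(f"frame_index must be a non-negative integer, got {self.frame_index!r}")
        object.__setattr__(self, "frame_index", int(self.frame_index))
        object.__setattr__(self, "timestamp", _require_finite("timestamp", self.timestamp))
        pts = tuple(sorted(self.points, key=lambda p: p.angle))
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class TrajectorySample:
    """One tracked position of one object at one instant."""

    timestamp: float
    object_id: int
    position: WorldPoint


def polar_to_world(p: PolarPoint, pose: SensorPose) -> WorldPoint:
    """Transform a polar return into the world frame.

    ``x = pose.x + range*cos(heading + angle)`` and analogously with sin
    for ``y``; the transform preserves the range as the distance from the
    sensor position.
    """
    theta = math.radians(pose.heading + p.angle)
    return WorldPoint(
        pose.position[0] + p.range * math.cos(theta),
        pose.position[1] + p.range * math.sin(theta),
    )


def frame_to_world(frame: ScanFrame, pose: SensorPose) -> np.ndarray:
    """All returns of one frame as an ``(n, 2)`` world-coordinate array."""
    if not frame.points:
        return np.empty((0, 2), dtype=float)
    angles = np.radians(pose.heading + np.array([p.angle for p in frame.points]))
    ranges = np.array([p.range for p in frame.points])
    return np.column_stack(
        (pose.position[0] + ranges * np.cos(angles), pose.position[1] + ranges * np.sin(angles))
    )


# ---------------------------------------------------------------------------
# file I/O


def _open_text(source, mode: str):
    """Return (stream, needs_close) for a path, text stream, or byte stream."""
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8", newline=""), True
    if isinstance(source, io.TextIOBase):
        return source, False
    # binary stream
    if "r" in mode:
        return io.TextIOWrapper(source, encoding="utf-8", newline=""), False
    return io.TextIOWrapper(source, encoding="utf-8", newline=""), False


def write_frames(frames: Iterable[ScanFrame], dest, header: Sequence[str] = ()) -> None:
    """Write frames in the line-delimited frame format.

    ``header`` lines are emitted first, prefixed with ``# ``.  Floats are
    written with ``repr`` so that ``read_frames(write_frames(x)) == x``
    exactly.
    """
    stream, close = _open_text(dest, "w")
    try:
        for line in header:
            stream.write(f"# {line}\n")
        for fr in frames:
            pts = ",".join(f"{p.angle!r}:{p.range!r}" for p in fr.points)
            stream.write(f"{fr.frame_index}\t{fr.timestamp!r}\t{pts}\n")
        if isinstance(stream, io.TextIOWrapper) and not close:
            stream.flush()
            stream.detach()
    finally:
        if close:
            stream.close()


def read_frames(source) -> list[ScanFrame]:
    """Parse a frame file; see the module docstring for the format.

    Raises :class:`FormatError` (naming the 1-based line number) on a
    malformed line and :class:`ValidationError` when frame indices or
    timestamps are not strictly increasing.
    """
    stream, close = _open_text(source, "r")
    frames: list[ScanFrame] = []
    try:
        for line_no, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"line {line_no}: expected 3 tab-separated fields, got {len(fields)}"
                )
            try:
                idx = int(fields[0])
                ts = float(fields[1])
                points = []
                if fields[2]:
                    for tok in fields[2].split(","):
                        a, _, r = tok.partition(":")
                        if not _:
                            raise ValueError(f"malformed point {tok!r}")
                        points.append(PolarPoint(float(a), float(r)))
                frame = ScanFrame(idx, ts, tuple(points))
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"line {line_no}: {exc}") from exc
            frames.append(frame)
    finally:
        if close:
            stream.close()
    for prev, cur in zip(frames, frames[1:]):
        if cur.frame_index <= prev.frame_index:
            raise ValidationError(
                f"frame_index not strictly increasing: {prev.frame_index} -> {cur.frame_index}"
            )
        if cur.timestamp <= prev.timestamp:
            raise ValidationError(
                f"timestamps not strictly increasing at frame {cur.frame_index}"
            )
    return frames


TRAJECTORY_HEADER = "timestamp_s,object_id,x_mm,y_mm"


def write_trajectory(samples: Iterable[TrajectorySample], dest, header: Sequence[str] = ()) -> None:
    """Write trajectory samples as CSV (``timestamp_s,object_id,x_mm,y_mm``)."""
    stream, close = _open_text(dest, "w")
    try:
        for line in header:
            stream.write(f"# {line}\n")
        stream.write(TRAJECTORY_HEADER + "\n")
        for s in samples:
            stream.write(f"{s.timestamp!r},{s.object_id},{s.position.x!r},{s.position.y!r}\n")
        if isinstance(stream, io.TextIOWrapper) and not close:
            stream.flush()
            stream.detach()
    finally:
        if close:
            stream.close()


def read_trajectory(source) -> list[TrajectorySample]:
    """Read a trajectory CSV; validates per-object timestamp monotonicity."""
    stream, close = _open_text(source, "r")
    samples: list[TrajectorySample] = []
    try:
        saw_header = False
        for line_no, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if not saw_header:
                if line != TRAJECTORY_HEADER:
                    raise FormatError(
                        f"line {line_no}: expected header {TRAJECTORY_HEADER!r}, got {line!r}"
                    )
                saw_header = True
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise FormatError(f"line {line_no}: expected 4 fields, got {len(parts)}")
            try:
                samples.append(
                    TrajectorySample(
                        float(parts[0]), int(parts[1]), WorldPoint(float(parts[2]), float(parts[3]))
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"line {line_no}: {exc}") from exc
    finally:
        if close:
            stream.close()
    last_t: dict[int, float] = {}
    for s in samples:
        prev = last_t.get(s.object_id)
        if prev is not None and s.timestamp <= prev:
            raise ValidationError(
                f"object {s.object_id}: timestamps not strictly increasing at t={s.timestamp}"
            )
        last_t[s.object_id] = s.timestamp
    return samples


def split_trajectory(samples: Iterable[TrajectorySample]) -> dict[int, list[TrajectorySample]]:
    """Partition samples by object_id, preserving order."""
    out: dict[int, list[TrajectorySample]] = {}
    for s in samples:
        out.setdefault(s.object_id, []).append(s)
    return out
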