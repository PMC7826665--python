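"""Per-frame object detection: clustering plus size and curvature filtering.

A leg at ankle height appears to a 2D-LiDAR as a short arc of points
bulging toward the sensor.  Detection proceeds in two stages:

1. nearest-neighbour (single-linkage) clustering of the frame's world
   points into point groups, and
2. filtering of the groups by point count, spatial extent, and fitted
   curvature, keeping only leg-like arcs as *object snapshots* — the
   candidate ankle observations handed to the tracker.

Background structure (walls, furniture) is removed by the filters alone:
walls form long or flat groups, and concave or oversized arcs fail the
curvature test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .scan_io import ScanFrame, SensorPose, WorldPoint, frame_to_world

__all__ = [
    "PointGroup",
    "ObjectSnapshot",
    "DetectionCriteria",
    "cluster_points",
    "fit_circle",
    "fit_circle_radius",
    "filter_snapshots",
    "detect_frame",
]


@dataclass
class PointGroup:
    """A cluster of world points from one frame.

    ``centroid`` is the arithmetic mean of the members; ``bbox`` the
    axis-aligned (x-extent, y-extent) in mm.
    """

    members: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        m = np.asarray(self.members, dtype=float).reshape(-1, 2)
        if m.shape[0] == 0:
            raise ValueError("PointGroup requires at least one member")
        self.members = m

    @property
    def centroid(self) -> WorldPoint:
        c = self.members.mean(axis=0)
        return WorldPoint(float(c[0]), float(c[1]))

    @property
    def bbox(self) -> tuple[float, float]:
        spans = self.members.max(axis=0) - self.members.min(axis=0)
        return (float(spans[0]), float(spans[1]))

    def __len__(self) -> int:
        return self.members.shape[0]


@dataclass(frozen=True)
class ObjectSnapshot:
    """A point group that passed the size and curvature criteria.

    ``centroid`` is the raw arithmetic mean of the member points.  Because
    the sensor samples only the front arc of a leg, that mean is biased
    toward the sensor by (pi/4) x leg radius on average; ``position`` is
    the disc-center estimate with that bias removed (the centroid shifted
    away from the sensor along the viewing ray by the expected arc depth
    of a nominal leg).  Trackers should use ``position``.
    """

    frame_index: int
    snapshot_index: int
    timestamp: float
    centroid: WorldPoint
    n_points: int
    extent: tuple[float, float]
    curvature_radius: float
    position: WorldPoint

    @property
    def xy(self) -> np.ndarray:
        return self.position.xy


@dataclass(frozen=True)
class DetectionCriteria:
    """Thresholds of the detection filters (all config-exposed).

    link_distance
        Clustering threshold, mm.  Must bridge the inter-point gap at the
        far end of the working range (~39 mm at 10 m with 0.225 deg
        resolution) with margin, yet keep two ankles >= ~150 mm apart
        separate.
    min_points
        Minimum returns per snapshot.
    extent_range
        Admissible (min, max) of the larger bounding-box side, mm: an
        ankle/lower-leg cross-section is ~60-150 mm; the upper bound
        tolerates trousers while staying below the span of two ankles
        momentarily fused into one cluster as the feet pass each other
        (>= ~190 mm even for partial fusions at walking step widths) —
        fused groups must be rejected, not tracked, or they corrupt the
        tracker's velocity anchors.
    radius_range
        Admissible fitted circle radius, mm; arcs must also be convex
        toward the sensor (fitted center farther from the sensor than the
        centroid) — walls fit huge radii or concave arcs.
    nominal_radius
        Expected leg radius, mm, used to push the visible-arc centroid
        back to the leg center (see :class:`ObjectSnapshot`).
    split_gap
        A cluster is split where consecutive points (in bearing order)
        jump by more than this value *laterally*, i.e. perpendicular to
        the viewing ray: two legs fused into one cluster remain two arcs
        separated laterally by at least the inter-leg surface gap
        (~40 mm at walking step widths), while within a genuine arc the
        lateral spacing is one ray step (< ~35 mm inside the working
        range) and noise is purely radial.
    """

    link_distance: float = 100.0
    min_points: int = 3
    extent_range: tuple[float, float] = (30.0, 160.0)
    radius_range: tuple[float, float] = (20.0, 300.0)
    nominal_radius: float = 60.0
    split_gap: float = 40.0

    def __post_init__(self) -> None:
        if self.link_distance <= 0:
            raise ValueError("link_distance must be positive")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")
        for name in ("extent_range", "radius_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"{name} must satisfy 0 < min < max")


def cluster_points(
    points, link_distance: float, sensor_xy=(0.0, 0.0)
) -> list[PointGroup]:
    """Single-linkage clustering: same group iff joined by a chain of
    pairwise distances <= ``link_distance``.

    Groups are returned ordered by the angle of their centroid as seen
    from ``sensor_xy``.  Empty input yields an empty list.
    """
    if link_distance <= 0:
        raise ValueError("link_distance must be positive")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = pts.shape[0]
    if n == 0:
        return []
    if n == 1:
        labels = np.array([1])
    else:
        Z = linkage(pts, method="single")
        labels = fcluster(Z, t=link_distance, criterion="distance")
    groups = [PointGroup(pts[labels == lab]) for lab in np.unique(labels)]
    s = np.asarray(sensor_xy, dtype=float)

    def _angle(g: PointGroup) -> float:
        d = g.centroid.xy - s
        return math.atan2(d[1], d[0]) % (2 * math.pi)

    groups.sort(key=_angle)
    return groups


def fit_circle(points: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Geometric least-squares circle fit.

    An algebraic (Kasa) solve — minimizing sum((x^2 + y^2 + D x + E y
    + F)^2) — provides the starting point, then a few Gauss-Newton steps
    minimize the true radial residuals sum((|p - c| - r)^2); the
    algebraic solution alone underestimates the radius of short noisy
    arcs.  Returns ``(center, radius)``, or ``None`` for fewer than 3
    points or a (numerically) collinear set, where no finite circle
    exists.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 3:
        return None
    # center for conditioning
    mean = pts.mean(axis=0)
    q = pts - mean
    A = np.column_stack((q, np.ones(len(q))))
    b = (q**2).sum(axis=1)
    if np.linalg.matrix_rank(A) < 3:
        return None
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx**2 + cy**2
    if not np.isfinite(r2) or r2 <= 0:
        return None
    c = mean + np.array([cx, cy])
    r = float(math.sqrt(r2))
    for _ in range(8):
        d = pts - c
        dist = np.linalg.norm(d, axis=1)
        if dist.min() < 1e-9:
            break
        f = dist - r
        J = np.column_stack((-d[:, 0] / dist, -d[:, 1] / dist, -np.ones(len(pts))))
        step, *_ = np.linalg.lstsq(J, -f, rcond=None)
        if not np.all(np.isfinite(step)):
            break
        c = c + step[:2]
        r = r + float(step[2])
        if np.linalg.norm(step) < 1e-10 * max(1.0, r):
            break
    if not (np.isfinite(r) and r > 0 and np.all(np.isfinite(c))):
        return None
    return c, float(r)


def fit_circle_radius(group: PointGroup) -> float:
    """Least-squares circle radius of a group; +inf when degenerate
    (fewer than 3 points, or collinear points)."""
    fit = fit_circle(group.members)
    return math.inf if fit is None else fit[1]


def _center_corrected(group: PointGroup, criteria: DetectionCriteria, sensor: np.ndarray) -> WorldPoint:
    """Disc-center estimate: centroid pushed away from the sensor, along
    the viewing ray, by the expected front-arc depth (pi/4) * r_nominal
    (the mean of sqrt(r^2 - b^2) over impact parameters b, for either a
    fully or half visible arc).  A fixed offset adds no variance, unlike
    a per-frame circle-fit shift, whose radial scatter at low point
    counts corrupts the velocity estimates the tracker depends on."""
    g = group.centroid.xy
    ray = g - sensor
    norm = np.linalg.norm(ray)
    if norm == 0:
        return group.centroid
    p = g + (math.pi / 4.0) * criteria.nominal_radius * (ray / norm)
    return WorldPoint(float(p[0]), float(p[1]))


def _split_group(g: PointGroup, criteria: DetectionCriteria, sensor: np.ndarray) -> list[PointGroup]:
    """Split a cluster at its largest *lateral* internal gap when that
    gap marks a two-leg fusion (feet passing each other).

    Points are ordered by bearing from the sensor.  The jump between
    consecutive points is projected perpendicular to the viewing ray:
    fused legs separate laterally, whereas the large jumps within a
    genuine arc (its near-tangent edge, range noise) are radial.
    """
    if len(g) < 2 * criteria.min_points:
        return [g]
    d = g.members - sensor
    order = np.argsort(np.arctan2(d[:, 1], d[:, 0]))
    pts = g.members[order]
    diffs = np.diff(pts, axis=0)
    mids = (pts[:-1] + pts[1:]) / 2.0 - sensor
    u = mids / np.linalg.norm(mids, axis=1, keepdims=True)
    lateral = np.abs(u[:, 0] * diffs[:, 1] - u[:, 1] * diffs[:, 0])
    cut = int(np.argmax(lateral))
    if lateral[cut] <= criteria.split_gap:
        return [g]
    return [PointGroup(pts[: cut + 1]), PointGroup(pts[cut + 1 :])]


def filter_snapshots(
    groups: list[PointGroup],
    criteria: DetectionCriteria,
    frame: ScanFrame,
    pose: SensorPose = SensorPose(),
) -> list[ObjectSnapshot]:
    """Keep leg-like groups; assign snapshot indices 0..K-1 in retained order.

    A group is retained iff it has at least ``min_points`` members, its
    larger bounding-box side lies within ``extent_range``, its fitted
    circle radius lies within ``radius_range``, and the arc is convex
    toward the sensor.  A group with a fusion-scale internal gap (see
    ``split_gap``) is first split there — two legs fused into one cluster
    — and the halves are filtered individually.
    """
    sensor = pose.xy
    expanded: list[PointGroup] = []
    for g in groups:
        expanded.extend(_split_group(g, criteria, sensor))
    retained: list[ObjectSnapshot] = []
    for g in expanded:
        if len(g) < criteria.min_points:
            continue
        extent = g.bbox
        lo, hi = criteria.extent_range
        if not (lo <= max(extent) <= hi):
            continue
        fit = fit_circle(g.members)
        radius = math.inf if fit is None else fit[1]
        rlo, rhi = criteria.radius_range
        if not (rlo <= radius <= rhi):
            continue
        # convex toward the sensor: fitted center behind the arc
        if np.linalg.norm(fit[0] - sensor) <= np.linalg.norm(g.centroid.xy - sensor):
            continue
        retained.append(
            ObjectSnapshot(
                frame_index=frame.frame_index,
                snapshot_index=len(retained),
                timestamp=frame.timestamp,
                centroid=g.centroid,
                n_points=len(g),
                extent=extent,
                curvature_radius=radius,
                position=_center_corrected(g, criteria, sensor),
            )
        )
    return retained


def detect_frame(
    frame: ScanFrame, pose: SensorPose, criteria: DetectionCriteria = DetectionCriteria()
) -> list[ObjectSnapshot]:
    """Full per-frame detection: transform, cluster, filter."""
    world = frame_to_world(frame, pose)
    groups = cluster_points(world, criteria.link_distance, sensor_xy=pose.position)
    return filter_snapshots(groups, criteria, frame, pose)
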