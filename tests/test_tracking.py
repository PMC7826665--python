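import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lidargait.detection import ObjectSnapshot
from lidargait.scan_io import WorldPoint
from lidargait.tracking import (
    TargetPair,
    TrackState,
    TrackedObject,
    Tracker,
    TrackerConfig,
    assign_ids,
    candidate_velocity,
    designate_targets,
    step_tracker,
    velocity_score,
)


def snap(k, t, x, y, frame=0):
    p = WorldPoint(x, y)
    return ObjectSnapshot(
        frame_index=frame, snapshot_index=k, timestamp=t, centroid=p,
        n_points=5, extent=(50.0, 100.0), curvature_radius=60.0, position=p,
    )


def obj(m, x, y, vx, vy, t=0.0, frame=0, state=TrackState.ACTIVE):
    o = TrackedObject(
        object_id=m, position=np.array([x, y]), velocity=np.array([vx, vy]),
        state=state, last_seen=(frame, t),
    )
    from lidargait.scan_io import TrajectorySample
    o.history.append(TrajectorySample(t, m, WorldPoint(x, y)))
    return o


# ---------------------------------------------------------------------------
# the velocity-similarity score


@pytest.mark.parametrize(
    "v1,v2,expected",
    [
        ((500, 0), (500, 0), 1.0),
        ((300, 400), (0, 0), 1 / 501),  # 3-4-5 triangle, d = 500
        ((1000, 0), (997, 4), 1 / 6),  # 3-4-5 triangle, d = 5
    ],
)
def test_velocity_score_closed_form(v1, v2, expected):
    assert velocity_score(v1, v2) == pytest.approx(expected, abs=1e-7)


@given(
    vx1=st.floats(-5000, 5000), vy1=st.floats(-5000, 5000),
    vx2=st.floats(-5000, 5000), vy2=st.floats(-5000, 5000),
)
def test_velocity_score_range_symmetry_and_identity(vx1, vy1, vx2, vy2):
    s = velocity_score((vx1, vy1), (vx2, vy2))
    assert 0 < s <= 1
    assert s == velocity_score((vx2, vy2), (vx1, vy1))
    d = math.hypot(vx1 - vx2, vy1 - vy2)
    assert s == pytest.approx(1.0 / (1.0 + d))
    if (vx1, vy1) == (vx2, vy2):
        assert s == 1.0


def test_candidate_velocity_finite_difference():
    o = obj(1, 0, 0, 0, 0, t=0.0)
    v = candidate_velocity(snap(0, 0.1, 100, 0), o)
    assert v == pytest.approx([1000.0, 0.0])


def test_candidate_velocity_zero_displacement():
    o = obj(1, 50, 50, 0, 0, t=0.0)
    assert candidate_velocity(snap(0, 0.1, 50, 50), o) == pytest.approx([0.0, 0.0])


def test_candidate_velocity_spans_occlusion_gap():
    """After 3 missed frames, the candidate is displacement over the full
    gap divided by the full gap time (hand-computed)."""
    o = obj(1, 1000, 0, 1200, 0, t=1.0)
    # 4 frame intervals of 1/15 s later, observed 320 mm further on
    t = 1.0 + 4 / 15
    v = candidate_velocity(snap(0, t, 1320.0, 0.0), o)
    assert v == pytest.approx([320.0 / (4 / 15), 0.0])


def test_candidate_velocity_rejects_nonpositive_dt():
    o = obj(1, 0, 0, 0, 0, t=1.0)
    with pytest.raises(ValueError):
        candidate_velocity(snap(0, 1.0, 10, 0), o)


# ---------------------------------------------------------------------------
# greedy one-to-one assignment


def test_assign_unambiguous_two_objects():
    dt = 0.1
    objects = [obj(1, 0, 0, 1200, 0), obj(2, 1000, 0, -1200, 0)]
    snaps = [snap(0, dt, 120, 0), snap(1, dt, 880, 0)]
    matches, new, unseen = assign_ids(snaps, objects, TrackerConfig())
    assert sorted(matches) == [(0, 1), (1, 2)]
    assert new == [] and unseen == []


def test_assign_cold_start_spawns_all_new():
    snaps = [snap(k, 0.1, 100 * k, 0) for k in range(3)]
    matches, new, unseen = assign_ids(snaps, [], TrackerConfig())
    assert matches == [] and new == [0, 1, 2] and unseen == []


def test_assign_matches_exhaustive_oracle_on_crossing_fixture():
    """Three objects crossing; greedy must equal the best of all 3!
    one-to-one assignments (fixture chosen so both agree)."""
    dt = 0.1
    objects = [
        obj(1, 0, 0, 1000, 0),
        obj(2, 500, 300, 0, -800),
        obj(3, 900, -200, -1000, 200),
    ]
    snaps = [
        snap(0, dt, 95, 3),
        snap(1, dt, 505, 220),
        snap(2, dt, 805, -180),
    ]
    matches, _, _ = assign_ids(snaps, objects, TrackerConfig())

    def total(pairing):
        s = 0.0
        for k, o in pairing:
            vc = (snaps[k].xy - objects[o].anchor) / dt
            s += velocity_score(vc, objects[o].velocity)
        return s

    best = max(
        (tuple(zip(range(3), perm)) for perm in itertools.permutations(range(3))),
        key=total,
    )
    got = tuple(sorted((k, m - 1) for k, m in matches))
    assert got == tuple(sorted(best))


@pytest.mark.parametrize("n_scenes", [100])
def test_greedy_near_optimal_and_no_switches_on_unambiguous_scenes(n_scenes):
    """On random scenes with <= 4 well-separated objects the greedy total
    score stays >= 95% of the exhaustive optimum, with zero mismatches."""
    rng = np.random.default_rng(42)
    worst_ratio = 1.0
    switches = 0
    for _ in range(n_scenes):
        n = int(rng.integers(2, 5))
        dt = 1 / 15
        objects = []
        for m in range(1, n + 1):
            pos = rng.uniform(-3000, 3000, 2)
            vel = rng.uniform(-2000, 2000, 2)
            objects.append(obj(m, *pos, *vel))
        # snapshots follow each object's inertia with modest perturbation
        snaps = []
        order = rng.permutation(n)
        for k, idx in enumerate(order):
            o = objects[idx]
            p = o.anchor + o.velocity * dt + rng.normal(0, 10, 2)
            snaps.append(snap(k, dt, p[0], p[1]))
        matches, _, _ = assign_ids(snaps, objects, TrackerConfig())
        for k, m in matches:
            if objects[order[k]].object_id != m:
                switches += 1

        def total(pairing):
            return sum(
                velocity_score((snaps[k].xy - objects[o].anchor) / dt, objects[o].velocity)
                for k, o in pairing
            )

        greedy_total = total([(k, m - 1) for k, m in matches])
        best_total = max(
            total(list(zip(range(n), perm))) for perm in itertools.permutations(range(n))
        )
        worst_ratio = min(worst_ratio, greedy_total / best_total)
    assert worst_ratio >= 0.95
    assert switches == 0


# ---------------------------------------------------------------------------
# frame stepping, occlusion, loss


def test_step_tracker_constant_velocity_history():
    tracker = Tracker()
    for i in range(10):
        t = i / 15
        tracker.step([snap(0, t, 1000 * t, 50, frame=i)], i, t)
    (o,) = tracker.objects
    assert o.state is TrackState.ACTIVE
    assert len(o.history) == 10
    xs = np.array([s.position.x for s in o.history])
    assert np.allclose(np.diff(xs), 1000 / 15, atol=1e-9)
    assert o.velocity == pytest.approx([1000.0, 0.0])


def test_occluded_object_coasts_and_resumes_same_id():
    tracker = Tracker()
    dt = 1 / 15
    v = 1200.0
    # 5 visible frames, 5 occluded (~0.33 s), then reappears on the path
    for i in range(12):
        t = i * dt
        if 5 <= i < 10:
            snaps = []
        else:
            snaps = [snap(0, t, v * t, 0, frame=i)]
        tracker.step(snaps, i, t)
        if i == 6:
            (o,) = tracker.objects
            assert o.state is TrackState.OCCLUDED
            # coasted prediction keeps advancing at the last velocity
            assert o.position[0] == pytest.approx(v * t, abs=1.0)
    (o,) = tracker.objects
    assert o.state is TrackState.ACTIVE
    assert o.object_id == 1
    assert len(tracker.objects) == 1  # no spurious new identity


def test_occlusion_beyond_timeout_is_lost_and_id_not_reissued():
    cfg = TrackerConfig(occlusion_timeout=0.3)
    tracker = Tracker(cfg)
    dt = 1 / 15
    for i in range(3):
        tracker.step([snap(0, i * dt, 1000 * i * dt, 0, frame=i)], i, i * dt)
    for i in range(3, 11):
        tracker.step([], i, i * dt)
    assert tracker.objects[0].state is TrackState.LOST
    t = 11 * dt
    tracker.step([snap(0, t, 1000 * t, 0, frame=11)], 11, t)
    ids = [o.object_id for o in tracker.objects]
    assert ids == [1, 2]  # the lost id is never reissued
    assert tracker.objects[0].state is TrackState.LOST


def test_step_tracker_rejects_out_of_order_frames():
    tracker = Tracker()
    tracker.step([snap(0, 1.0, 0, 0, frame=0)], 0, 1.0)
    with pytest.raises(ValueError):
        tracker.step([snap(0, 0.5, 0, 0, frame=1)], 1, 0.5)


def test_step_tracker_function_mutates_object_list():
    objects = []
    step_tracker([snap(0, 0.0, 0, 0)], objects, TrackerConfig(), 0, 0.0)
    step_tracker([snap(0, 1 / 15, 80, 0, frame=1)], objects, TrackerConfig(), 1, 1 / 15)
    assert [o.object_id for o in objects] == [1]
    assert len(objects[0].history) == 2


# ---------------------------------------------------------------------------
# automatic target designation


def _walking_track(m, y, x0=0.0, direction=1, n=12, dt=1 / 15, speed=1000.0):
    o = obj(m, x0, y, direction * speed, 0)
    from lidargait.scan_io import TrajectorySample
    o.history = [
        TrajectorySample(i * dt, m, WorldPoint(x0 + direction * speed * i * dt, y))
        for i in range(n)
    ]
    return o


def test_designation_left_is_larger_y():
    tracks = [_walking_track(1, -80.0), _walking_track(2, 80.0)]
    pair = designate_targets(tracks, TrackerConfig())
    assert pair is not None
    assert pair.left_id == 2 and pair.right_id == 1


def test_designation_reflection_swaps_labels():
    tracks = [_walking_track(1, -80.0), _walking_track(2, 80.0)]
    mirrored = [_walking_track(1, 80.0), _walking_track(2, -80.0)]
    a = designate_targets(tracks, TrackerConfig())
    b = designate_targets(mirrored, TrackerConfig())
    assert (a.left_id, a.right_id) == (b.right_id, b.left_id)


def test_designation_ignores_stationary_tracks():
    movers = [_walking_track(3, 80.0), _walking_track(4, -80.0)]
    still = [obj(m, 500.0 * m, 200.0 + m, 0, 0) for m in (1, 2, 5, 6)]
    pair = designate_targets(still + movers, TrackerConfig())
    assert {pair.left_id, pair.right_id} == {3, 4}


def test_designation_pending_with_single_mover():
    tracks = [_walking_track(1, 80.0), obj(2, 0, -80, 0, 0)]
    assert designate_targets(tracks, TrackerConfig()) is None


def test_designation_requires_consistent_direction():
    fwd = _walking_track(1, 80.0, direction=1)
    rev = _walking_track(2, -80.0, direction=-1)
    assert designate_targets([fwd, rev], TrackerConfig()) is None


def test_target_pair_rejects_equal_ids():
    with pytest.raises(ValueError):
        TargetPair(left_id=1, right_id=1, designated_at=0.0)


# ---------------------------------------------------------------------------
# properties on the simulated pipeline


def test_noise_free_tracking_quantization_bound(noisefree_walk):
    """Zero noise, no occlusion: tracked positions deviate from truth by
    less than one angular-resolution arc length at the operating range."""
    cfg, _, truth, tracker = noisefree_walk
    pair = tracker.target_pair
    wt = truth.walkers[0]
    for oid, ref in ((pair.left_id, wt.left), (pair.right_id, wt.right)):
        ref_by_t = {s.timestamp: s.position for s in ref}
        for s in tracker.history_of(oid):
            p = ref_by_t[s.timestamp]
            rng = math.hypot(p.x - cfg.sensor.position[0], p.y - cfg.sensor.position[1])
            arc = rng * math.radians(cfg.angular_resolution)
            err = math.hypot(s.position.x - p.x, s.position.y - p.y)
            assert err < max(arc, 5.0)


def test_id_conservation_over_run(crossing_run):
    """Ids are unique, and lost objects never resume."""
    _, frames, _, tracker = crossing_run
    ids = [o.object_id for o in tracker.objects]
    assert len(ids) == len(set(ids))
    for o in tracker.objects:
        ts = [s.timestamp for s in o.history]
        assert ts == sorted(ts)
        if o.state is TrackState.LOST:
            assert o.last_seen[1] < frames[-1].timestamp
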