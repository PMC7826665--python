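# Methods

This note records the models, algorithmic choices, and their rationale.
Units throughout: millimetres, seconds, degrees in files and configs
(radians only inside computations).

## Sensing model and coordinates

A 2D-LiDAR returns, once per revolution, an (angle, range) pair per
emitted ray in a single horizontal plane.  The package assumes a scanner
with 10–15 Hz scan rate, 0.225° angular resolution, and a reliable range
of 10 m, mounted at ankle height at one end of a roughly 6000 × 2000 mm
monitored area.  World coordinates: origin at the area's center, x along
the walking axis, y lateral, angles counter-clockwise from above; the
default sensor pose is (−4000, 0) mm with its 0° ray along +x.  The
angular zero of the physical sensor relative to the walking axis is a
mounting convention, not a measured fact; the heading field of the
sensor pose absorbs it.

## Detection

Each frame's returns are transformed to world coordinates and clustered
by single linkage: two points share a group iff a chain of pairwise
distances ≤ `link_distance` connects them.  The threshold must bridge
the inter-point gap on one leg at the far end of the range
(≈ 39 mm at 10 m) with margin, while keeping separate things separate;
default **100 mm**.

Groups are filtered to *object snapshots* by four criteria, all exposed
in the `[detection]` config section:

* `min_points` (default **3**) — a circle fit needs three points.
* `extent_range` (default **30–160 mm** for the larger bounding-box
  side).  A bare ankle/lower-leg cross-section spans ~60–150 mm.  The
  upper bound matters more than it looks: when the swing foot passes the
  stance foot the two leg arcs fuse into one cluster spanning upward of
  ~190 mm, and a fused blob accepted as a "leg" plants a corrupted
  anchor in the tracker right before an occlusion — the single most
  damaging failure mode found during development.  160 mm sits between
  the measured single-leg maximum (~122 mm over thousands of simulated
  snapshots at 10 mm noise) and the smallest fused spans (~194 mm).
* `radius_range` (default **20–300 mm**) on the radius of a circle fit
  to the group, plus a convexity requirement: the fitted center must lie
  farther from the sensor than the centroid.  Legs bulge toward the
  sensor; walls fit huge radii or concave arcs.
* a **fusion split**: before filtering, a cluster is split where
  consecutive points (ordered by bearing) jump by more than `split_gap`
  (default **40 mm**) *laterally*, i.e. perpendicular to the viewing
  ray.  Fused legs separate laterally by at least the inter-leg surface
  gap; jumps inside a genuine arc (near-tangent edges, range noise) are
  radial.  Splitting keeps both feet observed through their mutual
  pass, which shortens occlusion gaps and keeps tracker anchors honest.

**Circle fit.** Algebraic (Kåsa) least squares gives the initial center
and radius; a few Gauss–Newton steps on the radial residuals
Σ(|p−c|−r)² refine it.  The algebraic solution alone underestimates the
radius of short noisy arcs.  Collinear or < 3-point groups have no
finite circle and are reported as radius +∞.

**Position estimate.** The sensor samples only the front arc of a leg,
so the arc centroid is biased toward the sensor by the mean arc depth
E[√(r²−b²)] = (π/4)·r over impact parameters b — about 47 mm for a
60 mm leg, and identical for a fully or half visible arc.  Snapshots
therefore carry both the raw `centroid` and a `position`: the centroid
pushed away from the sensor along the viewing ray by
(π/4)·`nominal_radius` (default **60 mm**).  A per-frame circle-fit
shift was evaluated and rejected: measured on rendered discs with 10 mm
range noise, the fit-based shift has bias −5…−14 mm and SD 5–13 mm
(exploding at 3–5 points per leg), whereas the fixed offset has
|bias| < 6 mm and SD 2–4 mm, and in the noise-free case stays within
one angular-resolution arc length of the true center at every range.
Velocity estimates inherit position noise at twice the scan rate, so
the low-variance estimator is what keeps inertia matching stable.

## Tracking (IOTA)

The tracker assumes inter-frame velocity changes are small.  For
snapshot k and live object m it computes the candidate velocity the
snapshot would imply — displacement from the object's last *observed*
position over the full time gap since that observation — and the score
S = 1/(1+d) with d the Euclidean distance to the object's previous
velocity.  Identities are resolved by greedy one-to-one matching over
all (k, m) entries in descending score (ties: smaller object id, then
smaller snapshot index).  A per-snapshot argmax alone could hand two
snapshots the same identity.

* `score_min` (default **1e-4**, a mismatch of 10 m/s) is an absurdity
  bound, not a tuning knob.  A swinging ankle sampled at 10–15 Hz
  legitimately changes its frame-averaged velocity by several m/s
  between frames (peak swing acceleration ~(π/2)·v_peak/T_swing), so
  any threshold tight enough to "filter noise" also rejects correct
  matches mid-swing.  Discrimination comes from the relative greedy
  comparison.
* Unmatched snapshots spawn new objects with velocity (0, 0) — the
  standing-start prior.
* Unmatched objects become *occluded*: their position estimate coasts
  at the last velocity (position += v·Δt each frame) while matching
  continues to measure candidates from the last observed position over
  the full gap, so an object reappearing on its inertial path scores
  ≈ 1 however many frames it was hidden.
* `occlusion_timeout` (default **1.0 s**) turns occluded objects into
  *lost*; lost ids are never reissued or revived.  The default sits
  above the few-tenths-of-a-second gaps that people crossing the scene
  produce, and below the point where a coasted prediction stops meaning
  anything.

**Target designation.**  The first two tracks whose net displacement
along the walking axis exceeds `designation_displacement` (default
**300 mm**, in the direction set by the first qualifier) become the
monitored ankles; at designation the track with the larger y is
labelled *left*.  Qualification times are computed from track
histories, so designation is deterministic and independent of frame
arrival details.  Bystanders' standing legs never qualify; in the
bundled crossing demo the crossers start moving after the subject so
the subject's pair qualifies first, matching how a monitored walk in a
busy corridor begins.

**Known failure mode.**  Velocity similarity carries no appearance
information.  If an occlusion gap spans a foot's landing or lift-off,
the stored velocity is stale by up to the acceleration times the gap,
and when two near-stationary feet are simultaneously hidden and
co-located the re-association is genuinely ambiguous.  The detection
layer's fusion split and extent cap exist mostly to keep such gaps
short; the residual ambiguity is inherent to inertia-only tracking.

## Gait events and parameters

Through stance the ankle's forward speed is near zero; in swing it
peaks near twice the walking speed.  Stance intervals are maximal runs
of samples with |dx/dt| (central differences) below `v_stance_frac`
(default **0.2**) times that ankle's mean forward speed.  Runs shorter
than 2 samples are discarded; runs separated by less than
`min_swing_time` (default **0.3 s**, below the ~0.35–0.45 s swing of
any walking cadence) are merged, so a one-sample speed spike — noise,
or a sample distorted by the contralateral foot passing — cannot split
one true stance into two same-side contacts.  Event *positions* are the
mean ankle position over the run; event *times* are the sub-sample
threshold crossings interpolated between the neighbouring speed
samples (sample-resolution timing alone lags the true contact by up to
~1.5 frames because central differences smear the transition).  A run
touching the trajectory boundary emits only its interior event: a run
that starts at the first sample has no observed contact instant — this
also resolves the standing start, where both feet begin in stance and
would otherwise yield two simultaneous contacts.

From contacts C₁…C_M (strictly alternating sides, enforced):
step length |Δx| and step width |Δy| between consecutive contacts,
step time Δt; stride quantities between consecutive same-side contacts;
cadence 60(M−1)/(t_M−t₁); gait speed |x_M−x₁|/(t_M−t₁) — first-to-last
displacement over time, the stopwatch-over-walkway convention.  Stance
time is foot-off − contact within a cycle, swing time the remainder;
only complete cycles contribute, so first/last partial cycles are
excluded by construction.  Per-cycle stance + swing equals stride time
exactly.  Means use all available steps; SDs are sample SDs (n−1).

## Simulator

Walkers are pairs of vertical leg cylinders → 2-D discs of
`leg_radius` (default **60 mm**) at ankle height, feet offset
±`step_width`/2 (default **160 mm**) from the walker's lane.  Each foot
alternates frozen stance and a swing that advances one stride
(2 × step length, step length = speed·60000/cadence) with sinusoidal
forward velocity, zero at both contacts; feet are half a stride out of
phase; `duty_factor` (default **0.62**) sets the stance fraction.  The
mean forward speed equals the configured gait speed exactly, and the
generator emits the exact contact/foot-off event list along with
trajectories sampled at scan instants.  Walkers normally walk along ±x;
an `axis = "y"` walker traverses the area laterally, which is how the
crossing demo produces brief (≲ 0.3 s) occlusions of the monitored
ankles: a lateral crosser's foot sweeps the sensor–subject bearing
corridor in a fraction of a swing, whereas an occluder moving purely
along x sits in the corridor for seconds.

Rendering casts one ray per 0.225° step per frame, returns the distance
to the nearest disc intersection (nearer discs occlude farther ones),
clips at `max_range` (default **10 000 mm**), and adds Gaussian range
noise (`range_noise_sd`, default **10 mm**, seeded).  Rays that hit
nothing yield no point.

**What the simulator does and does not emulate.**  It reproduces the
geometry that drives the method — angular quantization and its
range-dependent point sparsity, the front-arc bias, occlusion, dropout,
standing starts — with circular leg cross-sections, a perfectly
horizontal scan plane, an instantaneous sweep, and Gaussian range
noise.  Real legs are non-circular and clothed, real scanners sweep
over ~70 ms and wobble in elevation, real ankles move vertically so the
scan plane cuts different limb sections through the cycle, and real
scenes contain static background that the size/curvature filters must
reject.  Passing tests therefore demonstrate the correctness and
internal consistency of the algorithms under the stated sensing
geometry, not the field accuracy of any particular sensor on any
particular population.

## Numerical and interface choices

* Frame and trajectory files store floats via `repr`, so
  read(write(x)) == x exactly; outputs embed the tool version, a
  SHA-256 digest of the effective configuration, and the seed, and the
  whole pipeline is byte-deterministic for a fixed seed.
* One global seed (config `seed`, CLI `--seed`) drives the only random
  element, range noise; walker kinematics are analytic.
* Degenerate inputs are contracts, not crashes: empty frames are legal
  scenes, empty clusters detect nothing, a constant-velocity trajectory
  raises an insufficient-data error, non-alternating contacts raise an
  event-sequence error naming the offending pair.
* Bland–Altman limits use the fixed 1.96 normal multiplier on the
  sample SD of differences (no t-correction); such dashed lines are
  sometimes labelled "95% confidence intervals" in validation plots,
  but they are limits of agreement — bounds on individual differences,
  not on the bias estimate.  Pearson p-values use the exact t-transform
  with n−2 degrees of freedom.
* Trajectory alignment interpolates the denser series onto the sparser
  one's timestamps, restricted to their overlap; nothing is
  extrapolated.

## Problem sizes

Bundled scenes run 4–6 s at 15 Hz (60–90 frames, 1600 rays each); the
acceptance script's agreement batch uses twelve such walks spanning
0.8–1.4 m/s and 95–125 steps/min, sizes at which every quantity it
reports is stable to well under the tolerances checked in the test
suite.

## Limitations

* Inertia-only association: no appearance features, no Kalman smoothing
  (a deliberate non-goal), so simultaneous occlusion of two co-located,
  near-stationary feet can swap identities — see the tracking section.
* Gait parameters need a monitored walker moving predominantly along
  one axis; the designation convention assumes that axis is x.
* The event detector presumes walking (clear stance/swing speed
  contrast); running (duty factor < 0.5) and shuffling gaits with no
  stationary stance are out of scope.
* Whole-body kinematics are unobservable in a single horizontal plane;
  the package reports ankle-derived spatiotemporal parameters only.
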