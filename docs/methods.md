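# Methods

This note records what the model actually is, which numbers are inputs
versus products of calibration, and where the implementation cuts
corners on purpose.

## Skeletal model

Minimal-coordinate rigid-body tree, assembled by d'Alembert's principle:

- **torso** fixed to ground (a seated, restrained trunk);
- **scapula** on a planar 2-DOF scapulothoracic glide (X protraction,
  Z elevation), with elastic centering (4000 N/m, 60 N s/m) standing in
  for the scapula–rib contact and soft stops at ±4 cm;
- **humerus** on a spherical 3-DOF glenohumeral joint, intrinsic-XYZ
  Euler angles, penalty range stops, and lumped elastic centering
  (65 N m/rad, 1.5 N m s/rad) standing in for capsule and ligaments;
  the tight lower limit on the third axis (−0.35 rad) models arm–torso
  contact in adduction;
- **forearm** locked to the humerus at a 130° included elbow angle.

Generalized coordinates: 2 (scapula) + 3 (glenohumeral) = 5.  Jacobians
are exact (velocities are linear in the rates, so unit-rate velocity
passes give the columns); the velocity-product bias accelerations come
from a central difference of the velocity field along the motion
(h = 1 µs).  Time stepping is fixed-step semi-implicit Euler at 1 ms
(RK4 available via the config).  A constant generalized feedforward
force, computed once at the build pose, cancels gravity and tonic muscle
force — the stand-in for postural support, so the arm starts in
equilibrium.

Segment masses (torso 30, scapula 0.8, humerus 2.1, forearm 1.9 kg) and
inertias are plausible single-subject magnitudes, not fitted data.

## Muscles

Fifteen point-to-point line actuators (with via points where needed;
every element of a series chain carries the same tension, and muscle
force enters the dynamics as −F·dL/dq).  Hill-type force:
`F = F_max (a·fL·fV + fP + damping)`, clamped at zero (muscles only
pull), with a Gaussian force–length (width 0.45), a Hill hyperbola on
the shortening side (a_rel 0.25, v_max 10 L0/s) saturating at 1.5 F_max
eccentrically, an exponential passive curve and parallel damping.
Optimal length defaults to the build-pose path length, so every muscle
starts on the plateau of its force–length curve.

**The PCSAs are effective, not anatomical.**  The passive model and the
closed-loop responses were calibrated against the frozen synthetic
volunteer corridors (see below) by moving *model* parameters only:
glenohumeral centering stiffness/damping, the Hill passive-curve scale
(0.05 → 0.01), and the APF-muscle PCSAs.  The large adductors in
particular (pectoralis major, latissimus) are strongly derated; with
anatomical PCSAs their feedback response overpowered the abduction-side
loads by a factor of ~2.5.  The calibration history is deliberate and
one-directional: synthetic-fixture defaults, seeds, gains, delays and
acceptance thresholds were fixed first and never adjusted afterwards.

Bi-articular handling: the elbow is locked, so biceps and triceps are
modelled as shoulder-crossing actuators with `shoulder_fraction = 0.5` —
half their PCSA responds to the shoulder controller (their activations
are scaled by that fraction before entering the dynamics).  In the STP
pipeline their EMG-derived weights are divided by the shoulder/elbow
MVIC ratios 1.56 (biceps) and 1.82 (triceps).

## Controller

- **APF**: one PD loop on the angular deviation `theta` of a
  humerus-fixed reference vector, measured in a local frame with X along
  the initial humerus axis and Y lateral.  The frame can be fixed to
  ground (`frame_mode: ground`, submodel use) or to the torso (`torso`,
  so rigid whole-body motion produces no error).  Pure 30 ms transport
  delay (integer ring buffer; the delay must be an integer multiple of
  the step).  The D term differentiates the *delayed* error by backward
  difference.  Reference gains P = 1.6 1/rad, D = 150 1/(rad·ms⁻¹); the
  command is clamped to [0, 1] *before* STP distribution, baselines are
  added after, and the per-muscle excitation is clamped again.
- **STP**: per-direction muscle weights built from MVIC-normalized EMG
  peaks in a post-onset window, averaged across subjects, then rescaled
  per direction so the most active included muscle has weight 1.  The
  window length is a named preset: `methods` = 1000 ms and
  `limitations` = 500 ms — the source protocol states both values in
  different places, so the ambiguity is surfaced as a parameter instead
  of silently picking one (default 1000 ms).
- **MLF**: per-muscle one-sided PD on chain elongation in mm
  (P = 0.5 1/mm, D = 5 1/(mm·ms⁻¹)), 10 ms delay, scalar baseline 0.01.
- **Activation dynamics**: first-order, exact exponential update,
  τ = 15 ms when excitation exceeds activation, 40 ms otherwise.
- **Gain calibration**: `P = 1/max|theta_delayed|`,
  `D = 1/max|dtheta_delayed/dt|` over a passive error trace, so each
  term's maximum contribution is exactly 1.  On the bundled model the
  passive flexion drop gives max|theta_delayed| = 0.623 rad and hence
  P = 1.605, which is where the reference value 1.6 comes from.

## Weight-drop experiment

An 8 kg point mass hangs from a massless inextensible cable routed over
frictionless pulleys to the elbow; the first routing point sits 1.5 m
from the elbow along the loading direction (eight directions, 45° apart,
in the plane perpendicular to the initial humerus axis; φ measured from
+Y lateral toward +Z superior, abduction = 0°).  The mass starts with a
0.77 m/s downward velocity — release slack — and engages the cable
through an inelastic impulse
`λ = m·c⁻ / (1 + m·∇ℓᵀM⁻¹∇ℓ)` that zeroes the relative constraint
velocity `c = ẏ + ∇ℓᵀq̇`.  While taut, the mass is reduced onto the arm
coordinates: `(M + m∇ℓ∇ℓᵀ) q̈ = Q − m(g+γ)∇ℓ` with the cable tension
`T = m(g + ∇ℓᵀq̈ + γ)`; when T would go negative the cable goes slack
and the mass free-falls with an exact constant-acceleration update.
Trials last 1 s and are fully deterministic.

The sensitivity grid runs seven gain sets (baseline; P, D, and both
scaled ±50%) plus the passive model in all eight directions: 64 trials.
A zero-gain, zero-baseline controller reproduces the passive trajectory
bit-for-bit (transparency invariant, enforced by a test).

## Evaluation

Elbow trajectories are projected onto the plane perpendicular to the
initial humerus axis (displacement in mm relative to the first sample).
Ensemble statistics within an 800 ms window: per-timestep polar average
(mean magnitude + circular mean direction), 1-SD covariance ellipses
(eigendecomposition of the 2×2 sample covariance, ddof = 1), and peak /
time-to-peak by two methods — `peak_of_average` (peak of the ensemble
mean trace) and `average_of_peaks` (mean ± SD of per-trace peaks; the
former never exceeds the latter).  Ties resolve to the earliest maximum;
"within 1 SD" is a closed interval.

## Synthetic data — scope

No human data ship with this package.  The generators in `synth.py`
emulate the *structure* of a volunteer experiment, not its values:

- **EMG**: 17 subjects × 13 muscles × 8 directions, sampled at 500 Hz
  with 0.6 s pre-onset baseline; a Gaussian burst (peak 300 ms after
  onset) whose amplitude follows rectified-cosine² tuning around each
  muscle's preferred loading direction (opposite its mechanical action),
  plus additive Gaussian noise and a per-subject/muscle MVIC scale that
  cancels under normalization.  With the noise switched off, the STP
  builder recovers the generating table exactly — that identity is the
  test oracle.
- **Kinematics**: per-direction volunteer ensembles as under-damped
  second-order return profiles (ζ = 0.35), peak and time-to-peak drawn
  per subject from per-direction normal distributions (e.g. flexion
  180 ± 50 mm, TTP 0.25 ± 0.06 s), direction jittered by 0.15 rad.

All draws come from a single seeded `default_rng`; identical parameters
and seed give bitwise-identical output.  The bundled STP table
(`data/default_stp.tsv`) was built from the seed-0 EMG fixture and is
marked as synthetic in its provenance line.

## Numerical choices

- Fixed 1 ms step everywhere (control and dynamics share the grid), so
  the 30/10 ms delays are exact 30/10-sample shifts.
- Semi-implicit Euler for the arm: robust for the stiff penalty stops at
  this step size; RK4 available but not the default.
- Exact exponential activation update and exact constant-acceleration
  free-fall: both are closed-form, so tests can assert machine-precision
  agreement.
- Angular deviation uses `atan2(‖a×b‖, a·b)` (stable near 0 and π);
  the deviation direction is undefined at exactly π and reported as NaN.
- Cable-constraint curvature `γ` uses the same central-difference-in-time
  device as the bias accelerations.

## Limitations

- The skeleton is a 5-DOF surrogate; no clavicle, no humeral-head
  translation, no wrapping surfaces (straight-line paths with fixed via
  points), no elbow DOF.
- Muscle strengths are calibrated, not measured; do not reuse them as
  anatomical values.
- The gravity-compensation feedforward is constant; it is exact only at
  the build pose, and the residual appears as a mild flexion/extension
  asymmetry in the passive response.
- The synthetic volunteer corridors are plausibility envelopes; passing
  "within 1 SD" against them demonstrates the pipeline, not biofidelity.
- Single-threaded, fixed-step, no contact beyond penalty stops.
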