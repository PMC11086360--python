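# Methods

This note documents the model, the estimator, the numerical choices, and
what the synthetic-data generator does and does not emulate.

## Articulated human model

The body is 12 rigid links — pelvis, trunk (head and neck folded in), upper
arms, forearms (hands folded in), thighs, shanks, feet — with 21 rotational
joint DOFs: 3-DOF hips, lumbar and shoulders (intrinsic X–Y–Z Euler
sequences: flexion–extension, adduction–abduction, axial rotation), 1-DOF
knees, elbows and ankles.  A 6-DOF virtual joint (3 translations + X–Y–Z
Euler rotations) connects the pelvis to the ground frame, for 27 generalized
coordinates `q`.  The global frame has X to the subject's left, Y posterior,
Z up; gravity is (0, 0, −9.81) m/s².

Segment masses, lengths, COM positions and principal moments of inertia are
scaled from body height and weight through a pluggable anthropometry table
(`src/grfest/data/anthropometry.yaml`).  The default fractions are adapted
from published adjusted adult-male segment-inertia data, renormalized so the
segment masses sum exactly to the input body weight, with inertia
`m·(k·L)²` per axis from radius-of-gyration fractions `k`.  The table is a
stand-in for subject-specific regression equations and is fully
overridable; nothing downstream depends on its exact numbers.

## Forward dynamics

The equations of motion `M(q) q̈ + Γ(q, q̇, F_v, F_h, τ_virtual) = τ` are
evaluated with recursive Newton–Euler (bias terms, O(n)) and the
composite-rigid-body algorithm (mass matrix), treating every DOF as a
1-DOF prismatic/revolute node in a 27-node tree.  Contact forces enter as
external wrenches on the feet; the virtual balance torque acts on the three
root Euler DOFs.  Two implementations exist: a clear reference
(`grfest._core`) and a fused allocation-free kernel (`grfest._fast`,
~15× faster); their agreement on random states is asserted in the tests.

Joint torque is PD control toward the reference angles,
`τ_a = K_PD (q_r − q) + D_PD (q̇_r − q̇)` with K_PD = 1000 N·m/rad and
D_PD = 10 N·m/(rad/s), plus a passive limit-range torque
`τ_p = a·(e^{b(q_min−q)} − e^{b(q−q_max)}) − c·q̇` (defaults a = 2 N·m,
b = 20 rad⁻¹, c = 0.1 N·m·s/rad): a double-exponential that is negligible
in mid-range and restoring beyond the anatomical limits.  Maximum
positive/negative torques per DOF (used for the effort cost) ship as a
literature-plausible adult table with τ₋ stored negative.

### Contact model

22 contact points per foot are laid out from named landmarks (heel, MTP and
toe-tip distances; heel/MTP/toe widths; ankle and phalanx heights) as 11
rows × 2 points with a piecewise-linear width profile.  Per point,

* vertical: `F_v = max(0, −K_G (r_z − r_z0) − D_G ṙ_z s(d))` while
  `r_z < r_z0`, else 0 — clamped both ways so the ground neither sucks nor
  pulls; K_G = 1.0e3 N/m, D_G = 1.0e4 N/(m/s), r_z0 = 0.  The damping ramp
  `s(d) = min(1, d / 1 mm)` over the first millimetre of penetration
  (Hunt–Crossley-style) keeps the force continuous at touchdown: an
  instantaneous damping jump is both unphysical and ruinous for the stiff
  solver's step size;
* horizontal: regularized Coulomb friction opposing the sliding velocity,
  `|F_h| = μ(v_h)·F_v·min(1, v_h/v₀)` with
  `μ(v_h) = μ_d + (μ_s − μ_d)e^{−v_h/v₀}`, μ_s = 0.7, μ_d = 0.5,
  v₀ = 0.01 m/s.  The ramp below v₀ removes the discontinuity at rest and
  guarantees `|F_h| ≤ μ_s F_v` everywhere.

### Balance

A virtual torque `τ_virtual = −K_virtual q_virtual − D_virtual q̇_virtual`
acts on the root Euler angles with K = (400, 400, 0) N·m/rad and
D = (40, 40, 0) N·m·s/rad: sagittal and frontal rotations are restrained,
yaw is free (the movements of interest twist about the vertical axis).

### Integration

The contact damping places fast real eigenvalues (~1e5–1e6 s⁻¹) in the foot
dynamics during stance, so the default integrator is LSODA (variable-step,
stiff-capable; rtol 1e-6, atol 1e-8) with dense output on a uniform grid
(1000 Hz by default).  An explicit RK45 mode exists but takes ~100× more
steps in stance.  A third mode, used for the thousands of candidate
evaluations inside the optimizer, is a fixed-step velocity-implicit scheme
(semi-implicit Euler at dt = 1e-4 s): the contact damping — the stiff part —
enters through per-point damping coefficients and point Jacobians in the
iteration matrix, `(M + dt C) Δq̇ = dt (τ − Γ)`, and everything else is
explicit.  On the jump scenarios it reproduces the LSODA ground-reaction
curves with correlation above 0.998 at ~1/15 the cost; truth generation and
the final re-simulation of the optimized trajectory always use LSODA.

Simulation output includes the generalized trajectories, per-point and
total GRF, the GRM of either foot about its ankle's ground projection in a
foot-aligned horizontal frame, active torques, segment orientations, and
the pelvis sensor's specific force.

Integration aborts with a diagnostic if the state becomes non-finite or any
joint angle passes its limit by more than 1 rad (the passive torque is the
only joint stop).

## Paired-IMU orientation EKF

Two IMUs spanning a joint both measure the gravitational-plus-translational
acceleration of the joint point once each sensor's own centripetal and
tangential terms `ω×(ω×l) + ω̇×l` are subtracted (the lever `l` runs from
the shared joint to the sensor).  Equality of those compensated
accelerations, each mapped into the other sensor's frame through the
relative rotation, is the EKF observation; the state is the stacked pair of
scalar-first quaternions, propagated by first-order integration of the gyro
rates `x ← (I + dt/2·blkdiag(Ω_s, Ω_{s+1}))x` and renormalized after every
step.  Process noise w = 1e-3 (per state component), observation noise
v = 1e-1 m/s², and P₀ = diag(1e2) follow the printed filter constants.

Numerical choices that matter:

* ω̇ comes from central differences of the low-passed gyro signal, and the
  accelerometers pass through the *same* 4th-order 18 Hz zero-phase
  Butterworth before the update: differentiating raw gyro noise is hopeless,
  and filtering only one side of the observation identity de-synchronizes it
  during impacts.
* The observation Jacobian is the analytic derivative of `R(q)·a`
  (verified against finite differences in the tests), projected onto the
  unit-quaternion tangent space so accelerometer-magnitude mismatches
  cannot masquerade as rotations through the norm direction.
* The covariance is symmetrized and its eigenvalues capped at 1 after every
  step: unit-quaternion components are bounded by 1, so larger variances
  carry no information, and leaving P₀'s deliberately vague 1e2 in the
  weakly observed directions (relative rotation about the measured
  acceleration, absolute heading) amplifies noise through tiny linearized
  sensitivities.

Only relative orientation across each joint is observable; the pelvis root
is integrated by gyro strapdown from the calibration attitude and global
heading drifts accordingly (no magnetometer, by design).  Whole-body
estimates compose pairwise relative rotations outward from the pelvis;
segments without a sensor are skipped, and the graph must stay connected.
Calibration (roll/pitch from time-averaged gravity, yaw defined zero,
neutral joint angles from the relative attitudes) uses a quasi-static
window; the pipeline defaults to the trial's first 0.15 s since the
generator's trials open at rest.

## Trajectory optimization

Reference joint angles are cubic splines through a small node set per DOF:
2 nodes (start/end) for upper-body joints, 5 evenly spaced for jump-leg
joints, 3 for other joints.  Splines are clamped to zero velocity at the
start (motion begins at rest) with a natural end.  The cost is

    I_all = ξ₁ I_Q + ξ₂ I_a,pelvis + ξ₃ I_muscle,   ξ = (1e3, 1e3, 10)

with `I_Q` the integrated squared X–Y–Z Euler error over the tracked
segments (angle differences wrapped to ±π), `I_a,pelvis` the integrated
squared pelvis specific-force error in the sensor frame, and `I_muscle` the
integrated cubed torques normalized by the per-DOF maxima (the negative
maximum stored negative, so both ratios are positive and extension effort is
penalized).  Costs are evaluated on a 100 Hz grid by trapezoidal quadrature.

The search is a memetic real-coded GA, deterministic per seed:
tournament-5 selection, simulated binary crossover (η = 15), per-gene
Gaussian mutation scaled to the current population spread with a
1/5-success global step adaptation, 2-elite survival, joint-limit bounds,
and a short (1+1)-ES polish of the incumbent each generation (8 trials,
own success-adapted step; the polished incumbent replaces the worst
individual).  The polish is what gives the endgame precision a plain
fixed-step GA lacks: on a 12-D convex check problem the hybrid recovers the
optimum to ~1e-4 in 50 generations where the plain variant stalls near 0.1.
The population is seeded around an inverse-kinematics first guess — joint
angles read off the EKF segment orientations at the node times — which is
what makes a population-30 / 30-generation budget productive on a single
CPU.  Candidates whose simulation diverges receive a penalty cost.
Full-fidelity defaults are population 60 / 100 generations.

## Synthetic data

The generator runs the same forward model on hand-designed node sets
(squat-jump, single-leg hop, calibration pose; a `twist` flag adds yaw) and
synthesizes every sensor's ideal signals analytically from the simulated
kinematics — specific force `R_s→g⁻¹(a_point − g)` including translational,
centripetal and tangential components, and body rates in the sensor frame —
then adds white accelerometer/gyro noise (0.05 m/s², 0.005 rad/s) and a slow
gyro bias random walk (1e-4 rad/s·√s), all seeded.  Scenario node values
were chosen so the motions are dynamically stable, show the unloading-dip /
propulsion-peak / flight GRF signature, clear the swing foot, and land with
a flexed, absorbing knee (soft landings are also what keeps the synthetic
signals inside the realm the filter constants were printed for).  Trials
open with a 0.3 s quiet-standing lead-in in the starting posture — the
calibration phase of a real measurement session — from a settled
equilibrium, so there is no spurious transient at t = 0 and the pipeline
can read its initial sensor attitudes off genuinely static data.

What the generator does **not** emulate: soft-tissue artifact (sensors ride
rigidly on the bones), mounting misplacement, magnetometer disturbance
(no magnetometer anywhere), foot deformation/footwear, and the anthropometry
of any specific subject.  Passing the inverse-crime tests therefore shows
the estimator is self-consistent at realistic noise levels — not that it
reaches any particular accuracy on real recordings.

## Evaluation machinery

All measurement processing uses the 4th-order Butterworth (−3 dB at 18 Hz),
zero-phase by default (single-pass available for gain checks).  Contact
events are threshold crossings of the vertical GRF (default 20 N, linear
interpolation; episodes may begin/end at the series boundaries).  Curves
are resampled to 101 points between heel strike and toe-off, normalized by
body weight (forces, %BW) or weight × height (moments, %BW·BH), and
compared by Pearson ρ (bands: weak ≤ 0.35 < moderate ≤ 0.67 < strong ≤ 0.9
< excellent, applied to the signed value), RMSE, and rRMSE (RMSE over the
mean of the two ranges, in percent).

## Problem sizes

The shipped tests and the acceptance script use desk-scale sizes chosen as
package defaults: 1.5 s motions (1.8 s recordings) at 1000 Hz, 2 s standing
checks, 10 s hinge benchmarks, and a population-30 / 30-generation GA
(~1100 forward simulations).  The pipeline's full-fidelity GA defaults are
larger and run proportionally longer.

## Known limitations

* Absolute heading is open-loop gyro integration; long trials drift in yaw.
* The GA explores locally around the IK seed; grossly wrong calibration
  would need the larger uniform-initialization budget.
* The contact model is a point-viscoelastic approximation: very stiff
  landings produce higher-frequency force content than force plates show.
* Reduced-sensor mode drops the orientation-error terms of uninstrumented
  segments rather than inferring them.
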