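# grfest

Ground-reaction-force estimation from wearable IMUs with a 3D
forward-dynamics human model.

Measuring the ground reaction force (GRF) and moment (GRM) of sports
movements normally requires force plates — expensive, location-bound, and
impossible on ice rinks, spring floors, or outdoors.  `grfest` estimates
GRF, GRM, joint angles and joint torques from body-worn inertial sensors
alone: twelve IMUs (3-axis accelerometer + gyroscope, 1000 Hz) strapped to
the pelvis, trunk, arms, forearms, thighs, shanks and feet, plus the
subject's height and weight.

## Method

A 12-link rigid-body model (21 joint DOFs + a 6-DOF pelvis root, 27
generalized coordinates) is driven by PD torques toward reference joint
angles q_r(t), with passive limit-range torques, a viscoelastic 22-point
foot–ground contact model with regularized Coulomb friction, and a virtual
balance torque on the root:

    M(q) q̈ + Γ(q, q̇, F_v, F_h, τ_virtual) = τ,
    τ_a = K_PD (q_r − q) + D_PD (q̇_r − q̇)

Reference angles are cubic splines through a small set of nodes per DOF
(2 for upper-body joints, 5 for jump-leg joints, 3 otherwise).  A genetic
algorithm adjusts the node values to minimize

    I_all = ξ₁ I_Q + ξ₂ I_a,pelvis + ξ₃ I_muscle

— orientation error against the measured segment attitudes, pelvis
acceleration error, and cubed normalized joint effort.  Segment attitudes
come from a paired-IMU extended Kalman filter: after subtracting each
sensor's centripetal/tangential terms about the shared joint, both sensors
of a joint measure the same gravitational-plus-translational acceleration,
and that equality (mapped through the relative rotation) is the filter's
observation — accurate under large dynamic accelerations, no magnetometer
needed.  The GRF/GRM of the optimized motion are read off the contact
model.  See `docs/methods.md` for the full model and numerical choices.

Because real recordings of this kind are not publicly deposited, the
package ships a synthetic-trial generator (`grfest.synth`): ground-truth
motions with full GRF traces and the corresponding noisy multi-sensor IMU
signals, used throughout the tests as an inverse-crime benchmark.

## Worked example

```python
import numpy as np
from grfest import build_model
from grfest.synth import synthesize
from grfest.pipeline import estimate
from grfest.optimize import GAConfig
from grfest.metrics import compare, detect_events, normalize_grf, phase_normalize

model = build_model(height=1.69, weight=63.3)
fixture = synthesize("single-leg-hop", seed=7)          # truth + noisy IMUs
result = estimate(fixture.trial, model,
                  ga=GAConfig(population=16, generations=10, seed=0))

truth = fixture.truth
grf_true = truth.point_forces[:, :22, 2].sum(axis=1)    # left-foot vertical GRF
grf_est = result.sim.point_forces[:, :22, 2].sum(axis=1)
events = detect_events(grf_true, truth.t)               # heel strike / toe-off
ref = phase_normalize(normalize_grf(grf_true, 63.3), truth.t, events)
est = phase_normalize(normalize_grf(grf_est, 63.3), result.sim.t, events)
m = compare(est, ref)
c = result.opt.cost
print(f"cost: I_all={c.I_all:.0f} (I_Q={c.I_Q:.2f}, "
      f"I_a_pelvis={c.I_a_pelvis:.2f}, I_muscle={c.I_muscle:.2f})")
print(f"vertical GRF vs truth: rho={m.rho:.3f} ({m.rho_class}), "
      f"RMSE={m.rmse:.1f} %BW, rRMSE={m.rrmse:.1f} %")
```

Output (about 2 minutes on one CPU):

```
cost: I_all=74422 (I_Q=16.04, I_a_pelvis=58.26, I_muscle=12.28)
vertical GRF vs truth: rho=0.865 (strong), RMSE=28.7 %BW, rRMSE=11.5 %
```

The cost terms are the weighted orientation, pelvis-acceleration and muscle
effort integrals of the best candidate; the metrics compare the estimated
and true vertical GRF on the 101-point contact phase, in percent body
weight.  The deliberately small search budget above already tracks the true
force curve strongly; the standard budget (population 30, 30 generations,
used by the test suite and acceptance script) reaches ρ ≈ 0.93–0.96 and
rRMSE ≈ 7–9 %.

The same pipeline is available from the shell:

```
grfest synth --scenario single-leg-hop --seed 7 --out fixtures/hop
grfest estimate --trial fixtures/hop/trial.csv --out results/hop
grfest evaluate --est results/hop/estimate.csv --ref fixtures/hop/truth.csv
```

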