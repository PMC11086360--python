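# Joint table: rotational DOFs per joint, anatomical limits, maximum
# positive/negative torques, and passive-torque coefficients.
#
# Axis convention (global frame at the neutral pose): X points to the
# subject's left (medio-lateral), Y points posterior, Z points up; gravity is
# (0,0,-9.81) m/s^2.  Rotation about X is flexion-extension, about Y
# adduction-abduction, about Z axial rotation; 3-DOF joints use the intrinsic
# X-Y-Z Euler sequence.
#
# q_min/q_max in rad; tau_plus_max > 0 and tau_minus_max < 0 in N*m
# (tau_minus_max is stored negative).  Torque limits are literature-plausible
# healthy-adult maxima and are fully overridable; passive-torque coefficients
# (a [N*m], b [1/rad], c [N*m*s/rad]) parameterize the double-exponential
# limit-range law tau_p = a*(exp(b*(q_min-q)) - exp(b*(q-q_max))) - c*qdot.

joints:
  lumbar:
    parent: pelvis
    child: trunk
    dofs:
      - {axis: x, q_min: -1.00, q_max: 0.80, tau_plus_max: 150.0, tau_minus_max: -200.0}
      - {axis: y, q_min: -0.60, q_max: 0.60, tau_plus_max: 150.0, tau_minus_max: -150.0}
      - {axis: z, q_min: -0.80, q_max: 0.80, tau_plus_max: 90.0,  tau_minus_max: -90.0}
  shoulder:
    parent: trunk
    child: upper_arm
    dofs:
      - {axis: x, q_min: -3.10, q_max: 1.00, tau_plus_max: 70.0, tau_minus_max: -70.0}
      - {axis: y, q_min: -1.60, q_max: 1.60, tau_plus_max: 60.0, tau_minus_max: -60.0}
      - {axis: z, q_min: -1.60, q_max: 1.60, tau_plus_max: 40.0, tau_minus_max: -40.0}
  elbow:
    parent: upper_arm
    child: forearm
    dofs:
      - {axis: x, q_min: -2.60, q_max: 0.05, tau_plus_max: 50.0, tau_minus_max: -60.0}
  hip:
    parent: pelvis
    child: thigh
    dofs:
      - {axis: x, q_min: -2.20, q_max: 0.60, tau_plus_max: 120.0, tau_minus_max: -180.0}
      - {axis: y, q_min: -0.90, q_max: 0.90, tau_plus_max: 100.0, tau_minus_max: -100.0}
      - {axis: z, q_min: -0.80, q_max: 0.80, tau_plus_max: 60.0,  tau_minus_max: -60.0}
  knee:
    parent: thigh
    child: shank
    dofs:
      - {axis: x, q_min: -0.10, q_max: 2.40, tau_plus_max: 150.0, tau_minus_max: -240.0}
  ankle:
    parent: shank
    child: foot
    dofs:
      - {axis: x, q_min: -0.60, q_max: 0.90, tau_plus_max: 170.0, tau_minus_max: -50.0}

passive_defaults: {a: 2.0, b: 20.0, c: 0.1}
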