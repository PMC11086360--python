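"""Synthetic trials: ground-truth motion, GRF/GRM, and noisy IMU signals.

The generator runs the same forward-dynamics model used for estimation,
converts the resulting segment kinematics into ideal IMU readings (gravity +
translational + centripetal + tangential components in each sensor frame,
gyro angular rates), and adds white noise plus a slow gyro bias random walk.
Scenarios are simplified planar-dominant jumps with unambiguous ground
truth; a yaw component can be added for 3D coverage.  Default noise levels
(accel 0.05 m/s^2, gyro 0.005 rad/s, bias walk 1e-4 rad/s/sqrt(s)) are
plausible for commercial strap-on sports IMUs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import _core
from .body import BodyModel, SEGMENTS, ModelState, build_model, neutral_pose
from .dynamics import SimResult, SolverOptions, SimulationError, simulate, _arrays
from .ekf import IMUTrial
from .quat import quat_to_matrix
from .reference import ReferenceTrajectory, allocate_nodes

SCENARIOS = ("calibration-pose", "squat-jump", "single-leg-hop")


@dataclass
class NoiseModel:
    accel_std: float = 0.05         # m/s^2
    gyro_std: float = 0.005         # rad/s
    bias_walk_std: float = 1e-4     # rad/s/sqrt(s)
    seed: int = 0

    def __post_init__(self):
        if min(self.accel_std, self.gyro_std, self.bias_walk_std) < 0:
            raise ValueError("noise stds must be non-negative")


@dataclass
class SyntheticTrial:
    trial: IMUTrial
    truth: SimResult
    reference: ReferenceTrajectory
    noise: NoiseModel
    height: float
    weight: float
    scenario: str
    lead_in: float = 0.0            # quiet-standing preamble, s


def _set(traj: ReferenceTrajectory, name: str, values) -> None:
    k = traj.dof_names.index(name)
    vals = np.asarray(values, dtype=float)
    if vals.size != traj.node_values[k].size:
        raise ValueError(f"{name}: expected {traj.node_values[k].size} nodes")
    traj.node_values[k] = vals


def synth_motion(model: BodyModel, scenario: str, duration: float = 1.5,
                 seed: int = 0, twist: bool = False,
                 start: float = 0.0) -> ReferenceTrajectory:
    """Scenario node sets producing a dynamically stable simulation.

    The seeded variation scales the flexion amplitudes by a few percent so
    different seeds give distinct but qualitatively identical movements.
    ``start`` shifts the motion window (the reference holds its first node
    value before it, giving a static lead-in).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    traj = allocate_nodes(model, (start, start + duration))
    if scenario == "calibration-pose":
        return traj
    amp = 1.0 + 0.04 * rng.standard_normal()
    amp = float(np.clip(amp, 0.92, 1.08))
    if scenario == "squat-jump":
        # symmetric crouch -> extension -> flight -> absorbed landing
        for side in ("l", "r"):
            _set(traj, f"hip_{side}_x", amp * np.array([0.0, -0.75, -0.05, -0.45, -0.20]))
            _set(traj, f"knee_{side}_x", amp * np.array([0.10, 1.40, 0.0, 0.80, 0.35]))
            _set(traj, f"ankle_{side}_x", amp * np.array([0.0, -0.30, 0.40, -0.20, 0.0]))
    else:  # single-leg-hop: stance left leg, right foot held clear
        _set(traj, "hip_l_x", amp * np.array([0.0, -0.62, -0.05, -0.45, -0.20]))
        _set(traj, "knee_l_x", amp * np.array([0.10, 1.20, 0.0, 0.80, 0.35]))
        _set(traj, "ankle_l_x", amp * np.array([0.0, -0.28, 0.50, -0.20, 0.0]))
        _set(traj, "hip_l_y", np.full(5, 0.12))
        _set(traj, "hip_r_x", np.full(5, -1.10))
        _set(traj, "knee_r_x", np.full(5, 2.10))
        _set(traj, "ankle_r_x", np.full(5, -0.40))
    if twist:
        for side in ("l", "r"):
            _set(traj, f"hip_{side}_z",
                 amp * np.array([0.0, 0.0, 0.15, 0.25, 0.25]))
    return traj


def initial_state_from_reference(model: BodyModel,
                                 reference: ReferenceTrajectory) -> ModelState:
    """Rest state matching the reference at its start, with the root lowered
    so the lowest contact point just touches the ground."""
    from .reference import spline_reference
    from .dynamics import contact_forces
    q0, _ = spline_reference(reference, reference.t_span[0])
    st = neutral_pose(model)
    st.q[:21] = q0
    cf = contact_forces(model, st)
    st.q[23] -= cf.point_positions[:, 2].min()
    return st


def imu_from_sim(sim: SimResult, model: BodyModel,
                 mountings=None) -> IMUTrial:
    """Noise-free IMU signals for every mounted sensor along a simulated
    trajectory: specific force ``R_sensor->global^-1 (a_point - g)`` and
    body rates in the sensor frame."""
    mountings = mountings or model.mountings
    arr = _arrays(model)
    P = arr.int2pub
    seg_to_body = {s: arr.seg_body[i] for i, s in enumerate(SEGMENTS)}
    sens_body = np.array([seg_to_body[m.segment] for m in mountings])
    sens_pos = np.stack([m.lever_arm for m in mountings])
    sens_rot = np.stack([quat_to_matrix(m.mount_rotation) for m in mountings])
    acc, gyr = _core.sensor_series(sim.q[:, P], sim.q_dot[:, P],
                                   sim.q_ddot[:, P], arr.parent, arr.jtype,
                                   arr.axis, arr.p_off, sens_body, sens_pos,
                                   sens_rot, _core.G)
    return IMUTrial(t=sim.t.copy(), sensors=[m.segment for m in mountings],
                    accel=acc, gyro=gyr, rate=sim.rate)


def add_noise(trial: IMUTrial, noise: NoiseModel) -> IMUTrial:
    """Additive white sensor noise plus integrated gyro bias random walk,
    reproducible per seed."""
    rng = np.random.default_rng(noise.seed)
    T, S, _ = trial.accel.shape
    dt = 1.0 / trial.rate
    accel = trial.accel + noise.accel_std * rng.standard_normal((T, S, 3))
    gyro = trial.gyro + noise.gyro_std * rng.standard_normal((T, S, 3))
    bias = np.cumsum(noise.bias_walk_std * np.sqrt(dt)
                     * rng.standard_normal((T, S, 3)), axis=0)
    return IMUTrial(t=trial.t.copy(), sensors=list(trial.sensors),
                    accel=accel, gyro=gyro + bias, rate=trial.rate)


def settle_state(model: BodyModel, reference: ReferenceTrajectory,
                 settle_time: float = 0.5) -> ModelState:
    """Equilibrium state under the reference's starting pose: the geometric
    touch-down guess is simulated under a constant reference until the
    contact transient has damped out."""
    from .reference import constant_reference, spline_reference
    q0, _ = spline_reference(reference, reference.t_span[0])
    hold = constant_reference(model, q0, (0.0, settle_time))
    st = initial_state_from_reference(model, reference)
    sim = simulate(model, hold, initial_state=st,
                   solver_opts=SolverOptions(output_rate=200.0))
    return ModelState(q=sim.q[-1].copy(), q_dot=sim.q_dot[-1].copy(),
                      t=reference.t_span[0])


def synthesize(scenario: str = "single-leg-hop", height: float = 1.69,
               weight: float = 63.3, duration: float = 1.5, seed: int = 0,
               noise: NoiseModel | None = None, twist: bool = False,
               model: BodyModel | None = None,
               output_rate: float = 1000.0,
               lead_in: float = 0.3) -> SyntheticTrial:
    """Build a full synthetic trial in memory (model, truth, noisy IMU).

    The recording opens with ``lead_in`` seconds of quiet standing in the
    starting posture (the calibration-posture phase of a real session)
    before the ``duration``-second motion."""
    model = model or build_model(height, weight)
    reference = synth_motion(model, scenario, duration, seed, twist,
                             start=lead_in)
    state0 = settle_state(model, reference)
    try:
        truth = simulate(model, reference, t_span=(0.0, lead_in + duration),
                         initial_state=state0,
                         solver_opts=SolverOptions(output_rate=output_rate))
    except SimulationError as exc:
        raise SimulationError(
            f"scenario {scenario!r} failed to simulate: {exc}") from exc
    clean = imu_from_sim(truth, model)
    noise = noise if noise is not None else NoiseModel(seed=seed + 1)
    noisy = add_noise(clean, noise) if noise.accel_std or noise.gyro_std \
        or noise.bias_walk_std else clean
    return SyntheticTrial(trial=noisy, truth=truth, reference=reference,
                          noise=noise, height=height, weight=weight,
                          scenario=scenario, lead_in=lead_in)


def make_fixture(scenario: str, height: float, weight: float,
                 noise: NoiseModel | None, seed: int, outdir) -> SyntheticTrial:
    """Generate a trial and write trial.csv, truth.csv and meta.yaml."""
    from . import io as gio
    st = synthesize(scenario, height, weight, seed=seed, noise=noise)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gio.write_trial_csv(outdir / "trial.csv", st.trial)
    gio.write_sim_csv(outdir / "truth.csv", st.truth)
    meta = {
        "scenario": st.scenario,
        "height": float(st.height),
        "weight": float(st.weight),
        "seed": int(seed),
        "lead_in": float(st.lead_in),
        "noise": {"accel_std": float(st.noise.accel_std),
                  "gyro_std": float(st.noise.gyro_std),
                  "bias_walk_std": float(st.noise.bias_walk_std),
                  "seed": int(st.noise.seed)},
        "rate": float(st.trial.rate),
        "reference_nodes": {nm: [float(x) for x in v] for nm, v in
                            zip(st.reference.dof_names, st.reference.node_values)},
        "t_span": [float(x) for x in st.reference.t_span],
    }
    with open(outdir / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
    return st
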