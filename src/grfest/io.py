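"""CSV/YAML input and output.

Trial CSV: one row per sample, columns ``time_s`` then
``<segment>_{ax,ay,az,gx,gy,gz}`` per sensor, SI units (m/s^2, rad/s).
Simulation CSV: ``time_s``, the 27 generalized coordinates/velocities by DOF
name, total GRF, per-foot vertical GRF, left/right ankle GRM, and the
pelvis-sensor acceleration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .body import BodyModel
from .dynamics import SimResult, grm_about_ankle
from .ekf import IMUTrial

_AXES6 = ("ax", "ay", "az", "gx", "gy", "gz")


def write_trial_csv(path, trial: IMUTrial) -> None:
    data = {"time_s": trial.t}
    for s, seg in enumerate(trial.sensors):
        for j, ax in enumerate(_AXES6[:3]):
            data[f"{seg}_{ax}"] = trial.accel[:, s, j]
        for j, ax in enumerate(_AXES6[3:]):
            data[f"{seg}_{ax}"] = trial.gyro[:, s, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def read_trial_csv(path) -> IMUTrial:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    sensors = []
    for col in df.columns:
        if col.endswith("_ax"):
            sensors.append(col[:-3])
    accel = np.stack([df[[f"{s}_ax", f"{s}_ay", f"{s}_az"]].to_numpy()
                      for s in sensors], axis=1)
    gyro = np.stack([df[[f"{s}_gx", f"{s}_gy", f"{s}_gz"]].to_numpy()
                     for s in sensors], axis=1)
    rate = 1.0 / np.median(np.diff(t))
    return IMUTrial(t=t, sensors=sensors, accel=accel, gyro=gyro, rate=float(rate))


def write_sim_csv(path, sim: SimResult, model: BodyModel | None = None) -> None:
    model = model or sim.model
    names = model.dof_names()
    data = {"time_s": sim.t}
    for i, nm in enumerate(names):
        data[f"q_{nm}"] = sim.q[:, i]
    for i, nm in enumerate(names):
        data[f"qd_{nm}"] = sim.q_dot[:, i]
    for j, ax in enumerate("xyz"):
        data[f"grf_{ax}"] = sim.grf[:, j]
    data["grf_l_z"] = sim.point_forces[:, :22, 2].sum(axis=1)
    data["grf_r_z"] = sim.point_forces[:, 22:, 2].sum(axis=1)
    for side in ("l", "r"):
        grm = grm_about_ankle(sim, model, side)
        for j, comp in enumerate(("sag", "fro", "tra")):
            data[f"grm_{side}_{comp}"] = grm[:, j]
    for j, ax in enumerate("xyz"):
        data[f"pelvis_acc_{ax}"] = sim.pelvis_acc[:, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def read_sim_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_orientation_csv(path, est) -> None:
    data = {"time_s": est.t}
    eul = est.euler()
    for s, seg in enumerate(est.segments):
        for j, c in enumerate("wxyz"):
            data[f"{seg}_q{c}"] = est.quat[s, :, j]
        for j, c in enumerate(("phi", "theta", "psi")):
            data[f"{seg}_{c}"] = eul[s, :, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def load_run_config(path) -> dict:
    """Run configuration YAML (model, gains, ground, weights, GA, noise,
    seeds); missing sections fall back to the package defaults."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def default_run_config() -> dict:
    """All tunable constants with their standard defaults, suitable for
    writing a template run.yaml."""
    return {
        "model": {"height": 1.69, "weight": 63.3},
        "gains": {"K_PD": 1000.0, "D_PD": 10.0,
                  "K_virtual": [400.0, 400.0, 0.0],
                  "D_virtual": [40.0, 40.0, 0.0]},
        "ground": {"K_G": 1.0e3, "D_G": 1.0e4, "mu_s": 0.7, "mu_d": 0.5,
                   "rz0": 0.0, "friction_reg_speed": 0.01},
        "weights": {"xi1": 1.0e3, "xi2": 1.0e3, "xi3": 10.0},
        "ekf": {"w": 1.0e-3, "v": 1.0e-1, "P0": 1.0e2},
        "ga": {"population": 60, "generations": 100, "seed": 0},
        "noise": {"accel_std": 0.05, "gyro_std": 0.005,
                  "bias_walk_std": 1.0e-4, "seed": 0},
        "filter": {"order": 4, "cutoff_hz": 18.0},
        "events": {"threshold_n": 20.0},
    }
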