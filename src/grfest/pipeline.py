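"""End-to-end GRF estimation: EKF orientation fusion -> inverse-kinematics
first guess -> GA trajectory optimization -> forward simulation of the best
reference trajectory."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

from .body import BodyModel
from .costs import CostWeights
from .dynamics import ControlGains, GroundParams, SimResult, SolverOptions, simulate
from .ekf import EKFParams, IMUTrial, OrientationEstimate, chain_orientations
from .metrics import butterworth_lowpass
from .optimize import GAConfig, Measurements, OptResult, ik_first_guess, optimize
from .reference import allocate_nodes
from .synth import settle_state

log = logging.getLogger("grfest")


@dataclass
class EstimateResult:
    orientation: OrientationEstimate
    opt: OptResult
    sim: SimResult
    measurements: Measurements


def build_measurements(trial: IMUTrial, est: OrientationEstimate,
                       cost_rate: float = 100.0,
                       filter_cutoff: float = 18.0) -> Measurements:
    """Down-sample the EKF orientations and the (low-passed) pelvis
    acceleration onto the cost-evaluation grid."""
    step = max(1, int(round(trial.rate / cost_rate)))
    idx = np.arange(0, trial.t.size, step)
    from .ekf import _euler_series
    seg_euler = np.stack([_euler_series(est.quat[s][idx])
                          for s in range(len(est.segments))])
    pa = trial.accel[:, trial.idx("pelvis"), :]
    if trial.rate > 2 * filter_cutoff:
        pa = butterworth_lowpass(pa, trial.rate, cutoff=filter_cutoff)
    return Measurements(t=trial.t[idx], segments=list(est.segments),
                        seg_euler=seg_euler, pelvis_acc=pa[idx])


def estimate(trial: IMUTrial, model: BodyModel,
             ekf_params: EKFParams | None = None,
             ga: GAConfig | None = None,
             weights: CostWeights | None = None,
             gains: ControlGains | None = None,
             ground: GroundParams | None = None,
             init_quats: dict | None = None,
             calibration: IMUTrial | None = None,
             motion_start: float = 0.3,
             cost_rate: float = 100.0,
             output_rate: float = 1000.0) -> EstimateResult:
    """Run the full pipeline on one trial.

    The trial is expected to open with a quiet-standing calibration phase of
    ``motion_start`` seconds (relative to the first sample); it provides the
    initial sensor attitudes and the model's starting posture, and node
    placement covers the remaining motion window."""
    t0 = time.perf_counter()
    ekf_params = ekf_params or EKFParams(dt=1.0 / trial.rate)
    refine = None
    if init_quats is None and calibration is None:
        from .ekf import init_from_calibration
        if motion_start >= 0.1:
            calibration = trial.window(trial.t[0],
                                       trial.t[0] + motion_start - 0.02)
        else:
            # no usable static phase: crude attitudes from the first samples,
            # then refine by backcasting the converged estimate to t0
            win = trial.window(trial.t[0], trial.t[0] + 0.05)
            init_quats, _ = init_from_calibration(win, model,
                                                  gyro_threshold=1.0)
            refine = 0.4
    est = chain_orientations(trial, model, ekf_params,
                             init_quats=init_quats, calibration=calibration,
                             refine_init_t=refine)
    log.info("EKF orientation fusion: %.1f s", time.perf_counter() - t0)

    meas = build_measurements(trial, est, cost_rate=cost_rate)
    span = (float(trial.t[0]) + motion_start, float(trial.t[-1]))
    skeleton = allocate_nodes(model, span)
    guess = ik_first_guess(model, est, skeleton)
    # settle the starting posture on the ground so the simulated contact
    # state matches a subject standing still through the calibration phase
    meas.initial_state = settle_state(model, skeleton.with_vector(guess))

    t1 = time.perf_counter()

    def _log_gen(gen, best):
        log.info("GA generation %d: best I_all = %.4g (%.1f s)",
                 gen, best, time.perf_counter() - t1)

    opt = optimize(model, meas, skeleton, ga=ga, weights=weights,
                   gains=gains, ground=ground, init_guess=guess,
                   callback=_log_gen)
    log.info("GA optimization: %.1f s (%d evals, %d failures)",
             time.perf_counter() - t1, opt.n_evals, opt.failures)

    full_span = (float(trial.t[0]), float(trial.t[-1]))
    sim = simulate(model, opt.best, gains=gains, ground=ground,
                   t_span=full_span,
                   solver_opts=SolverOptions(output_rate=output_rate),
                   initial_state=meas.initial_state)
    return EstimateResult(orientation=est, opt=opt, sim=sim, measurements=meas)
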