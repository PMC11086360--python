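"""Trajectory-evaluation cost function.

The optimizer scores a candidate motion by
``I_all = xi1 * I_Q + xi2 * I_a_pelvis + xi3 * I_muscle``:

* ``I_Q`` -- time-integrated squared error between simulated and measured
  segment orientations (X-Y-Z Euler angles, all tracked segments);
* ``I_a_pelvis`` -- time-integrated squared error of pelvis-sensor
  acceleration (specific force, sensor frame);
* ``I_muscle`` -- cubed active torques normalized by each DOF's maximum
  positive/negative torque, integrated and summed over the 21 joint DOFs;
  the negative maximum is stored as a negative number so both ratios are
  non-negative and extension effort is penalized, not rewarded.

Defaults xi = (1e3, 1e3, 10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .body import ConfigurationError


@dataclass
class CostWeights:
    xi1: float = 1e3
    xi2: float = 1e3
    xi3: float = 10.0

    def __post_init__(self):
        if min(self.xi1, self.xi2, self.xi3) < 0:
            raise ValueError("cost weights must be non-negative")


@dataclass
class CostBreakdown:
    I_Q: float
    I_a_pelvis: float
    I_muscle: float
    I_all: float


def _wrap(angle):
    """Wrap angle differences to (-pi, pi] so orientation errors are geodesic."""
    return (angle + np.pi) % (2.0 * np.pi) - np.pi


def cost_IQ(model_euler: np.ndarray, measured_euler: np.ndarray,
            t: np.ndarray) -> float:
    """Sum over segments of the integrated squared Euler-angle error
    (rad^2 s), trapezoidal quadrature."""
    model_euler = np.asarray(model_euler)
    measured_euler = np.asarray(measured_euler)
    if model_euler.shape != measured_euler.shape or model_euler.shape[1] != t.size:
        raise ValueError("orientation series shapes/grid disagree")
    d = _wrap(model_euler - measured_euler)
    integrand = (d ** 2).sum(axis=(0, 2))
    return float(np.trapezoid(integrand, t))


def cost_Ia_pelvis(model_acc: np.ndarray, measured_acc: np.ndarray,
                   t: np.ndarray) -> float:
    """Integrated squared pelvis-acceleration error ((m/s^2)^2 s)."""
    model_acc = np.asarray(model_acc)
    measured_acc = np.asarray(measured_acc)
    if model_acc.shape != measured_acc.shape or model_acc.shape[0] != t.size:
        raise ValueError("acceleration series shapes/grid disagree")
    integrand = ((model_acc - measured_acc) ** 2).sum(axis=1)
    return float(np.trapezoid(integrand, t))


def cost_Imuscle(tau_a: np.ndarray, tau_plus: np.ndarray,
                 tau_minus: np.ndarray, t: np.ndarray) -> float:
    """Integrated cubed normalized active torques (s)."""
    tau_a = np.asarray(tau_a)
    tau_plus = np.asarray(tau_plus, dtype=float)
    tau_minus = np.asarray(tau_minus, dtype=float)
    if np.any(tau_plus == 0) or np.any(tau_minus == 0):
        raise ConfigurationError("zero maximum torque in the joint table")
    sig_p = np.where(tau_a >= 0, tau_a / tau_plus, 0.0)
    sig_m = np.where(tau_a < 0, tau_a / tau_minus, 0.0)
    integrand = (sig_p ** 3 + sig_m ** 3).sum(axis=1)
    return float(np.trapezoid(integrand, t))


def total_cost(I_Q: float, I_a_pelvis: float, I_muscle: float,
               weights: CostWeights | None = None) -> CostBreakdown:
    w = weights or CostWeights()
    return CostBreakdown(I_Q=I_Q, I_a_pelvis=I_a_pelvis, I_muscle=I_muscle,
                         I_all=w.xi1 * I_Q + w.xi2 * I_a_pelvis + w.xi3 * I_muscle)
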