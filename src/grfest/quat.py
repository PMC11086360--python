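"""Scalar-first Hamilton quaternion helpers.

Quaternions are (w, x, y, z) with the real part first; ``R = quat_to_matrix(q)``
rotates body-frame vectors into the global frame.  scipy's Rotation uses the
(x, y, z, w) layout, so these wrappers keep the conversion in one place.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def to_scipy(q: np.ndarray) -> Rotation:
    q = np.asarray(q)
    return Rotation.from_quat(np.roll(q, -1, axis=-1))


def from_scipy(rot: Rotation) -> np.ndarray:
    return np.roll(rot.as_quat(), 1, axis=-1)


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    return to_scipy(q).as_matrix()


def quat_from_matrix(R: np.ndarray) -> np.ndarray:
    return from_scipy(Rotation.from_matrix(R))


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def quat_conj(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_normalize(q: np.ndarray) -> np.ndarray:
    return q / np.linalg.norm(q)


def euler_xyz(q: np.ndarray) -> np.ndarray:
    """Intrinsic X-Y-Z Euler angles of the rotation q (radians)."""
    return to_scipy(q).as_euler("XYZ")


def quat_from_euler_xyz(angles) -> np.ndarray:
    return from_scipy(Rotation.from_euler("XYZ", angles))


def rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector v by quaternion q (body -> global)."""
    return quat_to_matrix(q) @ np.asarray(v)
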