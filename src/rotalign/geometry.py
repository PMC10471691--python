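"""Low-level rigid-body geometry shared by the frame, metrics and sweep layers.

All coordinates are millimetres in a right-handed world frame:
+x medial, +y anterior, +z cranial (for a right-convention leg).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def unit(v: np.ndarray) -> np.ndarray:
    """Return v normalized to unit length; raises on (near-)zero input."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize a zero-length vector")
    return v / n


def rotate_about_axis(
    points: np.ndarray,
    axis_point: np.ndarray,
    axis_direction: np.ndarray,
    angle_deg: float,
) -> np.ndarray:
    """Rigidly rotate points about the line (axis_point, axis_direction).

    Positive angles follow the right-hand rule about ``axis_direction``.
    Accepts a single point (shape (3,)) or a stack (N, 3).
    """
    p = np.asarray(points, dtype=float)
    d = unit(axis_direction)
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * d)
    single = p.ndim == 1
    q = np.atleast_2d(p) - axis_point
    out = rot.apply(q) + axis_point
    return out[0] if single else out


def mirror_x(points: np.ndarray) -> np.ndarray:
    """Reflect points across the x = 0 plane (left/right side swap)."""
    p = np.array(points, dtype=float, copy=True)
    p[..., 0] *= -1.0
    return p


def rotation_2d(angle_deg: float) -> np.ndarray:
    """Counter-clockwise rotation matrix in the projected (x, z) plane."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])
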