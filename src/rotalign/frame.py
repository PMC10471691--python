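"""Anatomical coordinate system of the leg from a best-fit epicondylar cylinder.

The medial-lateral axis is the central axis of a least-squares cylinder
fitted to the femoral epicondylar surface cloud (a proxy for the knee's
flexion axis).  Two perpendicular axes through the femoral notch point (FKC)
and the femoral head centre (FHC) complete the frame; the origin sits at the
centre of the epicondylar cylinder.  Aligning a leg to this frame puts the
epicondyles parallel to the radiographic detector: the neutral position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .geometry import mirror_x, unit
from .models import LegModel


class CylinderFitError(RuntimeError):
    """Raised when the cylinder fit fails to converge or the cloud is degenerate."""


@dataclass(frozen=True)
class CylinderFit:
    """Least-squares cylinder: axis line, radius and residual diagnostics."""

    axis_point: np.ndarray
    axis_direction: np.ndarray
    radius: float
    rms_residual: float

    def __post_init__(self) -> None:
        if abs(np.linalg.norm(self.axis_direction) - 1.0) > 1e-12:
            raise ValueError("axis_direction must be a unit vector")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be non-negative")


@dataclass(frozen=True)
class AnatomicalFrame:
    """Origin plus right-handed orthonormal axes (x medial, y anterior, z cranial)."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        axes = np.stack([self.x_axis, self.y_axis, self.z_axis])
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-10):
            raise ValueError("frame axes must be orthonormal")
        if not np.allclose(np.cross(self.x_axis, self.y_axis), self.z_axis, atol=1e-10):
            raise ValueError("frame must be right-handed (x cross y = z)")

    @property
    def rotation(self) -> np.ndarray:
        """World-from-frame rotation matrix (columns are the frame axes)."""
        return np.stack([self.x_axis, self.y_axis, self.z_axis], axis=1)


def _axis_distances(points, axis_point, direction):
    d = points - axis_point
    along = d @ direction
    radial = d - np.outer(along, direction)
    return np.linalg.norm(radial, axis=1)


def _direction_from_angles(a: float, b: float) -> np.ndarray:
    return np.array([np.cos(a) * np.cos(b), np.sin(a) * np.cos(b), np.sin(b)])


def fit_cylinder(points: np.ndarray, medial_hint: np.ndarray | None = None) -> CylinderFit:
    """Nonlinear least-squares cylinder fit (axis point + direction + radius).

    Minimizes the sum of squared radial residuals (distance-to-axis minus
    radius).  The axis direction is initialized from the principal direction
    of the cloud; the 5-parameter search runs over two direction angles, a
    2D axis-point offset in the plane through the centroid, and the radius.

    ``medial_hint`` (a vector pointing medially, e.g. ME - LE) fixes the sign
    of the returned axis direction; without it the sign is arbitrary.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 12:
        raise CylinderFitError("need at least 12 points of shape (N, 3)")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    cov = centred.T @ centred / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] < 1e-10:  # rank < 2: collinear cloud
        raise CylinderFitError("degenerate (collinear) point cloud")
    d0 = evecs[:, -1]  # principal direction

    a0 = float(np.arctan2(d0[1], d0[0]))
    b0 = float(np.arcsin(np.clip(d0[2], -1.0, 1.0)))

    def basis(direction):
        helper = np.array([0.0, 0.0, 1.0])
        if abs(direction @ helper) > 0.9:
            helper = np.array([1.0, 0.0, 0.0])
        u = unit(np.cross(helper, direction))
        return u, np.cross(direction, u)

    def residuals(params):
        a, b, c1, c2, r = params
        direction = _direction_from_angles(a, b)
        u, v = basis(direction)
        axis_point = centroid + c1 * u + c2 * v
        return _axis_distances(pts, axis_point, direction) - r

    # Algebraic (Kasa) circle fit of the projected cloud seeds the axis-point
    # offset and radius; with an arc-shaped cloud the centroid itself is far
    # off-axis, so this matters for convergence.
    u0, v0 = basis(d0)
    uu, vv = centred @ u0, centred @ v0
    amat = np.column_stack([2 * uu, 2 * vv, np.ones_like(uu)])
    bvec = uu**2 + vv**2
    (uc, vc, g), *_ = np.linalg.lstsq(amat, bvec, rcond=None)
    r_init = float(np.sqrt(max(g + uc**2 + vc**2, 1e-6)))
    x0 = np.array([a0, b0, uc, vc, max(r_init, 1e-3)])
    cost0 = 0.5 * float(np.sum(residuals(x0) ** 2))
    sol = least_squares(residuals, x0, xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=200 * 6)
    if not sol.success:
        raise CylinderFitError(
            f"cylinder fit did not converge (status {sol.status}, cost {sol.cost:.3g})"
        )
    if sol.cost > cost0 + 1e-12:
        raise CylinderFitError("cylinder fit increased the residual objective")
    a, b, c1, c2, r = sol.x
    if r <= 0:
        raise CylinderFitError(f"cylinder fit returned non-positive radius {r:.3g}")
    direction = _direction_from_angles(a, b)
    u, v = basis(direction)
    axis_point = centroid + c1 * u + c2 * v
    if medial_hint is not None and float(direction @ np.asarray(medial_hint, float)) < 0:
        direction = -direction
    res = _axis_distances(pts, axis_point, direction) - r
    return CylinderFit(
        axis_point=axis_point,
        axis_direction=unit(direction),
        radius=float(r),
        rms_residual=float(np.sqrt(np.mean(res**2))),
    )


def build_frame(leg: LegModel, fit: CylinderFit) -> AnatomicalFrame:
    """Anatomical frame from the cylinder fit and the FHC/FKC landmarks.

    x = fitted transepicondylar axis (medial), z = component of FHC - FKC
    orthogonal to x (cranial), y = z cross x (anterior); origin = axis point
    midway between the extremal projections of the cloud onto the axis (the
    centre of the epicondylar cylinder).

    Expects a right-convention leg (left legs mirrored first) so that +x is
    medial and +y anterior.
    """
    x = unit(fit.axis_direction)
    femoral = leg.point("FHC") - leg.point("FKC")
    zraw = femoral - (femoral @ x) * x
    if np.linalg.norm(zraw) < 1e-9 * np.linalg.norm(femoral):
        raise ValueError("femoral mechanical axis is parallel to the transepicondylar axis")
    z = unit(zraw)
    y = np.cross(z, x)
    along = (leg.epicondylar_cloud - fit.axis_point) @ x
    origin = fit.axis_point + 0.5 * (along.min() + along.max()) * x
    return AnatomicalFrame(origin=origin, x_axis=x, y_axis=y, z_axis=z)


def align_to_neutral(leg: LegModel, frame: AnatomicalFrame) -> LegModel:
    """Rigidly map the leg so its anatomical frame coincides with the world axes.

    Afterwards the transepicondylar axis is parallel to world x (epicondyles
    parallel to the detector plane x-z) and the femoral mechanical axis lies
    along world z through the origin.
    """
    rot = frame.rotation  # world-from-frame; transpose maps world -> frame coords
    origin = frame.origin

    def fn(p):
        return (np.asarray(p, float) - origin) @ rot

    return leg.transformed(fn)


def neutralize(leg: LegModel) -> LegModel:
    """Full normalization: fit the epicondylar cylinder and align to neutral.

    Left legs are mirrored to the right-handed medial-positive convention for
    the frame construction and mirrored back afterwards, so the returned leg
    is in its own side's coordinates (measurements re-apply the convention).
    """
    right = leg.to_right_convention()
    hint = right.point("ME") - right.point("LE")
    fit = fit_cylinder(right.epicondylar_cloud, medial_hint=hint)
    frame = build_frame(right, fit)
    aligned = align_to_neutral(right, frame)
    if leg.side == "left":
        aligned = aligned.transformed(mirror_x)
    return aligned
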