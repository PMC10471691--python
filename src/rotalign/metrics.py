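"""Orthographic coronal projection and the four landmark-based measurements.

Parallel X-rays are assumed: the detector is the world x-z plane and the
projection simply discards the antero-posterior (y) coordinate, mimicking a
long-leg radiograph taken of a leg whose epicondyles are parallel to the
detector in the neutral position.

Measurements:

* HKA  -- medial angle at the knee between the mechanical femoral axis
  (FKC -> FHC) and the mechanical tibial axis (TKC -> AJC); 180 deg = neutral,
  < 180 deg = varus under the medial-positive convention used here.
* MPTA -- medial angle between the tibial plateau line (MPT-LPT) and the
  tibial mechanical axis.
* MAD  -- signed perpendicular distance from the knee centre to the line
  FHC-AJC; positive when the line passes medial to the knee centre.
* Patellar position -- medial-lateral offset of the PLP-PMP midpoint from
  TKC in the projected plane; negative = lateralized.
"""

from __future__ import annotations

import numpy as np

from .geometry import rotate_about_axis, unit
from .models import AlignmentMeasures, LegModel


def project_coronal(point: np.ndarray) -> np.ndarray:
    """Orthographic projection onto the detector (coronal x-z) plane.

    Returns (x, z); works on a single point or an (N, 3) stack.
    """
    p = np.asarray(point, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("cannot project a non-finite point")
    return p[..., [0, 2]]


def _lean_from_vertical(v: np.ndarray, downward: bool) -> float:
    """Signed angle (deg) of a projected axis from the vertical.

    Positive when the far end leans medial (+x).  ``downward`` selects whether
    the reference vertical points distally (-z) or proximally (+z).
    """
    vx, vz = float(v[0]), float(v[1])
    if np.hypot(vx, vz) < 1e-12:
        raise ValueError("zero-length axis vector")
    ref = -vz if downward else vz
    return float(np.degrees(np.arctan2(vx, ref)))


def hka(fhc: np.ndarray, fkc: np.ndarray, tkc: np.ndarray, ajc: np.ndarray) -> float:
    """Medial hip-knee-ankle angle (deg) from projected 2D landmarks."""
    alpha = _lean_from_vertical(np.asarray(fhc, float) - np.asarray(fkc, float), downward=False)
    beta = _lean_from_vertical(np.asarray(ajc, float) - np.asarray(tkc, float), downward=True)
    return 180.0 - (alpha + beta)


def mpta(mpt: np.ndarray, lpt: np.ndarray, tkc: np.ndarray, ajc: np.ndarray) -> float:
    """Medial proximal tibial angle (deg) from projected 2D landmarks.

    Angle between the plateau line (as a line: label order is irrelevant) and
    the tibial mechanical axis, measured on the medial side.
    """
    w = np.asarray(mpt, float) - np.asarray(lpt, float)
    if np.linalg.norm(w) < 1e-12:
        raise ValueError("coincident plateau points")
    v = np.asarray(ajc, float) - np.asarray(tkc, float)
    if np.linalg.norm(v) < 1e-12:
        raise ValueError("zero-length tibial axis")
    w = w / np.linalg.norm(w)
    if w[0] < 0:  # orient the plateau direction medially
        w = -w
    v = v / np.linalg.norm(v)
    return float(np.degrees(np.arccos(np.clip(np.dot(w, v), -1.0, 1.0))))


def mad(fhc: np.ndarray, ajc: np.ndarray, knee_centre: np.ndarray) -> float:
    """Signed mechanical axis deviation (mm) from projected 2D landmarks.

    Positive when the FHC-AJC line passes medial to the knee centre.
    """
    fhc = np.asarray(fhc, float)
    ajc = np.asarray(ajc, float)
    k = np.asarray(knee_centre, float)
    ell = ajc - fhc
    n = np.linalg.norm(ell)
    if n < 1e-12:
        raise ValueError("FHC and AJC coincide")
    ell = ell / n
    d = k - fhc
    # 2D cross product; with ell pointing distally this is positive when the
    # line passes medial (+x) to the knee centre.
    return float(d[0] * ell[1] - d[1] * ell[0])


def patellar_position(plp: np.ndarray, pmp: np.ndarray, tkc: np.ndarray) -> float:
    """Medial-lateral patellar midpoint offset (mm) relative to TKC.

    Implements midpoint(PLP, PMP) - TKC restricted to the medial-lateral
    component of the projected plane; negative = lateralized.
    """
    plp = np.asarray(plp, float)
    pmp = np.asarray(pmp, float)
    if np.linalg.norm(plp - pmp) < 1e-12:
        raise ValueError("coincident patellar poles")
    mid = plp + (pmp - plp) / 2.0
    return float(mid[0] - np.asarray(tkc, float)[0])


def rotation_axis(leg: LegModel, which: str = "frame"):
    """Return (axis_point, axis_direction) of the longitudinal rotation axis.

    ``frame`` (the default) uses the world z-axis of the neutral anatomical
    frame; ``mechanical`` uses the line through FHC and AJC.  Direction
    points cranially so that positive angles are external rotation for a
    right-convention leg.
    """
    if which == "mechanical":
        fhc, ajc = leg.point("FHC"), leg.point("AJC")
        return fhc, unit(fhc - ajc)
    if which == "frame":
        return np.zeros(3), np.array([0.0, 0.0, 1.0])
    raise ValueError(f"unknown rotation axis {which!r}")


def measure(
    leg: LegModel,
    rotation_deg: float = 0.0,
    *,
    axis: str = "frame",
    knee_centre: str = "fkc",
) -> AlignmentMeasures:
    """All four projected measurements of a neutral-frame leg at a rotation.

    The leg is rigidly rotated about its longitudinal axis (positive =
    external) while the detector plane stays fixed; measurements are taken on
    the projected, rotated landmarks.  Left legs are mirrored to the
    right-handed medial-positive convention first, so signs are
    side-independent.
    """
    right = leg.to_right_convention()
    pts = {n: right.point(n) for n in ("FHC", "FKC", "TKC", "AJC", "PLP", "PMP", "MPT", "LPT")}
    if rotation_deg != 0.0:
        ap, ad = rotation_axis(right, axis)
        pts = {n: rotate_about_axis(p, ap, ad, rotation_deg) for n, p in pts.items()}
    proj = {n: project_coronal(p) for n, p in pts.items()}
    if knee_centre == "fkc":
        kc = proj["FKC"]
    elif knee_centre == "midpoint":
        kc = (proj["FKC"] + proj["TKC"]) / 2.0
    else:
        raise ValueError(f"unknown knee centre choice {knee_centre!r}")
    return AlignmentMeasures(
        rotation_deg=float(rotation_deg),
        hka_deg=hka(proj["FHC"], proj["FKC"], proj["TKC"], proj["AJC"]),
        mpta_deg=mpta(proj["MPT"], proj["LPT"], proj["TKC"], proj["AJC"]),
        mad_mm=mad(proj["FHC"], proj["AJC"], kc),
        patellar_position_mm=patellar_position(proj["PLP"], proj["PMP"], proj["TKC"]),
    )
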