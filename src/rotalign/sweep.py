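"""Axial rotation sweep, patellar centralization, and the cohort comparison.

Each neutral-positioned leg is rotated about its longitudinal axis (by
default the frame z-axis; optionally the mechanical FHC-AJC line) in 1
degree increments over +/-15 degrees -- 31 positions per leg -- and the
four projected measurements are recorded
together with their deviations from the zero position.  The centralizing
rotation (the angle at which the projected patella sits exactly over TKC) is
found by bisection, and a cohort table compares the centralized-patella
orientation with the neutral knee-forward orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .geometry import rotate_about_axis
from .metrics import measure, rotation_axis
from .models import AlignmentMeasures, LegModel

DEFAULT_ANGLES = tuple(range(-15, 16))
PARAMS = ("hka_deg", "mpta_deg", "mad_mm", "patellar_position_mm")


class CentralizationError(RuntimeError):
    """Raised when the patellar position does not change sign on the bracket."""


@dataclass(frozen=True)
class SweepResult:
    """Per-leg measurements across the rotation grid plus zero-position deviations."""

    leg_id: str
    angles: np.ndarray
    measures: List[AlignmentMeasures]
    deviations: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if len(self.measures) != len(self.angles):
            raise ValueError("angles and measures must have equal length")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (leg, angle), values plus deviation columns."""
        rows = [m.as_dict() for m in self.measures]
        df = pd.DataFrame(rows)
        df.insert(0, "leg_id", self.leg_id)
        for name in PARAMS:
            df[f"{name}_dev"] = self.deviations[name]
        return df


@dataclass(frozen=True)
class CentralizationResult:
    """Rotation zeroing the projected patellar position and the induced deltas."""

    leg_id: str
    theta_c: float
    residual_mm: float
    deltas: Dict[str, float] = field(default_factory=dict)
    centralizable: bool = True


def rotate_leg(leg: LegModel, theta_deg: float, *, axis: str = "frame") -> LegModel:
    """Rigidly rotate a neutral-frame leg about its longitudinal axis.

    Positive angles are external rotation (an anterior patella moves
    laterally) for either side; left legs rotate with the opposite world
    sense so the anatomical meaning is side-independent.
    """
    right = leg.to_right_convention()
    ap, ad = rotation_axis(right, axis)
    sense = 1.0 if leg.side == "right" else -1.0
    if leg.side == "left":
        # express the axis in the leg's own (mirrored) coordinates
        ap = ap * np.array([-1.0, 1.0, 1.0])
        ad = ad * np.array([-1.0, 1.0, 1.0])
    return leg.transformed(lambda p: rotate_about_axis(p, ap, ad, sense * theta_deg))


def sweep(
    leg: LegModel,
    angles: Sequence[float] = DEFAULT_ANGLES,
    *,
    axis: str = "frame",
    knee_centre: str = "fkc",
) -> SweepResult:
    """Measure the leg at every rotation angle and subtract the zero position."""
    angles = np.asarray(list(angles), dtype=float)
    if 0.0 not in angles:
        raise ValueError("the rotation grid must contain the zero position")
    measures = [measure(leg, a, axis=axis, knee_centre=knee_centre) for a in angles]
    zero = measures[int(np.where(angles == 0.0)[0][0])]
    deviations = {
        name: np.array([getattr(m, name) - getattr(zero, name) for m in measures])
        for name in PARAMS
    }
    return SweepResult(
        leg_id=leg.leg_id, angles=angles, measures=measures, deviations=deviations
    )


def find_centralization(
    leg: LegModel,
    bracket: tuple = (-30.0, 10.0),
    tol_deg: float = 1e-3,
    *,
    axis: str = "frame",
    knee_centre: str = "fkc",
) -> CentralizationResult:
    """Bisection for the rotation that centres the patella over TKC.

    The default bracket covers the clinically reported extremes of
    centralizing rotations; a bracket without a sign change means the patella
    cannot be centralized within it and is reported as such with the boundary
    values.
    """

    def f(theta):
        return measure(leg, theta, axis=axis, knee_centre=knee_centre).patellar_position_mm

    lo, hi = float(bracket[0]), float(bracket[1])
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        theta_c = lo
    elif fhi == 0.0:
        theta_c = hi
    elif flo * fhi > 0:
        boundary = lo if abs(flo) < abs(fhi) else hi
        return CentralizationResult(
            leg_id=leg.leg_id,
            theta_c=boundary,
            residual_mm=min(flo, fhi, key=abs),
            deltas={},
            centralizable=False,
        )
    else:
        while hi - lo > tol_deg:
            mid = 0.5 * (lo + hi)
            fm = f(mid)
            if fm == 0.0:
                lo = hi = mid
                break
            if flo * fm < 0:
                hi, fhi = mid, fm
            else:
                lo, flo = mid, fm
        theta_c = 0.5 * (lo + hi)

    at_c = measure(leg, theta_c, axis=axis, knee_centre=knee_centre)
    at_0 = measure(leg, 0.0, axis=axis, knee_centre=knee_centre)
    deltas = {name: getattr(at_c, name) - getattr(at_0, name) for name in PARAMS}
    return CentralizationResult(
        leg_id=leg.leg_id,
        theta_c=float(theta_c),
        residual_mm=at_c.patellar_position_mm,
        deltas=deltas,
        centralizable=True,
    )


def compare_cohort(results: Sequence[CentralizationResult]) -> pd.DataFrame:
    """Cohort comparison of centralized-patella vs knee-forward orientation.

    Columns: centralizing rotation and the induced HKA/MAD/MPTA alterations;
    rows: mean, SD, most-internal (most negative) and most-external (most
    positive) alteration.  Mirrors the structure of a clinical comparison
    table for n legs.
    """
    results = [r for r in results if r.centralizable]
    if len(results) < 2:
        raise ValueError("need at least 2 centralizable legs")
    cols = {
        "rotation_deg": np.array([r.theta_c for r in results]),
        "hka_deg": np.array([r.deltas["hka_deg"] for r in results]),
        "mad_mm": np.array([r.deltas["mad_mm"] for r in results]),
        "mpta_deg": np.array([r.deltas["mpta_deg"] for r in results]),
    }
    rows = ["mean", "sd", "max_alteration_internal", "max_alteration_external"]
    data = {
        name: [vals.mean(), vals.std(ddof=1), vals.min(), vals.max()]
        for name, vals in cols.items()
    }
    return pd.DataFrame(data, index=rows)


def sweep_cohort(
    legs: Sequence[LegModel],
    angles: Sequence[float] = DEFAULT_ANGLES,
    *,
    axis: str = "frame",
    knee_centre: str = "fkc",
) -> List[SweepResult]:
    """Convenience: sweep every leg of a cohort."""
    return [sweep(leg, angles, axis=axis, knee_centre=knee_centre) for leg in legs]
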