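"""Shared domain containers: legs, landmark vocabulary, measurement records.

A leg is represented purely by named landmarks plus an epicondylar surface
point cloud; every measurement in the pipeline is landmark-based, so no bone
surface model is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional

import numpy as np

from .geometry import mirror_x

#: Controlled vocabulary of required landmark names.
#:   FHC  femoral head centre            FKC  femoral notch point (femoral knee centre)
#:   TKC  tibial knee centre             AJC  ankle joint centre
#:   PLP/PMP  patellar lateral/medial poles
#:   MPT/LPT  most proximal medial/lateral tibia (plateau line)
#:   ME/LE    medial/lateral epicondyle reference points
REQUIRED_LANDMARKS = ("FHC", "FKC", "TKC", "AJC", "PLP", "PMP", "MPT", "LPT", "ME", "LE")

#: Minimum number of epicondylar cloud points for a stable cylinder fit.
MIN_CLOUD_POINTS = 12


@dataclass(frozen=True)
class LegTruth:
    """Generating ground truth retained for parameter-recovery tests.

    Offsets and the transepicondylar axis are recorded in the right-handed,
    medial-positive convention regardless of side.
    """

    axis_point: np.ndarray
    axis_direction: np.ndarray
    hka_deg: float
    mpta_deg: float
    lateral_offset_mm: float
    anterior_offset_mm: float
    tibial_coronal_deg: float
    tibial_sagittal_deg: float
    plateau_slope_deg: float
    femoral_sagittal_deg: float


@dataclass(frozen=True)
class LegModel:
    """Named 3D landmarks (mm) plus an epicondylar point cloud for one leg."""

    leg_id: str
    side: str  # "left" | "right"
    landmarks: Dict[str, np.ndarray]
    epicondylar_cloud: np.ndarray
    truth: Optional[LegTruth] = None

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        missing = [n for n in REQUIRED_LANDMARKS if n not in self.landmarks]
        if missing:
            raise ValueError(f"leg {self.leg_id}: missing landmarks {missing}")
        for name, p in self.landmarks.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValueError(f"leg {self.leg_id}: landmark {name} is not a finite 3D point")
        cloud = np.asarray(self.epicondylar_cloud, dtype=float)
        if cloud.ndim != 2 or cloud.shape[1] != 3:
            raise ValueError(f"leg {self.leg_id}: epicondylar cloud must be (N, 3)")
        if cloud.shape[0] < MIN_CLOUD_POINTS:
            raise ValueError(
                f"leg {self.leg_id}: epicondylar cloud needs >= {MIN_CLOUD_POINTS} points"
            )
        if np.linalg.matrix_rank(cloud - cloud.mean(axis=0), tol=1e-8) < 2:
            raise ValueError(f"leg {self.leg_id}: epicondylar cloud is collinear")
        if np.linalg.norm(self.landmarks["PLP"] - self.landmarks["PMP"]) <= 0.0:
            raise ValueError(f"leg {self.leg_id}: patella has zero width (PLP == PMP)")

    def point(self, name: str) -> np.ndarray:
        return np.asarray(self.landmarks[name], dtype=float)

    def transformed(self, fn) -> "LegModel":
        """Apply a point-wise coordinate map to every landmark and the cloud."""
        landmarks = {k: np.asarray(fn(v), dtype=float) for k, v in self.landmarks.items()}
        cloud = np.asarray(fn(self.epicondylar_cloud), dtype=float)
        return replace(self, landmarks=landmarks, epicondylar_cloud=cloud)

    def mirrored(self) -> "LegModel":
        """Reflect across x = 0 and flip the side label."""
        other = "left" if self.side == "right" else "right"
        leg = self.transformed(mirror_x)
        return replace(leg, side=other)

    def to_right_convention(self) -> "LegModel":
        """Return the leg in the right-handed medial-positive (+x) convention.

        Right legs are returned unchanged; left legs are mirrored across x = 0
        (keeping their side label) so that medial/lateral signs are
        side-independent in every downstream measurement.
        """
        if self.side == "right":
            return self
        return self.transformed(mirror_x)


@dataclass(frozen=True)
class AlignmentMeasures:
    """The four projected measurements at one rotation angle.

    Sign conventions: rotation negative = internal / positive = external;
    HKA < 180 deg = varus; MAD > 0 = mechanical axis passes medial to the knee
    centre; patellar position < 0 = lateralized.
    """

    rotation_deg: float
    hka_deg: float
    mpta_deg: float
    mad_mm: float
    patellar_position_mm: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "rotation_deg": self.rotation_deg,
            "hka_deg": self.hka_deg,
            "mpta_deg": self.mpta_deg,
            "mad_mm": self.mad_mm,
            "patellar_position_mm": self.patellar_position_mm,
        }
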