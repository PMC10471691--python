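"""Landmark file formats, run configuration, and the end-to-end study runner.

The canonical landmark format is versioned JSON (nested per-leg records with
an optional epicondylar cloud and ground-truth sidecar); a flat CSV
alternative carries landmarks only.  Coordinates are millimetres in the
right-handed convention defined by the anatomical frame.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .cohort import GeneratorParams, sample_cohort
from .frame import neutralize
from .models import REQUIRED_LANDMARKS, LegModel, LegTruth
from .stats import (
    MixedModelSummary,
    RegressionSummary,
    fit_mixed_models,
    fit_patellar_regression,
    table1_analogue,
)
from .sweep import compare_cohort, find_centralization, sweep

log = logging.getLogger(__name__)

FORMAT_VERSION = "1.0"


class LandmarkParseError(ValueError):
    """Raised when a landmark file is malformed beyond per-leg recovery."""


def write_landmarks(legs: Sequence[LegModel], path, include_cloud: bool = True) -> None:
    """Write legs to the canonical JSON format (+ truth sidecar if present)."""
    path = Path(path)
    records, truths = [], {}
    for leg in legs:
        rec = {
            "leg_id": leg.leg_id,
            "side": leg.side,
            "landmarks": {k: [float(x) for x in v] for k, v in leg.landmarks.items()},
        }
        if include_cloud:
            rec["epicondylar_cloud"] = np.asarray(leg.epicondylar_cloud).tolist()
        records.append(rec)
        if leg.truth is not None:
            t = dataclasses.asdict(leg.truth)
            truths[leg.leg_id] = {
                k: (np.asarray(v).tolist() if isinstance(v, np.ndarray) else float(v))
                for k, v in t.items()
            }
    payload = {"format_version": FORMAT_VERSION, "legs": records}
    path.write_text(json.dumps(payload))
    if truths:
        sidecar = path.with_name(path.stem + "_truth.json")
        sidecar.write_text(json.dumps(truths))


def read_landmarks(path) -> List[LegModel]:
    """Read and validate legs from the canonical JSON format.

    Unknown landmark names are warned about and ignored; a leg missing a
    required landmark is rejected with a named warning while the remaining
    legs load.  A truth sidecar next to the file is picked up automatically.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
        records = payload["legs"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise LandmarkParseError(f"malformed landmark file {path}: {exc}") from exc
    sidecar = path.with_name(path.stem + "_truth.json")
    truths = json.loads(sidecar.read_text()) if sidecar.exists() else {}

    legs: List[LegModel] = []
    for i, rec in enumerate(records):
        try:
            leg_id = rec["leg_id"]
            side = rec["side"]
            raw = rec["landmarks"]
        except (KeyError, TypeError) as exc:
            raise LandmarkParseError(f"malformed leg record #{i} in {path}: {exc}") from exc
        unknown = sorted(set(raw) - set(REQUIRED_LANDMARKS))
        if unknown:
            warnings.warn(f"leg {leg_id}: ignoring unknown landmarks {unknown}")
        landmarks = {
            k: np.asarray(v, dtype=float) for k, v in raw.items() if k in REQUIRED_LANDMARKS
        }
        cloud = np.asarray(rec.get("epicondylar_cloud", np.zeros((0, 3))), dtype=float)
        truth = None
        if leg_id in truths:
            t = truths[leg_id]
            truth = LegTruth(
                axis_point=np.asarray(t["axis_point"], float),
                axis_direction=np.asarray(t["axis_direction"], float),
                hka_deg=t["hka_deg"],
                mpta_deg=t["mpta_deg"],
                lateral_offset_mm=t["lateral_offset_mm"],
                anterior_offset_mm=t["anterior_offset_mm"],
                tibial_coronal_deg=t["tibial_coronal_deg"],
                tibial_sagittal_deg=t["tibial_sagittal_deg"],
                plateau_slope_deg=t["plateau_slope_deg"],
                femoral_sagittal_deg=t["femoral_sagittal_deg"],
            )
        try:
            legs.append(
                LegModel(
                    leg_id=leg_id,
                    side=side,
                    landmarks=landmarks,
                    epicondylar_cloud=cloud.reshape(-1, 3),
                    truth=truth,
                )
            )
        except ValueError as exc:
            warnings.warn(f"rejecting leg {leg_id}: {exc}")
    return legs


def write_landmarks_csv(legs: Sequence[LegModel], path) -> None:
    """Flat CSV alternative (leg_id, side, landmark, x, y, z); no cloud."""
    rows = [
        {"leg_id": leg.leg_id, "side": leg.side, "landmark": name,
         "x": p[0], "y": p[1], "z": p[2]}
        for leg in legs
        for name, p in ((n, leg.point(n)) for n in REQUIRED_LANDMARKS)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmarks_csv(path) -> List[dict]:
    """Read the flat CSV alternative into raw per-leg landmark dicts.

    Returned records lack a cloud, so they cannot be neutralized; intended
    for interoperability and manual inspection.
    """
    df = pd.read_csv(path)
    out = []
    for (leg_id, side), grp in df.groupby(["leg_id", "side"], sort=False):
        landmarks = {
            r.landmark: np.array([r.x, r.y, r.z], dtype=float) for r in grp.itertuples()
        }
        out.append({"leg_id": leg_id, "side": side, "landmarks": landmarks})
    return out


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full simulation study run."""

    params: GeneratorParams = field(default_factory=GeneratorParams)
    sweep_min: int = -15
    sweep_max: int = 15
    sweep_step: int = 1
    centralization_bracket: Tuple[float, float] = (-30.0, 10.0)
    knee_centre: str = "fkc"  # "fkc" | "midpoint"
    rotation_axis: str = "frame"  # "frame" | "mechanical"
    seed: int = 0
    output_dir: str = "rotalign_out"

    def __post_init__(self) -> None:
        if self.sweep_step <= 0:
            raise ValueError("sweep step must be positive")
        if (self.sweep_max - self.sweep_min) % self.sweep_step != 0:
            raise ValueError("sweep step must divide the sweep range")
        if self.sweep_min > 0 or self.sweep_max < 0:
            raise ValueError("sweep range must contain the zero position")

    @property
    def angles(self) -> List[int]:
        return list(range(self.sweep_min, self.sweep_max + 1, self.sweep_step))

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        params = GeneratorParams(**d.pop("params"))
        bracket = tuple(d.pop("centralization_bracket"))
        return cls(params=params, centralization_bracket=bracket, **d)


@dataclass(frozen=True)
class CohortReport:
    """Bundled outputs of a full study run."""

    regression: RegressionSummary
    mixed: List[MixedModelSummary]
    table1: pd.DataFrame
    table2: pd.DataFrame
    sweep_frame: pd.DataFrame
    n_legs: int
    n_positions: int


def run_study(config: RunConfig) -> CohortReport:
    """Run the full pipeline and write all report files to the output directory.

    Stages: generate cohort -> build frames and align to neutral -> rotation
    sweep -> centralization -> regression and mixed models -> tables.  Any
    stage failure aborts with the stage name and leg id; per-stage counts and
    timings are logged.  Two runs with the same configuration produce
    byte-identical reports.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = replace(config.params, seed=config.seed)

    t0 = time.perf_counter()
    legs = sample_cohort(params)
    log.info("generated %d legs in %.2fs", len(legs), time.perf_counter() - t0)
    write_landmarks(legs, outdir / "cohort.json")

    stage = "neutralize"
    neutral = []
    t0 = time.perf_counter()
    for leg in legs:
        try:
            neutral.append(neutralize(leg))
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed for leg {leg.leg_id}: {exc}") from exc
    log.info("neutralized %d legs in %.2fs", len(neutral), time.perf_counter() - t0)

    stage = "sweep"
    t0 = time.perf_counter()
    sweeps = []
    for leg in neutral:
        try:
            sweeps.append(
                sweep(leg, config.angles, axis=config.rotation_axis,
                      knee_centre=config.knee_centre)
            )
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed for leg {leg.leg_id}: {exc}") from exc
    sweep_df = pd.concat([s.to_frame() for s in sweeps], ignore_index=True)
    n_positions = len(sweep_df)
    log.info("swept %d legs (%d positions) in %.2fs",
             len(sweeps), n_positions, time.perf_counter() - t0)
    sweep_df.to_csv(outdir / "sweep.csv", index=False, float_format="%.6f")

    stage = "centralization"
    t0 = time.perf_counter()
    centralizations = []
    for leg in neutral:
        try:
            centralizations.append(
                find_centralization(
                    leg, config.centralization_bracket,
                    axis=config.rotation_axis, knee_centre=config.knee_centre,
                )
            )
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed for leg {leg.leg_id}: {exc}") from exc
    log.info("centralized %d legs in %.2fs", len(centralizations), time.perf_counter() - t0)
    pd.DataFrame(
        [
            {"leg_id": c.leg_id, "theta_c_deg": c.theta_c,
             "residual_mm": c.residual_mm, "centralizable": c.centralizable,
             **{f"delta_{k}": v for k, v in c.deltas.items()}}
            for c in centralizations
        ]
    ).to_csv(outdir / "centralization.csv", index=False, float_format="%.6f")

    stage = "statistics"
    t0 = time.perf_counter()
    try:
        reg = fit_patellar_regression(sweeps)
        mixed = fit_mixed_models(sweeps)
        table1 = table1_analogue(reg, mixed)
        table2 = compare_cohort(centralizations).round(6)
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc
    log.info("fitted models in %.2fs", time.perf_counter() - t0)

    table1.to_csv(outdir / "table1.csv")
    table2.to_csv(outdir / "table2.csv")
    (outdir / "regression.json").write_text(json.dumps(dataclasses.asdict(reg), indent=2))
    (outdir / "mixed_models.json").write_text(
        json.dumps(
            [
                {**dataclasses.asdict(m),
                 "categorical_estimates": {str(k): v for k, v in m.categorical_estimates.items()},
                 "categorical_se": {str(k): v for k, v in m.categorical_se.items()}}
                for m in mixed
            ],
            indent=2,
        )
    )
    # Estimated-deviation-vs-rotation line (plot data) for the patellar model.
    pd.DataFrame(
        {"rotation_deg": config.angles,
         "estimated_patellar_deviation_mm": [reg.slope * a for a in config.angles]}
    ).to_csv(outdir / "patellar_regression_line.csv", index=False, float_format="%.6f")

    config_json = config.to_json()
    manifest = {
        "rotalign_version": __version__,
        "seed": config.seed,
        "n_legs": len(legs),
        "n_positions": n_positions,
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return CohortReport(
        regression=reg,
        mixed=mixed,
        table1=table1,
        table2=table2,
        sweep_frame=sweep_df,
        n_legs=len(legs),
        n_positions=n_positions,
    )
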