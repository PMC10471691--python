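"""Statistical layer: pooled patellar regression, linear mixed models, tables.

The patellar analysis pools per-leg deviations from the zero position over
all rotation angles and fits ordinary least squares on the rotation degree;
using leg-specific deviations implicitly accounts for the repeated-measures
structure.  HKA, MAD and MPTA deviations are analysed with linear mixed
models (random intercept per leg): a continuous fit supplies the per-degree
slope and a categorical fit on the 5-degree increments supplies the
table-cell estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .sweep import SweepResult

#: measurement column -> short parameter label
MIXED_PARAMS = {"hka_deg": "HKA", "mad_mm": "MAD", "mpta_deg": "MPTA"}
TABLE_ANGLES = (-15, -10, -5, 5, 10, 15)


@dataclass(frozen=True)
class RegressionSummary:
    """Pooled OLS of patellar deviation on rotation degree."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class MixedModelSummary:
    """Mixed-model results for one alignment parameter.

    ``per_degree_slope`` comes from the continuous random-intercept model;
    ``categorical_estimates`` are the deviations at the 5-degree increments
    relative to the 0-degree reference.  ``method`` records whether the mixed
    fit succeeded or a flagged pooled-OLS fallback was used.
    """

    parameter: str
    per_degree_slope: float
    categorical_estimates: Dict[int, float]
    categorical_se: Dict[int, float] = field(default_factory=dict)
    conditional_r2: float = float("nan")
    method: str = "mixedlm"


def sweeps_to_frame(sweeps: Sequence[SweepResult]) -> pd.DataFrame:
    """Long-format deviations table: one row per (leg, angle)."""
    frames = [s.to_frame() for s in sweeps]
    df = pd.concat(frames, ignore_index=True)
    return df


def fit_patellar_regression(sweeps: Sequence[SweepResult]) -> RegressionSummary:
    """Pooled OLS (with intercept) of patellar deviation on rotation degree."""
    if len(sweeps) < 1:
        raise ValueError("need at least one sweep")
    df = sweeps_to_frame(sweeps)
    if df["rotation_deg"].nunique() < 2:
        raise ValueError("need at least two distinct rotation angles")
    x = sm.add_constant(df["rotation_deg"].to_numpy())
    fit = sm.OLS(df["patellar_position_mm_dev"].to_numpy(), x).fit()
    return RegressionSummary(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        n_points=int(fit.nobs),
    )


def _conditional_r2(result) -> float:
    """Nakagawa-style conditional R^2: (fixed + random) / total variance."""
    fitted_fixed = result.model.exog @ result.fe_params
    var_f = float(np.var(fitted_fixed))
    var_r = float(result.cov_re.to_numpy().ravel()[0]) if result.cov_re.size else 0.0
    var_e = float(result.scale)
    total = var_f + var_r + var_e
    return float("nan") if total <= 0 else (var_f + var_r) / total


def fit_mixed_models(sweeps: Sequence[SweepResult]) -> List[MixedModelSummary]:
    """Continuous and categorical mixed models for HKA, MAD and MPTA deviations.

    Continuous: deviation ~ rotation degree with a random intercept per leg,
    fitted by REML.  Categorical: the 5-degree-increment subset with 0 deg as
    the reference level.  Singular fits (the deviations are exactly zero at
    the reference angle, so the intercept variance often sits on the
    boundary) fall back to pooled OLS and are flagged via ``method``.
    """
    if len(sweeps) < 3:
        raise ValueError("need at least three legs for a mixed model")
    df = sweeps_to_frame(sweeps)
    df5 = df[np.isclose(np.mod(df["rotation_deg"], 5.0), 0.0)].copy()
    df5["angle_cat"] = df5["rotation_deg"].astype(int)
    out: List[MixedModelSummary] = []
    for col, label in MIXED_PARAMS.items():
        y = df[f"{col}_dev"].to_numpy()
        if float(np.var(y)) < 1e-18:
            # Rotation-invariant parameter (e.g. planar legs): nothing to model.
            out.append(
                MixedModelSummary(
                    parameter=label,
                    per_degree_slope=0.0,
                    categorical_estimates={a: 0.0 for a in TABLE_ANGLES},
                    categorical_se={a: 0.0 for a in TABLE_ANGLES},
                    conditional_r2=float("nan"),
                    method="degenerate",
                )
            )
            continue
        method = "mixedlm"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cont = smf.mixedlm(
                    f"{col}_dev ~ rotation_deg", df, groups=df["leg_id"]
                ).fit(reml=True)
                cat = smf.mixedlm(
                    f"{col}_dev ~ C(angle_cat, Treatment(reference=0))",
                    df5,
                    groups=df5["leg_id"],
                ).fit(reml=True)
            slope = float(cont.fe_params["rotation_deg"])
            cr2 = _conditional_r2(cont)
            estimates, ses = {}, {}
            for a in TABLE_ANGLES:
                key = f"C(angle_cat, Treatment(reference=0))[T.{a}]"
                estimates[a] = float(cat.fe_params[key])
                ses[a] = float(cat.bse[key])
            if not np.isfinite(slope) or not all(np.isfinite(v) for v in estimates.values()):
                raise ValueError("non-finite mixed-model estimates")
        except Exception:
            method = "ols_fallback"
            x = sm.add_constant(df["rotation_deg"].to_numpy())
            ols = sm.OLS(y, x).fit()
            slope = float(ols.params[1])
            cr2 = float(ols.rsquared)
            grouped = df5.groupby("angle_cat")[f"{col}_dev"]
            means, sds, ns = grouped.mean(), grouped.std(ddof=1), grouped.count()
            estimates = {a: float(means[a]) for a in TABLE_ANGLES}
            ses = {a: float(sds[a] / np.sqrt(ns[a])) for a in TABLE_ANGLES}
        out.append(
            MixedModelSummary(
                parameter=label,
                per_degree_slope=slope,
                categorical_estimates=estimates,
                categorical_se=ses,
                conditional_r2=cr2,
                method=method,
            )
        )
    return out


def table1_analogue(
    reg: RegressionSummary, mixed: Sequence[MixedModelSummary]
) -> pd.DataFrame:
    """Model-derived deviations from zero position at the 5-degree increments.

    The patellar row is the pooled regression line evaluated at each angle
    (slope times angle); the HKA/MAD/MPTA rows are the categorical
    mixed-model estimates.  Values rounded to one decimal, as printed in
    clinical tables.
    """
    cols = list(TABLE_ANGLES)
    rows = {"Patellar position (mm)": [round(reg.slope * a, 1) for a in cols]}
    units = {"HKA": "HKA (deg)", "MAD": "MAD (mm)", "MPTA": "MPTA (deg)"}
    for m in mixed:
        rows[units[m.parameter]] = [round(m.categorical_estimates[a], 1) for a in cols]
    return pd.DataFrame(rows, index=cols).T


def estimate_rotation_from_patellar_shift(delta_mm: float, slope: float) -> float:
    """Invert the linear relationship: rotation (deg) from a patellar shift (mm).

    A patellar shift between an image pair divided by the per-degree slope
    estimates the inter-image limb rotation.
    """
    if slope == 0:
        raise ValueError("slope must be non-zero")
    return float(delta_mm) / float(slope)
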