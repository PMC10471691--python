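import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rotalign import cohort as cohort_mod
from rotalign.frame import neutralize
from rotalign.stats import fit_mixed_models, fit_patellar_regression
from rotalign.sweep import find_centralization, sweep

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: master seed of the acceptance-scale study fixture (fixed study conditions)
STUDY_SEED = 1


@pytest.fixture(scope="session")
def default_params():
    """Calibrated default study conditions (30 subjects, 60 legs)."""
    return cohort_mod.default_params(n_subjects=30, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def small_params():
    """Small, fast cohort for structural tests (4 legs, light clouds)."""
    return dataclasses.replace(
        cohort_mod.default_params(n_subjects=2, seed=STUDY_SEED),
        cloud_n_points=300,
    )


@pytest.fixture(scope="session")
def planar_params():
    """Strictly planar, deterministic leg: straight axes, level plateau.

    All rotation responses of HKA/MPTA vanish identically; the patella keeps
    its lateral and anterior offsets, so its projected position still follows
    the d0*cos(theta) - a*sin(theta) closed form.
    """
    base = cohort_mod.GeneratorParams()
    return dataclasses.replace(
        base,
        hka_mean=180.0, hka_sd=0.0,
        mpta_mean=90.0, mpta_sd=0.0,
        patella_lateral_offset_mean=-8.3, patella_lateral_offset_sd=0.0,
        patella_anterior_offset_mean=51.569, patella_anterior_offset_sd=0.0,
        offset_correlation=0.0, hka_mpta_correlation=0.0,
        femoral_sagittal_angle=0.0, tibial_sagittal_angle=0.0,
        plateau_posterior_slope=0.0, knee_anterior_offset=0.0,
        cloud_n_points=300, cloud_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def sample_planar_leg(planar_params):
    rng = np.random.default_rng(0)
    return cohort_mod.sample_leg(planar_params, "right", rng, leg_id="planar")


@pytest.fixture(scope="session")
def study(default_params):
    """Full default study: cohort, neutralized legs, sweeps, fits.

    Session-scoped: this is the 60-leg, 1860-position simulation all
    cohort-level checks share.
    """
    legs = cohort_mod.sample_cohort(default_params)
    neutral = [neutralize(leg) for leg in legs]
    sweeps = [sweep(leg) for leg in neutral]
    regression = fit_patellar_regression(sweeps)
    mixed = {m.parameter: m for m in fit_mixed_models(sweeps)}
    centralizations = [find_centralization(leg) for leg in neutral]
    return {
        "params": default_params,
        "legs": legs,
        "neutral": neutral,
        "sweeps": sweeps,
        "regression": regression,
        "mixed": mixed,
        "centralizations": centralizations,
    }
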