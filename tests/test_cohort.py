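"""Synthetic cohort generation, calibration closed forms, and recovery."""

import dataclasses

import numpy as np
import pytest

from rotalign import cohort, metrics
from rotalign.cohort import CalibrationError, GeneratorParams, calibrate_generator
from rotalign.models import MIN_CLOUD_POINTS


class TestCalibration:
    def test_anterior_offset_inverts_target_slope(self):
        p = calibrate_generator(target_slope_mm_per_deg=-0.9)
        assert p.patella_anterior_offset_mean == pytest.approx(51.57, abs=0.01)
        # oracle: one degree of rotation moves the patella by the target
        assert p.patella_anterior_offset_mean * np.sin(np.deg2rad(1.0)) == pytest.approx(
            0.9, abs=1e-6
        )

    def test_anterior_offset_other_target(self):
        # deeper patella: a consistent centralization target must accompany it
        p = calibrate_generator(
            target_slope_mm_per_deg=-1.0,
            target_centralization_deg=np.degrees(np.arctan2(-8.3, 57.3)) - 0.4,
        )
        assert p.patella_anterior_offset_mean == pytest.approx(57.30, abs=0.01)

    def test_centralization_matching_first_order_needs_no_correlation(self):
        """Targeting the atan of the mean offsets leaves the offsets nearly
        uncorrelated (the correlation only corrects second-order terms)."""
        theta0 = np.degrees(np.arctan2(-8.3, 51.569))
        p = calibrate_generator(target_centralization_deg=theta0)
        assert abs(p.offset_correlation) < 0.1

    def test_slope_targets_reproduced_by_closed_forms(self):
        p = calibrate_generator()
        g = cohort.CALIBRATION_GRID
        coronal = 180.0 - p.hka_mean
        hk = [cohort.projected_hka(t, coronal, p.tibial_sagittal_angle) for t in g]
        mp = [
            cohort.projected_mpta(
                t, coronal, p.tibial_sagittal_angle, p.mpta_mean, p.plateau_posterior_slope
            )
            for t in g
        ]
        assert np.polyfit(g, hk, 1)[0] == pytest.approx(-0.03, abs=1e-9)
        assert np.polyfit(g, mp, 1)[0] == pytest.approx(0.02, abs=1e-9)

    def test_unreachable_anterior_offset_reported(self):
        with pytest.raises(CalibrationError):
            calibrate_generator(target_slope_mm_per_deg=-0.1)  # 5.7 mm: not a knee
        with pytest.raises(CalibrationError):
            calibrate_generator(target_slope_mm_per_deg=-2.0)  # 114.6 mm
        with pytest.raises(CalibrationError):
            calibrate_generator(target_slope_mm_per_deg=0.0)

    def test_unreachable_centralization_reported(self):
        with pytest.raises(CalibrationError):
            calibrate_generator(target_centralization_deg=-45.0)


class TestGeneratorParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"femur_length": -1.0},
            {"hka_sd": -0.1},
            {"offset_correlation": 1.5},
            {"hka_mpta_correlation": -2.0},
            {"n_subjects": 0},
            {"cloud_n_points": 5},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GeneratorParams(**kwargs)


class TestSampleLeg:
    def test_deterministic_symmetric_leg(self):
        """All SDs zero, neutral HKA, centred patella: every measurement is
        exactly its configured value."""
        p = dataclasses.replace(
            GeneratorParams(),
            hka_mean=180.0, hka_sd=0.0, mpta_sd=0.0,
            patella_lateral_offset_mean=0.0, patella_lateral_offset_sd=0.0,
            patella_anterior_offset_sd=0.0,
            cloud_noise_sd=0.0, cloud_n_points=200,
        )
        leg = cohort.sample_leg(p, "right", np.random.default_rng(0))
        m = metrics.measure(leg)
        assert m.patellar_position_mm == pytest.approx(0.0, abs=1e-9)
        assert m.hka_deg == pytest.approx(180.0, abs=1e-9)
        assert m.mpta_deg == pytest.approx(87.7, abs=1e-9)

    def test_zero_position_measurements_match_sampled_truth(self, default_params):
        rng = np.random.default_rng(42)
        for _ in range(5):
            leg = cohort.sample_leg(default_params, "right", rng)
            m = metrics.measure(leg)
            assert m.hka_deg == pytest.approx(leg.truth.hka_deg, abs=1e-9)
            assert m.mpta_deg == pytest.approx(leg.truth.mpta_deg, abs=1e-9)
            assert m.patellar_position_mm == pytest.approx(
                leg.truth.lateral_offset_mm, abs=1e-9
            )

    def test_generated_legs_pass_model_invariants(self, small_params):
        for leg in cohort.sample_cohort(small_params):
            assert leg.epicondylar_cloud.shape[0] >= MIN_CLOUD_POINTS
            assert np.linalg.norm(leg.point("PLP") - leg.point("PMP")) > 0
            for p in leg.landmarks.values():
                assert np.all(np.isfinite(p))

    def test_left_leg_is_mirrored(self, small_params):
        rng1 = np.random.default_rng([9, 0])
        rng2 = np.random.default_rng([9, 0])
        right = cohort.sample_leg(small_params, "right", rng1)
        left = cohort.sample_leg(small_params, "left", rng2)
        assert left.side == "left"
        assert np.allclose(left.point("FHC"), right.point("FHC") * [-1, 1, 1])
        assert np.allclose(left.point("PMP"), right.point("PMP") * [-1, 1, 1])

    def test_mirror_twins_measure_identically(self, small_params):
        rng = np.random.default_rng(11)
        right = cohort.sample_leg(small_params, "right", rng)
        left = right.mirrored()
        for theta in (-15.0, -7.0, 0.0, 4.0, 15.0):
            a = metrics.measure(right, theta)
            b = metrics.measure(left, theta)
            for name in ("hka_deg", "mpta_deg", "mad_mm", "patellar_position_mm"):
                assert getattr(a, name) == pytest.approx(getattr(b, name), abs=1e-9)

    def test_bad_side_rejected(self, small_params):
        with pytest.raises(ValueError):
            cohort.sample_leg(small_params, "upward", np.random.default_rng(0))


class TestSampleCohort:
    def test_cohort_size_and_sides(self, small_params):
        legs = cohort.sample_cohort(small_params)
        assert len(legs) == 2 * small_params.n_subjects
        assert sum(leg.side == "left" for leg in legs) == small_params.n_subjects

    def test_single_subject(self):
        p = dataclasses.replace(GeneratorParams(), n_subjects=1, cloud_n_points=100)
        legs = cohort.sample_cohort(p)
        assert [leg.side for leg in legs] == ["right", "left"]

    def test_same_seed_bit_identical(self, small_params):
        a = cohort.sample_cohort(small_params)
        b = cohort.sample_cohort(small_params)
        for la, lb in zip(a, b):
            assert la.leg_id == lb.leg_id
            for name in la.landmarks:
                assert np.array_equal(la.point(name), lb.point(name))
            assert np.array_equal(la.epicondylar_cloud, lb.epicondylar_cloud)

    def test_different_seeds_differ(self, small_params):
        a = cohort.sample_cohort(small_params)
        b = cohort.sample_cohort(dataclasses.replace(small_params, seed=12345))
        assert not np.allclose(a[0].point("AJC"), b[0].point("AJC"))

    def test_parameter_recovery_at_large_n(self):
        """Generator means are recovered through direct measurement of the
        generated neutral pose (law of large numbers, 3 SE at n = 1000)."""
        p = dataclasses.replace(
            cohort.default_params(seed=77), n_subjects=500, cloud_n_points=50
        )
        legs = cohort.sample_cohort(p)
        assert len(legs) == 1000
        ms = [metrics.measure(leg) for leg in legs]
        truth_d0 = np.mean([leg.truth.lateral_offset_mm for leg in legs])
        assert truth_d0 == pytest.approx(-8.3, abs=3 * 5.4 / np.sqrt(1000))
        assert np.mean([m.patellar_position_mm for m in ms]) == pytest.approx(
            -8.3, abs=3 * 5.4 / np.sqrt(1000)
        )
        assert np.mean([m.hka_deg for m in ms]) == pytest.approx(
            180.1, abs=3 * 3.1 / np.sqrt(1000)
        )
        assert np.mean([m.mpta_deg for m in ms]) == pytest.approx(
            87.7, abs=3 * 2.6 / np.sqrt(1000)
        )

    def test_emergent_mad_within_envelope(self, study):
        """MAD is not sampled: it must emerge with a physiological spread."""
        mads = [metrics.measure(leg).mad_mm for leg in study["legs"]]
        assert np.mean(np.abs(mads)) < 17.0
        assert 1.0 < np.std(mads) < 21.0
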