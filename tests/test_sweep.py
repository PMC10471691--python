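"""Rotation sweep, closed-form oracles, centralization and cohort comparison."""

import dataclasses

import numpy as np
import pytest

from rotalign import cohort, metrics
from rotalign.sweep import (
    CentralizationResult,
    compare_cohort,
    find_centralization,
    rotate_leg,
    sweep,
)


def rodrigues(points, axis_point, axis_dir, theta_deg):
    """Independent rotation oracle: explicit Rodrigues rotation matrix."""
    k = np.asarray(axis_dir, float)
    k = k / np.linalg.norm(k)
    t = np.deg2rad(theta_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    R = np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)
    p = np.atleast_2d(points) - axis_point
    out = p @ R.T + axis_point
    return out[0] if np.asarray(points).ndim == 1 else out


@pytest.fixture(scope="module")
def tilted_leg(default_params):
    """A default leg with genuine coronal/sagittal tilts (MAD != 0)."""
    return cohort.sample_leg(default_params, "right", np.random.default_rng(21))


class TestRotateLeg:
    def test_rotation_roundtrip_restores_coordinates(self, tilted_leg):
        back = rotate_leg(rotate_leg(tilted_leg, 9.0), -9.0)
        for name in tilted_leg.landmarks:
            assert np.allclose(back.point(name), tilted_leg.point(name), atol=1e-9)

    def test_axis_points_are_fixed(self, tilted_leg):
        rot = rotate_leg(tilted_leg, 12.0, axis="mechanical")
        assert np.allclose(rot.point("FHC"), tilted_leg.point("FHC"), atol=1e-9)
        assert np.allclose(rot.point("AJC"), tilted_leg.point("AJC"), atol=1e-9)

    def test_rigidity(self, tilted_leg):
        rot = rotate_leg(tilted_leg, -13.0)
        names = list(tilted_leg.landmarks)
        for a in names[::2]:
            for b in names[1::2]:
                d0 = np.linalg.norm(tilted_leg.point(a) - tilted_leg.point(b))
                d1 = np.linalg.norm(rot.point(a) - rot.point(b))
                assert d1 == pytest.approx(d0, abs=1e-9)

    def test_external_rotation_moves_anterior_patella_laterally(self, tilted_leg):
        p0 = metrics.measure(tilted_leg, 0.0).patellar_position_mm
        p5 = metrics.measure(tilted_leg, 5.0).patellar_position_mm
        assert p5 < p0

    def test_left_leg_rotation_sense_matches_right(self, tilted_leg):
        left = tilted_leg.mirrored()
        for theta in (-8.0, 8.0):
            a = metrics.measure(tilted_leg, theta).patellar_position_mm
            b = metrics.measure(left, theta).patellar_position_mm
            assert a == pytest.approx(b, abs=1e-9)
        rot = rotate_leg(left, 5.0)
        assert metrics.measure(rot, 0.0).patellar_position_mm == pytest.approx(
            metrics.measure(left, 5.0).patellar_position_mm, abs=1e-9
        )


class TestSweepOracles:
    def test_patellar_deviation_matches_closed_form(self, study):
        """Frame-axis rotation: the projected patellar offset follows
        d0*cos(theta) - a*sin(theta) exactly (no small-angle approximation)."""
        for s, leg in list(zip(study["sweeps"], study["neutral"]))[:10]:
            m0 = metrics.measure(leg)
            d0 = m0.patellar_position_mm
            mid = (leg.point("PLP") + leg.point("PMP")) / 2.0
            a = mid[1] - leg.point("TKC")[1]
            expected = [
                cohort.patellar_shift(t, d0, a) - d0 for t in s.angles
            ]
            assert np.allclose(s.deviations["patellar_position_mm"], expected, atol=1e-6)

    def test_mechanical_axis_sweep_matches_rodrigues_oracle(self, tilted_leg):
        """Tilted-axis rotation agrees with an explicit rotation-matrix oracle."""
        ap = tilted_leg.point("FHC")
        ad = tilted_leg.point("FHC") - tilted_leg.point("AJC")
        for theta in (-15.0, -6.5, 3.0, 15.0):
            rotated = rotate_leg(tilted_leg, theta, axis="mechanical")
            for name in tilted_leg.landmarks:
                expected = rodrigues(tilted_leg.point(name), ap, ad, theta)
                assert np.allclose(rotated.point(name), expected, atol=1e-9)
            m = metrics.measure(tilted_leg, theta, axis="mechanical")
            oracle_pts = {
                n: rodrigues(tilted_leg.point(n), ap, ad, theta)
                for n in ("PLP", "PMP", "TKC")
            }
            expected_pat = metrics.patellar_position(
                metrics.project_coronal(oracle_pts["PLP"]),
                metrics.project_coronal(oracle_pts["PMP"]),
                metrics.project_coronal(oracle_pts["TKC"]),
            )
            assert m.patellar_position_mm == pytest.approx(expected_pat, abs=1e-9)

    def test_patellar_deviation_strictly_monotone(self, study):
        """The anterior offset dominates, so the patellar deviation decreases
        strictly with external rotation for every default leg."""
        for s in study["sweeps"]:
            assert np.all(np.diff(s.deviations["patellar_position_mm"]) < 0)

    def test_planar_leg_angles_rotation_invariant(self, sample_planar_leg):
        base = metrics.measure(sample_planar_leg, 0.0)
        for theta in (-15.0, -5.0, 5.0, 15.0):
            m = metrics.measure(sample_planar_leg, theta)
            assert m.hka_deg == pytest.approx(base.hka_deg, abs=1e-9)
            assert m.mpta_deg == pytest.approx(base.mpta_deg, abs=1e-9)

    def test_axis_choice_changes_headline_numbers_negligibly(self, tilted_leg):
        """Regression guard: frame-axis vs mechanical-axis rotation must stay
        within a small, documented band for the per-leg responses."""
        s_frame = sweep(tilted_leg, axis="frame")
        s_mech = sweep(tilted_leg, axis="mechanical")
        pat_slope = {
            k: np.polyfit(s.angles, s.deviations["patellar_position_mm"], 1)[0]
            for k, s in (("f", s_frame), ("m", s_mech))
        }
        hka_slope = {
            k: np.polyfit(s.angles, s.deviations["hka_deg"], 1)[0]
            for k, s in (("f", s_frame), ("m", s_mech))
        }
        assert abs(pat_slope["f"] - pat_slope["m"]) < 0.03
        assert abs(hka_slope["f"] - hka_slope["m"]) < 0.005


class TestSweepStructure:
    def test_31_positions_with_zero_deviation_at_origin(self, tilted_leg):
        s = sweep(tilted_leg)
        assert len(s.angles) == 31
        assert s.angles[0] == -15 and s.angles[-1] == 15
        i0 = int(np.where(s.angles == 0)[0][0])
        for name, dev in s.deviations.items():
            assert dev[i0] == 0.0
        df = s.to_frame()
        assert len(df) == 31

    def test_cohort_total_positions(self, study):
        assert sum(len(s.angles) for s in study["sweeps"]) == 1860

    def test_grid_must_contain_zero(self, tilted_leg):
        with pytest.raises(ValueError):
            sweep(tilted_leg, angles=[-2, -1, 1, 2])


class TestCentralization:
    def test_centred_patella_needs_no_rotation(self, planar_params):
        p = dataclasses.replace(planar_params, patella_lateral_offset_mean=0.0)
        leg = cohort.sample_leg(p, "right", np.random.default_rng(0))
        res = find_centralization(leg)
        assert res.centralizable
        assert res.theta_c == pytest.approx(0.0, abs=0.01)

    def test_bisection_matches_analytic_root(self, sample_planar_leg):
        res = find_centralization(sample_planar_leg)
        expected = np.degrees(np.arctan2(-8.3, 51.569))
        assert res.theta_c == pytest.approx(expected, abs=0.01)
        assert abs(res.residual_mm) < 0.01

    def test_planar_leg_angle_deltas_vanish(self, sample_planar_leg):
        res = find_centralization(sample_planar_leg)
        assert res.deltas["hka_deg"] == pytest.approx(0.0, abs=1e-9)
        assert res.deltas["mpta_deg"] == pytest.approx(0.0, abs=1e-9)

    def test_default_cohort_all_centralizable(self, study):
        assert all(c.centralizable for c in study["centralizations"])
        for c in study["centralizations"]:
            assert abs(c.residual_mm) < 0.01

    def test_no_sign_change_reported_not_raised(self, sample_planar_leg):
        res = find_centralization(sample_planar_leg, bracket=(5.0, 10.0))
        assert not res.centralizable
        assert res.theta_c in (5.0, 10.0)


class TestCompareCohort:
    def test_identical_legs_have_zero_spread(self):
        r = CentralizationResult(
            "a", -5.0, 0.0,
            {"hka_deg": 0.1, "mad_mm": 0.2, "mpta_deg": -0.1, "patellar_position_mm": 0.0},
        )
        table = compare_cohort([r, dataclasses.replace(r, leg_id="b")])
        assert np.allclose(table.loc["sd"], 0.0)
        assert table.loc["mean", "rotation_deg"] == pytest.approx(-5.0)

    def test_two_leg_mean(self):
        deltas = {"hka_deg": 0.0, "mad_mm": 0.0, "mpta_deg": 0.0,
                  "patellar_position_mm": 0.0}
        rs = [
            CentralizationResult("a", -5.0, 0.0, deltas),
            CentralizationResult("b", -15.0, 0.0, deltas),
        ]
        table = compare_cohort(rs)
        assert table.loc["mean", "rotation_deg"] == pytest.approx(-10.0)
        assert table.loc["max_alteration_internal", "rotation_deg"] == pytest.approx(-15.0)

    def test_requires_two_centralizable_legs(self):
        r = CentralizationResult("a", -5.0, 0.0, {}, centralizable=False)
        with pytest.raises(ValueError):
            compare_cohort([r, r])
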