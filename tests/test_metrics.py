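"""Space-curve fitting and per-point fibre metrics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fibredvc.fibres import FibrePolyline
from fibredvc.metrics import (
    compute_metrics,
    curvature_at,
    delta_metrics,
    displacement_gradient_at,
    fit_space_curve,
    lagrange_strain,
    orientation_at,
    tangent_at,
    wrap_angle_difference,
)
from fibredvc.phantom import analytic_curve
from fibredvc.seeding import FibrePointCloud, seed_points


def cloud_from_curve(fb: FibrePolyline, spacing: float = 8.0) -> FibrePointCloud:
    return seed_points([fb], spacing=spacing)


def unit_disp_table(cloud: FibrePointCloud, uvw_vox: np.ndarray, residual: float = 1e-4) -> pd.DataFrame:
    n = len(cloud)
    uvw = np.broadcast_to(uvw_vox, (n, 3))
    return pd.DataFrame(
        {
            "n": cloud.points["n"],
            "u": uvw[:, 0],
            "v": uvw[:, 1],
            "w": uvw[:, 2],
            "residual": residual,
            "converged": True,
            "n_iter": 3,
            "status": 0,
        }
    )


class TestFitSpaceCurve:
    def test_exact_cubic_recovers_coefficients(self):
        s = np.linspace(0.0, 9.0, 10)
        x = 2 * s**3 - s + 5
        pos = np.stack([x, np.zeros_like(s), np.zeros_like(s)], axis=1)
        fit = fit_space_curve(s, pos)
        np.testing.assert_allclose(fit.coeffs[0], [2.0, 0.0, -1.0, 5.0], atol=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.mean_residual_vox == pytest.approx(0.0, abs=1e-9)

    def test_huge_residual_point_is_effectively_ignored(self):
        s = np.arange(10.0)
        pos = np.stack([s, 0.1 * s, np.zeros_like(s)], axis=1)
        pos_out = pos.copy()
        pos_out[4] += (0.0, 5.0, 0.0)  # outlier
        residuals = np.full(10, 1e-4)
        residuals[4] = 1e2  # 10^6 x the others
        w = 1.0 / residuals
        fit_out = fit_space_curve(s, pos_out, w)
        fit_ref = fit_space_curve(np.delete(s, 4), np.delete(pos, 4, axis=0))
        eval_s = np.linspace(0, 9, 25)
        np.testing.assert_allclose(fit_out.position(eval_s), fit_ref.position(eval_s), atol=1e-3)

    def test_short_circle_arc_residual_below_point1_percent_of_radius(self):
        R = 100.0
        arc = analytic_curve("circle", {"radius": R}, n_points=20, spacing=R * np.radians(30) / 19)
        s = arc.arc_lengths()
        fit = fit_space_curve(s, arc.vertices, voxel_size=1.0)
        # analytic distance of each fitted point from the true circle
        fitted = fit.position(s)
        dist = np.abs(np.linalg.norm(fitted[:, [0, 2]], axis=1) - R)
        assert dist.mean() < 1e-3 * R

    def test_too_few_or_coincident_points_rejected(self):
        s = np.array([0.0, 1.0, 2.0])
        pos = np.zeros((3, 3))
        with pytest.raises(ValueError, match=">= 4 points"):
            fit_space_curve(s, pos)
        s4 = np.array([0.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_space_curve(s4, np.zeros((4, 3)))


class TestTangent:
    def test_line_tangent_constant(self):
        fb = analytic_curve("line", {"direction": (1, 0, 0)}, 10, 8.0)
        fit = fit_space_curve(fb.arc_lengths(), fb.vertices)
        t = tangent_at(fit, np.array([0.0, 30.0, 70.0]))
        np.testing.assert_allclose(t, [[1, 0, 0]] * 3, atol=1e-9)

    def test_helix_tangent_within_half_degree_at_midspan(self):
        # short arc (~1 rad of turn) so a cubic approximates the helix well
        fb = analytic_curve("helix", {"radius": 3.0, "pitch": 4.0}, 12, 0.5)
        s = fb.arc_lengths()
        fit = fit_space_curve(s, fb.vertices)
        mid = len(s) // 2
        t = tangent_at(fit, s[mid : mid + 1])[0]
        angle = np.degrees(np.arccos(np.clip(np.dot(t, fb.true_tangent[mid]), -1, 1)))
        assert angle < 0.5

    def test_reversing_point_order_flips_tangent(self):
        fb = analytic_curve("helix", {"radius": 5.0, "pitch": 2.0}, 10, 2.0)
        s = fb.arc_lengths()
        fit_fwd = fit_space_curve(s, fb.vertices)
        fit_rev = fit_space_curve(s, fb.vertices[::-1])
        t_f = tangent_at(fit_fwd, s[5:6])[0]
        t_r = tangent_at(fit_rev, (s[-1] - s)[5:6])[0]
        np.testing.assert_allclose(t_f, -t_r, atol=1e-6)


class TestCurvature:
    def test_line_curvature_zero(self):
        fb = analytic_curve("line", {"direction": (1, 2, 3)}, 10, 8.0)
        fit = fit_space_curve(fb.arc_lengths(), fb.vertices)
        np.testing.assert_allclose(curvature_at(fit, fb.arc_lengths()), 0.0, atol=1e-12)

    def test_circle_curvature_one_over_radius(self):
        R = 100.0
        fb = analytic_curve("circle", {"radius": R}, 20, R * np.radians(30) / 19)
        s = fb.arc_lengths()
        fit = fit_space_curve(s, fb.vertices)
        k_mid = curvature_at(fit, s[9:11])
        np.testing.assert_allclose(k_mid, 1.0 / R, rtol=0.02)

    def test_helix_curvature_closed_form(self):
        fb = analytic_curve("helix", {"radius": 3.0, "pitch": 4.0}, 14, 0.5)
        s = fb.arc_lengths()
        fit = fit_space_curve(s, fb.vertices)
        k_mid = curvature_at(fit, s[6:8])
        np.testing.assert_allclose(k_mid, 0.12, rtol=0.05)


class TestOrientation:
    @pytest.mark.parametrize(
        "t, expected",
        [
            ((1.0, 0.0, 0.0), 0.0),
            ((0.0, 0.0, 1.0), 90.0),
            ((1 / np.sqrt(2), 0.0, 1 / np.sqrt(2)), 45.0),
            ((-1 / np.sqrt(2), 0.0, 1 / np.sqrt(2)), 135.0),  # mirrored family
            ((np.cos(np.radians(30)), 0.0, np.sin(np.radians(30))), 30.0),
            ((np.cos(np.radians(30)), 0.0, -np.sin(np.radians(30))), 150.0),
        ],
    )
    def test_fixture_angles(self, t, expected):
        assert orientation_at(np.array([t]))[0] == pytest.approx(expected, abs=1e-9)

    def test_antipodal_tangents_equal_theta(self):
        rng = np.random.default_rng(4)
        t = rng.normal(size=(50, 3))
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        np.testing.assert_allclose(orientation_at(t), orientation_at(-t), atol=1e-9)

    def test_non_unit_tangent_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            orientation_at(np.array([[2.0, 0.0, 0.0]]))


class TestDisplacementGradientAndStrain:
    def test_uniform_translation_gives_zero_gradient(self):
        s = np.arange(10.0) * 8.0
        disp = np.tile([3.0, -2.0, 1.0], (10, 1))
        t = np.tile([1.0, 0.0, 0.0], (10, 1))
        m, r2 = displacement_gradient_at(s, disp, t)
        np.testing.assert_allclose(m, 0.0, atol=1e-12)

    def test_linear_stretch_field_gives_constant_gradient(self):
        s = np.arange(10.0) * 8.0
        disp = np.stack([0.02 * s, np.zeros_like(s), np.zeros_like(s)], axis=1)
        t = np.tile([1.0, 0.0, 0.0], (10, 1))
        m, r2 = displacement_gradient_at(s, disp, t)
        np.testing.assert_allclose(m, 0.02, atol=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_lagrange_strain_identities(self):
        assert lagrange_strain(0.0) == 0.0
        assert lagrange_strain(0.02) == pytest.approx(0.0202, abs=1e-15)
        lam = 0.98
        np.testing.assert_allclose(lagrange_strain(lam - 1.0), (lam**2 - 1) / 2, atol=1e-15)
        assert lagrange_strain(lam - 1.0) == pytest.approx(-0.0198, abs=1e-12)

    def test_strain_never_below_algebraic_minimum(self):
        m = np.linspace(-5, 5, 201)
        assert (lagrange_strain(m) >= -0.5).all()


class TestComputeMetrics:
    def test_unit_tangents_and_nonnegative_curvature(self):
        fb = analytic_curve("helix", {"radius": 40.0, "pitch": 30.0}, 16, 8.0)
        met = compute_metrics(cloud_from_curve(fb))
        t = met[["tx", "ty", "tz"]].to_numpy()
        np.testing.assert_allclose(np.linalg.norm(t, axis=1), 1.0, atol=1e-9)
        assert (met["k"] >= 0).all()

    def test_end_points_flagged(self):
        fb = analytic_curve("line", {"direction": (1, 0, 0)}, 10, 8.0)
        met = compute_metrics(cloud_from_curve(fb))
        flags = met.sort_values("p")["flag"].to_numpy()
        assert flags[0] and flags[-1]
        assert not flags[1:-1].any()
        assert flags.mean() == pytest.approx(2 / len(met))


class TestDeltaMetrics:
    def test_rigid_translation_changes_nothing(self):
        fb = analytic_curve("circle", {"radius": 150.0}, 12, 8.0)
        cloud = cloud_from_curve(fb)
        disp = unit_disp_table(cloud, np.array([2.0, -1.0, 0.5]))
        out = delta_metrics(cloud, disp)
        np.testing.assert_allclose(out["dk"], 0.0, atol=1e-6)
        np.testing.assert_allclose(out["dtheta"], 0.0, atol=1e-6)

    def test_rotation_about_height_axis_preserves_elevation(self):
        # rotating in the transverse plane cannot change the angle from it
        fb = analytic_curve(
            "line", {"direction": (np.cos(np.radians(30)), 0, np.sin(np.radians(30))), "start": (50, 50, 50)}, 10, 8.0
        )
        cloud = cloud_from_curve(fb)
        pos = cloud.points[["x", "y", "z"]].to_numpy()
        ang = np.radians(5.0)
        R = np.array([[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        disp_vox = (pos @ R.T - pos) / cloud.voxel_size
        disp = unit_disp_table(cloud, np.zeros(3))
        disp[["u", "v", "w"]] = disp_vox
        out = delta_metrics(cloud, disp)
        np.testing.assert_allclose(out["dtheta"], 0.0, atol=1e-6)
        np.testing.assert_allclose(out["dk"], 0.0, atol=1e-9)

    def test_inplane_rotation_changes_theta_by_rotation_angle(self):
        # rotation about the lamella normal (y) tilts the fibre out of the
        # transverse plane by exactly the rotation angle; curvature invariant
        for base, sign in ((30.0, 1.0), (-30.0, 1.0)):
            d = (np.cos(np.radians(base)), 0.0, np.sin(np.radians(base)))
            fb = analytic_curve("line", {"direction": d, "start": (100, 100, 100)}, 10, 8.0)
            cloud = cloud_from_curve(fb)
            pos = cloud.points[["x", "y", "z"]].to_numpy()
            ang = np.radians(5.0)
            R = np.array([[np.cos(ang), 0, -np.sin(ang)], [0, 1, 0], [np.sin(ang), 0, np.cos(ang)]])
            disp = unit_disp_table(cloud, np.zeros(3))
            disp[["u", "v", "w"]] = (pos @ R.T - pos) / cloud.voxel_size
            out = delta_metrics(cloud, disp)
            assert np.allclose(np.abs(out["dtheta"]), 5.0, atol=0.3)
            np.testing.assert_allclose(out["dk"], 0.0, atol=1e-6)

    def test_rigid_motion_equivariance_of_curvature_and_strain(self):
        # applying one rigid transform to both configurations (reference
        # positions and their displaced counterparts) must leave k and L
        # unchanged: the per-axis least-squares fit is equivariant under
        # rotation and translation
        fb = analytic_curve("helix", {"radius": 60.0, "pitch": 40.0}, 14, 8.0)
        cloud = cloud_from_curve(fb)
        pos = cloud.points[["x", "y", "z"]].to_numpy()
        disp = unit_disp_table(cloud, np.array([1.5, -0.8, 0.4]))
        rng = np.random.default_rng(6)
        disp[["u", "v", "w"]] += 0.05 * rng.normal(size=(len(cloud), 3))
        met = compute_metrics(cloud, displacements=disp)

        ang = np.radians(11.0)
        R = np.array([[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        shift = np.array([13.0, -4.0, 7.0])
        moved_pts = cloud.points.copy()
        moved_pts[["x", "y", "z"]] = pos @ R.T + shift
        cloud_r = FibrePointCloud(moved_pts, cloud.spacing, cloud.voxel_size)
        disp_r = disp.copy()
        disp_r[["u", "v", "w"]] = disp[["u", "v", "w"]].to_numpy() @ R.T
        met_r = compute_metrics(cloud_r, displacements=disp_r)
        np.testing.assert_allclose(met_r["k"], met["k"], atol=1e-6)
        np.testing.assert_allclose(met_r["L"], met["L"], atol=1e-6)


class TestAngleWrap:
    def test_wrap_to_half_open_interval(self):
        np.testing.assert_allclose(wrap_angle_difference([170.0]), [-10.0])
        np.testing.assert_allclose(wrap_angle_difference([-170.0]), [10.0])
        np.testing.assert_allclose(wrap_angle_difference([90.0]), [90.0])
        np.testing.assert_allclose(wrap_angle_difference([-90.0]), [90.0])
        np.testing.assert_allclose(wrap_angle_difference([5.0, -5.0]), [5.0, -5.0])
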