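"""Ray tracing, calibration LUT and optical-PSA simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psakit import optics
from psakit.optics import (CameraModel, EyeGeometry, EyeState,
                           TotalInternalReflectionError, apparent_angle,
                           brute_force_surface_param, build_calibration_lut,
                           ellipsoidal_variant, perceived_pupil_center,
                           refract, simulate_psa, snell_residual,
                           trace_pupil_ray)


# ---------------------------------------------------------------------------
# refraction
# ---------------------------------------------------------------------------


class TestRefract:
    def test_normal_incidence_passes_straight(self):
        out = refract([0.0, 1.0], [0.0, 1.0], 1.0, 1.336)
        np.testing.assert_allclose(out, [0.0, 1.0], atol=1e-12)

    def test_equal_indices_identity(self):
        v = np.array([np.cos(0.3), np.sin(0.3)])
        out = refract(v, [1.0, 0.0], 1.4, 1.4)
        np.testing.assert_allclose(out, v, atol=1e-12)

    def test_snell_closed_form_30deg(self):
        # air -> aqueous at 30 deg: theta_t = arcsin(sin(30)/1.336)
        ti = np.radians(30.0)
        incident = [np.sin(ti), -np.cos(ti)]  # heading into the surface
        out = refract(incident, [0.0, 1.0], 1.0, 1.336)
        expected_tt = np.arcsin(np.sin(ti) / 1.336)
        got_tt = np.arctan2(abs(out[0]), abs(out[1]))
        assert got_tt == pytest.approx(expected_tt, abs=1e-12)

    def test_total_internal_reflection_detected(self):
        ti = np.radians(60.0)  # beyond critical angle for 1.336 -> 1.0
        incident = [np.sin(ti), -np.cos(ti)]
        with pytest.raises(TotalInternalReflectionError):
            refract(incident, [0.0, 1.0], 1.336, 1.0)

    def test_normal_sign_irrelevant(self):
        ti = np.radians(20.0)
        incident = [np.sin(ti), -np.cos(ti)]
        a = refract(incident, [0.0, 1.0], 1.0, 1.336)
        b = refract(incident, [0.0, -1.0], 1.0, 1.336)
        np.testing.assert_allclose(a, b, atol=1e-14)

    @settings(deadline=None, max_examples=50)
    @given(ti=st.floats(0.01, 0.9), n1=st.floats(1.0, 1.35),
           n2=st.floats(1.336, 1.6))
    def test_snell_law_holds(self, ti, n1, n2):
        incident = [np.sin(ti), -np.cos(ti)]
        out = refract(incident, [0.0, 1.0], n1, n2)
        assert n1 * np.sin(ti) == pytest.approx(n2 * abs(out[0]), abs=1e-12)
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# pupil-ray tracing
# ---------------------------------------------------------------------------


class TestTracePupilRay:
    def test_zero_angle_mirror_symmetry(self, geometry, camera):
        eye = EyeState(geometry, 0.0, 4.0)
        near = trace_pupil_ray(eye, camera, "near")
        far = trace_pupil_ray(eye, camera, "far")
        assert near == pytest.approx(-far, abs=1e-12)
        assert 0.5 * (near + far) == pytest.approx(0.0, abs=1e-12)

    def test_shrinking_pupil_converges(self, geometry, camera):
        gaps = []
        for d in (2.0, 0.5, 0.1, 0.02):
            eye = EyeState(geometry, 8.0, d)
            gaps.append(abs(trace_pupil_ray(eye, camera, "far")
                            - trace_pupil_ray(eye, camera, "near")))
        assert all(np.diff(gaps) < 0)
        # the near/far image gap shrinks proportionally to the diameter
        assert gaps[-1] < gaps[0] * (0.02 / 2.0) * 1.5

    @pytest.mark.parametrize("elliptical", [False, True])
    def test_solver_matches_brute_force_search(self, camera, elliptical):
        geometry = (ellipsoidal_variant() if elliptical else EyeGeometry())
        rng = np.random.default_rng(42)
        for _ in range(25):
            th = rng.uniform(-15, 15)
            off = rng.uniform(-3, 3)
            phi, status = optics._solve_surface_params(
                geometry, camera, np.array([th]), np.array([off]))
            assert status[0] == 0
            phi_bf = brute_force_surface_param(geometry, camera, th, off)
            assert abs(phi[0] - phi_bf) <= 1e-6

    def test_snell_residual_below_tolerance(self, geometry, camera):
        rng = np.random.default_rng(1)
        for _ in range(20):
            th = rng.uniform(-15, 15)
            off = rng.uniform(-3, 3)
            phi, status = optics._solve_surface_params(
                geometry, camera, np.array([th]), np.array([off]))
            assert status[0] == 0
            assert snell_residual(geometry, camera, th, off,
                                  phi[0]) <= 1e-10


class TestPerceivedCenter:
    def test_zero_angle_center_on_axis(self, geometry, camera):
        for d in (2.0, 4.0, 6.0):
            res = perceived_pupil_center(EyeState(geometry, 0.0, d), camera)
            assert res.ok
            assert res.perceived_center == pytest.approx(0.0, abs=1e-12)

    def test_mirror_antisymmetry(self, geometry, camera):
        for th in (3.0, 9.0, 15.0):
            a = perceived_pupil_center(EyeState(geometry, th, 5.0), camera)
            b = perceived_pupil_center(EyeState(geometry, -th, 5.0), camera)
            assert a.perceived_center == pytest.approx(-b.perceived_center,
                                                       abs=1e-12)

    def test_mean_of_two_rays(self, geometry, camera):
        eye = EyeState(geometry, 7.0, 3.0)
        res = perceived_pupil_center(eye, camera)
        assert res.perceived_center == pytest.approx(
            0.5 * (res.near_ray_image_pos + res.far_ray_image_pos))

    def test_extreme_perimeter_rays_bound_interior(self, geometry, camera):
        """In 2-D the perimeter consists of the two edge points; rays from
        interior pupil points must land between the two edge rays."""
        eye = EyeState(geometry, 10.0, 6.0)
        near_off, far_off = optics._near_far_offsets(eye, camera)
        edges = []
        interior = []
        for off in np.linspace(near_off, far_off, 9):
            pos, status = optics._trace_offsets(
                geometry, camera, np.array([eye.viewing_angle]),
                np.array([off]))
            assert status[0] == 0
            (edges if off in (near_off, far_off) else interior).append(pos[0])
        lo, hi = min(edges), max(edges)
        assert all(lo <= p <= hi for p in interior)


# ---------------------------------------------------------------------------
# calibration LUT
# ---------------------------------------------------------------------------


class TestCalibrationLUT:
    def test_default_grid_length(self, geometry, camera):
        lut = build_calibration_lut(geometry, camera, angle_min=-1.0,
                                    angle_max=1.0, step=0.001)
        assert lut.angle_grid.size == 2001  # (2/0.001)+1
        # and the full default span works out to (40/0.001)+1
        n_default = int(round((20.0 - -20.0) / 0.001)) + 1
        assert n_default == 40001

    def test_monotone_positions(self, coarse_lut):
        assert np.all(np.diff(coarse_lut.center_positions) > 0)

    def test_round_trip_on_grid(self, coarse_lut):
        idx = np.arange(0, coarse_lut.angle_grid.size, 97)
        got = apparent_angle(coarse_lut, coarse_lut.center_positions[idx])
        np.testing.assert_allclose(got, coarse_lut.angle_grid[idx],
                                   atol=coarse_lut.step)

    def test_midpoint_interpolation(self, coarse_lut):
        j = 500
        mid = 0.5 * (coarse_lut.center_positions[j]
                     + coarse_lut.center_positions[j + 1])
        expect = 0.5 * (coarse_lut.angle_grid[j]
                        + coarse_lut.angle_grid[j + 1])
        assert apparent_angle(coarse_lut, mid) == pytest.approx(expect,
                                                                abs=1e-12)

    def test_out_of_range_raises(self, coarse_lut):
        with pytest.raises(ValueError):
            apparent_angle(coarse_lut, coarse_lut.center_positions[-1] + 1.0)

    def test_coarse_vs_fine_grid_agreement(self, geometry, camera):
        coarse = build_calibration_lut(geometry, camera, angle_min=-5.0,
                                       angle_max=5.0, step=0.1)
        fine = build_calibration_lut(geometry, camera, angle_min=-5.0,
                                     angle_max=5.0, step=0.001)
        rng = np.random.default_rng(3)
        pos = rng.uniform(coarse.center_positions[0],
                          coarse.center_positions[-1], 50)
        diff = np.abs(apparent_angle(coarse, pos) - apparent_angle(fine, pos))
        assert diff.max() <= 0.1

    def test_inverse_against_root_finder(self, geometry, camera, coarse_lut):
        """apparent_angle agrees with a monotone-inverse root finder on the
        forward model itself (not the table)."""
        from scipy.optimize import brentq

        def forward(theta):
            res = perceived_pupil_center(
                EyeState(geometry, theta, coarse_lut.calibration_pupil_diameter),
                camera)
            return res.perceived_center

        rng = np.random.default_rng(5)
        for pos in rng.uniform(coarse_lut.center_positions[0],
                               coarse_lut.center_positions[-1], 5):
            th_root = brentq(lambda t: forward(t) - pos, -20.0, 20.0,
                             xtol=1e-10)
            assert abs(apparent_angle(coarse_lut, pos)
                       - th_root) <= coarse_lut.step


# ---------------------------------------------------------------------------
# PSA simulation
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def result(geometry, camera, coarse_lut):
    return simulate_psa(geometry, camera, lut=coarse_lut,
                        pupil_grid=np.arange(2.0, 6.01, 0.25))


class TestSimulatePsa:
    def test_zero_deviation_at_calibration_pupil(self, result, coarse_lut):
        j = int(np.argmin(np.abs(result.pupil_grid - 4.0)))
        assert result.pupil_grid[j] == 4.0
        np.testing.assert_allclose(result.deviations[:, j], 0.0,
                                   atol=2 * coarse_lut.step)

    def test_zero_artefact_at_zero_angle(self, result, coarse_lut):
        i = int(np.argmin(np.abs(result.viewing_angles)))
        np.testing.assert_allclose(result.deviations[i], 0.0,
                                   atol=2 * coarse_lut.step)

    def test_slope_antisymmetry(self, result):
        assert result.slopes[0] == pytest.approx(-result.slopes[-1],
                                                 abs=1e-6)
        assert result.slopes[1] == pytest.approx(-result.slopes[-2],
                                                 abs=1e-6)
        i = int(np.argmin(np.abs(result.viewing_angles)))
        assert result.slopes[i] == pytest.approx(0.0, abs=1e-6)

    def test_deviation_antisymmetry(self, result):
        np.testing.assert_allclose(result.deviations[0],
                                   -result.deviations[-1], atol=1e-6)

    def test_summary_and_frame(self, result):
        s = result.summary()
        assert "deg/mm" in s.replace("[deg/mm]", "deg/mm")
        df = result.to_frame()
        assert len(df) == result.viewing_angles.size * result.pupil_grid.size


class TestEllipsoidalVariant:
    def test_equal_axes_degenerate_to_sphere(self, camera):
        sphere = EyeGeometry()
        ellipse = ellipsoidal_variant(7.8, 7.8)
        for th in (-9.0, 4.0, 12.0):
            for d in (2.5, 5.5):
                a = perceived_pupil_center(EyeState(sphere, th, d), camera)
                b = perceived_pupil_center(EyeState(ellipse, th, d), camera)
                assert a.perceived_center == pytest.approx(
                    b.perceived_center, abs=1e-9)

    def test_full_sweep_runs_without_failures(self, camera):
        res = simulate_psa(ellipsoidal_variant(), camera, lut_step=0.02,
                           pupil_grid=np.arange(2.0, 6.01, 0.5))
        assert np.all(np.isfinite(res.deviations))
        assert np.all(np.isfinite(res.slopes))

    def test_slope_signs_reported(self, camera, capsys):
        """The variant's slope directions are reported alongside the
        spherical model's rather than asserted (their sign depends on the
        corneal asphericity chosen)."""
        sph = simulate_psa(EyeGeometry(), camera, lut_step=0.05,
                           viewing_angles=[-12.0, 12.0],
                           pupil_grid=[2.0, 4.0, 6.0])
        ell = simulate_psa(ellipsoidal_variant(), camera, lut_step=0.05,
                           viewing_angles=[-12.0, 12.0],
                           pupil_grid=[2.0, 4.0, 6.0])
        print(f"spherical slopes: {sph.slopes}; "
              f"ellipsoidal slopes: {ell.slopes}")
        assert sph.slopes.shape == ell.slopes.shape == (2,)

    def test_degenerate_ellipse_rejected(self):
        with pytest.raises(ValueError):
            ellipsoidal_variant(-1.0, 8.0)


class TestValidation:
    def test_geometry_invariants(self):
        with pytest.raises(ValueError):
            EyeGeometry(corneal_radius=-1.0)
        with pytest.raises(ValueError):
            EyeGeometry(n_inside=0.9)
        with pytest.raises(ValueError):
            EyeGeometry(pupil_plane_depth=20.0)

    def test_state_invariants(self, geometry):
        with pytest.raises(ValueError):
            EyeState(geometry, 25.0, 4.0)
        with pytest.raises(ValueError):
            EyeState(geometry, 0.0, 20.0)

    def test_camera_invariants(self):
        with pytest.raises(ValueError):
            CameraModel(pinhole_distance=-5.0)
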