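"""Geometry, temporal profile, rotation law and material motion."""

import numpy as np
import pytest

from lvste import kinematics as K


class TestMaterialLaw:
    def test_zero_strain_zero_stress(self):
        assert K.stress_strain(0.0) == 0.0

    def test_exponential_doubling_point(self):
        # strain chosen so the exponential term equals 2
        eps = np.log(2.0) / 10.25
        assert K.stress_strain(eps) == pytest.approx(7525.8, rel=1e-12)

    def test_direct_evaluation(self):
        assert K.stress_strain(0.1) == pytest.approx(
            7525.8 * (np.exp(1.025) - 1.0), rel=1e-12)

    def test_strictly_monotone(self):
        eps = np.linspace(-0.5, 0.5, 101)
        assert np.all(np.diff(K.stress_strain(eps)) > 0)


class TestTemporalProfile:
    def test_cycle_endpoints_and_peak(self):
        assert K.norm_profile(0.0) == 0.0
        assert K.norm_profile(0.370) == 1.0
        assert K.norm_profile(K.N_FRAMES / K.FPS) == 0.0

    def test_outside_cycle_rejected(self):
        with pytest.raises(ValueError):
            K.norm_profile(-0.01)
        with pytest.raises(ValueError):
            K.norm_profile(1.2)

    def test_peak_frame_is_nearest_nominal_peak_time(self):
        t_es = K.end_systole_frame()
        times = K.frame_times()
        assert t_es == int(np.argmin(np.abs(times - 0.370))) + 1
        assert K.frame_norm()[t_es - 1] == 1.0

    def test_rise_monotone(self):
        t = np.linspace(0, 0.36, 40)
        assert np.all(np.diff(K.norm_profile(t)) > 0)


class TestGeometry:
    def test_es_semi_axes_are_reference_values(self):
        g = K.geometry_at_phase(1.0)
        assert (g.a_int, g.b_int, g.a_ext, g.b_ext) == (72.0, 15.75, 85.5, 29.25)

    def test_ed_calibration(self):
        g = K.geometry_at_phase(0.0)
        assert g.b_int == 23.0
        assert g.cavity_volume_cm3 == pytest.approx(94.5, rel=1e-9)

    def test_cavity_volume_examples(self):
        assert round(K.cavity_volume(72.0, 15.75), 1) == 37.4
        # hemisphere with unit semi-axes
        assert K.cavity_volume(1.0, 1.0) * 1000 == pytest.approx(2 * np.pi / 3)
        # invert for the long axis given b = 23 mm and V = 94.5 cm^3
        a = 3 * 94.5e3 / (2 * np.pi * 23.0 ** 2)
        assert a == pytest.approx(85.3, abs=0.05)
        with pytest.raises(ValueError):
            K.cavity_volume(-1.0, 2.0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            K.SpheroidGeometry(10.0, 20.0, 30.0, 40.0)
        with pytest.raises(ValueError):
            K.SpheroidGeometry(70.0, 20.0, 60.0, 30.0)

    def test_wall_volume_monotone_with_phase(self):
        # compressible wall: volume shrinks smoothly toward peak contraction
        s = np.linspace(0, 1, 11)
        v = [K.geometry_at_phase(x).wall_volume_mm3 for x in s]
        assert np.all(np.diff(v) < 0)
        assert v[0] / v[-1] == pytest.approx(K.WALL_VOLUME_RATIO_ED, rel=1e-6)


class TestRotation:
    def test_zero_when_profile_zero(self):
        assert K.rotation_angle(30.0, 80.0, 0.0) == 0.0

    def test_peak_values_at_level_sixths(self):
        la = 85.0
        t_peak = 24 / 65
        assert K.rotation_angle(la / 6, la, t_peak) == pytest.approx(6.9)
        assert K.rotation_angle(5 * la / 6, la, t_peak) == pytest.approx(-13.0)

    def test_affine_in_level(self):
        la = 80.0
        x = np.array([10.0, 35.0, 60.0])
        th = K.rotation_angle(x, la, 0.2)
        assert th[1] - th[0] == pytest.approx(th[2] - th[1], rel=1e-12)

    def test_invalid_lax_length(self):
        with pytest.raises(ValueError):
            K.rotation_angle(10.0, 0.0, 0.2)


class TestKinematicField:
    def test_reference_frame_is_zero(self, field):
        pts = np.array([[25.0, 3.0, -40.0], [29.0, -4.0, -15.0]])
        assert np.abs(field.displacement(pts, 1)).max() < 1e-12

    def test_cycle_closure(self, field):
        pts = np.array([[25.0, 3.0, -40.0], [14.0, 8.0, -70.0]])
        assert np.abs(field.displacement(pts, 65)).max() < 1e-9

    def test_apex_stays_on_axis(self, field):
        g = field.ed_shape.geometry
        apex = np.array([[1e-9, 0.0, -0.5 * (g.a_int + g.a_ext)]])
        u = field.displacement(apex, field.t_es)
        assert np.abs(u[0, :2]).max() < 1e-6

    def test_outside_wall_rejected(self, field):
        with pytest.raises(ValueError):
            field.displacement(np.array([[0.0, 0.0, -40.0]]), 10)

    def test_material_coordinate_roundtrip(self, field):
        rng = np.random.default_rng(3)
        pts = np.column_stack([rng.uniform(24, 30, 50),
                               rng.uniform(-3, 3, 50),
                               rng.uniform(-30, -5, 50)])
        sel = field.ed_shape.contains(np.hypot(pts[:, 0], pts[:, 1]), pts[:, 2])
        pts = pts[sel]
        back = field.position_from_coords(field.material_coords(pts), 1)
        assert np.abs(back - pts).max() < 1e-9

    def test_deformation_gradient_matches_finite_differences(self, field):
        pts = np.array([[25.0, 3.0, -40.0], [29.0, -4.0, -15.0],
                        [14.0, 8.0, -70.0], [2.0, 1.0, -90.0]])
        f_an = field.deformation_gradient(pts, 20)

        def fd(h):
            out = np.zeros_like(f_an)
            for k in range(3):
                e = np.zeros(3)
                e[k] = h
                out[:, :, k] = (field.position(pts + e, 20)
                                - field.position(pts - e, 20)) / (2 * h)
            return out

        # Richardson extrapolation removes the O(h^2) truncation of the
        # 0.1 mm central difference
        f_fd = (4.0 * fd(0.05) - fd(0.1)) / 3.0
        rel = np.abs(f_an - f_fd).max() / np.abs(f_an).max()
        assert rel < 1e-6

    def test_avpd_zeroes_band_mean(self, field):
        # volume-weighted longitudinal displacement over the correction band
        # vanishes after the correction
        shape = field.shape_at_frame(field.t_es)
        d = np.linspace(0.0, 1.0, 24)
        m = np.linspace(0.0, 1.0, 900)
        dd, mm = np.meshgrid(d, m, indexing="ij")
        _, z0 = field.ed_shape.wall_point(dd, mm)
        rho1, z1, drdd, dzdd, drdm, dzdm = shape.wall_point_and_jac(dd, mm)
        la = shape.geometry.a_int
        x_p = z1 + la
        band = (x_p >= 0.15 * la) & (x_p <= 0.25 * la)
        w = (rho1 * np.abs(drdd * dzdm - dzdd * drdm))[band]
        uz = (z1 - z0)[band] + field.avpd_offset(field.t_es)
        assert abs(np.average(uz, weights=w)) < 0.05

    def test_basal_displacement_in_reference_range(self, field):
        g = field.ed_shape.geometry
        base = np.array([[0.5 * (g.b_int + g.b_ext), 0.0, 0.0]])
        uz = field.displacement(base, field.t_es)[0, 2]
        assert -20.4 < uz < -5.2


class TestAvpdCorrect:
    def test_zero_band_mean_is_identity(self):
        x_p = np.linspace(5, 60, 40)
        u = np.zeros((40, 3))
        u[:, 2] = np.sin(x_p)
        la = 70.0
        band = (x_p >= 0.15 * la) & (x_p <= 0.25 * la)
        u[band, 2] -= u[band, 2].mean()
        out = K.avpd_correct(u, x_p, la)
        assert np.allclose(out, u)

    def test_uniform_offset_invariance(self):
        rng = np.random.default_rng(0)
        x_p = rng.uniform(0, 70, 200)
        u = rng.standard_normal((200, 3))
        out1 = K.avpd_correct(u, x_p, 70.0)
        shifted = u.copy()
        shifted[:, 2] += 5.0
        out2 = K.avpd_correct(shifted, x_p, 70.0)
        assert np.allclose(out1, out2)

    def test_linear_field_vanishes_at_band_centroid(self):
        x_p = np.linspace(0, 70, 701)
        u = np.zeros((701, 3))
        u[:, 2] = 2.0 * x_p
        out = K.avpd_correct(u, x_p, 70.0)
        la = 70.0
        band = (x_p >= 0.15 * la) & (x_p <= 0.25 * la)
        centroid = x_p[band].mean()
        i = np.argmin(np.abs(x_p - centroid))
        assert abs(out[i, 2]) < 1e-9

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            K.avpd_correct(np.zeros((5, 3)), np.full(5, 60.0), 70.0)
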