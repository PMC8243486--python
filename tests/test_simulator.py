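"""Sector configurations, scatterer phantom and PSF-convolution renderer."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.signal import hilbert

from lvste.kinematics import KinematicField
from lvste.simulator import (PSFModel, advect, default_density, depth_samples,
                             envelope, make_mask, make_plane, render_frame,
                             seed_scatterers, simulate_view)
from lvste.views import all_views, make_view


class TestViews:
    def test_full_a2c_row(self):
        v = make_view(5)
        assert v.projection == "A2C"
        assert v.imaged_segments == (1, 4, 7, 10, 13, 15, 17)
        assert (v.d_min, v.d_max, v.width) == (0.5, 11.4, 90.0)
        assert v.view_type == "Full" and v.fps == 65.0

    def test_full_psaxm_row(self):
        v = make_view(1)
        assert v.projection == "pSAXM"
        assert v.imaged_segments == (7, 8, 9, 10, 11, 12)
        assert v.width == 60.0 and v.view_type == "Full"

    def test_unknown_view_rejected(self):
        with pytest.raises(ValueError):
            make_view(0)

    def test_focus_depth_is_mid_sector(self):
        for n in all_views():
            v = make_view(n)
            assert v.focus_depth == pytest.approx((v.d_min + v.d_max) / 2,
                                                  abs=1e-9)

    def test_scaling_reduces_lines(self):
        v = make_view(1).scaled(0.25)
        assert v.n_lines == round(106 * 0.25)
        with pytest.raises(ValueError):
            make_view(1).scaled(0.0)


class TestScatterers:
    def test_seed_reproducibility(self, field, desk_psf):
        sector = make_view(2).scaled(0.25)
        plane = make_plane(field, "pSAXM")
        c1 = seed_scatterers(field, plane, desk_psf, sector, seed=4)
        c2 = seed_scatterers(field, plane, desk_psf, sector, seed=4)
        assert np.array_equal(c1.ref_positions, c2.ref_positions)
        assert np.array_equal(c1.amplitudes, c2.amplitudes)
        c3 = seed_scatterers(field, plane, desk_psf, sector, seed=5)
        assert c3.ref_positions.shape != c1.ref_positions.shape or \
            not np.allclose(c3.ref_positions, c1.ref_positions)

    def test_advect_frame_one_is_reference(self, field, desk_psf):
        sector = make_view(8).scaled(0.25)
        plane = make_plane(field, "A2C")
        cloud = seed_scatterers(field, plane, desk_psf, sector, seed=1,
                                density=0.05)
        assert np.allclose(advect(cloud, field, 1), cloud.ref_positions,
                           atol=1e-9)

    def test_advect_matches_pointwise_field(self, field, desk_psf):
        sector = make_view(8).scaled(0.25)
        plane = make_plane(field, "A2C")
        cloud = seed_scatterers(field, plane, desk_psf, sector, seed=1,
                                density=0.05)
        sub = cloud.ref_positions[:50]
        expected = sub + field.displacement(sub, 30)
        got = advect(cloud, field, 30)[:50]
        assert np.abs(got - expected).max() < 1e-9


class TestRenderer:
    def test_single_scatterer_peak_depth(self, desk_sector, desk_psf):
        rf = render_frame(np.array([[0.0, 45.0]]), np.array([1.0]),
                          desk_sector, desk_psf)
        env = envelope(rf)
        line = np.argmin(np.abs(desk_sector.beam_angles))
        depths = depth_samples(desk_sector, desk_psf)
        assert abs(depths[np.argmax(env[line])] - 45.0) < desk_psf.sample_spacing_mm

    def test_renderer_deterministic(self, desk_sector, desk_psf):
        rng = np.random.default_rng(0)
        pos = np.column_stack([rng.uniform(-20, 20, 500),
                               rng.uniform(35, 55, 500)])
        amp = rng.standard_normal(500)
        a = render_frame(pos, amp, desk_sector, desk_psf)
        b = render_frame(pos, amp, desk_sector, desk_psf)
        assert np.array_equal(a, b)

    def test_axial_shift_theorem(self, speckle_pair, desk_psf):
        # a radial shift of the cloud shifts the RF lines by shift/dr samples
        a = speckle_pair["frame_a"]
        b = speckle_pair["frame_b"]
        line_a = a[a.shape[0] // 2]
        line_b = b[b.shape[0] // 2]
        # phase of the cross spectrum at the carrier gives the sub-sample lag
        fa = np.fft.rfft(line_a * np.hanning(line_a.size))
        fb = np.fft.rfft(line_b * np.hanning(line_b.size))
        cross = fa * np.conj(fb)
        k = np.argmax(np.abs(cross))
        lag = -np.angle(cross[k]) / (2 * np.pi * k / line_a.size)
        assert lag == pytest.approx(-speckle_pair["shift_samples"], abs=0.1)

    def test_envelope_bounds_rf(self, speckle_pair):
        rf = speckle_pair["frame_a"]
        env = envelope(rf)
        assert np.all(env >= np.abs(rf) - 1e-9 * np.abs(rf).max())

    def test_envelope_of_gaussian_burst_is_gaussian(self, desk_psf):
        x = (np.arange(4000) - 2000) * desk_psf.sample_spacing_mm / 4
        g = np.exp(-0.5 * (x / desk_psf.sigma_r_mm) ** 2)
        burst = g * np.cos(desk_psf.carrier_k * x)
        env = np.abs(hilbert(burst))
        core = np.abs(x) < 3 * desk_psf.sigma_r_mm
        assert np.abs(env[core] - g[core]).max() < 0.02

    def test_psf_sampling_constraint(self):
        with pytest.raises(ValueError):
            PSFModel(f0_mhz=10.0, fs_mhz=25.0)


class TestMasks:
    def test_psaxm_mask_is_annulus(self, field):
        sector = make_view(1).scaled(0.25)
        psf = PSFModel().scaled(0.25)
        m = make_mask(field, sector, 1, psf=psf)
        plane = make_plane(field, "pSAXM")
        ang = np.deg2rad(m.grid_x)
        xx = np.sin(ang)[:, None] * m.grid_y[None, :]
        yy = np.cos(ang)[:, None] * m.grid_y[None, :]
        w = plane.to_world(xx, yy).reshape(-1, 3)
        g = field.ed_shape.geometry
        z_rel = plane.z_plane
        r_in = g.b_int * np.sqrt(1 - (z_rel / g.a_int) ** 2)
        r_out = g.b_ext * np.sqrt(1 - (z_rel / g.a_ext) ** 2)
        r = np.hypot(w[:, 0], w[:, 1]).reshape(m.mask.shape)
        inside = (r >= r_in) & (r <= r_out)
        assert np.array_equal(m.mask, inside)

    def test_masks_follow_wall_thickening(self, field):
        sector = make_view(8).scaled(0.25)
        psf = PSFModel().scaled(0.25)
        m1 = make_mask(field, sector, 1, psf=psf)
        mes = make_mask(field, sector, field.t_es, psf=psf)
        assert m1.mask.sum() != mes.mask.sum()

    def test_a2c_mask_area_matches_analytic(self, field):
        # full-view wall pixels integrate to the analytic cross-section area
        sector = make_view(5).scaled(0.25)
        psf = PSFModel().scaled(0.25)
        m = make_mask(field, sector, 1, psf=psf)
        ang = np.deg2rad(m.grid_x)
        # polar pixel area: r * dtheta * dr
        dth = np.deg2rad(sector.line_spacing_deg)
        dr = psf.sample_spacing_mm
        areas = (m.grid_y[None, :] * dth * dr) * m.mask
        g = field.ed_shape.geometry
        analytic = np.pi / 2 * (g.a_ext * g.b_ext - g.a_int * g.b_int)
        assert areas.sum() == pytest.approx(analytic, rel=0.02)


class TestSpeckleMotion:
    def test_subsample_motion_lag(self, desk_sector, desk_psf):
        # q samples/frame of prescribed axial motion shows up as a cross-
        # spectrum lag of q +- 0.1 samples
        rng = np.random.default_rng(21)
        n = 40000
        x = rng.uniform(-40, 40, n)
        y = rng.uniform(25, 70, n)
        amp = rng.standard_normal(n)
        q = 0.6
        dy = q * desk_psf.sample_spacing_mm
        beta = np.arctan2(x, y)
        r = np.hypot(x, y)
        lags = []
        for j in (0, 1):
            rr = r + j * dy
            rf = render_frame(np.column_stack([rr * np.sin(beta),
                                               rr * np.cos(beta)]),
                              amp, desk_sector, desk_psf)
            lags.append(rf[rf.shape[0] // 2])
        fa = np.fft.rfft(lags[0] * np.hanning(lags[0].size))
        fb = np.fft.rfft(lags[1] * np.hanning(lags[1].size))
        cross = fa * np.conj(fb)          # delayed signal: phase +omega*q
        k = np.argmax(np.abs(cross))
        lag = np.angle(cross[k]) / (2 * np.pi * k / lags[0].size)
        assert lag == pytest.approx(q, abs=0.1)
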