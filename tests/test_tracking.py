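"""Block matching: windows, NCC, subpixel refinement, fusion, resampling."""

import numpy as np
import pytest

from lvste import _kernels
from lvste.simulator import PSFModel, envelope
from lvste.smoothing import ESTIMATE_P, REFERENCE_P, smooth1d, smooth_grid
from lvste.tracking import (CartesianGrid, IterationParams,
                            PolarDisplacementField, WindowSpec,
                            fuse_bidirectional, hbm_displacement,
                            interpolate_lines, match_pair, regularize,
                            size_windows, subpixel_refine, to_cartesian,
                            CartesianField, HBM_ITERATIONS)
from lvste.views import make_view


class TestLineInterpolation:
    def test_constant_preserved(self):
        out = interpolate_lines(np.full((3, 10), 2.5))
        assert np.allclose(out, 2.5)
        assert out.shape == (3, 37)

    def test_linear_ramp_exact(self):
        ramp = np.arange(20.0)[None, :]
        out = interpolate_lines(ramp)
        assert np.allclose(out, np.arange(0, 19.0 + 0.25, 0.25))

    def test_original_samples_preserved(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 50))
        out = interpolate_lines(x)
        assert np.allclose(out[:, ::4], x)


class TestWindowSizing:
    def test_first_view_kernel_sequence(self):
        # view 1: first-iteration axial kernel 11.59 mm -> 2.89 mm
        psf = PSFModel()
        sector = make_view(1)
        w = size_windows(11.59 / 15.0, 10.69 / 15.0, psf, sector)
        assert w.kernel_ax_mm[0] == pytest.approx(11.59, abs=0.02)
        assert w.kernel_ax_mm[1] == pytest.approx(2.89, abs=0.02)
        # tabulated 13.90; one RF sample of rounding slack
        assert w.search_ax_mm[0] == pytest.approx(13.90, abs=0.04)

    def test_floors_bind_for_tiny_displacement(self):
        psf = PSFModel()
        sector = make_view(1)
        w = size_windows(0.01, 0.005, psf, sector)
        assert w.kernel_ax_mm[0] >= 3 * psf.wavelength_mm - psf.sample_spacing_mm
        assert w.kernel_lat_deg[0] >= 3 * sector.line_spacing_deg - 1e-9

    def test_search_exceeds_kernel_margins(self):
        psf = PSFModel()
        sector = make_view(5)
        for mx, ml in ((0.01, 0.01), (0.5, 0.3), (1.2, 0.9)):
            w = size_windows(mx, ml, psf, sector)
            assert np.all(w.search_ax_mm - w.kernel_ax_mm
                          >= 4 * psf.sample_spacing_mm - 1e-9)
            assert np.all(w.search_lat_deg - w.kernel_lat_deg
                          >= 4 * sector.line_spacing_deg - 1e-9)

    def test_iteration_signal_schedule(self):
        assert [p.input_signal for p in HBM_ITERATIONS] == \
            ["envelope", "envelope", "rf"]
        assert [p.subpixel_factor for p in HBM_ITERATIONS] == [16, 32, 64]


class TestMatchPair:
    def test_identical_frames_zero_displacement(self, speckle_pair):
        img = envelope(interpolate_lines(speckle_pair["frame_a"]))
        mask = np.zeros(img.shape, dtype=bool)
        mask[5:-5, 300:-300] = True
        params = IterationParams(1, "envelope", 16)
        nl, na, lag_lat, lag_ax, peak, valid = match_pair(
            img, img, params, (5, 61), (9, 101), mask)
        sel = valid
        assert sel.sum() > 10
        assert np.abs(lag_ax[sel]).max() == 0.0
        assert np.abs(lag_lat[sel]).max() == 0.0
        assert np.all(peak[sel] > 0.999999)

    def test_integer_shift_matches_exhaustive_oracle(self, speckle_pair):
        """Integer-lag NCC peaks equal a brute-force full-search oracle."""
        img_a = envelope(interpolate_lines(speckle_pair["frame_a"]))
        shift = 12
        img_b = np.roll(img_a, shift, axis=1)
        rng = np.random.default_rng(2)
        nodes_lat = rng.integers(6, img_a.shape[0] - 6, 120).astype(np.int64)
        nodes_ax = rng.integers(350, img_a.shape[1] - 350, 120).astype(np.int64)
        ka, kl = 121, 7
        n_lag_ax, n_lag_lat = 41, 5
        zeros = np.zeros(120, dtype=np.int64)
        maps, valid = _kernels.ncc_maps(img_a, img_b, nodes_ax, nodes_lat,
                                        zeros, zeros, ka, kl, n_lag_ax,
                                        n_lag_lat)
        assert valid.sum() >= 100
        for i in np.flatnonzero(valid):
            la, lt = nodes_ax[i] - ka // 2, nodes_lat[i] - kl // 2
            a = img_a[lt:lt + kl, la:la + ka]
            ac = a - a.mean()
            best_val, best_lag = -2.0, None
            for il in range(n_lag_lat):
                for ia in range(n_lag_ax):
                    ob = la + ia - n_lag_ax // 2
                    lb = lt + il - n_lag_lat // 2
                    b = img_b[lb:lb + kl, ob:ob + ka]
                    bc = b - b.mean()
                    v = (ac * bc).sum() / np.sqrt((ac ** 2).sum()
                                                  * (bc ** 2).sum())
                    if v > best_val:
                        best_val, best_lag = v, (il, ia)
            got = np.unravel_index(maps[i].argmax(), maps[i].shape)
            assert got == best_lag
            assert maps[i].max() == pytest.approx(best_val, abs=1e-12)
            # and the oracle peak is the true shift
            assert best_lag[1] - n_lag_ax // 2 == shift

    def test_displacement_bounded_by_search_extent(self, speckle_pair):
        psf = PSFModel().scaled(0.25)
        sector = make_view(2).scaled(0.25)
        fa = interpolate_lines(speckle_pair["frame_a"])
        fb = interpolate_lines(speckle_pair["frame_b"])
        mask = np.zeros(fa.shape, dtype=bool)
        mask[3:-3, 250:-250] = True
        w = size_windows(0.77, 0.7, psf, sector)
        f = hbm_displacement(fa, fb, w, psf, sector, mask)
        dri = psf.sample_spacing_mm / 4
        half_ax = (w.search_ax_mm - w.kernel_ax_mm).sum() / 2 + dri
        half_lat = (w.search_lat_deg - w.kernel_lat_deg).sum() / 2 \
            + sector.line_spacing_deg
        assert np.abs(f.u_ax_mm[f.valid]).max() <= half_ax
        assert np.abs(f.u_lat_deg[f.valid]).max() <= half_lat


class TestSubpixel:
    def test_symmetric_peak_refines_to_zero(self):
        x = np.arange(-2.0, 2.5)
        patch = np.exp(-0.5 * (x[:, None] ** 2 + x[None, :] ** 2))
        d0, d1, ok = subpixel_refine(patch, 16)
        assert (d0, d1) == (0.0, 0.0)

    def test_offset_peak_recovered(self):
        x = np.arange(-2.0, 2.5)
        xx, yy = np.meshgrid(x, x, indexing="ij")
        patch = np.exp(-0.5 * ((xx - 0.25) ** 2 + (yy + 0.375) ** 2))
        d0, d1, ok = subpixel_refine(patch, 64)
        assert d0 == pytest.approx(0.25, abs=1 / 32)
        assert d1 == pytest.approx(-0.375, abs=1 / 32)


def _polar(n, u_ax, u_lat, xcc, valid=None):
    z = np.zeros(n)
    return PolarDisplacementField(
        np.arange(n, dtype=np.int64), np.arange(n, dtype=np.int64),
        z.copy(), z + 50.0, np.asarray(u_ax, dtype=float),
        np.asarray(u_lat, dtype=float), np.asarray(xcc, dtype=float),
        np.ones(n, dtype=bool) if valid is None else valid)


class TestFusion:
    def test_equal_weights_average(self):
        f = _polar(1, [1.0], [0.0], [0.5])
        b = _polar(1, [-2.0], [0.0], [0.5])
        out = fuse_bidirectional(f, b)
        assert out.u_ax_mm[0] == pytest.approx(1.5)

    def test_zero_backward_weight_keeps_forward(self):
        f = _polar(1, [1.0], [0.2], [0.8])
        b = _polar(1, [-2.0], [0.0], [0.0])
        out = fuse_bidirectional(f, b)
        assert out.u_ax_mm[0] == pytest.approx(1.0)
        assert out.u_lat_deg[0] == pytest.approx(0.2)

    def test_hand_computed_fusion(self):
        f = _polar(1, [1.0], [0.0], [0.8])
        b = _polar(1, [-1.2], [0.0], [0.4])
        out = fuse_bidirectional(f, b)
        assert out.u_ax_mm[0] == pytest.approx((0.8 * 1.0 + 0.4 * 1.2) / 1.2)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        f = _polar(20, rng.standard_normal(20), rng.standard_normal(20),
                   rng.uniform(0.2, 1, 20))
        b = _polar(20, rng.standard_normal(20), rng.standard_normal(20),
                   rng.uniform(0.2, 1, 20))
        out1 = fuse_bidirectional(f, b)
        out2 = fuse_bidirectional(b, f)
        assert np.allclose(out1.u_ax_mm, -out2.u_ax_mm)
        assert np.allclose(out1.u_lat_deg, -out2.u_lat_deg)

    def test_both_invalid_marks_node(self):
        f = _polar(1, [1.0], [0.0], [0.0])
        b = _polar(1, [1.0], [0.0], [0.0])
        out = fuse_bidirectional(f, b)
        assert not out.valid[0]


class TestCartesianResampling:
    def test_zero_field_stays_zero(self):
        rng = np.random.default_rng(0)
        n = 50
        f = PolarDisplacementField(
            np.zeros(n, dtype=np.int64), np.zeros(n, dtype=np.int64),
            rng.uniform(-20, 20, n), rng.uniform(40, 70, n),
            np.zeros(n), np.zeros(n), np.ones(n), np.ones(n, dtype=bool))
        grid = CartesianGrid.from_bbox(-20, 20, 40, 65, pad=0)
        out = to_cartesian(f, grid)
        assert np.abs(out.ux).max() < 1e-12
        assert np.abs(out.uy).max() < 1e-12

    def test_axial_displacement_on_vertical_beam(self):
        n = 20
        f = PolarDisplacementField(
            np.zeros(n, dtype=np.int64), np.zeros(n, dtype=np.int64),
            np.zeros(n), np.linspace(40, 60, n),
            np.full(n, 0.4), np.zeros(n), np.ones(n), np.ones(n, dtype=bool))
        grid = CartesianGrid.from_bbox(-1, 1, 45, 55, pad=0)
        out = to_cartesian(f, grid)
        assert np.abs(out.ux).max() < 1e-9
        assert np.allclose(out.uy, 0.4)

    def test_uniform_translation_roundtrip(self):
        rng = np.random.default_rng(5)
        n = 400
        beta = np.deg2rad(rng.uniform(-25, 25, n))
        r = rng.uniform(40, 70, n)
        t = np.array([0.3, -0.2])
        u_ax = t[0] * np.sin(beta) + t[1] * np.cos(beta)
        u_lat_mm = t[0] * np.cos(beta) - t[1] * np.sin(beta)
        f = PolarDisplacementField(
            np.zeros(n, dtype=np.int64), np.zeros(n, dtype=np.int64),
            np.degrees(beta), r, u_ax, np.degrees(u_lat_mm / r),
            np.ones(n), np.ones(n, dtype=bool))
        grid = CartesianGrid.from_bbox(-15, 15, 45, 62, pad=0)
        out = to_cartesian(f, grid)
        assert np.abs(out.ux - 0.3).max() < 1e-6
        assert np.abs(out.uy + 0.2).max() < 1e-6


class TestRegularization:
    def test_interpolating_limit(self):
        rng = np.random.default_rng(0)
        grid = CartesianGrid.from_bbox(0, 5, 0, 5, pad=0)
        z = rng.standard_normal(grid.shape)
        f = CartesianField(grid, z, z.copy(), np.ones(grid.shape),
                           np.ones(grid.shape, dtype=bool))
        out = regularize(f, p=1.0)
        assert np.array_equal(out.ux, z)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(1)
        grid = CartesianGrid.from_bbox(0, 30, 0, 30, pad=0)
        z = rng.standard_normal(grid.shape)
        f = CartesianField(grid, z, z.copy(), np.ones(grid.shape),
                           np.ones(grid.shape, dtype=bool))
        out = regularize(f, p=ESTIMATE_P)
        assert out.ux.var() < z.var()

    def test_smooth_quadratic_preserved_at_reference_p(self):
        grid = CartesianGrid.from_bbox(0, 40, 0, 40, pad=0)
        xx, yy = grid.meshgrid()
        q = ((xx - 20) ** 2 + 0.5 * (yy - 15) ** 2) / 100.0
        f = CartesianField(grid, q, q.copy(), np.ones(grid.shape),
                           np.ones(grid.shape, dtype=bool))
        out = regularize(f, p=REFERENCE_P)
        # away from the natural-spline boundary layer
        core = (slice(10, -10), slice(10, -10))
        dev = np.abs(out.ux - q)[core].max() / (q.max() - q.min())
        assert dev < 1e-3


class TestSmoothing1D:
    def test_linear_in_nullspace(self):
        x = np.arange(100) * 0.2e-3
        lin = 3.0 * x + 1.0
        assert np.allclose(smooth1d(lin, 0.5, 0.2e-3), lin)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            smooth1d(np.zeros(10), 0.0, 1.0)
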