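"""Hierarchical block-matching (HBM) displacement estimation on polar RF.

Three coarse-to-fine iterations of normalized-cross-correlation block
matching (envelope, envelope, RF input), kernels overlapping 2/3, search
windows recentred by the previous iteration's field, cubic B-spline
subpixel refinement (16x / 32x / 64x), bidirectional estimation fused with
correlation weights, conversion to a 0.2 mm Cartesian grid and
smoothing-spline regularization.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.ndimage import spline_filter1d

from . import _kernels
from .simulator import PSFModel, RFFrameSet, envelope
from .smoothing import ESTIMATE_P, smooth_grid
from .views import SectorConfig

LINE_INTERP = 4          # axial linear interpolation factor of the RF lines
KERNEL_OVERLAP = 2.0 / 3.0
GRID_PITCH_MM = 0.2


@dataclass(frozen=True)
class IterationParams:
    iteration: int
    input_signal: str        # "envelope" | "rf"
    subpixel_factor: int


HBM_ITERATIONS = (
    IterationParams(1, "envelope", 16),
    IterationParams(2, "envelope", 32),
    IterationParams(3, "rf", 64),
)


@dataclass
class WindowSpec:
    """Kernel and search dimensions per iteration (mm axially, deg laterally)."""

    kernel_ax_mm: np.ndarray
    kernel_lat_deg: np.ndarray
    search_ax_mm: np.ndarray
    search_lat_deg: np.ndarray

    def __post_init__(self):
        for k, s in ((self.kernel_ax_mm, self.search_ax_mm),
                     (self.kernel_lat_deg, self.search_lat_deg)):
            if np.any(np.asarray(k) <= 0) or np.any(np.asarray(s) <= np.asarray(k)):
                raise ValueError("search must exceed kernel, all positive")


def size_windows(max_ax_mm: float, max_lat_deg: float, psf: PSFModel,
                 sector: SectorConfig, n_iterations: int = 3) -> WindowSpec:
    """Window sizes from the per-view maximal interframe displacement.

    First-iteration kernel is 15x and the search window 18x the maximal
    displacement; both shrink 4x per iteration; the kernel is floored at
    3 RF wavelengths axially and 3 lines laterally, the search window always
    exceeds the kernel by at least 4 RF samples / 4 lines, and all sizes are
    rounded to whole samples / lines.
    """
    if max_ax_mm <= 0 or max_lat_deg <= 0:
        raise ValueError("maximal displacements must be positive")
    dr = psf.sample_spacing_mm
    dl = sector.line_spacing_deg
    ka, kl, sa, sl = [], [], [], []
    for it in range(n_iterations):
        shrink = 4.0 ** it
        k_ax = 15.0 * max_ax_mm / shrink
        k_lat = 15.0 * max_lat_deg / shrink
        s_ax = 18.0 * max_ax_mm / shrink
        s_lat = 18.0 * max_lat_deg / shrink
        k_ax = max(k_ax, 3.0 * psf.wavelength_mm)
        k_lat = max(k_lat, 3.0 * dl)
        s_ax = max(s_ax, k_ax + 4.0 * dr)
        s_lat = max(s_lat, k_lat + 4.0 * dl)
        ka.append(round(k_ax / dr) * dr)
        kl.append(round(k_lat / dl) * dl)
        sa.append(max(round(s_ax / dr), round(k_ax / dr) + 4) * dr)
        sl.append(max(round(s_lat / dl), round(k_lat / dl) + 4) * dl)
    return WindowSpec(np.array(ka), np.array(kl), np.array(sa), np.array(sl))


def interpolate_lines(rf: np.ndarray, factor: int = LINE_INTERP) -> np.ndarray:
    """Linear axial upsampling of RF lines; original samples preserved."""
    rf = np.asarray(rf, dtype=float)
    n = rf.shape[-1]
    if n < 2:
        raise ValueError("need at least two samples per line")
    idx = np.arange((n - 1) * factor + 1) / factor
    i0 = np.floor(idx).astype(int)
    frac = idx - i0
    i1 = np.minimum(i0 + 1, n - 1)
    return rf[..., i0] * (1 - frac) + rf[..., i1] * frac


@dataclass
class PolarDisplacementField:
    """Incremental displacement estimates at block-matching nodes."""

    node_lat: np.ndarray       # line indices
    node_ax: np.ndarray        # interpolated-sample indices
    angles_deg: np.ndarray     # beam angle per node
    depths_mm: np.ndarray      # depth per node
    u_ax_mm: np.ndarray
    u_lat_deg: np.ndarray
    xcc: np.ndarray
    valid: np.ndarray


def _bspline3(t: np.ndarray) -> np.ndarray:
    at = np.abs(t)
    out = np.zeros_like(at)
    m1 = at < 1
    out[m1] = 2.0 / 3.0 - at[m1] ** 2 + 0.5 * at[m1] ** 3
    m2 = (at >= 1) & (at < 2)
    out[m2] = ((2.0 - at[m2]) ** 3) / 6.0
    return out


def subpixel_refine(ncc_patch: np.ndarray, factor: int) -> tuple[float, float]:
    """Subpixel peak of a single (2k+1)^2 NCC patch centred on the integer
    peak, via cubic B-spline interpolation on a 1/factor lag grid."""
    d0, d1, flag = _subpixel_batch(ncc_patch[None], factor)
    return float(d0[0]), float(d1[0]), bool(flag[0])


def _subpixel_batch(patches: np.ndarray, factor: int):
    """Vectorized B-spline subpixel refinement of (N, P, P) NCC patches.

    Returns per-node offsets (rows, cols) within +-1 of the patch centre and
    an 'interior' flag (False when the centre was on the map border and the
    caller substituted a clamped patch).
    """
    n, p, _ = patches.shape
    c = (p - 1) // 2
    coeff = spline_filter1d(patches, order=3, axis=1, mode="mirror")
    coeff = spline_filter1d(coeff, order=3, axis=2, mode="mirror")
    t = c + np.arange(-factor, factor + 1) / factor
    basis = _bspline3(t[:, None] - np.arange(p)[None, :])   # (T, P)
    interp = np.einsum("nij,ai,bj->nab", coeff, basis, basis, optimize=True)
    flat = interp.reshape(n, -1).argmax(axis=1)
    i0, i1 = np.unravel_index(flat, interp.shape[1:])
    d0 = (i0 - factor) / factor
    d1 = (i1 - factor) / factor
    ok = np.ones(n, dtype=bool)
    return d0, d1, ok


def _node_grid(mask: np.ndarray, spacing_lat: int, spacing_ax: int):
    nl, ns = mask.shape
    lat = np.arange(spacing_lat // 2, nl, max(spacing_lat, 1))
    ax = np.arange(spacing_ax // 2, ns, max(spacing_ax, 1))
    ll, aa = np.meshgrid(lat, ax, indexing="ij")
    sel = mask[ll, aa]
    return ll[sel].astype(np.int64), aa[sel].astype(np.int64)


def match_pair(img_a: np.ndarray, img_b: np.ndarray, params: IterationParams,
               kernel: tuple[int, int], search: tuple[int, int],
               mask: np.ndarray, prior_lat: np.ndarray | None = None,
               prior_ax: np.ndarray | None = None,
               node_lat: np.ndarray | None = None,
               node_ax: np.ndarray | None = None):
    """One block-matching iteration between two frames on identical grids.

    ``kernel``/``search`` are (lines, samples) window sizes in grid units.
    Returns node indices, integer+subpixel displacements (lines, samples),
    peak correlation values and validity flags.
    """
    kl, ka = kernel
    sl, sa = search
    if node_lat is None:
        spacing_lat = max(1, int(round(kl * (1 - KERNEL_OVERLAP))))
        spacing_ax = max(1, int(round(ka * (1 - KERNEL_OVERLAP))))
        node_lat, node_ax = _node_grid(mask, spacing_lat, spacing_ax)
    n_nodes = node_lat.size
    if prior_lat is None:
        prior_lat = np.zeros(n_nodes)
    if prior_ax is None:
        prior_ax = np.zeros(n_nodes)
    pl = np.round(prior_lat).astype(np.int64)
    pa = np.round(prior_ax).astype(np.int64)
    n_lag_lat = max(sl - kl + 1, 3)
    n_lag_ax = max(sa - ka + 1, 3)
    if n_lag_lat % 2 == 0:
        n_lag_lat += 1
    if n_lag_ax % 2 == 0:
        n_lag_ax += 1
    maps, valid = _kernels.ncc_maps(
        np.ascontiguousarray(img_a, dtype=np.float64),
        np.ascontiguousarray(img_b, dtype=np.float64),
        node_ax, node_lat, pa, pl, ka, kl, n_lag_ax, n_lag_lat)
    lag_lat = np.zeros(n_nodes)
    lag_ax = np.zeros(n_nodes)
    peak = np.zeros(n_nodes)
    if np.any(valid):
        v = np.where(valid)[0]
        mv = maps[v]
        flat = mv.reshape(len(v), -1).argmax(axis=1)
        il, ia = np.unravel_index(flat, mv.shape[1:])
        peak[v] = mv[np.arange(len(v)), il, ia]
        # ties: argmax picks the first (closest-to-prior ordering is handled
        # by the centred lag grid scanning outward is not needed in practice)
        il0 = il - n_lag_lat // 2
        ia0 = ia - n_lag_ax // 2
        # 5x5 patches around the peak, clamped inside the map
        pc = 2
        ilc = np.clip(il, pc, n_lag_lat - 1 - pc)
        iac = np.clip(ia, pc, n_lag_ax - 1 - pc)
        interior = (il == ilc) & (ia == iac)
        patches = np.empty((len(v), 2 * pc + 1, 2 * pc + 1))
        for k in range(len(v)):
            patches[k] = mv[k, ilc[k] - pc:ilc[k] + pc + 1,
                            iac[k] - pc:iac[k] + pc + 1]
        d0, d1, _ = _subpixel_batch(patches, params.subpixel_factor)
        # refinement is relative to the clamped centre; only trust it when
        # the integer peak was strictly inside the map.  A perfect match
        # (NCC = 1) is already the global optimum by Cauchy-Schwarz; spline
        # overshoot around it is an interpolation artifact, not a shift.
        usable = interior & (peak[v] < 1.0 - 1e-9)
        d0 = np.where(usable, d0, 0.0)
        d1 = np.where(usable, d1, 0.0)
        lag_lat[v] = pl[v] + il0 + d0
        lag_ax[v] = pa[v] + ia0 + d1
    return node_lat, node_ax, lag_lat, lag_ax, peak, valid


def _interp_to_nodes(src_lat, src_ax, values, dst_lat, dst_ax):
    """Linear scattered interpolation between node grids (nearest fallback)."""
    if src_lat.size == 0:
        return np.zeros(dst_lat.size)
    if src_lat.size < 4:
        interp = NearestNDInterpolator(np.column_stack([src_lat, src_ax]), values)
        return interp(np.column_stack([dst_lat, dst_ax]))
    pts = np.column_stack([src_lat, src_ax]).astype(float)
    lin = LinearNDInterpolator(pts, values)
    out = lin(np.column_stack([dst_lat, dst_ax]).astype(float))
    bad = ~np.isfinite(out)
    if np.any(bad):
        near = NearestNDInterpolator(pts, values)
        out[bad] = near(np.column_stack([dst_lat[bad], dst_ax[bad]]).astype(float))
    return out


def hbm_displacement(frame_a: np.ndarray, frame_b: np.ndarray,
                     windows: WindowSpec, psf: PSFModel, sector: SectorConfig,
                     mask: np.ndarray):
    """Full 3-iteration HBM estimate from frame_a to frame_b.

    Frames are interpolated polar images (lines x interp samples); returns
    the final-iteration node set with displacements in mm / degrees.
    """
    dr_i = psf.sample_spacing_mm / LINE_INTERP
    dl = sector.line_spacing_deg
    env_a, env_b = envelope(frame_a), envelope(frame_b)
    prior_lat = prior_ax = None
    node_lat = node_ax = None
    last = None
    for i, params in enumerate(HBM_ITERATIONS):
        ka = max(3, int(round(windows.kernel_ax_mm[i] / dr_i)))
        kl = max(3, int(round(windows.kernel_lat_deg[i] / dl)))
        sa = max(ka + 4 * LINE_INTERP, int(round(windows.search_ax_mm[i] / dr_i)))
        sl = max(kl + 4, int(round(windows.search_lat_deg[i] / dl)))
        img_a, img_b = (env_a, env_b) if params.input_signal == "envelope" \
            else (frame_a, frame_b)
        spacing_lat = max(1, int(round(kl * (1 - KERNEL_OVERLAP))))
        spacing_ax = max(1, int(round(ka * (1 - KERNEL_OVERLAP))))
        nl, na = _node_grid(mask, spacing_lat, spacing_ax)
        if last is not None:
            p_lat = _interp_to_nodes(last[0], last[1], last[2], nl, na)
            p_ax = _interp_to_nodes(last[0], last[1], last[3], nl, na)
        else:
            p_lat = np.zeros(nl.size)
            p_ax = np.zeros(nl.size)
        nl, na, lag_lat, lag_ax, peak, valid = match_pair(
            img_a, img_b, params, (kl, ka), (sl, sa), mask,
            prior_lat=p_lat, prior_ax=p_ax, node_lat=nl, node_ax=na)
        last = (nl[valid], na[valid], lag_lat[valid], lag_ax[valid])
        node_lat, node_ax = nl, na
        final = (nl, na, lag_lat, lag_ax, peak, valid)
    nl, na, lag_lat, lag_ax, peak, valid = final
    angles = np.asarray(sector.beam_angles, dtype=float)[nl]
    depths = sector.d_min * 10.0 + na * dr_i
    return PolarDisplacementField(
        nl, na, angles, depths, lag_ax * dr_i, lag_lat * dl, peak, valid)


def fuse_bidirectional(fwd: PolarDisplacementField,
                       bwd: PolarDisplacementField) -> PolarDisplacementField:
    """Correlation-weighted average of forward and (sign-flipped) backward
    incremental estimates on a common node grid."""
    if fwd.node_lat.shape != bwd.node_lat.shape or \
            np.any(fwd.node_lat != bwd.node_lat) or np.any(fwd.node_ax != bwd.node_ax):
        raise ValueError("fields must share the node grid")
    w_f = np.clip(fwd.xcc, 0.0, 1.0) * fwd.valid
    w_b = np.clip(bwd.xcc, 0.0, 1.0) * bwd.valid
    tot = w_f + w_b
    valid = tot > 0
    tot = np.where(valid, tot, 1.0)
    u_ax = (w_f * fwd.u_ax_mm + w_b * (-bwd.u_ax_mm)) / tot
    u_lat = (w_f * fwd.u_lat_deg + w_b * (-bwd.u_lat_deg)) / tot
    xcc = np.where(valid, np.maximum(fwd.xcc * fwd.valid, bwd.xcc * bwd.valid), 0.0)
    return PolarDisplacementField(fwd.node_lat, fwd.node_ax, fwd.angles_deg,
                                  fwd.depths_mm, u_ax, u_lat, xcc, valid)


@dataclass
class CartesianGrid:
    """Regular 0.2 mm image grid (x lateral, y depth)."""

    x: np.ndarray
    y: np.ndarray
    pitch: float = GRID_PITCH_MM

    @classmethod
    def from_bbox(cls, x0, x1, y0, y1, pitch: float = GRID_PITCH_MM,
                  pad: float = 4.0):
        x = np.arange(x0 - pad, x1 + pad + pitch / 2, pitch)
        y = np.arange(y0 - pad, y1 + pad + pitch / 2, pitch)
        return cls(x, y, pitch)

    @property
    def shape(self):
        return (self.x.size, self.y.size)

    def meshgrid(self):
        return np.meshgrid(self.x, self.y, indexing="ij")


@dataclass
class CartesianField:
    """Displacement components on the regular grid; mm everywhere."""

    grid: CartesianGrid
    ux: np.ndarray
    uy: np.ndarray
    weight: np.ndarray
    valid: np.ndarray


def to_cartesian(field: PolarDisplacementField, grid: CartesianGrid,
                 mask_fn=None) -> CartesianField:
    """Rotate (axial, lateral) estimates to (x, y) and resample on the grid.

    ``mask_fn(x, y)`` may restrict the valid region; nodes are interpolated
    linearly with nearest-neighbour extension.
    """
    sel = field.valid
    beta = np.deg2rad(field.angles_deg[sel])
    r = field.depths_mm[sel]
    u_ax = field.u_ax_mm[sel]
    u_lat = np.deg2rad(field.u_lat_deg[sel]) * r
    ux = u_ax * np.sin(beta) + u_lat * np.cos(beta)
    uy = u_ax * np.cos(beta) - u_lat * np.sin(beta)
    px = r * np.sin(beta)
    py = r * np.cos(beta)
    xx, yy = grid.meshgrid()
    out_x = np.zeros(xx.shape)
    out_y = np.zeros(xx.shape)
    out_w = np.zeros(xx.shape)
    valid = np.zeros(xx.shape, dtype=bool)
    if px.size >= 1:
        from scipy.spatial import QhullError
        pts = np.column_stack([px, py])
        q = np.column_stack([xx.ravel(), yy.ravel()])
        hull_ok = None
        for vals, target in ((ux, out_x), (uy, out_y),
                             (field.xcc[sel], out_w)):
            got = None
            if px.size >= 4:
                try:
                    lin = LinearNDInterpolator(pts, vals)
                    got = lin(q)
                except QhullError:   # degenerate (e.g. collinear) nodes
                    got = None
            if got is None:
                got = np.full(q.shape[0], np.nan)
            if hull_ok is None:
                hull_ok = np.isfinite(got)
            near = NearestNDInterpolator(pts, vals)
            got[~hull_ok] = near(q[~hull_ok])
            target[...] = got.reshape(xx.shape)
        valid[...] = True
    if mask_fn is not None:
        inside = mask_fn(xx, yy)
        valid &= inside
    return CartesianField(grid, out_x, out_y, out_w, valid)


def regularize(field: CartesianField, p: float = ESTIMATE_P) -> CartesianField:
    """Smoothing-spline regularization of both components (sites in meters)."""
    h = field.grid.pitch * 1e-3
    ux = smooth_grid(field.ux, p, h)
    uy = smooth_grid(field.uy, p, h)
    return CartesianField(field.grid, ux, uy, field.weight, field.valid)
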