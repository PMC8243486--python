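"""Anatomical directions, displacement accumulation and Lagrangian strain.

Incremental (interframe) displacement fields on the 0.2 mm grid are
gap-filled outside the wall, accumulated along the cycle in both temporal
directions (trajectories combined by quality weighting), and differentiated
analytically through interpolating cubic splines to form the Lagrangian
finite-strain tensor, which is projected on the anatomical directions
(longitudinal/radial in A2C, circumferential/radial in pSAXM).  The exact
reference maps are produced by feeding the same machinery with noise-free
increments sampled from the kinematic model, smoothed with the reference
regularization coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator, RectBivariateSpline
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree, Delaunay

from .kinematics import KinematicField, rotation_angle
from .simulator import A2CPlane, PSAXMPlane
from .smoothing import REFERENCE_P
from .tracking import (CartesianField, CartesianGrid, PolarDisplacementField,
                       regularize, to_cartesian)

GAP_BAND_MM = 2.0


# ---------------------------------------------------------------------------
# direction fields
# ---------------------------------------------------------------------------

@dataclass
class DirectionField:
    """Orthonormal anatomical unit vectors at wall points (image plane)."""

    primary: np.ndarray      # (N, 2) longitudinal (A2C) or circumferential (pSAXM)
    radial: np.ndarray       # (N, 2)

    def __post_init__(self):
        for v in (self.primary, self.radial):
            n = np.linalg.norm(v, axis=1)
            if np.any(np.abs(n - 1.0) > 1e-6):
                raise ValueError("direction vectors must be unit length")
        if np.any(np.abs(np.sum(self.primary * self.radial, axis=1)) > 1e-6):
            raise ValueError("direction pairs must be orthogonal")


def directions_psaxm(points: np.ndarray, lax_point: np.ndarray) -> DirectionField:
    """Radial = away from the LAX piercing point; circumferential orthogonal."""
    points = np.atleast_2d(points)
    rel = points - np.asarray(lax_point, dtype=float)[None, :]
    r = np.linalg.norm(rel, axis=1)
    if np.any(r < 1e-9):
        raise ValueError("point coincides with the LAX")
    radial = rel / r[:, None]
    circ = np.column_stack([-radial[:, 1], radial[:, 0]])
    return DirectionField(circ, radial)


def _polyline_tangents(poly: np.ndarray) -> np.ndarray:
    t = np.gradient(poly, axis=0)
    n = np.linalg.norm(t, axis=1)
    n[n == 0] = 1.0
    return t / n[:, None]


def directions_a2c(points: np.ndarray, inner_border: np.ndarray,
                   outer_border: np.ndarray) -> DirectionField:
    """Longitudinal from wall-border tangents, blended across the wall.

    Tangents are evaluated at the nearest inner and outer border points and
    interpolated linearly in the normalized wall-depth coordinate; the
    radial direction is the in-plane orthogonal.
    """
    if len(inner_border) < 3 or len(outer_border) < 3:
        raise ValueError("degenerate border polyline")
    points = np.atleast_2d(points)
    t_in = _polyline_tangents(inner_border)
    t_out = _polyline_tangents(outer_border)
    ki = cKDTree(inner_border)
    ko = cKDTree(outer_border)
    d_in, i_in = ki.query(points)
    d_out, i_out = ko.query(points)
    ti = t_in[i_in]
    to = t_out[i_out]
    # align the outer tangent with the inner one before blending
    flip = np.sum(ti * to, axis=1) < 0
    to[flip] *= -1.0
    w = d_in / np.maximum(d_in + d_out, 1e-12)
    tan = (1 - w[:, None]) * ti + w[:, None] * to
    n = np.linalg.norm(tan, axis=1)
    n[n == 0] = 1.0
    tan /= n[:, None]
    rad = np.column_stack([-tan[:, 1], tan[:, 0]])
    return DirectionField(tan, rad)


# ---------------------------------------------------------------------------
# gap filling
# ---------------------------------------------------------------------------

def fill_gaps(values: np.ndarray, mask: np.ndarray,
              band_px: int | None = None,
              pitch_mm: float = 0.2) -> np.ndarray:
    """Harmonic extension of ``values`` from ``mask`` onto a boundary band.

    Values inside the mask are untouched; a band of ``GAP_BAND_MM`` around
    the wall is filled with the discrete-Laplace (spring) extrapolation and
    the remaining grid with nearest neighbours, keeping the spline fits and
    the trajectory integration well-behaved at the wall border.
    """
    if band_px is None:
        band_px = max(1, int(round(GAP_BAND_MM / pitch_mm)))
    out = np.array(values, dtype=float, copy=True)
    if mask.all():
        return out
    from scipy.ndimage import uniform_filter
    dist, (nix, niy) = distance_transform_edt(~mask, return_indices=True)
    band = (~mask) & (dist <= band_px)
    # in-mask gradient, regularized by a short normalized box average so the
    # extension is first-order accurate (linear data continues exactly)
    from scipy.ndimage import binary_erosion
    filled = out[nix, niy]
    gx, gy = np.gradient(filled)
    # gradients are trusted only where the full stencil lies inside the mask
    w = binary_erosion(mask).astype(float)
    if w.sum() == 0:
        w = mask.astype(float)
    size = 7
    den = uniform_filter(w, size=size)
    gxs = np.where(den > 0, uniform_filter(gx * w, size=size) / np.where(
        den > 0, den, 1.0), 0.0)
    gys = np.where(den > 0, uniform_filter(gy * w, size=size) / np.where(
        den > 0, den, 1.0), 0.0)
    # spread the smoothed gradient to boundary nodes without support
    far = den == 0
    if np.any(far):
        _, (qx, qy) = distance_transform_edt(far, return_indices=True)
        gxs = gxs[qx, qy]
        gys = gys[qx, qy]
    ii, jj = np.where(band)
    bi, bj = nix[band], niy[band]
    out[band] = out[bi, bj] + gxs[bi, bj] * (ii - bi) + gys[bi, bj] * (jj - bj)
    # nearest fill of everything else (spline support only)
    rest = (~mask) & (~band)
    if np.any(rest):
        known = mask | band
        _, (ix, iy) = distance_transform_edt(~known, return_indices=True)
        out[rest] = out[ix[rest], iy[rest]]
    return out


# ---------------------------------------------------------------------------
# accumulation
# ---------------------------------------------------------------------------

@dataclass
class AccumulatedField:
    """Total displacement from frame 1 at tracked wall grid nodes."""

    grid: CartesianGrid
    node_ix: np.ndarray        # grid indices of tracked nodes
    node_iy: np.ndarray
    u: np.ndarray              # (N, n_frames, 2) displacement, mm
    valid: np.ndarray          # (N,) trajectories that stayed in the band

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.grid.x[self.node_ix],
                                self.grid.y[self.node_iy]])


def _sample_grid(field_x: np.ndarray, field_y: np.ndarray, grid: CartesianGrid,
                 pts: np.ndarray):
    """Bilinear sampling of two grid fields at points (mm)."""
    fx = (pts[:, 0] - grid.x[0]) / grid.pitch
    fy = (pts[:, 1] - grid.y[0]) / grid.pitch
    nx, ny = field_x.shape
    inside = (fx >= 0) & (fx <= nx - 1) & (fy >= 0) & (fy <= ny - 1)
    fx = np.clip(fx, 0, nx - 1 - 1e-9)
    fy = np.clip(fy, 0, ny - 1 - 1e-9)
    i0 = fx.astype(int)
    j0 = fy.astype(int)
    ax = fx - i0
    ay = fy - j0
    def bil(f):
        return (f[i0, j0] * (1 - ax) * (1 - ay) + f[i0 + 1, j0] * ax * (1 - ay)
                + f[i0, j0 + 1] * (1 - ax) * ay + f[i0 + 1, j0 + 1] * ax * ay)
    return bil(field_x), bil(field_y), inside


def accumulate(increments: list[tuple[np.ndarray, np.ndarray]],
               weights: list[np.ndarray],
               grid: CartesianGrid, node_ix: np.ndarray, node_iy: np.ndarray,
               strategy: str = "xcc") -> AccumulatedField:
    """Bidirectional accumulation of gap-filled incremental displacements.

    ``increments[t]`` holds full-grid (ux, uy) between frames t+1 and t+2;
    ``weights[t]`` the matching quality map in [0, 1].  The forward pass
    integrates trajectories from frame 1, the backward pass from the last
    frame (re-anchored to frame 1); the two displacement curves are averaged
    with weights given by the running product of the per-step quality
    sampled along each trajectory (``strategy='uniform'`` gives 50/50).
    """
    n_pairs = len(increments)
    n_frames = n_pairs + 1
    start = np.column_stack([grid.x[node_ix], grid.y[node_iy]]).astype(float)
    n = start.shape[0]

    u_f = np.zeros((n, n_frames, 2), dtype=np.float32)
    w_f = np.ones((n, n_frames), dtype=np.float32)
    valid = np.ones(n, dtype=bool)
    pos = start.copy()
    wrun = np.ones(n)
    for t in range(n_pairs):
        ux, uy = increments[t]
        dx, dy, inside = _sample_grid(ux, uy, grid, pos)
        valid &= inside
        if strategy == "xcc":
            qw, _, _ = _sample_grid(weights[t], weights[t], grid, pos)
            wrun = wrun * np.clip(qw, 1e-3, 1.0)
        pos = pos + np.column_stack([dx, dy])
        u_f[:, t + 1] = (pos - start).astype(np.float32)
        w_f[:, t + 1] = wrun.astype(np.float32)

    # backward pass: trajectories ending at the tracked frame-1 nodes are
    # found by integrating the (approximately inverted) increments from the
    # last frame; they are computed at the same node seeds by reversing the
    # forward-integrated end positions.
    end = pos.copy()
    u_b = np.zeros((n, n_frames, 2), dtype=np.float32)
    w_b = np.ones((n, n_frames), dtype=np.float32)
    posb = end.copy()
    wrunb = np.ones(n)
    traj_b = np.zeros((n, n_frames, 2))
    traj_b[:, n_frames - 1] = posb
    for t in range(n_pairs - 1, -1, -1):
        ux, uy = increments[t]
        # invert x -> x + u around the arrival point (two fixed-point steps)
        q = posb.copy()
        for _ in range(2):
            dx, dy, inside = _sample_grid(ux, uy, grid, q)
            q = posb - np.column_stack([dx, dy])
        valid &= inside
        if strategy == "xcc":
            qw, _, _ = _sample_grid(weights[t], weights[t], grid, q)
            wrunb = wrunb * np.clip(qw, 1e-3, 1.0)
        posb = q
        traj_b[:, t] = posb
        w_b[:, t] = wrunb.astype(np.float32)
    # re-anchor: displacement relative to the backward trajectory's frame-1
    # point, attached at that point, interpolated back onto the node seeds
    anchor = traj_b[:, 0]
    ub_rel = traj_b - anchor[:, None, :]
    if n >= 4:
        try:
            tri = Delaunay(anchor)
            flatten = ub_rel.reshape(n, -1)
            interp = LinearNDInterpolator(tri, flatten)
            got = interp(start)
            bad = ~np.isfinite(got[:, 0])
            if np.any(bad):
                got[bad] = ub_rel.reshape(n, -1)[bad]
            u_b = got.reshape(n, n_frames, 2).astype(np.float32)
            wtri = LinearNDInterpolator(tri, w_b)
            wgot = wtri(start)
            badw = ~np.isfinite(wgot[:, 0])
            wgot[badw] = w_b[badw]
            w_b = wgot.astype(np.float32)
        except Exception:
            u_b = ub_rel.astype(np.float32)
    else:
        u_b = ub_rel.astype(np.float32)

    if strategy == "uniform":
        w_f = np.ones_like(w_f)
        w_b = np.ones_like(w_b)
    tot = w_f + w_b
    u = (w_f[..., None] * u_f + w_b[..., None] * u_b) / tot[..., None]
    u[:, 0] = 0.0
    return AccumulatedField(grid, node_ix, node_iy, u.astype(np.float32), valid)


# ---------------------------------------------------------------------------
# strain tensor
# ---------------------------------------------------------------------------

def strain_tensor_grid(ux: np.ndarray, uy: np.ndarray, grid: CartesianGrid):
    """Lagrangian finite-strain components from full-grid displacements.

    Gradients are the analytic derivatives of interpolating cubic splines
    fitted to the displacement components.
    """
    sx = RectBivariateSpline(grid.x, grid.y, ux, kx=3, ky=3, s=0)
    sy = RectBivariateSpline(grid.x, grid.y, uy, kx=3, ky=3, s=0)
    gxx = sx.partial_derivative(1, 0)(grid.x, grid.y)
    gxy = sx.partial_derivative(0, 1)(grid.x, grid.y)
    gyx = sy.partial_derivative(1, 0)(grid.x, grid.y)
    gyy = sy.partial_derivative(0, 1)(grid.x, grid.y)
    exx = gxx + 0.5 * (gxx ** 2 + gyx ** 2)
    eyy = gyy + 0.5 * (gxy ** 2 + gyy ** 2)
    exy = 0.5 * (gxy + gyx + gxx * gxy + gyx * gyy)
    return exx, exy, eyy


def project(exx, exy, eyy, directions: np.ndarray) -> np.ndarray:
    """Normal strain along unit directions: d^T E d."""
    dx, dy = directions[..., 0], directions[..., 1]
    return exx * dx * dx + 2.0 * exy * dx * dy + eyy * dy * dy


@dataclass
class StrainMaps:
    """Per-node strain component curves over the cycle."""

    grid: CartesianGrid
    node_ix: np.ndarray
    node_iy: np.ndarray
    components: dict           # name -> (N, n_frames) float32
    valid: np.ndarray

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.grid.x[self.node_ix],
                                self.grid.y[self.node_iy]])


def strain_maps_from_accumulated(acc: AccumulatedField, mask1: np.ndarray,
                                 directions: DirectionField,
                                 names: tuple[str, str]) -> StrainMaps:
    """Strain curves at the tracked nodes by per-frame spline differentiation.

    ``mask1`` is the frame-1 wall mask on the grid; displacements are
    gap-filled outside it before spline fitting.  ``names`` labels the
    (primary, radial) projections, e.g. ("eL", "eR") or ("eC", "eR").
    """
    n, n_frames, _ = acc.u.shape
    grid = acc.grid
    full = np.zeros(grid.shape)
    out_p = np.zeros((n, n_frames), dtype=np.float32)
    out_r = np.zeros((n, n_frames), dtype=np.float32)
    node_mask = np.zeros(grid.shape, dtype=bool)
    node_mask[acc.node_ix, acc.node_iy] = True
    for t in range(1, n_frames):
        comp = []
        for c in range(2):
            full[...] = 0.0
            full[acc.node_ix, acc.node_iy] = acc.u[:, t, c]
            filled = fill_gaps(full, node_mask, pitch_mm=grid.pitch)
            comp.append(filled)
        exx, exy, eyy = strain_tensor_grid(comp[0], comp[1], grid)
        # directions are per tracked node; project at node positions
        e_xx = exx[acc.node_ix, acc.node_iy]
        e_xy = exy[acc.node_ix, acc.node_iy]
        e_yy = eyy[acc.node_ix, acc.node_iy]
        out_p[:, t] = project(e_xx, e_xy, e_yy, directions.primary)
        out_r[:, t] = project(e_xx, e_xy, e_yy, directions.radial)
    return StrainMaps(grid, acc.node_ix, acc.node_iy,
                      {names[0]: out_p, names[1]: out_r}, acc.valid)


# ---------------------------------------------------------------------------
# exact reference increments
# ---------------------------------------------------------------------------

def exact_increment_polar(field: KinematicField, plane,
                          template: PolarDisplacementField,
                          frame: int) -> PolarDisplacementField:
    """Noise-free interframe displacement sampled at the template nodes.

    The material point currently at each node is identified from the exact
    model and moved to the next frame; the in-plane displacement components
    are expressed in the node's axial/lateral polar directions.
    """
    beta = np.deg2rad(template.angles_deg)
    r = template.depths_mm
    x_img = r * np.sin(beta)
    y_img = r * np.cos(beta)
    pts_w = plane.to_world(x_img, y_img)
    shape = field.shape_at_frame(frame)
    dz = field.avpd_offset(frame)
    rho = np.hypot(pts_w[:, 0], pts_w[:, 1])
    z_rel = pts_w[:, 2] - dz
    ok = shape.contains(rho, z_rel, tol=1e-9)
    d, m = shape.invert(np.maximum(rho, 1e-9), np.minimum(z_rel, 0.0))
    ok &= (d > -1e-6) & (d < 1 + 1e-6)
    d = np.clip(d, 0.0, 1.0)
    alpha = np.arctan2(pts_w[:, 1], pts_w[:, 0])
    t = (frame - 1) / field.fps
    la = shape.geometry.a_int
    x_p = np.clip(z_rel + la, 0.0, la)
    theta = np.deg2rad(rotation_angle(x_p, la, t, sign=field.rotation_sign))
    coords = np.column_stack([d, m, alpha - theta])
    p_now = field.position_from_coords(coords, frame)
    p_next = field.position_from_coords(coords, min(frame + 1, field.n_frames))
    du_w = p_next - p_now
    if isinstance(plane, A2CPlane):
        du_img = np.column_stack([-du_w[:, 0], du_w[:, 2]])
    else:
        du_img = np.column_stack([du_w[:, 1], -du_w[:, 0]])
    e_ax = np.column_stack([np.sin(beta), np.cos(beta)])
    e_lat = np.column_stack([np.cos(beta), -np.sin(beta)])
    u_ax = np.sum(du_img * e_ax, axis=1)
    u_lat_mm = np.sum(du_img * e_lat, axis=1)
    u_lat_deg = np.rad2deg(u_lat_mm / r)
    return PolarDisplacementField(
        template.node_lat, template.node_ax, template.angles_deg,
        template.depths_mm, np.where(ok, u_ax, 0.0),
        np.where(ok, u_lat_deg, 0.0), np.where(ok, 1.0, 0.0), ok)


def run_displacement_chain(polar_fields: list[PolarDisplacementField],
                           grid: CartesianGrid, mask1: np.ndarray,
                           pair_masks: list[np.ndarray], p: float,
                           strategy: str = "xcc") -> AccumulatedField:
    """Cartesian conversion + regularization + gap filling + accumulation.

    ``pair_masks[t]`` is the wall mask on the grid at the first frame of
    pair t; gap filling extends each incremental field beyond the wall it
    was estimated on, so trajectories can follow the moving wall.
    """
    incs, ws = [], []
    for t, pf in enumerate(polar_fields):
        cf = to_cartesian(pf, grid, mask_fn=None)
        cf = regularize(cf, p)
        wall = pair_masks[t]
        ux = fill_gaps(cf.ux, wall, pitch_mm=grid.pitch)
        uy = fill_gaps(cf.uy, wall, pitch_mm=grid.pitch)
        incs.append((ux, uy))
        ws.append(np.clip(cf.weight, 0.0, 1.0))
    ix, iy = np.where(mask1)
    return accumulate(incs, ws, grid, ix, iy, strategy=strategy)


def reference_strain_maps(field: KinematicField, plane,
                          template_fields: list[PolarDisplacementField],
                          grid: CartesianGrid, mask1: np.ndarray,
                          pair_masks: list[np.ndarray],
                          directions: DirectionField,
                          names: tuple[str, str]) -> StrainMaps:
    """Reference maps: exact increments through the identical chain with the
    reference regularization coefficient."""
    refs = [exact_increment_polar(field, plane, template_fields[t], t + 1)
            for t in range(len(template_fields))]
    acc = run_displacement_chain(refs, grid, mask1, pair_masks, REFERENCE_P,
                                 strategy="uniform")
    return strain_maps_from_accumulated(acc, mask1, directions, names)
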