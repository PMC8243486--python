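"""Sector-scan pseudo-RF simulation of the moving scatterer phantom.

A point-spread-function convolution renderer stands in for a full acoustic
simulation: every scatterer contributes a Gaussian-modulated cosine along the
beam axis, a Gaussian lateral apodization across beams and a Gaussian
elevation weight across the slab around the imaging plane (2.5-D imaging).
Scatterers are seeded uniformly in the end-diastolic wall around the imaging
plane and advected with the exact material motion, so the speckle pattern
deforms, decorrelates and moves through the plane the way tissue does.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import hilbert

from . import _kernels
from .kinematics import KinematicField
from .views import (A2C_STANDOFF_MM, PSAXM_CENTER_DEPTH_MM, SectorConfig,
                    make_view)

CM2MM = 10.0


@dataclass(frozen=True)
class PSFModel:
    """Acoustic constants of the separable point-spread function.

    ``elevation_mm`` is the full slab thickness; the elevation weight is a
    Gaussian with sigma = elevation_mm / 2.  The lateral profile is Gaussian
    in beam angle with a FWHM of ``beamwidth_factor`` times the line spacing
    (a phased-array beam roughly matched to the line density).
    """

    f0_mhz: float = 3.5
    fractional_bandwidth: float = 0.6
    c_m_s: float = 1540.0
    fs_mhz: float = 25.0
    beamwidth_factor: float = 1.2
    elevation_mm: float = 3.0

    def __post_init__(self):
        if self.fs_mhz <= 2 * self.f0_mhz * (1 + self.fractional_bandwidth):
            raise ValueError("sampling rate below the RF band")

    @property
    def c_mm_s(self) -> float:
        return self.c_m_s * 1e3

    @property
    def sample_spacing_mm(self) -> float:
        """Depth increment of one RF sample (two-way travel)."""
        return self.c_mm_s / (2.0 * self.fs_mhz * 1e6)

    @property
    def wavelength_mm(self) -> float:
        """RF oscillation period along depth (two-way), c / (2 f0)."""
        return self.c_mm_s / (2.0 * self.f0_mhz * 1e6)

    @property
    def carrier_k(self) -> float:
        """Carrier wavenumber along depth (rad/mm)."""
        return 2.0 * np.pi / self.wavelength_mm

    @property
    def sigma_r_mm(self) -> float:
        """Axial Gaussian sigma of the pulse envelope in depth units."""
        sigma_f_hz = self.fractional_bandwidth * self.f0_mhz * 1e6 / 2.3548
        sigma_t = 1.0 / (2.0 * np.pi * sigma_f_hz)
        return self.c_mm_s * sigma_t / 2.0

    @property
    def elevation_sigma_mm(self) -> float:
        return self.elevation_mm / 2.0

    def lateral_sigma_deg(self, sector: SectorConfig) -> float:
        return self.beamwidth_factor * sector.line_spacing_deg / 2.3548

    def scaled(self, factor: float) -> "PSFModel":
        """Coarser PSF for reduced-resolution desk runs."""
        if not 0 < factor <= 1:
            raise ValueError("scale factor in (0, 1]")
        return replace(self, f0_mhz=self.f0_mhz * factor,
                       fs_mhz=self.fs_mhz * factor)


# ---------------------------------------------------------------------------
# imaging planes
# ---------------------------------------------------------------------------

class A2CPlane:
    """Apical two-chamber plane: the world x-z plane seen from the apex."""

    def __init__(self, field: KinematicField, standoff_mm: float = A2C_STANDOFF_MM):
        self.z_probe = -(field.ed_shape.geometry.a_ext + standoff_mm)

    def from_world(self, pts: np.ndarray):
        pts = np.atleast_2d(pts)
        return -pts[:, 0], pts[:, 2] - self.z_probe, pts[:, 1]

    def to_world(self, x_img, y_img, elev=0.0):
        x_img = np.asarray(x_img, dtype=float)
        y_img = np.asarray(y_img, dtype=float)
        return np.stack(np.broadcast_arrays(
            -x_img, np.full_like(x_img, 0.0) + elev, y_img + self.z_probe),
            axis=-1)


class PSAXMPlane:
    """Mid short-axis plane 5.2 cm above the ED apex, normal to the LAX.

    The probe views the annulus from wall azimuth ``probe_azimuth_deg``;
    the LAX pierces the image at (0, ``center_depth_mm``).
    """

    def __init__(self, field: KinematicField,
                 center_depth_mm: float = PSAXM_CENTER_DEPTH_MM,
                 probe_azimuth_deg: float = None):
        from .views import PSAXM_PROBE_AZIMUTH_DEG
        if probe_azimuth_deg is None:
            probe_azimuth_deg = PSAXM_PROBE_AZIMUTH_DEG
        self.z_plane = field.psaxm_plane_z()
        self.center_depth = center_depth_mm
        g = np.deg2rad(probe_azimuth_deg)
        self._axis = -np.array([np.cos(g), np.sin(g)])      # beam direction
        self._lat = np.array([-np.sin(g), np.cos(g)])       # image +x
        self._probe = -self.center_depth * self._axis       # world (x, y)

    def from_world(self, pts: np.ndarray):
        pts = np.atleast_2d(pts)
        v = pts[:, :2] - self._probe[None, :]
        return (v @ self._lat, v @ self._axis, pts[:, 2] - self.z_plane)

    def to_world(self, x_img, y_img, elev=0.0):
        x_img = np.asarray(x_img, dtype=float)
        y_img = np.asarray(y_img, dtype=float)
        wx = self._probe[0] + y_img * self._axis[0] + x_img * self._lat[0]
        wy = self._probe[1] + y_img * self._axis[1] + x_img * self._lat[1]
        return np.stack(np.broadcast_arrays(
            wx, wy, np.full_like(wx, self.z_plane) + elev), axis=-1)


def make_plane(field: KinematicField, projection: str):
    if projection == "A2C":
        return A2CPlane(field)
    if projection == "pSAXM":
        return PSAXMPlane(field)
    raise ValueError(f"unknown projection {projection!r}")


# ---------------------------------------------------------------------------
# scatterers
# ---------------------------------------------------------------------------

@dataclass
class ScattererCloud:
    """Material scatterers of one speckle realization."""

    coords: np.ndarray          # (N, 3) material (d, m, phi)
    ref_positions: np.ndarray   # (N, 3) world positions at ED
    amplitudes: np.ndarray      # (N,) i.i.d. standard normal reflectivities
    seed: int
    slab_halfwidth_mm: float


def default_density(psf: PSFModel, sector: SectorConfig,
                    per_cell: float = 10.0) -> float:
    """Scatterers per mm^3 giving ``per_cell`` per resolution cell at focus."""
    fwhm_ax = 2.3548 * psf.sigma_r_mm
    fwhm_lat = np.deg2rad(2.3548 * psf.lateral_sigma_deg(sector)) \
        * sector.focus_depth * CM2MM
    fwhm_el = 2.3548 * psf.elevation_sigma_mm
    return per_cell / (fwhm_ax * fwhm_lat * fwhm_el)


def out_of_plane_excursion(field: KinematicField, plane) -> float:
    """Largest out-of-plane material excursion over the cycle (mm)."""
    d = np.linspace(0.05, 0.95, 4)
    m = np.linspace(0.02, 0.98, 60)
    phi = np.linspace(-np.pi, np.pi, 48, endpoint=False)
    dd, mm, pp = np.meshgrid(d, m, phi, indexing="ij")
    coords = np.column_stack([dd.ravel(), mm.ravel(), pp.ravel()])
    _, _, e0 = plane.from_world(field.position_from_coords(coords, 1))
    frame_es = field.t_es
    _, _, e1 = plane.from_world(field.position_from_coords(coords, frame_es))
    near = np.abs(e0) < 25.0
    if not np.any(near):
        return 0.0
    return float(np.max(np.abs(e1 - e0)[near]))


def seed_scatterers(field: KinematicField, plane, psf: PSFModel,
                    sector: SectorConfig, seed: int,
                    density: float | None = None) -> ScattererCloud:
    """Uniform scatterers in the ED wall within the (motion-expanded) slab.

    The slab is widened by the maximal out-of-plane excursion so the imaging
    plane stays populated while material moves through it; each frame the
    elevation Gaussian selects the instantaneous contributors.
    """
    if density is None:
        density = default_density(psf, sector)
    if density <= 0:
        raise ValueError("density must be positive")
    halfwidth = 4.0 * psf.elevation_sigma_mm + out_of_plane_excursion(field, plane)
    g = field.ed_shape.geometry
    rng = np.random.default_rng(seed)
    if isinstance(plane, A2CPlane):
        lo = np.array([-g.b_ext, -halfwidth, -g.a_ext])
        hi = np.array([g.b_ext, halfwidth, 0.0])
    else:
        z0 = plane.z_plane
        lo = np.array([-g.b_ext, -g.b_ext, max(z0 - halfwidth, -g.a_ext)])
        hi = np.array([g.b_ext, g.b_ext, min(z0 + halfwidth, 0.0)])
    box_vol = np.prod(hi - lo)
    n_draw = int(np.ceil(density * box_vol))
    pts = rng.uniform(lo, hi, size=(n_draw, 3))
    rho = np.hypot(pts[:, 0], pts[:, 1])
    inside = field.ed_shape.contains(rho, pts[:, 2])
    pts = pts[inside]
    amps = rng.standard_normal(n_draw)[inside]
    coords = field.material_coords(pts)
    return ScattererCloud(coords, pts, amps, seed, halfwidth)


def advect(cloud: ScattererCloud, field: KinematicField, frame: int) -> np.ndarray:
    """World positions of the cloud at ``frame`` (moves with the material)."""
    if not 1 <= frame <= field.n_frames:
        raise ValueError("frame out of range")
    return field.position_from_coords(cloud.coords, frame)


# ---------------------------------------------------------------------------
# RF frames
# ---------------------------------------------------------------------------

@dataclass
class RFFrameSet:
    """Polar-grid RF frames of one view/realization."""

    samples: np.ndarray         # (n_lines, n_samples, n_frames) float32
    angles_deg: np.ndarray      # (n_lines,)
    depths_mm: np.ndarray       # (n_samples,)
    sector: SectorConfig
    psf: PSFModel
    seed: int

    @property
    def n_frames(self) -> int:
        return self.samples.shape[2]

    def envelope(self, frame: int) -> np.ndarray:
        """Envelope (analytic-signal magnitude) of one frame, 1-based."""
        return envelope(self.samples[:, :, frame - 1])


def envelope(rf: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal along the depth axis."""
    rf = np.asarray(rf, dtype=float)
    return np.abs(hilbert(rf, axis=-1))


def depth_samples(sector: SectorConfig, psf: PSFModel) -> np.ndarray:
    dr = psf.sample_spacing_mm
    r0 = sector.d_min * CM2MM
    n = int(np.floor((sector.d_max - sector.d_min) * CM2MM / dr)) + 1
    return r0 + dr * np.arange(n)


def render_frame(positions_img: np.ndarray, amplitudes: np.ndarray,
                 sector: SectorConfig, psf: PSFModel,
                 elevation: np.ndarray | None = None) -> np.ndarray:
    """Render one RF frame from in-plane scatterer positions (mm).

    ``positions_img`` holds (x, y) image coordinates; ``elevation`` the
    out-of-plane offsets (mm) applying the slab weight.
    """
    pos = np.atleast_2d(positions_img)
    amps = np.asarray(amplitudes, dtype=float)
    if elevation is not None:
        w = np.exp(-0.5 * (np.asarray(elevation) / psf.elevation_sigma_mm) ** 2)
        amps = amps * w
    beta = np.degrees(np.arctan2(pos[:, 0], pos[:, 1]))
    r = np.hypot(pos[:, 0], pos[:, 1])
    keep = amps != 0.0
    beta, r, amps = beta[keep], r[keep], amps[keep]
    order = np.argsort(beta).astype(np.int64)
    depths = depth_samples(sector, psf)
    rf = _kernels.render_lines(
        beta, r, amps, order, np.asarray(sector.beam_angles, dtype=float),
        depths[0], psf.sample_spacing_mm, depths.size,
        psf.lateral_sigma_deg(sector), psf.sigma_r_mm, psf.carrier_k)
    return rf


def simulate_view(field: KinematicField, view_no: int, seed: int,
                  scale: float = 1.0, density: float | None = None,
                  psf: PSFModel | None = None) -> RFFrameSet:
    """Simulate the full 65-frame RF sequence of one view/realization."""
    sector = make_view(view_no).scaled(scale)
    if psf is None:
        psf = PSFModel().scaled(scale)
    plane = make_plane(field, sector.projection)
    cloud = seed_scatterers(field, plane, psf, sector, seed, density)
    depths = depth_samples(sector, psf)
    n_frames = field.n_frames
    out = np.empty((sector.n_lines, depths.size, n_frames), dtype=np.float32)
    for frame in range(1, n_frames + 1):
        pos = advect(cloud, field, frame)
        x_img, y_img, elev = plane.from_world(pos)
        rf = render_frame(np.column_stack([x_img, y_img]), cloud.amplitudes,
                          sector, psf, elevation=elev)
        out[:, :, frame - 1] = rf
    return RFFrameSet(out, np.asarray(sector.beam_angles, dtype=float),
                      depths, sector, psf, seed)


# ---------------------------------------------------------------------------
# wall masks
# ---------------------------------------------------------------------------

@dataclass
class WallMask:
    """Boolean wall map on an image grid plus the wall border polylines."""

    mask: np.ndarray
    grid_x: np.ndarray          # lateral coordinates or beam angles
    grid_y: np.ndarray          # depth coordinates (mm)
    inner_border: np.ndarray    # (K, 2) image-plane polyline
    outer_border: np.ndarray
    frame: int
    kind: str                   # "polar" | "cartesian"


def wall_contains_image_points(field: KinematicField, plane, x_img, y_img,
                               frame: int) -> np.ndarray:
    """True where image-plane points lie inside the deformed wall."""
    pts = plane.to_world(np.asarray(x_img, dtype=float),
                         np.asarray(y_img, dtype=float))
    flat = pts.reshape(-1, 3)
    shape = field.shape_at_frame(frame)
    dz = field.avpd_offset(frame)
    rho = np.hypot(flat[:, 0], flat[:, 1])
    ok = shape.contains(rho, flat[:, 2] - dz)
    return ok.reshape(np.shape(x_img))


def _border_polylines(field: KinematicField, plane, frame: int, n: int = 400):
    shape = field.shape_at_frame(frame)
    dz = field.avpd_offset(frame)
    g = shape.geometry
    if isinstance(plane, A2CPlane):
        psi = np.linspace(0.0, np.pi / 2.0, n)
        inner = []
        outer = []
        for sgn in (-1.0, 1.0):
            wi = np.stack([sgn * g.b_int * np.sin(psi), 0 * psi,
                           -g.a_int * np.cos(psi) + dz], axis=-1)
            wo = np.stack([sgn * g.b_ext * np.sin(psi), 0 * psi,
                           -g.a_ext * np.cos(psi) + dz], axis=-1)
            inner.append(wi if sgn < 0 else wi[::-1])
            outer.append(wo if sgn < 0 else wo[::-1])
        wi = np.concatenate(inner)
        wo = np.concatenate(outer)
    else:
        z_rel = plane.z_plane - dz
        ri = g.b_int * np.sqrt(max(0.0, 1.0 - (z_rel / g.a_int) ** 2))
        ro = g.b_ext * np.sqrt(max(0.0, 1.0 - (z_rel / g.a_ext) ** 2))
        ang = np.linspace(-np.pi, np.pi, n)
        wi = np.stack([ri * np.cos(ang), ri * np.sin(ang),
                       np.full_like(ang, plane.z_plane)], axis=-1)
        wo = np.stack([ro * np.cos(ang), ro * np.sin(ang),
                       np.full_like(ang, plane.z_plane)], axis=-1)
    xi, yi, _ = plane.from_world(wi)
    xo, yo, _ = plane.from_world(wo)
    return np.column_stack([xi, yi]), np.column_stack([xo, yo])


def make_mask(field: KinematicField, sector: SectorConfig, frame: int,
              psf: PSFModel | None = None,
              cartesian_grid: tuple[np.ndarray, np.ndarray] | None = None
              ) -> WallMask:
    """Wall mask from the exact deformed geometry (no image segmentation).

    With ``cartesian_grid=(x, y)`` the mask is evaluated on that regular
    image grid; otherwise on the polar RF grid of ``sector``/``psf``.
    """
    plane = make_plane(field, sector.projection)
    if cartesian_grid is not None:
        gx, gy = cartesian_grid
        xx, yy = np.meshgrid(gx, gy, indexing="ij")
        mask = wall_contains_image_points(field, plane, xx, yy, frame)
        kind = "cartesian"
        grid_x, grid_y = gx, gy
    else:
        if psf is None:
            psf = PSFModel()
        depths = depth_samples(sector, psf)
        ang = np.deg2rad(np.asarray(sector.beam_angles, dtype=float))
        xx = np.sin(ang)[:, None] * depths[None, :]
        yy = np.cos(ang)[:, None] * depths[None, :]
        mask = wall_contains_image_points(field, plane, xx, yy, frame)
        kind = "polar"
        grid_x, grid_y = np.asarray(sector.beam_angles, dtype=float), depths
    inner, outer = _border_polylines(field, plane, frame)
    return WallMask(mask, grid_x, grid_y, inner, outer, frame, kind)
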