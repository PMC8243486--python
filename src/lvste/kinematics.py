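"""Analytic kinematic model of a contracting half-spheroidal left ventricle.

The phantom wall is the region between two concentric half-spheroids cut by
the base plane ``z = 0``; the long axis (LAX) is the ``z`` axis with the apex
at negative ``z``.  The end-systolic (ES) geometry uses the internal semi-axes
72 x 15.75 mm and external semi-axes 85.5 x 29.25 mm; the end-diastolic (ED)
geometry is calibrated against an end-diastolic short diameter of 46 mm and an
end-diastolic cavity volume of 94.5 cm^3.  Intermediate shapes interpolate the
internal semi-axes linearly with the contraction phase while the external
semi-axes are solved from a smoothly interpolated wall volume (the wall is
mildly compressible, emulating a nearly incompressible hyperelastic wall with
Poisson ratio below 0.5).

Material points are labelled by normalized wall depth ``d`` (0 endocardium,
1 epicardium), normalized meridional arc fraction ``m`` (0 apex, 1 base) and
azimuth ``phi``; a point at (d, m, phi) keeps those coordinates at every
phase, which defines the material motion.  A torsional rotation about the LAX
(linear in the LAX coordinate) and a global longitudinal shift enforcing a
zero mean longitudinal displacement near the apex (the AVPD correction) are
superposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import CubicSpline

MM3_PER_CM3 = 1000.0

# Printed geometry (mm) and deformation targets.
ES_A_INT = 72.0
ES_B_INT = 15.75
ES_A_EXT = 85.5
ES_B_EXT = 29.25
ED_B_INT = 23.0          # LVEDd = 46 mm
LVEDV_CM3 = 94.5
LVESV_CM3 = 37.4

# Rotation peaks (degrees) entering the torsion law.
THETA_A_ES = 13.0
THETA_B_ES = -6.9

# Temporal profile: 65 frames at 65 fps, peak contraction ~370 ms after ED.
N_FRAMES = 65
FPS = 65.0
T_RISE_END = 24.0 / 65.0      # ~0.369 s, the frame closest to the nominal 370 ms
T_PLATEAU_END = 0.55
T_FALL_END = 0.95

# Calibrated constants (frozen; see docs/methods.md).  The wall loses volume
# at peak contraction (ED wall volume = ratio x ES wall volume), material
# slides slightly apex-ward along the meridian at peak contraction
# (arc-fraction exponent 1 + bias * phase), and the global strain readouts
# use fixed transmural positions.
WALL_VOLUME_RATIO_ED = 1.2348669
MERIDIONAL_BIAS = 0.0185633
GLS_DEPTH_WEIGHT = 0.5041154    # weight of the endocardial meridian in GLS
GCS_DEPTH = 0.0                 # GCS is endocardial
PSAXM_ABOVE_APEX = 52.0         # mm above the ED internal apex (pSAXM level)
AVPD_BAND = (0.15, 0.25)        # LAX band (fraction of LA) for the AVPD fix

_ARC_N = 2048


def stress_strain(strain):
    """Uniaxial stress (Pa) of the wall material at a given strain.

    The empirical exponential law ``sigma = 7525.8 (exp(10.25 eps) - 1)``
    describing PVA cryogel; kept as a documented material utility (the motion
    itself is kinematic).
    """
    eps = np.asarray(strain, dtype=float)
    return 7525.8 * (np.exp(10.25 * eps) - 1.0)


def norm_profile(t):
    """Normalized amplitude of pressure load and rotation over one cycle.

    Raised-cosine rise on [0, 0.369 s], unit plateau to 0.55 s, raised-cosine
    fall to zero at 0.95 s, zero until the cycle end (1 s).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < -1e-12) or np.any(t > N_FRAMES / FPS + 1e-12):
        raise ValueError("time outside the cardiac cycle")
    out = np.zeros_like(t)
    rise = t < T_RISE_END
    out[rise] = 0.5 * (1.0 - np.cos(np.pi * t[rise] / T_RISE_END))
    plateau = (t >= T_RISE_END) & (t <= T_PLATEAU_END)
    out[plateau] = 1.0
    fall = (t > T_PLATEAU_END) & (t < T_FALL_END)
    out[fall] = 0.5 * (1.0 + np.cos(np.pi * (t[fall] - T_PLATEAU_END)
                                    / (T_FALL_END - T_PLATEAU_END)))
    return out if out.ndim else float(out)


def frame_times(n_frames: int = N_FRAMES, fps: float = FPS) -> np.ndarray:
    """Acquisition times of frames 1..n (frame 1 at t = 0)."""
    return np.arange(n_frames) / fps


def frame_norm(n_frames: int = N_FRAMES, fps: float = FPS) -> np.ndarray:
    return np.atleast_1d(norm_profile(frame_times(n_frames, fps)))


def end_systole_frame(n_frames: int = N_FRAMES, fps: float = FPS) -> int:
    """1-based index of the end-systolic frame (first frame of peak Norm)."""
    return int(np.argmax(frame_norm(n_frames, fps))) + 1


def cavity_volume(a, b):
    """Half-spheroid cavity volume (cm^3) from long/short semi-axes (mm)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("semi-axes must be positive")
    v = (2.0 / 3.0) * np.pi * a * b * b / MM3_PER_CM3
    return float(v) if v.ndim == 0 else v


def rotation_angle(x_p, la, t, *, sign: float = 1.0):
    """Torsional angular displacement (degrees) at LAX coordinate ``x_p``.

    Linear profile between the basal and apical rotation peaks scaled by the
    temporal profile.  ``x_p`` is the distance of the point's LAX projection
    from the apex; ``la`` the current LAX length.  ``sign`` flips the global
    sense of rotation (the nominal peak magnitudes are reproduced at
    ``x_p = la/6`` and ``x_p = 5 la/6`` with the default sign).
    """
    la = np.asarray(la, dtype=float)
    if np.any(la <= 0):
        raise ValueError("LAX length must be positive")
    nrm = norm_profile(t)
    theta_b = THETA_B_ES * nrm
    theta_a = THETA_A_ES * nrm
    x_p = np.asarray(x_p, dtype=float)
    theta = (theta_b - theta_a) / ((2.0 / 3.0) * la) * (x_p - la / 6.0) - theta_b
    return sign * theta


@dataclass(frozen=True)
class SpheroidGeometry:
    """Internal/external semi-axes (mm) of the wall at one phase."""

    a_int: float
    b_int: float
    a_ext: float
    b_ext: float
    phase_label: str = "intermediate"

    def __post_init__(self):
        if not (0 < self.b_int < self.a_int):
            raise ValueError("internal semi-axes must satisfy 0 < b < a")
        if self.a_ext <= self.a_int or self.b_ext <= self.b_int:
            raise ValueError("external surface must enclose the internal one")

    @property
    def wall_volume_mm3(self) -> float:
        return (2.0 / 3.0) * np.pi * (self.a_ext * self.b_ext ** 2
                                      - self.a_int * self.b_int ** 2)

    @property
    def cavity_volume_cm3(self) -> float:
        return cavity_volume(self.a_int, self.b_int)


def _ed_internal_axes() -> tuple[float, float]:
    b = ED_B_INT
    a = 3.0 * LVEDV_CM3 * MM3_PER_CM3 / (2.0 * np.pi * b * b)
    return a, b


def _solve_thickness(a_int: float, b_int: float, wall_volume: float) -> float:
    """Equal thickness increment t with (a+t)(b+t)^2 - a b^2 = 3 V_w / (2 pi)."""
    target = a_int * b_int ** 2 + wall_volume / ((2.0 / 3.0) * np.pi)
    # cubic in t: t^3 + (a+2b) t^2 + (b^2+2ab) t + (a b^2 - target) = 0
    roots = np.roots([1.0, a_int + 2 * b_int,
                      b_int ** 2 + 2 * a_int * b_int,
                      a_int * b_int ** 2 - target])
    real = roots[np.abs(roots.imag) < 1e-9].real
    pos = real[real > 0]
    if pos.size == 0:
        raise RuntimeError("no positive wall thickness solution")
    return float(pos.min())


def geometry_at_phase(s: float, *, wall_volume_ratio: float = WALL_VOLUME_RATIO_ED
                      ) -> SpheroidGeometry:
    """Wall geometry at contraction phase ``s`` (0 = ED, 1 = ES)."""
    if not (-1e-9 <= s <= 1 + 1e-9):
        raise ValueError("phase must lie in [0, 1]")
    s = float(np.clip(s, 0.0, 1.0))
    a_ed, b_ed = _ed_internal_axes()
    a_int = (1 - s) * a_ed + s * ES_A_INT
    b_int = (1 - s) * b_ed + s * ES_B_INT
    v_es = (2.0 / 3.0) * np.pi * (ES_A_EXT * ES_B_EXT ** 2 - ES_A_INT * ES_B_INT ** 2)
    v_wall = ((1 - s) * wall_volume_ratio + s) * v_es
    if s == 1.0:
        a_ext, b_ext = ES_A_EXT, ES_B_EXT
    else:
        t = _solve_thickness(a_int, b_int, v_wall)
        a_ext, b_ext = a_int + t, b_int + t
    label = "ED" if s == 0.0 else ("ES" if s == 1.0 else "intermediate")
    return SpheroidGeometry(a_int, b_int, a_ext, b_ext, label)


class _Meridian:
    """Quarter-ellipse meridian rho = B sin(psi), z = -A cos(psi) with an
    arc-length parametrization psi(m), m in [0, 1] from apex to base."""

    def __init__(self, a: float, b: float):
        self.a = a
        self.b = b
        psi = np.linspace(0.0, np.pi / 2.0, _ARC_N + 1)
        speed = np.sqrt((b * np.cos(psi)) ** 2 + (a * np.sin(psi)) ** 2)
        arc = cumulative_trapezoid(speed, psi, initial=0.0)
        self.length = float(arc[-1])
        self._psi_of_m = CubicSpline(arc / self.length, psi)
        self._dpsi_dm = self._psi_of_m.derivative()

    def point(self, m):
        psi = self._psi_of_m(m)
        return self.b * np.sin(psi), -self.a * np.cos(psi)

    def point_and_deriv(self, m):
        psi = self._psi_of_m(m)
        dpsi = self._dpsi_dm(m)
        rho = self.b * np.sin(psi)
        z = -self.a * np.cos(psi)
        drho = self.b * np.cos(psi) * dpsi
        dz = self.a * np.sin(psi) * dpsi
        return rho, z, drho, dz


class _PhaseShape:
    """Meridians of both surfaces at one phase plus blended-wall helpers.

    ``arc_exponent`` maps the material arc label m to the geometric arc
    fraction q = m**arc_exponent; an exponent above 1 slides material
    apex-ward, redistributing the longitudinal shortening along the wall.
    """

    def __init__(self, geometry: SpheroidGeometry, arc_exponent: float = 1.0):
        self.geometry = geometry
        self.arc_exponent = arc_exponent
        self.inner = _Meridian(geometry.a_int, geometry.b_int)
        self.outer = _Meridian(geometry.a_ext, geometry.b_ext)

    def _arc(self, m):
        e = self.arc_exponent
        if e == 1.0:
            return np.asarray(m, dtype=float), np.ones_like(np.asarray(m, dtype=float))
        m = np.asarray(m, dtype=float)
        safe = np.maximum(m, 1e-300)
        return m ** e, e * safe ** (e - 1.0)

    def wall_point(self, d, m):
        q, _ = self._arc(m)
        ri, zi = self.inner.point(q)
        ro, zo = self.outer.point(q)
        return (1 - d) * ri + d * ro, (1 - d) * zi + d * zo

    def wall_point_and_jac(self, d, m):
        q, dq = self._arc(m)
        ri, zi, dri, dzi = self.inner.point_and_deriv(q)
        ro, zo, dro, dzo = self.outer.point_and_deriv(q)
        rho = (1 - d) * ri + d * ro
        z = (1 - d) * zi + d * zo
        drho_dd = ro - ri
        dz_dd = zo - zi
        drho_dm = ((1 - d) * dri + d * dro) * dq
        dz_dm = ((1 - d) * dzi + d * dzo) * dq
        return rho, z, drho_dd, dz_dd, drho_dm, dz_dm

    def invert(self, rho, z, n_iter: int = 70):
        """Material (d, m) of meridian-plane points (rho >= 0, z <= 0)."""
        rho = np.asarray(rho, dtype=float)
        z = np.asarray(z, dtype=float)
        lo = np.zeros_like(rho)
        hi = np.ones_like(rho)

        def f(q):
            ri, zi = self.inner.point(q)
            ro, zo = self.outer.point(q)
            return (ro - ri) * (z - zi) - (zo - zi) * (rho - ri)

        flo = f(lo)
        for _ in range(n_iter):
            mid = 0.5 * (lo + hi)
            fm = f(mid)
            take_lo = (fm > 0) == (flo > 0)
            lo = np.where(take_lo, mid, lo)
            flo = np.where(take_lo, fm, flo)
            hi = np.where(take_lo, hi, mid)
        q = 0.5 * (lo + hi)
        ri, zi = self.inner.point(q)
        ro, zo = self.outer.point(q)
        seg2 = (ro - ri) ** 2 + (zo - zi) ** 2
        d = ((rho - ri) * (ro - ri) + (z - zi) * (zo - zi)) / seg2
        m = q ** (1.0 / self.arc_exponent) if self.arc_exponent != 1.0 else q
        return d, m

    def contains(self, rho, z, tol: float = 0.0):
        g = self.geometry
        rho = np.asarray(rho, dtype=float)
        z = np.asarray(z, dtype=float)
        fi = (rho / g.b_int) ** 2 + (z / g.a_int) ** 2
        fo = (rho / g.b_ext) ** 2 + (z / g.a_ext) ** 2
        return (fi >= 1.0 - tol) & (fo <= 1.0 + tol) & (z <= 1e-9 + tol * g.a_int)


class KinematicField:
    """Exact material motion of the LV wall over the cardiac cycle.

    Positions and displacements are in mm; frames are 1-based (frame 1 = ED,
    the reference configuration).
    """

    def __init__(self, n_frames: int = N_FRAMES, fps: float = FPS,
                 rotation_sign: float = 1.0,
                 wall_volume_ratio: float = WALL_VOLUME_RATIO_ED,
                 meridional_bias: float = MERIDIONAL_BIAS,
                 avpd_band: tuple[float, float] = AVPD_BAND):
        self.n_frames = n_frames
        self.fps = fps
        self.rotation_sign = rotation_sign
        self.wall_volume_ratio = wall_volume_ratio
        self.meridional_bias = meridional_bias
        self.avpd_band = avpd_band
        self.norm = frame_norm(n_frames, fps)
        self.t_es = end_systole_frame(n_frames, fps)
        self._shapes: dict[float, _PhaseShape] = {}
        self._avpd = self._compute_avpd_offsets()

    # -- geometry handling ------------------------------------------------
    def shape_at(self, s: float) -> _PhaseShape:
        key = round(float(s), 12)
        if key not in self._shapes:
            self._shapes[key] = _PhaseShape(
                geometry_at_phase(key, wall_volume_ratio=self.wall_volume_ratio),
                arc_exponent=1.0 + self.meridional_bias * key)
        return self._shapes[key]

    def shape_at_frame(self, frame: int) -> _PhaseShape:
        return self.shape_at(self.norm[frame - 1])

    @property
    def ed_shape(self) -> _PhaseShape:
        return self.shape_at(0.0)

    # -- AVPD correction ---------------------------------------------------
    def _band_mean_uz(self, s: float) -> float:
        """Mean longitudinal displacement (vs ED) of wall material located,
        at phase ``s``, within the configured LAX band above the apex."""
        nd, nm = 16, 600
        d = np.linspace(0.0, 1.0, nd)
        m = np.linspace(0.0, 1.0, nm)
        dd, mm = np.meshgrid(d, m, indexing="ij")
        shape0 = self.shape_at(0.0)
        shape1 = self.shape_at(s)
        _, z0 = shape0.wall_point(dd, mm)
        rho1, z1, drdd, dzdd, drdm, dzdm = shape1.wall_point_and_jac(dd, mm)
        la = shape1.geometry.a_int
        x_p = z1 + la
        band = (x_p >= self.avpd_band[0] * la) & (x_p <= self.avpd_band[1] * la)
        # deformed volume weights: rho * |d(rho,z)/d(d,m)|
        w = rho1 * np.abs(drdd * dzdm - dzdd * drdm)
        w = np.where(band, w, 0.0)
        if w.sum() <= 0:
            raise RuntimeError("empty AVPD band")
        return float(np.sum(w * (z1 - z0)) / np.sum(w))

    def _compute_avpd_offsets(self) -> np.ndarray:
        offsets = np.zeros(self.n_frames)
        cache: dict[float, float] = {}
        for i, s in enumerate(self.norm):
            key = round(float(s), 12)
            if key == 0.0:
                continue
            if key not in cache:
                cache[key] = -self._band_mean_uz(key)
            offsets[i] = cache[key]
        return offsets

    def avpd_offset(self, frame: int) -> float:
        """Longitudinal shift applied to the whole field at ``frame``."""
        return float(self._avpd[frame - 1])

    # -- material coordinates ---------------------------------------------
    def material_coords(self, points: np.ndarray) -> np.ndarray:
        """(d, m, phi) of reference (ED) points, shape (N, 3)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rho = np.hypot(pts[:, 0], pts[:, 1])
        phi = np.arctan2(pts[:, 1], pts[:, 0])
        shape0 = self.ed_shape
        inside = shape0.contains(rho, pts[:, 2], tol=1e-6)
        if not np.all(inside):
            raise ValueError("point outside the ED wall")
        d, m = shape0.invert(rho, pts[:, 2])
        return np.column_stack([np.clip(d, 0.0, 1.0), np.clip(m, 0.0, 1.0), phi])

    def position_from_coords(self, coords: np.ndarray, frame: int) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        d, m, phi = coords[:, 0], coords[:, 1], coords[:, 2]
        s = self.norm[frame - 1]
        t = (frame - 1) / self.fps
        shape = self.shape_at(s)
        rho, z = shape.wall_point(d, m)
        la = shape.geometry.a_int
        x_p = z + la
        theta = np.deg2rad(rotation_angle(x_p, la, t, sign=self.rotation_sign))
        alpha = phi + theta
        out = np.column_stack([rho * np.cos(alpha), rho * np.sin(alpha),
                               z + self._avpd[frame - 1]])
        return out

    def position(self, points: np.ndarray, frame: int) -> np.ndarray:
        return self.position_from_coords(self.material_coords(points), frame)

    def displacement(self, points: np.ndarray, frame: int) -> np.ndarray:
        """u(X, frame) for reference points X inside the ED wall."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if not 1 <= frame <= self.n_frames:
            raise ValueError("frame out of range")
        return self.position(pts, frame) - pts

    # -- deformation gradient ----------------------------------------------
    def _config_jacobian(self, coords: np.ndarray, frame: int) -> np.ndarray:
        """d(position)/d(d, m, phi) at one frame, shape (N, 3, 3)."""
        coords = np.atleast_2d(coords)
        d, m, phi = coords[:, 0], coords[:, 1], coords[:, 2]
        s = self.norm[frame - 1]
        t = (frame - 1) / self.fps
        shape = self.shape_at(s)
        rho, z, drdd, dzdd, drdm, dzdm = shape.wall_point_and_jac(d, m)
        la = shape.geometry.a_int
        x_p = z + la
        theta = np.deg2rad(rotation_angle(x_p, la, t, sign=self.rotation_sign))
        nrm = self.norm[frame - 1]
        slope = np.deg2rad(self.rotation_sign * (THETA_B_ES - THETA_A_ES) * nrm
                           / ((2.0 / 3.0) * la))
        alpha = phi + theta
        ca, sa = np.cos(alpha), np.sin(alpha)
        dalpha_dd = slope * dzdd
        dalpha_dm = slope * dzdm
        n = coords.shape[0]
        jac = np.empty((n, 3, 3))
        # columns: d, m, phi
        jac[:, 0, 0] = drdd * ca - rho * sa * dalpha_dd
        jac[:, 1, 0] = drdd * sa + rho * ca * dalpha_dd
        jac[:, 2, 0] = dzdd
        jac[:, 0, 1] = drdm * ca - rho * sa * dalpha_dm
        jac[:, 1, 1] = drdm * sa + rho * ca * dalpha_dm
        jac[:, 2, 1] = dzdm
        jac[:, 0, 2] = -rho * sa
        jac[:, 1, 2] = rho * ca
        jac[:, 2, 2] = 0.0
        return jac

    def deformation_gradient(self, points: np.ndarray, frame: int) -> np.ndarray:
        """F(X, frame) = dx/dX, shape (N, 3, 3)."""
        coords = self.material_coords(points)
        m_t = self._config_jacobian(coords, frame)
        m_0 = self._config_jacobian(coords, 1)
        return m_t @ np.linalg.inv(m_0)

    # -- global measures ----------------------------------------------------
    def wall_volume(self, frame: int) -> float:
        return self.shape_at_frame(frame).geometry.wall_volume_mm3

    def cavity_volume_at_frame(self, frame: int) -> float:
        g = self.shape_at_frame(frame).geometry
        return g.cavity_volume_cm3

    def _meridian_length(self, d: float, s: float, n: int = 4000) -> float:
        shape = self.shape_at(s)
        m = np.linspace(0.0, 1.0, n)
        rho, z = shape.wall_point(np.full_like(m, d), m)
        return float(np.sum(np.hypot(np.diff(rho), np.diff(z))))

    def psaxm_plane_z(self) -> float:
        """World z of the pSAXM imaging plane (fixed in space)."""
        return -self.ed_shape.geometry.a_int + PSAXM_ABOVE_APEX

    def _plane_material_m(self, d: float, z_plane: float, s: float = 0.0) -> float:
        shape = self.shape_at(s)
        lo, hi = 0.0, 1.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            _, z = shape.wall_point(d, mid)
            if z < z_plane:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def global_strains(self, *, gls_weight: float = GLS_DEPTH_WEIGHT,
                       gcs_depth: float = GCS_DEPTH) -> tuple[float, float, float]:
        """(GLS, GCS, GRS) in percent, Lagrangian, ES versus ED.

        GLS is a transmural weighted average of the meridian-length strains of
        the endo- and epicardial contours (A2C plane); GCS is the
        circumference strain of the material ring sitting at the pSAXM level
        at ED at a fixed transmural depth; GRS the transmural-segment length
        strain at the same level.
        """
        s_es = 1.0
        l0_in = self._meridian_length(0.0, 0.0)
        l1_in = self._meridian_length(0.0, s_es)
        l0_out = self._meridian_length(1.0, 0.0)
        l1_out = self._meridian_length(1.0, s_es)
        e_in = 0.5 * ((l1_in / l0_in) ** 2 - 1.0)
        e_out = 0.5 * ((l1_out / l0_out) ** 2 - 1.0)
        gls = 100.0 * (gls_weight * e_in + (1 - gls_weight) * e_out)

        z_p = self.psaxm_plane_z()
        m_c = self._plane_material_m(gcs_depth, z_p)
        shape0, shape1 = self.shape_at(0.0), self.shape_at(s_es)
        rho0, _ = shape0.wall_point(gcs_depth, m_c)
        rho1, _ = shape1.wall_point(gcs_depth, m_c)
        gcs = 100.0 * 0.5 * ((rho1 / rho0) ** 2 - 1.0)

        m_en = self._plane_material_m(0.0, z_p)
        m_ep = self._plane_material_m(1.0, z_p)
        p0 = np.array([shape0.wall_point(0.0, m_en), shape0.wall_point(1.0, m_ep)])
        p1 = np.array([shape1.wall_point(0.0, m_en), shape1.wall_point(1.0, m_ep)])
        th0 = np.linalg.norm(p0[1] - p0[0])
        th1 = np.linalg.norm(p1[1] - p1[0])
        grs = 100.0 * 0.5 * ((th1 / th0) ** 2 - 1.0)
        return gls, gcs, grs


def avpd_correct(displacements: np.ndarray, x_p: np.ndarray, la: float,
                 band: tuple[float, float] = AVPD_BAND,
                 weights: np.ndarray | None = None) -> np.ndarray:
    """Subtract the band-mean LAX displacement from a displacement field.

    ``displacements`` has the LAX component in its last column; ``x_p`` are
    the LAX distances of the points from the apex.
    """
    u = np.array(displacements, dtype=float, copy=True)
    x_p = np.asarray(x_p, dtype=float)
    sel = (x_p >= band[0] * la) & (x_p <= band[1] * la)
    if not np.any(sel):
        raise ValueError("empty AVPD band")
    w = np.ones(sel.sum()) if weights is None else np.asarray(weights)[sel]
    u[:, -1] -= np.average(u[sel, -1], weights=w)
    return u
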