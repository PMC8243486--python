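"""End-to-end experiment pipeline: simulate, track, estimate, analyze.

``ViewContext`` precomputes everything deterministic for one view (sector,
PSF, masks, grids, anatomical directions, window sizes); ``estimate_view``
runs the stochastic part for one speckle realization and returns estimate
and reference strain maps on the same tracked nodes.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import aha, errors
from .kinematics import KinematicField
from .simulator import (PSFModel, make_mask, make_plane, simulate_view,
                        wall_contains_image_points)
from .smoothing import ESTIMATE_P
from .strain import (DirectionField, directions_a2c, directions_psaxm,
                     run_displacement_chain, strain_maps_from_accumulated,
                     StrainMaps)
from .tracking import (CartesianGrid, LINE_INTERP, PolarDisplacementField,
                       WindowSpec, _node_grid, fuse_bidirectional,
                       hbm_displacement, interpolate_lines, size_windows)
from .views import PSAXM_CENTER_DEPTH_MM, SectorConfig, make_view


@dataclass
class ViewContext:
    """Deterministic per-view precomputation shared by all realizations."""

    field: KinematicField
    sector: SectorConfig
    psf: PSFModel
    plane: object
    windows: WindowSpec
    polar_masks: np.ndarray          # (n_frames, n_lines, n_interp_samples)
    grid: CartesianGrid
    cart_masks: np.ndarray           # (n_frames, nx, ny)
    directions: DirectionField       # at frame-1 wall grid nodes
    component_names: tuple[str, str]
    scale: float

    @property
    def mask1(self) -> np.ndarray:
        return self.cart_masks[0]


def max_reference_displacement(field: KinematicField, plane, sector,
                               n_probe: int = 2500, seed: int = 12345):
    """Largest interframe axial/lateral displacement of wall material, from
    the exact reference motion (used to size the matching windows)."""
    rng = np.random.default_rng(seed)
    coords = np.column_stack([rng.uniform(0, 1, n_probe),
                              rng.uniform(0.02, 1, n_probe),
                              rng.uniform(-np.pi, np.pi, n_probe)])
    max_ax, max_lat = 0.0, 0.0
    prev = None
    for frame in range(1, field.n_frames + 1):
        pos = field.position_from_coords(coords, frame)
        x, y, e = plane.from_world(pos)
        beta = np.arctan2(x, y)
        r = np.hypot(x, y)
        if prev is not None:
            b0, r0, e0 = prev
            near = np.abs(e0) < 10.0
            if np.any(near):
                max_ax = max(max_ax, float(np.max(np.abs(r - r0)[near])))
                max_lat = max(max_lat, float(np.rad2deg(
                    np.max(np.abs(beta - b0)[near]))))
        prev = (beta, r, e)
    return max_ax, max_lat


def build_view_context(field: KinematicField, view_no: int,
                       scale: float = 1.0) -> ViewContext:
    sector = make_view(view_no).scaled(scale)
    psf = PSFModel().scaled(scale)
    plane = make_plane(field, sector.projection)

    max_ax, max_lat = max_reference_displacement(field, plane, sector)
    windows = size_windows(max_ax, max_lat, psf, sector)

    # polar masks at the interpolated axial resolution
    from .simulator import depth_samples
    depths = depth_samples(sector, psf)
    dri = psf.sample_spacing_mm / LINE_INTERP
    depths_i = depths[0] + dri * np.arange((depths.size - 1) * LINE_INTERP + 1)
    ang = np.deg2rad(np.asarray(sector.beam_angles, dtype=float))
    xx = np.sin(ang)[:, None] * depths_i[None, :]
    yy = np.cos(ang)[:, None] * depths_i[None, :]
    n_frames = field.n_frames
    polar_masks = np.zeros((n_frames, ang.size, depths_i.size), dtype=bool)
    for f in range(1, n_frames + 1):
        polar_masks[f - 1] = wall_contains_image_points(field, plane, xx, yy, f)

    # Cartesian grid covering the wall through the whole cycle, clipped to
    # the sector, with the standard 0.2 mm pitch
    m1 = make_mask(field, sector, 1, psf=psf)
    union = polar_masks.any(axis=0)
    xs = xx[union]
    ys = yy[union]
    grid = CartesianGrid.from_bbox(xs.min(), xs.max(), ys.min(), ys.max())
    gx, gy = grid.meshgrid()
    cart_masks = np.zeros((n_frames,) + gx.shape, dtype=bool)
    beta_g = np.degrees(np.arctan2(gx, gy))
    r_g = np.hypot(gx, gy)
    in_sector = (beta_g >= sector.beam_angles[0] - 1e-9) & \
        (beta_g <= sector.beam_angles[-1] + 1e-9) & \
        (r_g >= depths_i[0]) & (r_g <= depths_i[-1])
    for f in range(1, n_frames + 1):
        cart_masks[f - 1] = wall_contains_image_points(
            field, plane, gx, gy, f) & in_sector

    ix, iy = np.where(cart_masks[0])
    pts = np.column_stack([grid.x[ix], grid.y[iy]])
    if sector.projection == "pSAXM":
        directions = directions_psaxm(pts, np.array([0.0, PSAXM_CENTER_DEPTH_MM]))
        names = ("eC", "eR")
    else:
        directions = directions_a2c(pts, m1.inner_border, m1.outer_border)
        names = ("eL", "eR")
    return ViewContext(field, sector, psf, plane, windows, polar_masks,
                       grid, cart_masks, directions, names, scale)


def _pair_templates(ctx: ViewContext) -> list[PolarDisplacementField]:
    """Final-iteration node sets per frame pair (for reference sampling)."""
    dri = ctx.psf.sample_spacing_mm / LINE_INTERP
    dl = ctx.sector.line_spacing_deg
    ka = max(3, int(round(ctx.windows.kernel_ax_mm[-1] / dri)))
    kl = max(3, int(round(ctx.windows.kernel_lat_deg[-1] / dl)))
    sp_ax = max(1, int(round(ka / 3)))
    sp_lat = max(1, int(round(kl / 3)))
    out = []
    angles = np.asarray(ctx.sector.beam_angles, dtype=float)
    for t in range(ctx.field.n_frames - 1):
        mask = ctx.polar_masks[t] | ctx.polar_masks[t + 1]
        nl, na = _node_grid(mask, sp_lat, sp_ax)
        ang = angles[nl]
        dep = ctx.sector.d_min * 10.0 + na * dri
        zero = np.zeros(nl.size)
        out.append(PolarDisplacementField(nl, na, ang, dep, zero.copy(),
                                          zero.copy(), zero + 1.0,
                                          np.ones(nl.size, dtype=bool)))
    return out


def track_view(ctx: ViewContext, rf_samples: np.ndarray
               ) -> list[PolarDisplacementField]:
    """Bidirectional 3-iteration HBM on all consecutive frame pairs."""
    frames = [interpolate_lines(rf_samples[:, :, t])
              for t in range(rf_samples.shape[2])]
    fields = []
    for t in range(len(frames) - 1):
        mask = ctx.polar_masks[t] | ctx.polar_masks[t + 1]
        fwd = hbm_displacement(frames[t], frames[t + 1], ctx.windows,
                               ctx.psf, ctx.sector, mask)
        bwd = hbm_displacement(frames[t + 1], frames[t], ctx.windows,
                               ctx.psf, ctx.sector, mask)
        fields.append(fuse_bidirectional(fwd, bwd))
    return fields


def pair_masks_list(ctx: ViewContext) -> list[np.ndarray]:
    return [ctx.cart_masks[t] for t in range(ctx.field.n_frames - 1)]


def reference_maps(ctx: ViewContext,
                   templates: list[PolarDisplacementField] | None = None
                   ) -> StrainMaps:
    if templates is None:
        templates = _pair_templates(ctx)
    from .strain import reference_strain_maps
    return reference_strain_maps(ctx.field, ctx.plane, templates, ctx.grid,
                                 ctx.mask1, pair_masks_list(ctx),
                                 ctx.directions, ctx.component_names)


def estimate_maps(ctx: ViewContext, tracked: list[PolarDisplacementField],
                  p: float = ESTIMATE_P, strategy: str = "xcc") -> StrainMaps:
    acc = run_displacement_chain(tracked, ctx.grid, ctx.mask1,
                                 pair_masks_list(ctx), p, strategy=strategy)
    return strain_maps_from_accumulated(acc, ctx.mask1, ctx.directions,
                                        ctx.component_names)


def run_realization(ctx: ViewContext, seed: int,
                    density: float | None = None) -> StrainMaps:
    """Simulate one speckle realization of the view and estimate strain."""
    rf = simulate_view(ctx.field, ctx.sector.view_no, seed, scale=ctx.scale,
                       density=density)
    tracked = track_view(ctx, rf.samples)
    return estimate_maps(ctx, tracked)


# ---------------------------------------------------------------------------
# per-view error analysis
# ---------------------------------------------------------------------------

def view_anatomy(ctx: ViewContext):
    """AHA17 anatomy and per-frame area factors of the tracked nodes."""
    ix, iy = np.where(ctx.mask1)
    pts = np.column_stack([ctx.grid.x[ix], ctx.grid.y[iy]])
    anatomy = aha.assign_aha17(ctx.field, ctx.plane, pts)
    factors = aha.node_area_factors(ctx.field, ctx.plane, pts)
    return anatomy, factors


def subsegment_curves(maps_est: StrainMaps, maps_ref: StrainMaps,
                      nodes: np.ndarray, component: str,
                      t_es: int) -> errors.StrainCurve:
    est = maps_est.components[component][nodes].mean(axis=0).astype(float)
    ref = maps_ref.components[component][nodes].mean(axis=0).astype(float)
    return errors.StrainCurve(est, ref, t_es)


def analyze_view(ctx: ViewContext, estimates: list[StrainMaps],
                 reference: StrainMaps, schemes: tuple[int, ...],
                 limits: tuple[float, ...] = errors.SAAA_LIMITS,
                 segments: tuple[int, ...] | None = None):
    """Error tables and SAAA for one view over all realizations.

    Returns (rows, saaa_rows): per (segment, scheme, component) robust error
    summaries and per (segment, component, limit) SAAA results.
    """
    anatomy, factors = view_anatomy(ctx)
    pixel_area = ctx.grid.pitch ** 2
    t_es = ctx.field.t_es
    if segments is None:
        segments = ctx.sector.imaged_segments
    rows = []
    saaa_rows = []
    for seg in segments:
        node_sel = np.flatnonzero(anatomy.segment == seg)
        if node_sel.size < 4:
            continue
        per_scheme = {}
        mss_list = []
        for scheme_no in schemes:
            scheme = aha.division_scheme(scheme_no)
            try:
                subs = aha.divide(node_sel, anatomy, scheme, seg, factors,
                                  pixel_area)
            except ValueError:
                continue
            agg_by_comp = {}
            for comp in ctx.component_names:
                curves = []
                for est in estimates:
                    for nodes in subs.node_sets:
                        curves.append(subsegment_curves(est, reference,
                                                        nodes, comp, t_es))
                agg = errors.summarize_errors(curves)
                agg_by_comp[comp] = agg
                rows.append(dict(
                    view=ctx.sector.view_no, view_type=ctx.sector.view_type,
                    projection=ctx.sector.projection, segment=seg,
                    scheme=scheme_no, component=comp, mss_mm2=subs.mss,
                    n_subsegments=len(subs.node_sets),
                    n_samples=agg.n_samples, n_excluded=agg.n_excluded,
                    med=agg.med, mad=agg.mad, medn=agg.medn, madn=agg.madn,
                    max_e_es=agg.max_e_es, max_ne_es=agg.max_ne_es,
                    mxcc=agg.mxcc))
            per_scheme[scheme_no] = (subs.mss, agg_by_comp)
            mss_list.append(subs.mss)
        if not per_scheme:
            continue
        ordered = sorted(per_scheme)
        for comp in ctx.component_names:
            points = [(per_scheme[s][0], per_scheme[s][1][comp].max_ne_es)
                      for s in ordered]
            for limit in limits:
                res = errors.saaa(points, limit)
                saaa_rows.append(dict(
                    view=ctx.sector.view_no, view_type=ctx.sector.view_type,
                    projection=ctx.sector.projection, segment=seg,
                    component=comp, limit_percent=limit, saaa=str(res),
                    saaa_mm2=res.value_mm2 if res.value_mm2 is not None
                    else np.nan, sentinel=res.sentinel or ""))
    return rows, saaa_rows


def mean_aha17_segment_area(field: KinematicField | None = None,
                            scale: float = 0.25) -> float:
    """Cycle-mean AHA17 segment cross-section area (mm^2) of the phantom.

    Averages the per-frame wall cross-section areas of the segments visible
    in the two full views (7 in A2C, 6 in pSAXM) over all 65 frames.
    """
    if field is None:
        field = KinematicField()
    per_segment = []
    for view_no in (5, 1):
        ctx = build_view_context(field, view_no, scale=scale)
        anatomy, factors = view_anatomy(ctx)
        areas = aha.segment_areas(anatomy, factors, ctx.grid.pitch ** 2,
                                  ctx.sector.imaged_segments)
        per_segment.extend(a.mean() for a in areas.values())
    return float(np.mean(per_segment))


# ---------------------------------------------------------------------------
# study runner
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Selection of views, realizations and analysis settings."""

    views: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9)
    seeds: tuple[int, ...] = tuple(range(1, 11))
    schemes: tuple[int, ...] = tuple(range(1, 11))
    limits: tuple[float, ...] = errors.SAAA_LIMITS
    scale: float = 0.25
    density_per_cell: float | None = None
    strategy: str = "xcc"
    out_dir: str = "study_out"

    def __post_init__(self):
        if not self.views or not self.seeds or not self.schemes:
            raise ValueError("views, seeds and schemes must be non-empty")
        if not 0 < self.scale <= 1:
            raise ValueError("scale must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path):
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        return cls(**kw)


def run_study(config: StudyConfig, field: KinematicField | None = None):
    """Full pipeline for every (view, seed): simulate, track, estimate,
    analyze; writes CSV tables, a JSON summary and a plain-text log."""
    import pandas as pd

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if field is None:
        field = KinematicField()
    log_lines = []
    all_rows, all_saaa = [], []
    summary = {"views": {}, "config": {
        "views": list(config.views), "seeds": list(config.seeds),
        "schemes": list(config.schemes), "limits": list(config.limits),
        "scale": config.scale, "strategy": config.strategy}}
    for view_no in config.views:
        t0 = time.time()
        ctx = build_view_context(field, view_no, scale=config.scale)
        reference = reference_maps(ctx)
        log_lines.append(f"view {view_no}: context+reference "
                         f"{time.time() - t0:.1f} s")
        estimates = []
        for seed in config.seeds:
            t1 = time.time()
            try:
                est = run_realization(ctx, seed)
            except Exception as exc:   # keep the study going
                log_lines.append(f"view {view_no} seed {seed}: FAILED {exc!r}")
                continue
            estimates.append(est)
            log_lines.append(f"view {view_no} seed {seed}: "
                             f"{time.time() - t1:.1f} s")
        if not estimates:
            continue
        rows, saaa_rows = analyze_view(ctx, estimates, reference,
                                       config.schemes, config.limits)
        all_rows.extend(rows)
        all_saaa.extend(saaa_rows)
        summary["views"][str(view_no)] = {
            "n_realizations": len(estimates),
            "seconds": round(time.time() - t0, 1)}
    errors_df = pd.DataFrame(all_rows)
    saaa_df = pd.DataFrame(all_saaa)
    # provenance: every row carries the seeds and a config digest
    import hashlib
    digest = hashlib.sha1(json.dumps(summary["config"],
                                     sort_keys=True).encode()).hexdigest()[:12]
    for df in (errors_df, saaa_df):
        if len(df):
            df["seeds"] = ",".join(str(s) for s in config.seeds)
            df["config_hash"] = digest
    summary["config_hash"] = digest
    errors_df.to_csv(out / "error_measures.csv", index=False)
    saaa_df.to_csv(out / "saaa.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return errors_df, saaa_df


# ---------------------------------------------------------------------------
# analytic test fixtures
# ---------------------------------------------------------------------------

def make_fixtures(kind: str, params: dict | None = None, out_path=None):
    """Small analytic fixtures with known ground truth for unit testing.

    Kinds: 'shift' (speckle frame pair with a known sub-sample translation),
    'rotation' (rigid in-plane rotation displacement field), 'stretch'
    (uniaxial stretch field), 'speckle' (one uniform speckle frame).
    """
    params = dict(params or {})
    rng = np.random.default_rng(int(params.pop("seed", 0)))
    if kind == "shift":
        from dataclasses import replace
        from .simulator import render_frame
        sector = make_view(2).scaled(0.25)
        sector = replace(sector, d_min=3.0, d_max=6.0)
        psf = PSFModel().scaled(0.25)
        shift = float(params.pop("shift_samples", 0.25))
        dy = shift * psf.sample_spacing_mm
        n = int(params.pop("n_scatterers", 30000))
        x = rng.uniform(-40, 40, n)
        y = rng.uniform(25, 70, n)
        amp = rng.standard_normal(n)
        beta = np.arctan2(x, y)
        r = np.hypot(x, y)
        a = render_frame(np.column_stack([x, y]), amp, sector, psf)
        rs = r + dy
        b = render_frame(np.column_stack([rs * np.sin(beta),
                                          rs * np.cos(beta)]), amp,
                         sector, psf)
        data = {"frame_a": a, "frame_b": b,
                "truth_axial_mm": np.array(dy),
                "truth_axial_samples": np.array(shift)}
    elif kind in ("rotation", "stretch"):
        grid = CartesianGrid.from_bbox(-10, 10, -10, 10, pad=0)
        xx, yy = grid.meshgrid()
        if kind == "rotation":
            ang = np.deg2rad(float(params.pop("degrees", 20.0)))
            ux = np.cos(ang) * xx - np.sin(ang) * yy - xx
            uy = np.sin(ang) * xx + np.cos(ang) * yy - yy
            truth = np.zeros(3)
        else:
            lam = float(params.pop("stretch", 1.1))
            ux = (lam - 1.0) * xx
            uy = np.zeros_like(yy)
            truth = np.array([(lam ** 2 - 1) / 2, 0.0, 0.0])
        data = {"x": grid.x, "y": grid.y, "ux": ux, "uy": uy,
                "truth_exx_exy_eyy": truth}
    elif kind == "speckle":
        from dataclasses import replace
        from .simulator import render_frame
        sector = replace(make_view(2), d_min=3.0, d_max=6.0).scaled(0.25)
        psf = PSFModel().scaled(0.25)
        n = int(params.pop("n_scatterers", 60000))
        x = rng.uniform(-45, 45, n)
        y = rng.uniform(25, 70, n)
        amp = rng.standard_normal(n)
        data = {"frame": render_frame(np.column_stack([x, y]), amp,
                                      sector, psf)}
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    if out_path is not None:
        import h5py
        with h5py.File(out_path, "w") as fh:
            for k, v in data.items():
                fh.create_dataset(k, data=v)
            fh.attrs["kind"] = kind
    return data
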