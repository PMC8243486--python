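"""AHA 17-segment labelling and subsegment division of the phantom wall.

Segments follow the standard scheme on the half-spheroid: the apical cap
(segment 17) covers the innermost 15 % of the normalized meridional arc,
the remaining arc is split into apical/mid/basal thirds, and each ring is
divided into the standard 4 / 6 / 6 azimuthal sectors.  The A2C plane
(world azimuth 0 and 180 degrees) runs through the centres of segments
1/7/13 and 4/10/15; the short-axis plane shows the mid ring 7..12.

Subsegment division uses the ten standard (N_LC, N_R) schemes: equal slices
along the in-wall coordinate (meridional arc in A2C, azimuth in pSAXM)
crossed with equal wall-depth layers; segment 17 is divided radially first
and each layer is split into subsegments of equal area matched to the
outermost layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import KinematicField
from .simulator import A2CPlane, PSAXMPlane

APICAL_CAP_ARC = 0.15
_LEVELS = (APICAL_CAP_ARC, APICAL_CAP_ARC + (1 - APICAL_CAP_ARC) / 3,
           APICAL_CAP_ARC + 2 * (1 - APICAL_CAP_ARC) / 3)

DIVISION_SCHEMES = {
    1: (1, 1), 2: (2, 1), 3: (3, 1), 4: (2, 2), 5: (4, 2),
    6: (6, 2), 7: (9, 3), 8: (12, 4), 9: (15, 5), 10: (18, 6),
}


@dataclass(frozen=True)
class DivisionScheme:
    index: int
    n_lc: int
    n_r: int


def division_scheme(index: int) -> DivisionScheme:
    try:
        n_lc, n_r = DIVISION_SCHEMES[int(index)]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"unknown division scheme {index!r}") from exc
    return DivisionScheme(int(index), n_lc, n_r)


def segment_from_level_azimuth(m: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """AHA17 index from meridional arc fraction (0 apex) and azimuth (rad)."""
    m = np.asarray(m, dtype=float)
    phi = np.asarray(phi, dtype=float)
    seg = np.full(m.shape, 17, dtype=int)
    deg = np.degrees(np.mod(phi, 2 * np.pi))
    apical = (m > _LEVELS[0]) & (m <= _LEVELS[1])
    sec4 = ((deg + 45.0) // 90.0).astype(int) % 4       # 0 at azimuth 0
    seg[apical] = 13 + sec4[apical]
    mid = (m > _LEVELS[1]) & (m <= _LEVELS[2])
    sec6 = ((deg + 30.0) // 60.0).astype(int) % 6
    seg[mid] = 7 + sec6[mid]
    basal = m > _LEVELS[2]
    seg[basal] = 1 + sec6[basal]
    return seg


@dataclass
class NodeAnatomy:
    """Material anatomy of tracked frame-1 grid nodes."""

    segment: np.ndarray        # AHA17 label
    depth: np.ndarray          # normalized wall depth (0 endo, 1 epi)
    arc: np.ndarray            # meridional arc fraction (0 apex)
    azimuth: np.ndarray        # world azimuth (rad)
    in_wall: np.ndarray        # division coordinate (arc signed / azimuth)


def assign_aha17(field: KinematicField, plane, points_img: np.ndarray
                 ) -> NodeAnatomy:
    """Label image-plane wall points (frame 1) with their AHA17 anatomy."""
    pts = np.atleast_2d(points_img)
    world = plane.to_world(pts[:, 0], pts[:, 1])
    shape = field.ed_shape
    rho = np.hypot(world[:, 0], world[:, 1])
    d, m = shape.invert(np.maximum(rho, 1e-9), np.minimum(world[:, 2], 0.0))
    d = np.clip(d, 0.0, 1.0)
    m = np.clip(m, 0.0, 1.0)
    phi = np.arctan2(world[:, 1], world[:, 0])
    seg = segment_from_level_azimuth(m, phi)
    if isinstance(plane, A2CPlane):
        # signed arc runs through the apex: positive on the azimuth-0 side
        in_wall = np.where(np.cos(phi) >= 0, m, -m)
    else:
        in_wall = phi
    return NodeAnatomy(seg, d, m, phi, in_wall)


def node_area_factors(field: KinematicField, plane, points_img: np.ndarray,
                      frames: np.ndarray | None = None) -> np.ndarray:
    """In-plane area scale |det F_2D| of each node at each frame.

    Multiplying the frame-1 pixel area by this factor advects node areas
    with the material, giving per-frame subsegment areas.
    """
    pts = np.atleast_2d(points_img)
    world = plane.to_world(pts[:, 0], pts[:, 1])
    coords = field.material_coords(world)
    if frames is None:
        frames = np.arange(1, field.n_frames + 1)
    if isinstance(plane, A2CPlane):
        e1 = np.array([-1.0, 0.0, 0.0])
        e2 = np.array([0.0, 0.0, 1.0])
    else:
        e1 = np.array([0.0, 1.0, 0.0])
        e2 = np.array([-1.0, 0.0, 0.0])
    m0 = field._config_jacobian(coords, 1)
    m0_inv = np.linalg.inv(m0)
    out = np.empty((pts.shape[0], len(frames)))
    for k, fr in enumerate(frames):
        mt = field._config_jacobian(coords, int(fr))
        f = mt @ m0_inv
        a11 = np.einsum("i,nij,j->n", e1, f, e1)
        a12 = np.einsum("i,nij,j->n", e1, f, e2)
        a21 = np.einsum("i,nij,j->n", e2, f, e1)
        a22 = np.einsum("i,nij,j->n", e2, f, e2)
        out[:, k] = np.abs(a11 * a22 - a12 * a21)
    return out


@dataclass
class SubsegmentSet:
    """Node partition of one AHA17 segment under one division scheme."""

    segment: int
    scheme: DivisionScheme
    node_sets: list            # list of node-index arrays (SSN order)
    areas_mm2: np.ndarray      # (n_subsegments, n_frames)

    @property
    def mss(self) -> float:
        """Mean subsegment surface over subsegments and all frames (mm^2)."""
        return float(self.areas_mm2.mean())


def _equal_count_split(order: np.ndarray, n_parts: int) -> list:
    bounds = np.linspace(0, order.size, n_parts + 1).round().astype(int)
    return [order[bounds[i]:bounds[i + 1]] for i in range(n_parts)]


def divide(node_idx: np.ndarray, anatomy: NodeAnatomy, scheme: DivisionScheme,
           segment: int, area_factors: np.ndarray, pixel_area_mm2: float
           ) -> SubsegmentSet:
    """Partition one segment's nodes into the scheme's subsegments."""
    if node_idx.size == 0:
        raise ValueError(f"segment {segment} has no nodes")
    coord = anatomy.in_wall[node_idx]
    depth = anatomy.depth[node_idx]
    sets = []
    if segment == 17:
        # radial layers first; every layer split into equal-area subsegments
        # matched in area to those of the outermost layer
        edges = np.linspace(0.0, 1.0, scheme.n_r + 1)
        layers = [node_idx[(depth >= edges[i] - 1e-12) & (depth < edges[i + 1]
                           + (1e-9 if i == scheme.n_r - 1 else 0.0))]
                  for i in range(scheme.n_r)]
        outer = layers[-1]
        if outer.size == 0:
            raise ValueError("empty outer layer in segment 17")
        target = outer.size / scheme.n_lc
        for layer in layers:
            if layer.size == 0:
                raise ValueError("empty radial layer in segment 17")
            n_parts = max(1, int(round(layer.size / target)))
            order = layer[np.argsort(anatomy.in_wall[layer])]
            sets.extend(_equal_count_split(order, n_parts))
    else:
        lo, hi = coord.min(), coord.max()
        span = max(hi - lo, 1e-12)
        ic = np.minimum((scheme.n_lc * (coord - lo) / span).astype(int),
                        scheme.n_lc - 1)
        idp = np.minimum((scheme.n_r * depth).astype(int), scheme.n_r - 1)
        for j in range(scheme.n_r):
            for i in range(scheme.n_lc):
                sub = node_idx[(ic == i) & (idp == j)]
                if sub.size == 0:
                    raise ValueError(
                        f"empty subsegment {i},{j} in segment {segment}")
                sets.append(sub)
    areas = np.stack([pixel_area_mm2 * area_factors[s].sum(axis=0)
                      for s in sets])
    return SubsegmentSet(segment, scheme, sets, areas)


def segment_areas(anatomy: NodeAnatomy, area_factors: np.ndarray,
                  pixel_area_mm2: float, segments: tuple[int, ...]
                  ) -> dict[int, np.ndarray]:
    """Per-frame cross-sectional area of each requested segment (mm^2)."""
    out = {}
    for s in segments:
        sel = anatomy.segment == s
        if not np.any(sel):
            continue
        out[s] = pixel_area_mm2 * area_factors[sel].sum(axis=0)
    return out
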