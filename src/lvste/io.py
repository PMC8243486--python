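"""HDF5 containers for RF sequences, displacement fields and strain maps."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .simulator import PSFModel, RFFrameSet, envelope
from .tracking import PolarDisplacementField
from .views import SectorConfig


def save_rf(path, rf: RFFrameSet, masks: np.ndarray | None = None,
            with_envelope: bool = False) -> None:
    """Write an RF frame set: /rf[line,sample,frame], /grid, /meta."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("rf", data=rf.samples, compression="gzip",
                          compression_opts=1)
        if with_envelope:
            env = np.stack([rf.envelope(t + 1) for t in range(rf.n_frames)],
                           axis=-1).astype(np.float32)
            fh.create_dataset("envelope", data=env, compression="gzip",
                              compression_opts=1)
        if masks is not None:
            fh.create_dataset("mask", data=masks.astype(bool),
                              compression="gzip", compression_opts=1)
        g = fh.create_group("grid")
        g.create_dataset("angles_deg", data=rf.angles_deg)
        g.create_dataset("depths_mm", data=rf.depths_mm)
        meta = fh.create_group("meta")
        meta.attrs["seed"] = rf.seed
        meta.attrs["sector"] = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in rf.sector.__dict__.items()})
        meta.attrs["psf"] = json.dumps(rf.psf.__dict__)


def load_rf(path) -> RFFrameSet:
    with h5py.File(path, "r") as fh:
        samples = fh["rf"][...]
        angles = fh["grid/angles_deg"][...]
        depths = fh["grid/depths_mm"][...]
        sector_raw = json.loads(fh["meta"].attrs["sector"])
        sector_raw["imaged_segments"] = tuple(sector_raw["imaged_segments"])
        sector = SectorConfig(**sector_raw)
        psf = PSFModel(**json.loads(fh["meta"].attrs["psf"]))
        seed = int(fh["meta"].attrs["seed"])
    return RFFrameSet(samples, angles, depths, sector, psf, seed)


def save_polar_fields(path, fields: list[PolarDisplacementField],
                      attrs: dict | None = None) -> None:
    """Write per-frame-pair incremental polar displacement estimates."""
    with h5py.File(path, "w") as fh:
        fh.attrs["n_pairs"] = len(fields)
        for k, v in (attrs or {}).items():
            fh.attrs[k] = v
        for t, f in enumerate(fields):
            g = fh.create_group(f"pair_{t:03d}")
            for name in ("node_lat", "node_ax", "angles_deg", "depths_mm",
                         "u_ax_mm", "u_lat_deg", "xcc", "valid"):
                g.create_dataset(name, data=getattr(f, name))


def load_polar_fields(path) -> list[PolarDisplacementField]:
    out = []
    with h5py.File(path, "r") as fh:
        for t in range(int(fh.attrs["n_pairs"])):
            g = fh[f"pair_{t:03d}"]
            out.append(PolarDisplacementField(
                g["node_lat"][...], g["node_ax"][...], g["angles_deg"][...],
                g["depths_mm"][...], g["u_ax_mm"][...], g["u_lat_deg"][...],
                g["xcc"][...], g["valid"][...].astype(bool)))
    return out


def save_strain_maps(path, maps, name: str = "strain") -> None:
    """Write strain curves per node: /strain/<component>[node, frame]."""
    with h5py.File(path, "w") as fh:
        g = fh.create_group(name)
        for comp, arr in maps.components.items():
            g.create_dataset(comp, data=arr, compression="gzip",
                             compression_opts=1)
        fh.create_dataset("node_ix", data=maps.node_ix)
        fh.create_dataset("node_iy", data=maps.node_iy)
        fh.create_dataset("grid_x", data=maps.grid.x)
        fh.create_dataset("grid_y", data=maps.grid.y)
        fh.create_dataset("valid", data=maps.valid)


def export_kinematics(path, field, points: np.ndarray,
                      frames: range | None = None) -> None:
    """Sample the kinematic model at reference points and export
    /X, /u[frame], /F[frame] for external use."""
    pts = np.atleast_2d(points)
    if frames is None:
        frames = range(1, field.n_frames + 1)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("X", data=pts)
        gu = fh.create_group("u")
        gf = fh.create_group("F")
        for fr in frames:
            gu.create_dataset(f"frame_{fr:03d}",
                              data=field.displacement(pts, fr))
            gf.create_dataset(f"frame_{fr:03d}",
                              data=field.deformation_gradient(pts, fr))
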