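"""File formats: NIfTI volumes, PLY meshes, CSV/JSON tables and maps.

Velocity volumes are stored as 5D NIfTI (nx, ny, nz, t, 3) in cm/s with
voxel spacing (mm) in the header zooms and the frame interval (ms) in the
temporal zoom; masks as 4D (nx, ny, nz, t) uint8.  World coordinates are
``index * spacing + origin`` with the origin taken from the affine
translation.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fields import VelocityField4D, LumenMask
from .geometry import SurfaceMesh, Centerline, WallFrameSet
from .projection import ProjectionMap

__all__ = [
    "write_velocity", "read_velocity", "write_mask", "read_mask",
    "write_mesh", "read_mesh", "write_centerline", "read_centerline",
    "write_frames", "write_map", "read_map", "render_map",
]


def _affine(spacing, origin):
    a = np.eye(4)
    a[:3, :3] = np.diag(spacing)
    a[:3, 3] = origin
    return a


def write_velocity(vel: VelocityField4D, path) -> None:
    # (frames, 3, nx, ny, nz) -> (nx, ny, nz, t, 3)
    arr = np.transpose(vel.data, (2, 3, 4, 0, 1)).astype(np.float32)
    img = nib.Nifti1Image(arr, _affine(vel.spacing, vel.origin))
    dt = float(np.median(np.diff(vel.frame_times))) if vel.n_frames > 1 else 1.0
    img.header.set_zooms(tuple(vel.spacing) + (dt, 1.0))
    nib.save(img, str(path))


def read_velocity(path) -> VelocityField4D:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=np.float64)
    if arr.ndim != 5:
        raise ValueError(
            f"expected a 5D velocity NIfTI (nx, ny, nz, t, 3), got {arr.ndim}D; "
            "if components are on axis 3, transpose to put them last"
        )
    if arr.shape[4] != 3:
        raise ValueError(
            f"component axis must be last with length 3, got shape {arr.shape}"
        )
    zooms = img.header.get_zooms()
    spacing = np.asarray(zooms[:3], dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("missing or non-positive voxel spacing in header")
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    dt = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    times = np.arange(arr.shape[3]) * dt
    data = np.transpose(arr, (3, 4, 0, 1, 2))
    return VelocityField4D(data, spacing=spacing, origin=origin, frame_times=times)


def write_mask(mask: LumenMask, path) -> None:
    arr = np.transpose(mask.data, (1, 2, 3, 0)).astype(np.uint8)
    img = nib.Nifti1Image(arr, _affine(mask.spacing, mask.origin))
    img.header.set_zooms(tuple(mask.spacing) + (1.0,))
    nib.save(img, str(path))


def read_mask(path) -> LumenMask:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    if arr.ndim == 3:
        arr = arr[..., None]
    if arr.ndim != 4:
        raise ValueError(f"expected a 3D/4D mask NIfTI, got {arr.ndim}D")
    zooms = img.header.get_zooms()
    spacing = np.asarray(zooms[:3], dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("missing or non-positive voxel spacing in header")
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return LumenMask(np.transpose(arr, (3, 0, 1, 2)) > 0, spacing=spacing,
                     origin=origin)


def write_mesh(mesh: SurfaceMesh, path) -> None:
    mesh.as_trimesh().export(str(path))


def read_mesh(path) -> SurfaceMesh:
    import trimesh
    tm = trimesh.load(str(path), process=False)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                       np.asarray(tm.vertex_normals, dtype=np.float64))


def write_centerline(cl: Centerline, path) -> None:
    df = pd.DataFrame({
        "x_mm": cl.points[:, 0], "y_mm": cl.points[:, 1], "z_mm": cl.points[:, 2],
        "arc_length_mm": cl.arc_length,
    })
    df.to_csv(path, index=False, float_format="%.6g")


def read_centerline(path) -> Centerline:
    df = pd.read_csv(path)
    pts = df[["x_mm", "y_mm", "z_mm"]].to_numpy()
    return Centerline(pts, arc_length=df["arc_length_mm"].to_numpy())


def write_frames(frames: WallFrameSet, path) -> None:
    df = pd.DataFrame({
        "node_id": frames.node_id, "z_mm": frames.z, "theta_deg": frames.theta,
        "valid": frames.valid.astype(int),
    })
    for name, arr in (("l", frames.l_hat), ("c", frames.c_hat), ("r", frames.r_hat)):
        for i, ax in enumerate("xyz"):
            df[f"{name}_{ax}"] = arr[:, i]
    df.to_csv(path, index=False, float_format="%.6g")


def write_map(pmap: ProjectionMap, path_csv) -> None:
    """CSV matrix (rows: z, columns: theta; NaN = invalid) + JSON sidecar."""
    path_csv = Path(path_csv)
    df = pd.DataFrame(np.where(pmap.valid, pmap.values, np.nan),
                      index=pmap.grid_z, columns=pmap.grid_theta)
    df.index.name = "z_mm\\theta_deg"
    df.to_csv(path_csv, float_format="%.6g")
    sidecar = {
        "z_step_mm": float(np.median(np.diff(pmap.grid_z))) if len(pmap.grid_z) > 1 else None,
        "theta_step_deg": float(np.median(np.diff(pmap.grid_theta))) if len(pmap.grid_theta) > 1 else None,
        "z_start_mm": float(pmap.grid_z[0]),
        "units": pmap.units,
        "invalid_encoding": "NaN",
    }
    path_csv.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_map(path_csv) -> ProjectionMap:
    path_csv = Path(path_csv)
    df = pd.read_csv(path_csv, index_col=0)
    units = ""
    sidecar = path_csv.with_suffix(".json")
    if sidecar.exists():
        units = json.loads(sidecar.read_text()).get("units", "")
    values = df.to_numpy(dtype=float)
    valid = np.isfinite(values)
    return ProjectionMap(df.index.to_numpy(dtype=float),
                         df.columns.to_numpy(dtype=float), values, valid,
                         units=units)


def render_map(pmap: ProjectionMap, path, title: str = "", cmap: str = "viridis",
               vmin=None, vmax=None) -> None:
    """PNG rendering with the P (0), OR (90), A (180), IR (270) annotation."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    m = pmap.masked()
    pc = ax.pcolormesh(pmap.grid_z, pmap.grid_theta, m.T, cmap=cmap,
                       vmin=vmin, vmax=vmax, shading="nearest")
    ax.set_xlabel("z (mm)")
    ax.set_ylabel("theta (deg)")
    ax.set_yticks([0, 90, 180, 270, 360],
                  ["0 (P)", "90 (OR)", "180 (A)", "270 (IR)", "360"])
    ax.set_ylim(0, 360)
    if title:
        ax.set_title(title)
    fig.colorbar(pc, ax=ax, label=pmap.units)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
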