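"""Cylindrical unwrapping of wall quantities into regular (z, theta) maps.

A projection map samples a scalar wall quantity on a regular grid with z
the centerline arc length (default step 1 um) and theta the circumferential
angle (default step 0.5 deg, periodic).  Scattered per-node values are
interpolated linearly with the point cloud replicated at theta +/- 360 deg
for a seamless wrap; cells far from any node (or closest to a node flagged
invalid, e.g. at branch ostia) are marked invalid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator, interp1d
from scipy.spatial import cKDTree

__all__ = [
    "ProjectionMap", "GridSpec", "project_nodes", "align_group",
    "extract_strip", "coarsen",
]


@dataclass
class GridSpec:
    """Grid steps of a (z, theta) map: z step in mm (default 1 um), theta
    step in degrees (default 0.5)."""

    z_step: float = 0.001
    theta_step: float = 0.5

    def validate(self):
        if self.z_step <= 0 or self.theta_step <= 0:
            raise ValueError("grid steps must be positive")


@dataclass
class ProjectionMap:
    """Regular (z, theta) grid of a scalar wall quantity.

    ``values`` has shape (len(grid_z), len(grid_theta)); ``valid`` marks
    cells with node coverage.  ``grid_theta`` covers [0, 360).
    """

    grid_z: np.ndarray
    grid_theta: np.ndarray
    values: np.ndarray
    valid: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.grid_z = np.asarray(self.grid_z, dtype=np.float64)
        self.grid_theta = np.asarray(self.grid_theta, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != (len(self.grid_z), len(self.grid_theta)):
            raise ValueError("values shape must be (n_z, n_theta)")
        if self.valid.shape != self.values.shape:
            raise ValueError("valid shape must match values")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.values, mask=~self.valid)


def project_nodes(z, theta, values, grid: GridSpec = None, valid=None,
                  z_range=None, cutoff_z: float = 0.06,
                  cutoff_theta: float = 3.0, units: str = "") -> ProjectionMap:
    """Interpolate scattered per-node (z, theta, value) triples onto a grid.

    ``cutoff_z`` (mm) and ``cutoff_theta`` (deg) define the anisotropic
    coverage radius: cells with no valid node inside it are invalid, as are
    cells whose nearest node is flagged invalid (branch ostia).
    """
    grid = grid or GridSpec()
    grid.validate()
    z = np.asarray(z, dtype=float)
    theta = np.mod(np.asarray(theta, dtype=float), 360.0)
    values = np.asarray(values, dtype=float)
    valid = np.ones(len(z), dtype=bool) if valid is None else np.asarray(valid, dtype=bool)

    good = valid & np.isfinite(values)
    if good.sum() < 3:
        raise ValueError("fewer than 3 valid nodes to project")

    if z_range is None:
        z_range = (z[good].min(), z[good].max())
    grid_z = np.arange(z_range[0], z_range[1] + 0.5 * grid.z_step, grid.z_step)
    grid_theta = np.arange(0.0, 360.0, grid.theta_step)

    def replicate(zz, tt, vv=None):
        Z = np.concatenate([zz, zz, zz])
        T = np.concatenate([tt - 360.0, tt, tt + 360.0])
        if vv is None:
            return Z, T
        return Z, T, np.concatenate([vv, vv, vv])

    Zr, Tr, Vr = replicate(z[good], theta[good], values[good])
    pts = np.column_stack([Zr, Tr])
    lin = LinearNDInterpolator(pts, Vr)
    ZZ, TT = np.meshgrid(grid_z, grid_theta, indexing="ij")
    out = lin(np.column_stack([ZZ.ravel(), TT.ravel()])).reshape(ZZ.shape)
    holes = ~np.isfinite(out)
    if holes.any():
        near = NearestNDInterpolator(pts, Vr)
        out[holes] = near(np.column_stack([ZZ[holes], TT[holes]]))

    # anisotropic coverage test: scale axes by their cutoffs
    scale = np.array([cutoff_z, cutoff_theta])
    tree_good = cKDTree(np.column_stack([Zr, Tr]) / scale)
    q = np.column_stack([ZZ.ravel(), TT.ravel()]) / scale
    d_good, _ = tree_good.query(q)
    cell_valid = (d_good <= 1.0).reshape(ZZ.shape)

    bad = (~valid) & np.isfinite(values)
    if bad.any():
        Zb, Tb = replicate(z[bad], theta[bad])
        tree_bad = cKDTree(np.column_stack([Zb, Tb]) / scale)
        d_bad, _ = tree_bad.query(q)
        cell_valid &= (d_bad.reshape(ZZ.shape) > d_good.reshape(ZZ.shape))

    out[~cell_valid] = np.nan
    return ProjectionMap(grid_z, grid_theta, out, cell_valid, units=units)


def align_group(maps, landmark_zs, prox_mm: float = 3.0, dist_mm: float = 4.0):
    """Resample maps so the landmark row coincides and extents match.

    Each map is clipped to [landmark - prox_mm, landmark + dist_mm] and its
    z axis re-zeroed at the proximal cut, producing identical grid shapes
    across animals so pixels correspond.  Theta axes must already agree.
    """
    maps = list(maps)
    landmark_zs = list(landmark_zs)
    if len(maps) != len(landmark_zs):
        raise ValueError("one landmark per map required")
    ref_theta = maps[0].grid_theta
    z_step = float(np.median(np.diff(maps[0].grid_z)))
    new_z = np.arange(0.0, prox_mm + dist_mm + 0.5 * z_step, z_step)

    out = []
    for m, lz in zip(maps, landmark_zs):
        if not np.allclose(m.grid_theta, ref_theta):
            raise ValueError("theta axes differ between maps")
        z0, z1 = lz - prox_mm, lz + dist_mm
        eps = 1e-9
        if z0 < m.grid_z[0] - z_step - eps or z1 > m.grid_z[-1] + z_step + eps:
            raise ValueError(
                f"landmark at {lz:.3f} mm leaves less than the requested "
                f"window inside the map extent"
            )
        src_z = new_z + z0
        vals = interp1d(m.grid_z, np.where(m.valid, m.values, np.nan), axis=0,
                        bounds_error=False, fill_value=np.nan)(src_z)
        vmask = interp1d(m.grid_z, m.valid.astype(float), axis=0, kind="nearest",
                         bounds_error=False, fill_value=0.0)(src_z) >= 0.5
        vmask &= np.isfinite(vals)
        vals[~vmask] = np.nan
        out.append(ProjectionMap(new_z, ref_theta.copy(), vals, vmask, units=m.units))
    return out


def extract_strip(pmap: ProjectionMap, center_theta: float, half_width: float,
                  z_range=None) -> float:
    """Mean of valid cells with theta in center +/- half_width (wrapped) and
    z inside ``z_range`` (whole extent if None).

    The study's histology strip is (270 +/- 30) deg along the inner radius.
    """
    dtheta = np.abs(np.mod(pmap.grid_theta - center_theta + 180.0, 360.0) - 180.0)
    tmask = dtheta <= half_width
    if z_range is None:
        zmask = np.ones(len(pmap.grid_z), dtype=bool)
    else:
        zmask = (pmap.grid_z >= z_range[0]) & (pmap.grid_z <= z_range[1])
    sel = pmap.valid & zmask[:, None] & tmask[None, :]
    if not sel.any():
        raise ValueError("strip contains no valid cells")
    return float(pmap.values[sel].mean())


def coarsen(pmap: ProjectionMap, factor_z: int, factor_theta: int) -> ProjectionMap:
    """Block-average valid cells into a coarser grid (for faster statistics)."""
    nz = (len(pmap.grid_z) // factor_z) * factor_z
    nt = (len(pmap.grid_theta) // factor_theta) * factor_theta
    v = np.where(pmap.valid, pmap.values, np.nan)[:nz, :nt]
    v = v.reshape(nz // factor_z, factor_z, nt // factor_theta, factor_theta)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(v, axis=(1, 3))
    count = np.isfinite(v).sum(axis=(1, 3))
    valid = count > 0
    gz = pmap.grid_z[:nz].reshape(-1, factor_z).mean(axis=1)
    gt = pmap.grid_theta[:nt].reshape(-1, factor_theta).mean(axis=1)
    mean[~valid] = np.nan
    return ProjectionMap(gz, gt, mean, valid, units=pmap.units)
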