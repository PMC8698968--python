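"""Wall shear stress from velocity gradients at the lumen surface.

The viscous traction exerted by the blood on the wall is
``tau = 2 * eta * eps @ n`` with ``eps`` the symmetrized velocity-gradient
(deformation-rate) tensor and ``n`` the wall normal pointing into the
fluid; with that orientation the longitudinal component of forward flow is
positive and the radial component is positive toward the centerline.

Gradients are one-sided: velocities are sampled by trilinear interpolation
along the inward normal at a few depths (staying inside the lumen, since
measured data violate no-slip and voxels beyond the wall are unreliable),
a quadratic polynomial in depth is fitted per velocity component
(using only samples whose trilinear lumen weight is 1, i.e. all eight
surrounding voxels inside), and its
slope at the node gives the normal derivative.  Tangential derivatives use
central differences one voxel below the surface.  The full gradient tensor
is assembled from these three directional derivatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fields import VelocityField4D, LumenMask
from .geometry import SurfaceMesh, WallFrameSet

__all__ = [
    "WallShearSeries", "deformation_tensor_at", "wss_vector",
    "temporal_average", "decompose", "osi", "compute_wall_shear",
    "component_table",
]

#: (cm/s)/mm -> 1/s
_SHEAR_UNIT = 10.0
#: default sampling depths in voxel units along the inward normal
DEFAULT_DEPTHS = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
#: minimum trilinear lumen weight for a sample to count as interior
_MIN_MASK_WEIGHT = 0.999


@dataclass
class WallShearSeries:
    """Time-resolved WSS vectors for all surface nodes.

    ``tau`` has shape (n_frames, n_nodes, 3) in Pa; ``valid`` flags nodes
    with enough interior samples in every frame.
    """

    node_id: np.ndarray
    tau: np.ndarray
    valid: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.tau.shape[0]

    @property
    def tau_mean(self) -> np.ndarray:
        """Temporal (frame-wise vector) mean, shape (n_nodes, 3)."""
        return self.tau.mean(axis=0)


def _orthonormal_tangents(normals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    trial = np.zeros_like(normals)
    smallest = np.argmin(np.abs(normals), axis=1)
    trial[np.arange(len(normals)), smallest] = 1.0
    t1 = np.cross(normals, trial)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(normals, t1)
    return t1, t2


def _gradient_tensors(nodes, inward, velocity, mask, frame, depths, h):
    """Velocity-gradient tensors G (N, 3, 3) in 1/s plus per-node validity."""
    n_nodes = len(nodes)
    s = np.asarray(depths, dtype=float) * h  # physical depths (mm)
    n_s = len(s)

    pts = nodes[:, None, :] + inward[:, None, :] * s[None, :, None]
    flat = pts.reshape(-1, 3)
    w = mask.sample_weight(flat, frame=min(frame, mask.n_frames - 1))
    w = (w >= _MIN_MASK_WEIGHT).astype(float).reshape(n_nodes, n_s)
    v = velocity.sample(flat, frame).reshape(n_nodes, n_s, 3)

    # weighted quadratic fit of v(s) per node and component; slope at s=0
    X = np.stack([np.ones_like(s), s, s * s], axis=1)  # (S, 3)
    A = np.einsum("ns,sk,sl->nkl", w, X, X)
    b = np.einsum("ns,sk,nsc->nkc", w, X, v)
    cnt = w.sum(axis=1)
    ok = cnt >= 3
    A = A + 1e-12 * np.eye(3)
    beta = np.linalg.solve(A, b)  # (N, 3, 3): coefficient x component
    dv_ds = beta[:, 1, :]                   # derivative along the inward ray
    dv_dn = dv_ds * _SHEAR_UNIT             # n here is the inward direction

    # tangential derivatives: central differences at the shallowest depth
    # (>= 1 voxel) where both offset points are fully interior; zero only
    # if no depth qualifies
    t1, t2 = _orthonormal_tangents(inward)
    mframe = min(frame, mask.n_frames - 1)
    tang_depths = (1.0, 1.5, 2.0, 2.5)
    dv_dt = []
    for t in (t1, t2):
        d_best = np.zeros((n_nodes, 3))
        found = np.zeros(n_nodes, dtype=bool)
        for dt in tang_depths:
            base = nodes + inward * (dt * h)
            p_plus = base + 0.5 * h * t
            p_minus = base - 0.5 * h * t
            w_pair = np.minimum(
                mask.sample_weight(p_plus, frame=mframe),
                mask.sample_weight(p_minus, frame=mframe),
            ) >= _MIN_MASK_WEIGHT
            take = w_pair & ~found
            if take.any():
                d = (velocity.sample(p_plus[take], frame)
                     - velocity.sample(p_minus[take], frame)) / h
                d_best[take] = d
                found |= take
            if found.all():
                break
        dv_dt.append(d_best * _SHEAR_UNIT)

    G = (dv_dn[:, :, None] * inward[:, None, :]
         + dv_dt[0][:, :, None] * t1[:, None, :]
         + dv_dt[1][:, :, None] * t2[:, None, :])
    return G, ok


def deformation_tensor_at(node, normal, velocity: VelocityField4D,
                          mask: LumenMask, frame: int,
                          depths=DEFAULT_DEPTHS) -> np.ndarray:
    """Deformation-rate tensor eps (3x3, 1/s) at one surface point.

    ``normal`` is the unit normal pointing into the fluid; samples are
    taken along it at ``depths`` (voxel units).  Raises if fewer than three
    samples land inside the lumen.
    """
    node = np.asarray(node, dtype=float).reshape(1, 3)
    normal = np.asarray(normal, dtype=float).reshape(1, 3)
    h = float(np.mean(velocity.spacing))
    G, ok = _gradient_tensors(node, normal, velocity, mask, frame, depths, h)
    if not ok[0]:
        raise ValueError("fewer than 3 interior samples reachable along the normal")
    return 0.5 * (G[0] + G[0].T)


def wss_vector(eps: np.ndarray, normal: np.ndarray, eta: float) -> np.ndarray:
    """tau = 2 * eta * eps @ n (Pa); ``normal`` must be unit length."""
    if eta <= 0:
        raise ValueError("eta must be positive")
    normal = np.asarray(normal, dtype=float)
    if abs(np.linalg.norm(normal) - 1.0) > 1e-6:
        raise ValueError("normal must be a unit vector")
    return 2.0 * eta * np.asarray(eps) @ normal


def temporal_average(series: WallShearSeries) -> np.ndarray:
    """Frame-wise arithmetic mean of the WSS vector (not of magnitudes)."""
    return series.tau_mean


def decompose(tau_mean: np.ndarray, frames: WallFrameSet):
    """Signed projections of tau on (l_hat, c_hat, r_hat).

    Returns (long_wss, circ_wss, rad_strain); rad_strain > 0 means the
    traction points toward the centerline.
    """
    tau = np.atleast_2d(np.asarray(tau_mean, dtype=float))
    long_wss = np.sum(tau * frames.l_hat, axis=1)
    circ_wss = np.sum(tau * frames.c_hat, axis=1)
    rad_strain = np.sum(tau * frames.r_hat, axis=1)
    return long_wss, circ_wss, rad_strain


def osi(series: WallShearSeries) -> np.ndarray:
    """Oscillatory shear index in percent, per node.

    OSI = 0.5 * (1 - |sum_i tau(i)| / sum_i |tau(i)|) * 100; 0 when the
    WSS vector never changes direction or magnitude, 50 when the vector sum
    cancels.  An all-zero series (no flow) maps to 0 by convention.
    """
    if series.n_frames < 2:
        raise ValueError("OSI needs at least 2 frames")
    vec_sum = np.linalg.norm(series.tau.sum(axis=0), axis=-1)
    mag_sum = np.linalg.norm(series.tau, axis=-1).sum(axis=0)
    out = np.zeros(series.tau.shape[1])
    nz = mag_sum > 0
    out[nz] = 0.5 * (1.0 - vec_sum[nz] / mag_sum[nz]) * 100.0
    return np.clip(out, 0.0, 50.0)


def compute_wall_shear(velocity: VelocityField4D, mask: LumenMask,
                       mesh: SurfaceMesh, eta: float = 0.004,
                       depths=DEFAULT_DEPTHS) -> WallShearSeries:
    """Time-resolved WSS vector at every mesh node (traction on the wall).

    The mesh's outward normals are flipped to point into the fluid before
    evaluating tau = 2 * eta * eps @ n, so longWSS of forward flow is
    positive.
    """
    inward = -mesh.node_normals
    inward = inward / np.linalg.norm(inward, axis=1, keepdims=True)
    h = float(np.mean(velocity.spacing))
    n_nodes = mesh.n_nodes
    tau = np.zeros((velocity.n_frames, n_nodes, 3))
    valid = np.ones(n_nodes, dtype=bool)
    for f in range(velocity.n_frames):
        G, ok = _gradient_tensors(mesh.nodes, inward, velocity, mask, f, depths, h)
        eps = 0.5 * (G + np.transpose(G, (0, 2, 1)))
        tau[f] = 2.0 * eta * np.einsum("nij,nj->ni", eps, inward)
        valid &= ok
    return WallShearSeries(node_id=np.arange(n_nodes), tau=tau, valid=valid)


def component_table(series: WallShearSeries, frames: WallFrameSet,
                    signed: bool = True) -> pd.DataFrame:
    """Per-node results table: z, theta, longWSS, circWSS, radStrain, OSI.

    Components are signed projections of the temporally averaged WSS vector
    by default; ``signed=False`` reports absolute values for the two shear
    components (radStrain keeps its sign, which is the quantity of
    interest).  Stresses in Pa, OSI in percent.
    """
    tau_mean = series.tau_mean
    long_wss, circ_wss, rad_strain = decompose(tau_mean, frames)
    if not signed:
        long_wss = np.abs(long_wss)
        circ_wss = np.abs(circ_wss)
    osi_vals = osi(series) if series.n_frames >= 2 else np.zeros(len(series.node_id))
    return pd.DataFrame({
        "node_id": series.node_id,
        "z_mm": frames.z,
        "theta_deg": frames.theta,
        "long_wss_pa": long_wss,
        "circ_wss_pa": circ_wss,
        "rad_strain_pa": rad_strain,
        "osi_pct": osi_vals,
        "valid": series.valid & frames.valid,
    })
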