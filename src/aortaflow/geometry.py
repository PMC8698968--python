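"""Lumen geometry: surface mesh, centerline and per-node wall frames.

The wall frame at a surface node is the orthonormal triad
(l_hat, c_hat, r_hat): longitudinal (parallel to the local centerline
tangent), circumferential, and radial (pointing from the node toward the
centerline).  Each node also carries cylindrical coordinates (z, theta):
z is centerline arc length (mm) and theta the circumferential angle with
the convention theta = 0 posterior, 90 outer curvature, 180 anterior,
270 inner curvature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from scipy.interpolate import splprep, splev
from skimage.measure import marching_cubes
from skimage.morphology import skeletonize
import trimesh

from .fields import LumenMask

__all__ = [
    "SurfaceMesh", "Centerline", "WallFrameSet",
    "extract_surface", "extract_centerline", "normalize_extent",
    "build_wall_frames",
]


@dataclass
class SurfaceMesh:
    """Triangulated lumen surface in world coordinates (mm).

    ``node_normals`` are unit outward normals (away from the lumen).
    """

    nodes: np.ndarray
    faces: np.ndarray
    node_normals: np.ndarray

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.intp)
        self.node_normals = np.asarray(self.node_normals, dtype=np.float64)
        if self.faces.size and self.faces.max() >= len(self.nodes):
            raise ValueError("face references a node outside the mesh")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def as_trimesh(self) -> "trimesh.Trimesh":
        return trimesh.Trimesh(vertices=self.nodes, faces=self.faces, process=False)

    @property
    def area(self) -> float:
        return float(self.as_trimesh().area)


@dataclass
class Centerline:
    """Ordered, smoothed lumen centerline with arc-length parameterization.

    ``arc_length`` starts at 0 at the proximal end and is strictly
    increasing; ``tangents`` are unit vectors pointing distally.
    """

    points: np.ndarray
    arc_length: np.ndarray = field(default=None)
    tangents: np.ndarray = field(default=None)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.arc_length is None:
            seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            self.arc_length = np.concatenate([[0.0], np.cumsum(seg)])
        self.arc_length = np.asarray(self.arc_length, dtype=np.float64)
        if np.any(np.diff(self.arc_length) <= 0):
            raise ValueError("arc_length must be strictly increasing")
        if self.tangents is None:
            self.tangents = _finite_difference_tangents(self.points, self.arc_length)
        self.tangents = np.asarray(self.tangents, dtype=np.float64)

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1] - self.arc_length[0])

    def point_at(self, z) -> np.ndarray:
        z = np.atleast_1d(np.asarray(z, dtype=float))
        out = np.stack([
            np.interp(z, self.arc_length, self.points[:, i]) for i in range(3)
        ], axis=-1)
        return out

    def tangent_at(self, z) -> np.ndarray:
        z = np.atleast_1d(np.asarray(z, dtype=float))
        t = np.stack([
            np.interp(z, self.arc_length, self.tangents[:, i]) for i in range(3)
        ], axis=-1)
        return t / np.linalg.norm(t, axis=-1, keepdims=True)

    def resample(self, spacing: float) -> "Centerline":
        n = max(int(np.ceil(self.total_length / spacing)) + 1, 2)
        z = np.linspace(self.arc_length[0], self.arc_length[-1], n)
        pts = self.point_at(z)
        return Centerline(pts, arc_length=z, tangents=self.tangent_at(z))

    def crop(self, z0: float, z1: float, spacing: float = 0.05) -> "Centerline":
        """Clip to arc-length window [z0, z1] and re-zero at the proximal cut."""
        eps = 1e-9
        if z0 < self.arc_length[0] - eps or z1 > self.arc_length[-1] + eps:
            raise ValueError(
                f"requested extent [{z0:.3f}, {z1:.3f}] mm exceeds the available "
                f"centerline [{self.arc_length[0]:.3f}, {self.arc_length[-1]:.3f}] mm"
            )
        n = max(int(np.round((z1 - z0) / spacing)) + 1, 2)
        z = np.linspace(z0, z1, n)
        return Centerline(self.point_at(z), arc_length=z - z0,
                          tangents=self.tangent_at(z))


def _finite_difference_tangents(points, arc):
    t = np.gradient(points, arc, axis=0)
    n = np.linalg.norm(t, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return t / n


def extract_surface(mask: LumenMask, frame="time-average",
                    smooth_sigma: float = 0.6) -> SurfaceMesh:
    """Watertight triangulated isosurface of the lumen at the 0.5 level.

    ``frame`` is a frame index or ``"time-average"`` (majority vote over
    frames).  The binary volume is Gaussian-smoothed by ``smooth_sigma``
    voxels before contouring: the 0.5 level of the blurred indicator stays
    on the true interface (to O(curvature * sigma^2)) while the staircase
    artifacts — whose normals would corrupt wall-gradient sampling — are
    removed.  The largest connected component is kept; a second component
    of comparable size signals a segmentation problem and raises.
    """
    if frame == "time-average":
        vol = mask.time_average()
    else:
        vol = mask.frame(int(frame))
    if not vol.any():
        raise ValueError("empty lumen mask")

    labels, n_comp = ndimage.label(vol)
    if n_comp > 1:
        sizes = np.bincount(labels.ravel())[1:]
        order = np.argsort(sizes)[::-1]
        if len(sizes) > 1 and sizes[order[1]] > 0.1 * sizes[order[0]]:
            raise ValueError(
                f"mask has {n_comp} connected components of comparable size; "
                "expected a single lumen"
            )
        vol = labels == (order[0] + 1)

    field = vol.astype(np.float64)
    if smooth_sigma > 0:
        field = ndimage.gaussian_filter(field, smooth_sigma)
    verts, faces, _, _ = marching_cubes(
        field, level=0.5, spacing=tuple(mask.spacing)
    )
    verts = verts + mask.origin
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if tm.volume < 0:  # ensure outward orientation
        tm.invert()
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                       np.asarray(tm.vertex_normals, dtype=np.float64))


def _skeleton_longest_path(skel: np.ndarray) -> np.ndarray:
    """Index coordinates of the longest geodesic path through a 3D skeleton."""
    coords = np.argwhere(skel)
    if len(coords) < 2:
        raise ValueError("degenerate mask: skeleton has fewer than 2 voxels")
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=np.sqrt(3) + 1e-6, output_type="ndarray")
    if len(pairs) == 0:
        raise ValueError("skeleton is disconnected at voxel scale")
    w = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    n = len(coords)
    g = coo_matrix((np.r_[w, w], (np.r_[pairs[:, 0], pairs[:, 1]],
                                  np.r_[pairs[:, 1], pairs[:, 0]])), shape=(n, n))

    d0 = dijkstra(g, indices=0)
    d0[np.isinf(d0)] = -1
    a = int(np.argmax(d0))
    da, pred = dijkstra(g, indices=a, return_predecessors=True)
    da[np.isinf(da)] = -1
    b = int(np.argmax(da))
    path = [b]
    while path[-1] != a:
        p = pred[path[-1]]
        if p < 0:
            raise ValueError("skeleton path reconstruction failed")
        path.append(int(p))
    return coords[path[::-1]]


def extract_centerline(mask: LumenMask, proximal_hint=None,
                       spacing: float = 0.05, smooth: float = None) -> Centerline:
    """Centerline of a tubular lumen mask.

    Skeletonizes the (time-averaged) mask, orders the skeleton by its
    longest geodesic path, fits a smoothing spline, and extends both ends
    along the end tangents to the mask boundary (skeletonization erodes
    roughly one radius at each open end).  ``proximal_hint`` (world mm)
    selects which end is z = 0; without it the lexicographically smaller
    endpoint is proximal.
    """
    vol = mask.time_average()
    if not vol.any():
        raise ValueError("empty lumen mask")
    skel = skeletonize(vol)
    path_idx = _skeleton_longest_path(skel)
    if len(path_idx) < 4:
        raise ValueError("degenerate mask: centerline too short")
    pts = path_idx * mask.spacing + mask.origin

    # smoothing spline; residual budget ~ half a voxel per point
    h = float(np.mean(mask.spacing))
    if smooth is None:
        smooth = len(pts) * (0.5 * h) ** 2
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(seg)])
    u /= u[-1]
    k = min(3, len(pts) - 1)
    tck, _ = splprep(pts.T, u=u, s=smooth, k=k)
    uu = np.linspace(0, 1, max(4 * len(pts), 50))
    sm = np.stack(splev(uu, tck), axis=1)

    sm = _extend_to_boundary(sm, mask, step=0.25 * h)

    cl = Centerline(sm)
    cl = cl.resample(spacing)
    if proximal_hint is not None:
        hint = np.asarray(proximal_hint, dtype=float)
        flip = (np.linalg.norm(cl.points[-1] - hint)
                < np.linalg.norm(cl.points[0] - hint))
    else:
        flip = tuple(cl.points[-1]) < tuple(cl.points[0])
    if flip:
        cl = Centerline(cl.points[::-1].copy())
        cl = cl.resample(spacing)
    return cl


def _extend_to_boundary(pts: np.ndarray, mask: LumenMask, step: float,
                        max_steps: int = 400) -> np.ndarray:
    """Extend a polyline linearly along its end tangents while inside the mask."""
    out = pts
    for end in (0, -1):
        p = out[end]
        t = out[-1] - out[-2] if end == -1 else out[0] - out[1]
        nt = np.linalg.norm(t)
        if nt == 0:
            continue
        t = t / nt
        ext = []
        q = p.copy()
        for _ in range(max_steps):
            q = q + step * t
            if mask.sample_weight(q[None])[0] < 0.5:
                break
            ext.append(q.copy())
        if ext:
            ext = np.asarray(ext)
            out = np.vstack([out, ext]) if end == -1 else np.vstack([ext[::-1], out])
    return out


def normalize_extent(centerline: Centerline, mesh: SurfaceMesh, landmark_z: float,
                     prox_mm: float = 3.0, dist_mm: float = 4.0
                     ) -> tuple[Centerline, SurfaceMesh]:
    """Clip centerline and mesh to [landmark - prox_mm, landmark + dist_mm].

    Matches the study's length normalization: a 7 mm window (3 mm proximal,
    4 mm distal of the landmark) with arc length re-zeroed at the proximal
    cut.  Raises if the requested extent exceeds the available centerline.
    """
    z0 = landmark_z - prox_mm
    z1 = landmark_z + dist_mm
    eps = 1e-9
    if not (centerline.arc_length[0] - eps <= landmark_z <= centerline.arc_length[-1] + eps):
        raise ValueError("landmark outside the centerline range")
    cl = centerline.crop(z0, z1)

    dense = centerline.resample(0.05)
    tree = cKDTree(dense.points)
    _, foot = tree.query(mesh.nodes)
    node_z = dense.arc_length[foot]
    keep = (node_z >= z0 - eps) & (node_z <= z1 + eps)
    new_index = -np.ones(mesh.n_nodes, dtype=np.intp)
    new_index[keep] = np.arange(keep.sum())
    fkeep = keep[mesh.faces].all(axis=1)
    faces = new_index[mesh.faces[fkeep]]
    sub = SurfaceMesh(mesh.nodes[keep], faces, mesh.node_normals[keep])
    return cl, sub


@dataclass
class WallFrameSet:
    """Per-node orthonormal wall frames and cylindrical coordinates.

    Arrays are aligned with the mesh nodes: ``l_hat``/``c_hat``/``r_hat``
    (N, 3), ``theta`` degrees in [0, 360), ``z`` arc length (mm), ``valid``
    flags (False near branch ostia or degenerate geometry).
    """

    node_id: np.ndarray
    l_hat: np.ndarray
    c_hat: np.ndarray
    r_hat: np.ndarray
    theta: np.ndarray
    z: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.node_id)


def parallel_transport_reference(tangents: np.ndarray, ref0: np.ndarray) -> np.ndarray:
    """Transport a reference direction along a curve by projecting out the
    tangent at each step (rotation-minimizing approximation)."""
    refs = np.empty_like(tangents)
    r = np.asarray(ref0, dtype=float)
    r = r - np.dot(r, tangents[0]) * tangents[0]
    nr = np.linalg.norm(r)
    if nr < 1e-8:
        raise ValueError("reference direction is parallel to the initial tangent")
    r /= nr
    for i, t in enumerate(tangents):
        r = r - np.dot(r, t) * t
        nr = np.linalg.norm(r)
        if nr < 1e-12:
            r = refs[i - 1]
            nr = 1.0
        r = r / nr
        refs[i] = r
    return refs


def build_wall_frames(mesh: SurfaceMesh, centerline: Centerline,
                      reference=None, invalid_regions=None,
                      foot_spacing: float = 0.05) -> WallFrameSet:
    """Attach (l_hat, c_hat, r_hat, z, theta) to every mesh node.

    The nearest point on the densely resampled centerline defines z and the
    longitudinal direction; the radial direction points from the node toward
    that foot point (orthogonalized against l_hat); c_hat completes the
    right-handed frame.  theta is measured from a posterior reference
    direction transported along the centerline without twist, increasing so
    that the outer curvature of an arch (away from its center) sits at 90
    degrees.  ``invalid_regions`` is an iterable of (center_mm, radius_mm)
    spheres (branch ostia) whose nodes are flagged invalid.
    """
    dense = centerline.resample(foot_spacing)
    if reference is None:
        t0 = dense.tangents[0]
        trial = np.eye(3)[np.argmin(np.abs(t0))]
        reference = trial
    refs = parallel_transport_reference(dense.tangents, reference)

    tree = cKDTree(dense.points)
    _, foot = tree.query(mesh.nodes)
    z = dense.arc_length[foot]
    l_hat = dense.tangents[foot]
    e_ref = refs[foot]

    u = mesh.nodes - dense.points[foot]
    u_perp = u - np.sum(u * l_hat, axis=1, keepdims=True) * l_hat
    nu = np.linalg.norm(u_perp, axis=1)
    valid = nu > 1e-9

    r_hat = np.zeros_like(u_perp)
    r_hat[valid] = -u_perp[valid] / nu[valid, None]
    c_hat = np.cross(l_hat, r_hat)

    e2 = np.cross(e_ref, l_hat)
    theta = np.degrees(np.arctan2(np.sum(u_perp * e2, axis=1),
                                  np.sum(u_perp * e_ref, axis=1)))
    theta = np.mod(theta, 360.0)

    # endpoints: the foot tangent is one-sided there; keep but flag extremes
    if invalid_regions:
        for center, radius in invalid_regions:
            d = np.linalg.norm(mesh.nodes - np.asarray(center, dtype=float), axis=1)
            valid &= d > radius

    return WallFrameSet(
        node_id=np.arange(mesh.n_nodes), l_hat=l_hat, c_hat=c_hat, r_hat=r_hat,
        theta=theta, z=z, valid=valid,
    )
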