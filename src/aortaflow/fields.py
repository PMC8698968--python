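"""Core volumetric containers for time-resolved velocity fields and lumen masks.

Conventions
-----------
* Voxel indexing is 0-based; world coordinates (mm) are
  ``world = index * spacing + origin`` — i.e. ``origin`` is the world
  position of voxel (0, 0, 0) and spacing may be anisotropic.
* Velocities are stored in cm/s (the usual phase-contrast convention);
  conversions to SI happen inside the consumers that need them.
* Frame times are in ms and cover one cardiac cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = ["VelocityField4D", "LumenMask"]


@dataclass
class VelocityField4D:
    """Time-resolved three-component velocity volume.

    Parameters
    ----------
    data : ndarray, shape (n_frames, 3, nx, ny, nz)
        Velocity components (vx, vy, vz) in cm/s per cardiac frame.
    spacing : ndarray, shape (3,)
        Voxel edge lengths in mm.
    origin : ndarray, shape (3,)
        World position (mm) of voxel (0, 0, 0).
    frame_times : ndarray, shape (n_frames,)
        Time of each frame in ms, strictly increasing within the cycle.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default=None)
    frame_times: np.ndarray = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 5 or self.data.shape[1] != 3:
            raise ValueError(
                "velocity data must have shape (n_frames, 3, nx, ny, nz), "
                f"got {self.data.shape}"
            )
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.frame_times is None:
            self.frame_times = np.arange(self.n_frames, dtype=np.float64)
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        if len(self.frame_times) != self.n_frames:
            raise ValueError("frame_times length must equal n_frames")
        if self.n_frames > 1 and np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape[2:]

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Convert world coordinates (mm) to fractional voxel indices."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=np.float64))
        return (pts - self.origin) / self.spacing

    def sample(self, points_mm: np.ndarray, frame: int) -> np.ndarray:
        """Trilinearly sample all three components at world points (N, 3) -> (N, 3) cm/s."""
        idx = self.world_to_index(points_mm).T  # (3, N)
        out = np.empty((idx.shape[1], 3))
        for c in range(3):
            out[:, c] = map_coordinates(
                self.data[frame, c], idx, order=1, mode="constant", cval=0.0
            )
        return out

    def sample_all_frames(self, points_mm: np.ndarray) -> np.ndarray:
        """Trilinear samples of all frames at once: (N, 3) points ->
        (n_frames, N, 3) cm/s.  The interpolation weights are computed once
        and reused across frames, which is much faster than per-frame
        ``sample`` for long cines."""
        idx = self.world_to_index(points_mm)  # (N, 3)
        dims = np.array(self.shape)
        i0 = np.floor(idx).astype(np.intp)
        frac = idx - i0
        inside = np.all((idx >= 0) & (idx <= dims - 1), axis=1)
        i0 = np.clip(i0, 0, dims - 2)
        frac = np.clip(idx - i0, 0.0, 1.0)

        n = len(idx)
        vals = np.zeros((self.n_frames, n, 3))
        for corner in range(8):
            off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
            w = np.prod(np.where(off, frac, 1.0 - frac), axis=1) * inside
            nz = w > 0
            if not nz.any():
                continue
            ci = i0[nz] + off
            block = self.data[:, :, ci[:, 0], ci[:, 1], ci[:, 2]]  # (F, 3, M)
            vals[:, nz, :] += w[nz][None, :, None] * np.transpose(block, (0, 2, 1))
        return vals


@dataclass
class LumenMask:
    """Time-resolved binary lumen segmentation.

    ``data`` has shape (n_frames, nx, ny, nz) (bool); a static mask may be
    stored with n_frames = 1 and broadcast by consumers.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim == 3:
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError(
                f"mask data must have shape (n_frames, nx, ny, nz), got {self.data.shape}"
            )
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape[1:]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def frame(self, i: int) -> np.ndarray:
        """Mask of frame ``i``; a static (single-frame) mask serves every frame."""
        return self.data[0] if self.n_frames == 1 else self.data[i]

    def time_average(self, threshold: float = 0.5) -> np.ndarray:
        """Voxels inside the lumen in at least ``threshold`` of the frames."""
        return self.data.mean(axis=0) >= threshold

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=np.float64))
        return (pts - self.origin) / self.spacing

    def sample_weight(self, points_mm: np.ndarray, frame: int = 0) -> np.ndarray:
        """Trilinearly interpolated lumen membership in [0, 1] at world points."""
        idx = self.world_to_index(points_mm).T
        return map_coordinates(
            self.frame(frame).astype(np.float64), idx, order=1,
            mode="constant", cval=0.0,
        )
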