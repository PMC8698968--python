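"""Through-plane flow, transit-time pulse wave velocity and lumen volume.

PWV is estimated with the multiple-point transit-time method: through-plane
flow curves are extracted at ~50 equidistant centerline positions, the foot
of the systolic upstroke is timestamped per plane as the intersection of a
line fitted to the early-systolic rise with a line fitted to the
pre-systolic baseline, and a least-squares line through the (position,
arrival time) pairs yields PWV = dx/dt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import VelocityField4D, LumenMask
from .geometry import Centerline

__all__ = [
    "FlowCurve", "PWVFit", "VolumeSeries", "PWVUnresolvableError",
    "through_plane_flow", "detect_upstroke", "estimate_pwv", "volume_series",
]

#: cm/s integrated over mm^2 -> mL/min
_CMS_MM2_TO_ML_MIN = 0.6


class PWVUnresolvableError(RuntimeError):
    """Raised when the wave transit is too fast (or reversed) to resolve."""


@dataclass
class FlowCurve:
    """Volumetric flow (mL/min) through one plane, per cardiac frame."""

    position: float          # arc length along the centerline (mm)
    flow: np.ndarray         # mL/min per frame
    frame_times: np.ndarray  # ms

    def __post_init__(self):
        self.flow = np.asarray(self.flow, dtype=np.float64)
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        if len(self.flow) != len(self.frame_times):
            raise ValueError("flow and frame_times lengths differ")
        if len(self.frame_times) > 1 and np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")


@dataclass
class PWVFit:
    """Transit-time fit: arrival times (ms) vs positions (mm) and the
    derived wave speed (m/s)."""

    positions: np.ndarray
    upstroke_times: np.ndarray
    pwv: float
    fit_r2: float


@dataclass
class VolumeSeries:
    """Time-resolved lumen volume (mm^3) with summary statistics."""

    volume: np.ndarray
    mean: float
    max: float
    min: float
    max_minus_min: float


def _plane_basis(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    trial = np.eye(3)[np.argmin(np.abs(tangent))]
    e1 = np.cross(tangent, trial)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(tangent, e1)
    return e1, e2


def through_plane_flow(velocity: VelocityField4D, mask: LumenMask,
                       centerline: Centerline, position: float,
                       halfwidth: float = None, pitch: float = None) -> FlowCurve:
    """Flow through the plane orthogonal to the centerline at ``position``.

    The plane is rasterized at half-voxel pitch; at each in-lumen plane
    pixel the velocity is sampled trilinearly and its component along the
    plane normal integrated: flow(t) = sum (v . n) dA, reported in mL/min.
    """
    if not (centerline.arc_length[0] - 1e-9 <= position <= centerline.arc_length[-1] + 1e-9):
        raise ValueError("plane position outside the centerline extent")
    p0 = centerline.point_at(position)[0]
    n = centerline.tangent_at(position)[0]
    e1, e2 = _plane_basis(n)

    h = float(np.mean(velocity.spacing))
    pitch = pitch or 0.5 * h
    if halfwidth is None:
        # generous bound: farthest mask voxel from this centerline point,
        # projected into the plane, capped for efficiency
        halfwidth = _mask_halfwidth(mask, p0)
    u = np.arange(-halfwidth, halfwidth + 0.5 * pitch, pitch)
    U, V = np.meshgrid(u, u, indexing="ij")
    pts = p0 + U.ravel()[:, None] * e1 + V.ravel()[:, None] * e2
    dA = pitch * pitch

    if mask.n_frames == 1:
        inside = mask.sample_weight(pts, frame=0) >= 0.5
        if not inside.any():
            raise ValueError("plane does not intersect the lumen")
        v = velocity.sample_all_frames(pts[inside])  # (F, M, 3)
        flows = (v @ n).sum(axis=1) * dA * _CMS_MM2_TO_ML_MIN
    else:
        flows = np.empty(velocity.n_frames)
        for f in range(velocity.n_frames):
            w = mask.sample_weight(pts, frame=min(f, mask.n_frames - 1))
            inside = w >= 0.5
            if f == 0 and not inside.any():
                raise ValueError("plane does not intersect the lumen")
            v = velocity.sample(pts[inside], f)
            flows[f] = np.sum(v @ n) * dA * _CMS_MM2_TO_ML_MIN
    return FlowCurve(position=float(position), flow=flows,
                     frame_times=velocity.frame_times.copy())


def _mask_halfwidth(mask: LumenMask, p0: np.ndarray) -> float:
    vox = np.argwhere(mask.time_average())
    if len(vox) == 0:
        raise ValueError("empty mask")
    pts = vox * mask.spacing + mask.origin
    d = np.linalg.norm(pts - p0, axis=1)
    # only nearby voxels can intersect the plane; 95th percentile of the
    # closest quarter is a robust tube-radius scale
    near = np.sort(d)[: max(len(d) // 4, 8)]
    return float(min(3.0 * near[-1], d.max()) + 2 * np.mean(mask.spacing))


def detect_upstroke(curve: FlowCurve, rise_lo: float = 0.2, rise_hi: float = 0.8,
                    baseline_frac: float = 0.10, min_amplitude_frac: float = 0.05
                    ) -> float:
    """Time (ms) of the systolic foot by baseline/upstroke line intersection.

    The upstroke line is fitted to samples between ``rise_lo`` and
    ``rise_hi`` of (peak - baseline) on the rising limb; the baseline line
    to the ~10% of frames preceding the foot candidate (first crossing of
    baseline + 10% amplitude).  Raises on a flat curve.
    """
    q0 = np.asarray(curve.flow, dtype=float)
    t0 = np.asarray(curve.frame_times, dtype=float)
    if len(q0) < 4:
        raise ValueError("flow curve too short for upstroke detection")
    # upsample (piecewise linear) so the fit windows move smoothly with
    # sub-frame shifts of the waveform instead of jumping at frame edges,
    # then smooth over one original frame interval to suppress sample noise
    up = 10
    t = np.linspace(t0[0], t0[-1], (len(t0) - 1) * up + 1)
    q = np.interp(t, t0, q0)
    kernel = np.ones(up + 1) / (up + 1)
    q = np.convolve(q, kernel, mode="same")
    n = len(q)
    peak_i = int(np.argmax(q))
    base = float(np.percentile(q, 5))  # robust pre-systolic level
    amp = q[peak_i] - base
    if amp <= min_amplitude_frac * max(abs(q).max(), 1e-12) or amp <= 0:
        raise ValueError("flat flow curve: no systolic upstroke")

    # candidate foot: last upward crossing of baseline + 10% amplitude
    # before the peak (backward scan is robust to baseline noise spikes)
    thresh = base + 0.10 * amp
    below = np.nonzero(q[: peak_i + 1] < thresh)[0]
    if len(below) == 0:
        raise ValueError("no crossing of the baseline threshold before the peak")
    cand = int(below[-1]) + 1

    n_base = max(int(round(baseline_frac * n)), 2)
    b_idx = np.arange(max(cand - n_base, 0), cand)
    if len(b_idx) >= 2:
        mb, cb = np.polyfit(t[b_idx], q[b_idx], 1)
    else:  # too few pre-systolic frames: horizontal baseline at the minimum
        mb, cb = 0.0, base

    lo = base + rise_lo * amp
    hi = base + rise_hi * amp
    seg = np.arange(cand, peak_i + 1)
    seg = seg[(q[seg] >= lo) & (q[seg] <= hi)]
    if len(seg) < 2:
        raise ValueError("upstroke too steep to fit")
    mu, cu = np.polyfit(t[seg], q[seg], 1)
    if mu <= mb:
        raise ValueError("upstroke slope does not exceed baseline slope")
    return float((cb - cu) / (mu - mb))


def estimate_pwv(curves, min_planes: int = 3) -> PWVFit:
    """Least-squares transit-time fit over plane positions.

    Arrival time is regressed on position (detection errors live in time);
    PWV = 1/slope converted to m/s, with the r^2 of the fit.  A
    non-positive or near-zero slope (wave faster than the temporal
    resolution resolves) raises :class:`PWVUnresolvableError`.
    """
    curves = list(curves)
    if len(curves) < min_planes:
        raise ValueError(f"need at least {min_planes} planes")
    x = np.array([c.position for c in curves], dtype=float)
    tt = np.array([detect_upstroke(c) for c in curves], dtype=float)

    slope, intercept = np.polyfit(x, tt, 1)  # ms per mm
    pred = slope * x + intercept
    ss_res = float(np.sum((tt - pred) ** 2))
    ss_tot = float(np.sum((tt - tt.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    dt_frame = float(np.median(np.diff(curves[0].frame_times)))
    span = x.max() - x.min()
    min_slope = 0.1 * dt_frame / span if span > 0 else np.inf
    if slope <= min_slope:
        raise PWVUnresolvableError(
            f"transit-time slope {slope:.4g} ms/mm is non-positive or below the "
            f"temporal resolution ({dt_frame:.3g} ms over {span:.3g} mm)"
        )
    return PWVFit(positions=x, upstroke_times=tt, pwv=float(1.0 / slope), fit_r2=r2)


def volume_series(mask: LumenMask, exclude: np.ndarray = None) -> VolumeSeries:
    """Per-frame lumen volume by voxel counting (exact, mm^3).

    ``exclude`` is an optional boolean volume flagging branch voxels to
    drop (the study excludes the three aortic branches).
    """
    vols = []
    for f in range(mask.n_frames):
        m = mask.frame(f)
        if exclude is not None:
            m = m & ~exclude
        count = int(m.sum())
        if count == 0:
            raise ValueError(f"frame {f} has an empty mask")
        vols.append(count * mask.voxel_volume)
    v = np.asarray(vols)
    return VolumeSeries(volume=v, mean=float(v.mean()), max=float(v.max()),
                        min=float(v.min()), max_minus_min=float(v.max() - v.min()))
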