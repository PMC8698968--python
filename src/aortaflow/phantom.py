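"""Synthetic flow phantoms with analytic ground truth.

Emulates the study geometry that the rest of the pipeline is designed for:
a straight tube or a 180-degree arch at 100 um isotropic resolution,
parabolic (optionally swirling) pulsatile axial flow sampled at 20 frames
per cardiac cycle (200 frames in PWV mode), with a travelling systolic
upstroke of prescribed wave speed and optional additive velocity noise.

Analytic ground truth (wall shear stress components, OSI, flow, lumen
volume, pulse wave velocity) is returned alongside the sampled fields so
every downstream estimator can be validated against closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .fields import VelocityField4D, LumenMask

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "add_velocity_noise"]

#: cm/s integrated over mm^2 -> mL/min
_CMS_MM2_TO_ML_MIN = 0.6
#: (cm/s)/mm -> 1/s
_SHEAR_UNIT = 10.0


@dataclass
class PhantomSpec:
    """Parameters of the synthetic phantom.

    Lengths in mm, times in ms, velocities in cm/s unless noted.

    Attributes
    ----------
    geometry : {"straight_cylinder", "torus_arch"}
    radius : tube radius R (mm)
    arch_radius : centerline radius of the half-torus arch (mm)
    length : cylinder length (mm)
    voxel_size : isotropic voxel edge (mm); the study used 0.1 mm
    n_frames : frames per cardiac cycle (20 WSS mode, 200 PWV mode)
    heart_period : cardiac cycle duration (ms); ~120 ms for a mouse
    v_max_axial : peak centerline axial velocity (cm/s)
    waveform : {"steady", "half_sine_pulse"}
    helical_v_c : peak azimuthal (swirl) speed at the wall (cm/s)
    wave_speed : pulse propagation speed (m/s); 0 means simultaneous
    systole_fraction : systolic duration as a fraction of the period
    onset_fraction : time of the systolic foot as a fraction of the period
    noise_sd : SD of additive velocity noise inside the lumen (cm/s)
    seed : RNG seed for the noise
    """

    geometry: str = "straight_cylinder"
    radius: float = 0.6
    arch_radius: float = 1.5
    length: float = 7.0
    voxel_size: float = 0.1
    n_frames: int = 20
    heart_period: float = 120.0
    v_max_axial: float = 100.0
    waveform: str = "steady"
    helical_v_c: float = 0.0
    wave_speed: float = 0.0
    systole_fraction: float = 0.30
    onset_fraction: float = 0.10
    noise_sd: float = 0.0
    seed: int = 0
    eta: float = 0.004  # Pa*s, used only for the analytic WSS truth

    def validate(self) -> None:
        if self.geometry not in ("straight_cylinder", "torus_arch"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.voxel_size >= self.radius:
            raise ValueError(
                f"voxel_size {self.voxel_size} mm cannot resolve a lumen of "
                f"radius {self.radius} mm"
            )
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.geometry == "torus_arch" and self.arch_radius <= self.radius:
            raise ValueError(
                "torus arch requires arch_radius > radius (self-intersection)"
            )
        if self.geometry == "straight_cylinder" and self.length <= 0:
            raise ValueError("length must be positive")
        if self.waveform not in ("steady", "half_sine_pulse"):
            raise ValueError(f"unknown waveform {self.waveform!r}")


@dataclass
class PhantomTruth:
    """Closed-form ground truth of a phantom (reference magnitudes).

    ``wss_long_wall`` = 2*eta*v_max/R and ``wss_circ_wall`` = eta*v_c/R in
    Pa at peak flow; ``osi_wall`` in percent; ``net_flow`` per frame in
    mL/min; ``lumen_volume`` in mm^3; ``pwv`` in m/s (0 if the wave is
    simultaneous).
    """

    wss_long_wall: float
    wss_circ_wall: float
    osi_wall: float
    net_flow: np.ndarray
    lumen_volume: float
    pwv: float
    foot_times: np.ndarray = field(default=None)  # ms, systolic foot per unit arc pos

    def as_dict(self) -> dict:
        d = asdict(self)
        d["net_flow"] = np.asarray(self.net_flow).tolist()
        if self.foot_times is not None:
            d["foot_times"] = np.asarray(self.foot_times).tolist()
        return d


def _waveform_factor(spec: PhantomSpec, t_ms: np.ndarray) -> np.ndarray:
    """Dimensionless amplitude of the axial waveform at times t (ms), peak 1."""
    if spec.waveform == "steady":
        return np.ones_like(np.asarray(t_ms, dtype=float))
    T = spec.heart_period
    t_sys = spec.systole_fraction * T
    t0 = spec.onset_fraction * T
    base = 0.05
    tp = np.mod(np.asarray(t_ms, dtype=float) - t0, T)
    amp = np.where(
        tp <= t_sys,
        base + (1.0 - base) * np.sin(np.pi * np.clip(tp, 0, t_sys) / t_sys),
        base,
    )
    return amp


def _cylinder_fields(spec: PhantomSpec):
    h = spec.voxel_size
    R, L = spec.radius, spec.length
    margin = 2 * h
    nx = int(np.ceil((L + 2 * margin) / h))
    n_perp = int(np.ceil(2 * (R + margin) / h))
    if n_perp % 2 == 0:
        n_perp += 1  # odd count puts a voxel-center line exactly on the axis
    x = (np.arange(nx) + 0.5) * h - margin
    y = (np.arange(n_perp) - (n_perp - 1) / 2) * h
    z = y.copy()
    origin = np.array([x[0], y[0], z[0]])

    X = x[:, None, None]
    Y = y[None, :, None]
    Z = z[None, None, :]
    r = np.sqrt(Y**2 + Z**2)
    inside = (r <= R) & (X >= 0) & (X <= L)
    s_axial = np.broadcast_to(X, inside.shape)  # arc position along the tube

    prof_ax = np.where(inside, 1.0 - (r / R) ** 2, 0.0)
    axial_dir = np.zeros(inside.shape + (3,))
    axial_dir[..., 0] = 1.0

    with np.errstate(invalid="ignore", divide="ignore"):
        prof_az = np.where(inside, (r / R) ** 2, 0.0)
        az_dir = np.zeros(inside.shape + (3,))
        rr = np.broadcast_to(r, inside.shape)
        safe = rr > 1e-12
        az_dir[..., 1] = np.where(safe, -np.broadcast_to(Z, inside.shape) / np.where(safe, rr, 1.0), 0.0)
        az_dir[..., 2] = np.where(safe, np.broadcast_to(Y, inside.shape) / np.where(safe, rr, 1.0), 0.0)

    volume = np.pi * R**2 * L
    return inside, s_axial, prof_ax, axial_dir, prof_az, az_dir, origin, volume


def _arch_fields(spec: PhantomSpec):
    h = spec.voxel_size
    R, Rc = spec.radius, spec.arch_radius
    margin = 2 * h
    half = Rc + R + margin
    nx = int(np.ceil(2 * half / h))
    n_y = int(np.ceil(2 * (R + margin) / h))
    if n_y % 2 == 0:
        n_y += 1
    nz = int(np.ceil((half + margin) / h))
    x = (np.arange(nx) - (nx - 1) / 2) * h
    y = (np.arange(n_y) - (n_y - 1) / 2) * h
    z = (np.arange(nz) + 0.5) * h - margin
    origin = np.array([x[0], y[0], z[0]])

    X = x[:, None, None]
    Y = y[None, :, None]
    Z = z[None, None, :]
    rho = np.sqrt(X**2 + Z**2)
    d = np.sqrt((rho - Rc) ** 2 + Y**2)
    inside = (d <= R) & (Z >= 0)

    phi = np.arctan2(Z, X)  # 0 at +x (proximal), pi at -x (distal)
    s_axial = np.broadcast_to(Rc * phi, inside.shape)

    prof_ax = np.where(inside, 1.0 - (d / R) ** 2, 0.0)
    tang = np.zeros(inside.shape + (3,))
    tang[..., 0] = np.broadcast_to(-np.sin(phi), inside.shape)
    tang[..., 2] = np.broadcast_to(np.cos(phi), inside.shape)

    # cross-section offset vector w from the centerline circle to the voxel
    with np.errstate(invalid="ignore", divide="ignore"):
        safe_rho = np.where(rho > 1e-12, rho, 1.0)
        w = np.zeros(inside.shape + (3,))
        w[..., 0] = np.broadcast_to((rho - Rc) * X / safe_rho, inside.shape)
        w[..., 1] = np.broadcast_to(Y * np.ones_like(rho), inside.shape)
        w[..., 2] = np.broadcast_to((rho - Rc) * Z / safe_rho, inside.shape)
        dd = np.broadcast_to(d, inside.shape)
        safe_d = dd > 1e-12
        w_hat = np.where(safe_d[..., None], w / np.where(safe_d, dd, 1.0)[..., None], 0.0)
    az_dir = np.cross(tang, w_hat)
    prof_az = np.where(inside, (d / R) ** 2, 0.0)

    volume = np.pi * R**2 * (np.pi * Rc)
    return inside, s_axial, prof_ax, tang, prof_az, az_dir, origin, volume


def generate_phantom(spec: PhantomSpec) -> tuple[VelocityField4D, LumenMask, PhantomTruth]:
    """Sample the phantom on its voxel grid and return field, mask and truth.

    Velocity inside the lumen follows v_axial(r, t) = v_max(t) (1 - (r/R)^2)
    along the local tube axis plus an optional swirl
    v_phi(r, t) = v_c(t) (r/R)^2; for wave_speed c > 0 the waveform at arc
    position s is evaluated at t - s/c. Voxels outside the lumen are zero.
    Noise (SD ``noise_sd``, seeded) is added to in-lumen velocities only.
    """
    spec.validate()
    if spec.geometry == "straight_cylinder":
        inside, s_ax, prof_ax, ax_dir, prof_az, az_dir, origin, volume = _cylinder_fields(spec)
    else:
        inside, s_ax, prof_ax, ax_dir, prof_az, az_dir, origin, volume = _arch_fields(spec)

    n = spec.n_frames
    times = np.arange(n) * spec.heart_period / n
    shape = inside.shape
    data = np.zeros((n, 3) + shape)

    # travelling-wave time shift in ms: s [mm] / c [m/s = mm/ms]
    if spec.wave_speed > 0:
        shift = s_ax / spec.wave_speed
    else:
        shift = np.zeros(shape)

    idx = np.nonzero(inside)
    shift_in = shift[idx]
    prof_ax_in = prof_ax[idx]
    prof_az_in = prof_az[idx]
    ax_dir_in = ax_dir[idx]
    az_dir_in = az_dir[idx]

    rng = np.random.default_rng(spec.seed)
    for f, t in enumerate(times):
        amp = _waveform_factor(spec, t - shift_in)
        v = (
            spec.v_max_axial * amp[:, None] * prof_ax_in[:, None] * ax_dir_in
            + spec.helical_v_c * amp[:, None] * prof_az_in[:, None] * az_dir_in
        )
        if spec.noise_sd > 0:
            v = v + rng.normal(0.0, spec.noise_sd, size=v.shape)
        for c in range(3):
            data[f, c][idx] = v[:, c]

    vel = VelocityField4D(data, spacing=[spec.voxel_size] * 3, origin=origin,
                          frame_times=times)
    mask = LumenMask(inside[None], spacing=[spec.voxel_size] * 3, origin=origin)

    amp_t = _waveform_factor(spec, times)
    R = spec.radius
    truth = PhantomTruth(
        wss_long_wall=2.0 * spec.eta * spec.v_max_axial * _SHEAR_UNIT / R,
        wss_circ_wall=spec.eta * spec.helical_v_c * _SHEAR_UNIT / R,
        osi_wall=0.0,
        net_flow=_CMS_MM2_TO_ML_MIN * np.pi * R**2 * spec.v_max_axial * amp_t / 2.0,
        lumen_volume=volume,
        pwv=spec.wave_speed,
        foot_times=(np.array([spec.onset_fraction * spec.heart_period])
                    if spec.waveform == "half_sine_pulse" else None),
    )
    return vel, mask, truth


def add_velocity_noise(vel: VelocityField4D, mask: LumenMask, sd: float,
                       rng: np.random.Generator) -> VelocityField4D:
    """Return a copy of ``vel`` with zero-mean Gaussian noise (SD ``sd``, cm/s)
    added to the velocity components inside the lumen."""
    data = vel.data.copy()
    if mask.n_frames == 1:
        idx = np.nonzero(mask.frame(0))
        noise = rng.normal(0.0, sd, size=(vel.n_frames, 3, idx[0].size))
        data[:, :, idx[0], idx[1], idx[2]] += noise
    else:
        for f in range(vel.n_frames):
            idx = np.nonzero(mask.frame(min(f, mask.n_frames - 1)))
            data[f, :, idx[0], idx[1], idx[2]] += rng.normal(
                0.0, sd, size=(idx[0].size, 3))
    return VelocityField4D(data, spacing=vel.spacing, origin=vel.origin,
                           frame_times=vel.frame_times)
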