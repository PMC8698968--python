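"""Shared fixtures: phantoms and derived geometry, session-scoped because
generation and surface/WSS extraction are the expensive steps."""

import numpy as np
import pytest

from aortaflow import (
    PhantomSpec, generate_phantom, extract_surface, extract_centerline,
    build_wall_frames, compute_wall_shear,
)

ETA = 0.004


@pytest.fixture(scope="session")
def poiseuille():
    """Steady Poiseuille cylinder at the study resolution (R=0.6 mm, 100 um)."""
    spec = PhantomSpec(geometry="straight_cylinder", radius=0.6, length=7.0,
                       voxel_size=0.1, n_frames=1, v_max_axial=100.0)
    vel, mask, truth = generate_phantom(spec)
    return spec, vel, mask, truth


@pytest.fixture(scope="session")
def poiseuille_mesh(poiseuille):
    _, _, mask, _ = poiseuille
    return extract_surface(mask)


@pytest.fixture(scope="session")
def poiseuille_wss(poiseuille, poiseuille_mesh):
    _, vel, mask, _ = poiseuille
    return compute_wall_shear(vel, mask, poiseuille_mesh, eta=ETA)


@pytest.fixture(scope="session")
def helical():
    """Cylinder with superimposed swirl: v_phi = v_c (r/R)^2, v_c = 50 cm/s."""
    spec = PhantomSpec(geometry="straight_cylinder", radius=0.6, length=7.0,
                       voxel_size=0.1, n_frames=1, v_max_axial=100.0,
                       helical_v_c=50.0)
    vel, mask, truth = generate_phantom(spec)
    mesh = extract_surface(mask)
    cl = extract_centerline(mask)
    frames = build_wall_frames(mesh, cl)
    series = compute_wall_shear(vel, mask, mesh, eta=ETA)
    return spec, truth, mesh, frames, series


@pytest.fixture(scope="session")
def arch():
    """Half-torus arch phantom (R=0.6 mm, arch radius 1.5 mm)."""
    spec = PhantomSpec(geometry="torus_arch", radius=0.6, arch_radius=1.5,
                       voxel_size=0.1, n_frames=1, v_max_axial=100.0)
    vel, mask, truth = generate_phantom(spec)
    return spec, vel, mask, truth


@pytest.fixture(scope="session")
def pwv_phantom():
    """PWV-mode phantom: 200 frames, travelling half-sine pulse at 3 m/s."""
    spec = PhantomSpec(geometry="straight_cylinder", radius=0.6, length=7.0,
                       voxel_size=0.1, n_frames=200, heart_period=120.0,
                       v_max_axial=100.0, waveform="half_sine_pulse",
                       wave_speed=3.0)
    vel, mask, truth = generate_phantom(spec)
    cl = extract_centerline(mask)
    return spec, vel, mask, truth, cl


def mid_section(mesh, lo, hi):
    """Nodes away from the cylinder end caps, where wall frames are clean."""
    return (mesh.nodes[:, 0] > lo) & (mesh.nodes[:, 0] < hi)
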