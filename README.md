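# aortaflow

Hemodynamic analysis of time-resolved ("4D flow") phase-contrast MRI of the
murine aortic arch: wall shear stress (WSS) vectors from velocity gradients
at the lumen surface, their longitudinal/circumferential/radial
decomposition, the oscillatory shear index (OSI), 2D *(z, θ)* projection
maps with pixel-wise group statistics, transit-time pulse wave velocity
(PWV), and time-resolved aortic volume.

It is written for small-animal imaging groups studying how local
hemodynamics change with ageing and atherosclerosis (e.g. *Apoe*⁻/⁻ vs
wildtype mice): the outputs are per-animal wall maps that can be compared
pixel-by-pixel between groups and correlated with histology. Because
in-vivo data of this kind are rarely public, the package ships a synthetic
flow-phantom generator with closed-form ground truth, so every estimator is
validated against analytic oracles.

## Model

At each node of the lumen surface mesh the viscous traction exerted by the
blood on the wall is

    τ = 2 η ε̇ n̂ ,     ε̇ᵢⱼ = ½ (∂vᵢ/∂xⱼ + ∂vⱼ/∂xᵢ)

with blood viscosity η = 0.004 Pa·s and n̂ the wall normal pointing into
the fluid. The time-averaged τ is projected onto the local wall frame —
longitudinal (along the centerline), circumferential, and radial (toward
the centerline, i.e. radial strain) — and the oscillatory shear index is

    OSI [%] = ½ (1 − |Σᵢ τ(i)| / Σᵢ |τ(i)|) · 100  ∈ [0, 50] ,

summed over the cardiac frames. Wall values are unwrapped into a regular
*(z, θ)* map (z = centerline arc length, θ = 0° posterior, 90° outer
curvature, 180° anterior, 270° inner curvature; default grid 1 µm × 0.5°).
PWV is estimated from through-plane flow at ~50 equidistant centerline
planes: the systolic-upstroke foot of each flow curve (baseline/upstroke
two-line intersection) is regressed on plane position, PWV = Δx/Δt.

## Worked example

```python
import numpy as np
from aortaflow import (PhantomSpec, generate_phantom, extract_surface,
                       extract_centerline, build_wall_frames,
                       compute_wall_shear, component_table, volume_series)

# pulsatile tube phantom at the study resolution (0.1 mm, 20 frames/cycle)
spec = PhantomSpec(radius=0.6, length=7.0, voxel_size=0.1, n_frames=20,
                   heart_period=120.0, v_max_axial=100.0,
                   waveform="half_sine_pulse", helical_v_c=25.0, seed=0)
vel, mask, truth = generate_phantom(spec)

mesh = extract_surface(mask)
cl = extract_centerline(mask)
frames = build_wall_frames(mesh, cl)
series = compute_wall_shear(vel, mask, mesh, eta=0.004)
table = component_table(series, frames)
ok = table["valid"]
print(f"wall nodes: {len(table)} ({ok.sum()} valid)")
print(f"mean longWSS : {table.loc[ok,'long_wss_pa'].mean():6.2f} Pa")
print(f"mean |circWSS|: {table.loc[ok,'circ_wss_pa'].abs().mean():6.2f} Pa")
print(f"mean OSI     : {table.loc[ok,'osi_pct'].mean():6.2f} %")
vol = volume_series(mask)
print(f"lumen volume : {vol.mean:6.2f} mm^3 (analytic {truth.lumen_volume:.2f})")
```

prints

```
wall nodes: 3298 (3296 valid)
mean longWSS :   2.78 Pa
mean |circWSS|:   0.40 Pa
mean OSI     :   0.00 %
lumen volume :   7.63 mm^3 (analytic 7.92)
```

The peak-systole longitudinal WSS oracle for this tube is
2ηv_max/R = 13.33 Pa; the temporal mean above is lower by the duty cycle of
the half-sine waveform (≈ 0.23), and the OSI is 0 because the WSS vector
never changes direction. A command-line interface mirrors the library:
`aortaflow phantom|wss|project|pwv|volume|pipeline` (see `--help`).

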