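# Methods

## Scope and data model

The package analyses time-resolved three-component velocity volumes
("4D flow") plus binary lumen segmentations. Volumes are NIfTI with voxel
spacing in the header; velocities are stored in cm/s (the phase-contrast
convention), geometry in mm, stresses in Pa, flow in mL/min, PWV in m/s,
volumes in mm³. World coordinates are `index * spacing + origin` with the
origin from the affine translation.

Two reconstruction modes of the same acquisition are assumed: a WSS mode
(100 µm isotropic, 20 frames per cardiac cycle) and a PWV mode (coarser
spatially, 200 frames per cycle). Frame counts are configuration, not
hard-coded; OSI accepts any n ≥ 2.

## Wall shear stress estimation

The traction on the wall is τ = 2ηε̇n̂ with ε̇ the symmetrized velocity
gradient and η = 0.004 Pa·s (configurable). Because the binary
segmentation is the only wall information, the gradient at a surface node
is estimated one-sidedly from inside the lumen:

* The mask is Gaussian-smoothed by 0.6 voxel before the marching-cubes
  isosurface at the 0.5 level. The 0.5 isolevel of a blurred indicator
  stays on the true interface up to O(curvature·σ²); without smoothing the
  staircase normals of a binary isosurface send sampling rays almost
  tangentially to the wall and the gradient estimate collapses at a
  quarter of the nodes.
* Velocities are sampled by trilinear interpolation at depths
  {0.5, 1.0, …, 3.0} voxels along the inward normal. A sample counts only
  if its interpolated lumen weight is ≈ 1 (all eight neighbouring voxels
  inside); shallower, partially-outside samples are biased toward zero by
  the empty exterior voxels. A quadratic polynomial in depth is fitted per
  velocity component (exact for the parabolic profiles the phantom
  prescribes) and its slope evaluated at the node gives the normal
  derivative; at least three interior samples are required, otherwise the
  node is flagged invalid. The value of the fit at depth 0 is never used —
  measured data violate no-slip, so only slopes are trusted.
* Tangential derivatives are central differences (±0.5 voxel) at the
  shallowest depth ≥ 1 voxel at which both offset points are fully
  interior. The full gradient tensor is assembled from the three
  directional derivatives in the orthonormal (normal, tangent, tangent)
  basis.

The normal passed to τ = 2ηε̇n̂ points *into* the fluid, so the
longitudinal component of forward flow is positive and the radial
component ("radial strain") is positive toward the centerline. With the
outward normal every sign would flip; only the convention, not the
physics, differs. Components are stored signed; map statistics run on
signed values by default with a magnitude option.

Measured accuracy on the steady Poiseuille phantom (R = 0.6 mm,
v_max = 100 cm/s): spatial mean |τ| within 2.7% of 2ηv_max/R at 100 µm
voxels, improving to 2.3% (50 µm) and 1.4% (25 µm). On the superimposed
swirl v_φ = v_c (r/R)², the circumferential component—which requires the
tangential curvature term −v_φ/r—agrees with ηv_c/R to ~13%.

## Geometry

The centerline is extracted by 3D skeletonization of the (time-averaged)
mask, ordering the skeleton by its longest geodesic path (two Dijkstra
sweeps), fitting a smoothing cubic spline (residual budget ≈ half a voxel
per point), and extending both ends linearly along the end tangents to the
mask boundary — skeletonization erodes roughly one radius at each open
end. The result is resampled at 50 µm with arc length and unit tangents.
Oracles: cylinder axis recovered within half a voxel and 7 mm ± 0.2 mm;
half-torus arc length within 2% of πR_arch.

Wall frames: each node's nearest point on the densely resampled centerline
defines z and the longitudinal direction; the radial direction points from
node toward that foot (orthogonalized against the tangent) and the
circumferential direction completes the right-handed triad. θ is measured
from a posterior reference direction transported along the centerline by
tangent-projection (rotation-minimizing), oriented so the outer curvature
of an arch sits at 90° and the inner at 270°. Transport avoids frame twist
where the projection of a fixed anatomical axis degenerates in the
strongly curved top region; this is one consistent reading of the
anatomical labels, which fix only four directions per slice. Nodes inside
caller-supplied branch-ostium spheres are flagged invalid rather than
deleted, and validity propagates to the maps.

Length normalization clips centerline and mesh to
[landmark − 3 mm, landmark + 4 mm] (7 mm total) and re-zeroes arc length
at the proximal cut, mirroring the landmark midway between the
brachiocephalic and left subclavian arteries.

## Projection maps

Scattered (z, θ, value) node triples are interpolated linearly (Delaunay)
with the point cloud replicated at θ ± 360° for a seamless wrap;
convex-hull gaps fall back to nearest-neighbour. A grid cell is valid if a
valid node lies within an anisotropic radius of 60 µm × 3°, and invalid if
the nearest node is itself invalid (branch ostia). The default grid is
1 µm × 0.5°, configurable; statistics may run on a coarsened grid
(block-averaging of valid cells) for speed. Group alignment resamples each
map to the common 7 mm landmark window so pixels correspond across
animals; landmark-plus-common-window is our explicit reading of how maps
of differing aortic lengths are brought into pixel correspondence.

## PWV and volume

Through-plane flow is integrated over plane pixels at half-voxel pitch
(trilinear velocity sampling, plane ⊥ centerline tangent). The upstroke
foot is the intersection of a line fitted to the 20–80% rising limb with a
line fitted to the ~10% of samples preceding the foot candidate. For
robustness the curve is first upsampled 10× (so fit windows move smoothly
with sub-frame shifts) and smoothed over one frame interval; the baseline
level is the 5th percentile and the foot candidate is the *last* upward
crossing of baseline + 10% amplitude before the peak, which is insensitive
to baseline noise spikes. Arrival time is regressed on plane position
(detection errors live in time) and inverted to PWV; a non-positive or
near-zero slope raises an "unresolvable" error instead of returning a
number. Noise-free recovery over 2/3/5 m/s is within 0.6%; with additive
flow noise of 5% of peak, the median of 100 repetitions is within 4%.

Volume is exact voxel counting × voxel volume per frame, with an optional
exclusion volume (branch voxels, or everything outside the 7 mm window via
the centerline foot-point map).

The half-sine waveform rides on a 5% baseline with systole spanning 30% of
the cycle, and its foot is placed at 10% of the cycle so every plane has
pre-systolic baseline samples for the two-line intersection; pulse
propagation is a pure time shift, so the prescribed wave speed is exactly
the ground-truth PWV.

## Group statistics

Pixel-wise comparisons compute per-pixel group means, SDs, difference and
a two-sided p-value; pixels invalid in either group are invalid in all
outputs and zero-variance pixels carry an undefined-p sentinel (NaN),
never 0 or 1. The default per-pixel test is the unpaired Welch t-test:
per-pixel normality testing at n = 4–6 animals is uninformative, and the
measured type-I rate under a null simulation (n = 5 vs 5, 10⁴ pixels) is
0.04–0.05. Mann-Whitney is available as an option. p is thresholded at
0.05 per pixel with no multiple-testing correction, matching the map
convention this analysis style uses; the fraction of significant pixels is
logged so users can gauge inflation. Inter-animal dispersion is summarized
by the spatial median and quartiles of the per-pixel SD; note the spatial
median of iid sample SDs converges to σ·sqrt(χ²median(n−1)/(n−1))
(≈ 0.933σ at n = 6), not to E[s] ≈ 0.951σ.

Scalar tests run iterative two-sided Grubbs outlier exclusion (critical
value from the t-distribution, capped at two removals to protect small
groups), then a Shapiro-Wilk gate at α = 0.05 per group: all normal →
Welch t-test / one-way ANOVA, otherwise Mann-Whitney U / Kruskal-Wallis;
groups with n < 3 fall back to the non-parametric branch. The chosen test
is returned for audit. Correlations are Pearson with listwise deletion.
Intragroup comparisons across timepoints are treated as unpaired.

## Synthetic phantom: what it does and does not emulate

The generator emulates the study geometry (straight tube or 180° torus
arch, R = 0.6 mm at 100 µm isotropic), parabolic axial flow with optional
(r/R)² swirl, a travelling half-sine systolic waveform with prescribed
wave speed, binary voxel-center lumen membership, and iid Gaussian
velocity noise inside the lumen (never on the mask). Ground truth is
closed-form: wall WSS 2ηv_max/R (axial) and ηv_c/R (swirl), OSI 0 for
direction-preserving waveforms, flow πR²v_max(t)/2, volume πR²L, PWV = the
prescribed wave speed.

It does **not** emulate: Womersley (Bessel) unsteady profiles, wall
motion/compliance, partial-volume or phase-wrap artifacts, spatially
correlated MR noise, displacement artifacts, or branch vessels. Passing
tests therefore demonstrate correctness of the estimators under ideal
sampling of known fields at the study's resolutions — not robustness to
every in-vivo artifact.

## Numerical choices and problem sizes

* Ridge 10⁻¹² stabilizes the per-node normal-equation solve; zero-signal
  tensors are reproduced to ~10⁻⁸ 1/s.
* OSI of an all-zero series is defined as 0 (no flow is non-oscillatory);
  the formula is 0/0 there.
* Ties in nearest-foot-point lookup resolve to the first (smaller-z)
  candidate of the KD-tree.
* Default test/acceptance problem sizes: 7 mm tubes at 100 µm (~3.3k
  surface nodes), 50 flow planes × 200 frames, 10⁴-pixel null
  simulations, 100-seed noise studies, and a 4-animal pipeline at 60
  frames on a 20 µm × 2° statistics grid — sizes chosen so the whole
  validation suite runs in minutes on a laptop while keeping every
  estimator in its asymptotic regime.

## Known limitations

* The WSS magnitude is biased low by ~2–3% at 100 µm (node placement and
  interpolation); the bias shrinks with voxel size.
* θ continuity through a strongly curved arch relies on transported
  references; maps from differently-oriented animals must share the same
  initial reference to be comparable.
* The per-pixel Welch test at n ≈ 5 is slightly conservative (measured
  type-I ≈ 0.045).
* PWV assumes a single coherent upstroke per cycle; multi-peaked or
  heavily aliased waveforms are rejected rather than fitted.
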