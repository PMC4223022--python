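# Methods

## Problem setting

Gross tumor volume (GTV) delineation for brain tumors in radiotherapy
planning draws on three co-registered image sets: planning CT (electron
density, bone), contrast-enhanced T1 MRI (soft-tissue and enhancing lesion)
and ¹⁸F-FDG PET (metabolic activity).  `trifuse` implements (i) a
transparency-weighted tri-modality fusion that displays all three in one
image, (ii) the mask algebra of the associated delineation protocol, and
(iii) quantitative inter-/intra-observer variation metrics — volume COV,
ADSC, and the median-surface local standard deviation SD_local — together
with a seeded synthetic phantom so that the entire pipeline is testable
without clinical data.

## Coordinate and unit conventions

Volumes are axis-aligned grids in a right-handed world frame; the world
coordinate of voxel index `i` is `origin + i·spacing` (voxel-center
convention, 0-based).  All geometry is computed in millimetres; volumes are
reported in cm³ and distances in cm.  Registration is out of scope: inputs
are assumed co-registered, and a rigid transform (orthonormal rotation,
det = +1 within 1e-6) can be supplied to resample a secondary volume onto the
primary CT grid (trilinear for images, nearest for masks; out-of-field fill
−1000 HU for CT, 0 for MR/PET).

## Fusion model

With CT as the opaque background and PET/MR as semi-transparent foreground
layers, the fused intensity is the sequential over-composite

    I_mix = t_P·I_PET + (1 − t_P)·[ t_M·I_MR + (1 − t_M)·I_CT ],

`t_P, t_M ∈ [0, 1]`.  `t = 1` fully shows a layer: (t_P, t_M) = (0,0), (0,1),
(1,0) reproduce pure CT, MR, PET exactly.  The per-voxel weights
`(t_P, (1−t_P)t_M, (1−t_P)(1−t_M))` are nonnegative and sum to one for every
setting, so the output is a convex combination of the inputs — bounded,
monotone in each factor, and affine in each factor separately.  A naive
additive blend `t_P·PET + t_M·MR + (1−t_P−t_M)·CT` loses convexity for
t_P + t_M > 1; the sequential form is used for exactly that reason.

Because the three modalities have incommensurate units, fusion requires
window normalization to [0, 1] first.  Defaults: CT bone window
(level 600, width 2800 HU; brain 40/80 available), MR and PET a robust
1st–99th percentile window of nonzero voxels.  The MR/PET windows are a
package choice — some normalization is mandatory and percentile windows are
the standard robust default; both are config-overridable.

## Delineation-variation metrics

**COV.**  Coefficient of variation of the per-observer volumes,
`COV = SD/mean` with the *sample* SD (n−1 denominator).  The convention is
pinned by a discriminating check in the test suite: the n-denominator
variant fails to reproduce the reference per-patient values (0.06 vs 0.07
for the first patient), the n−1 variant reproduces all of them.

**ADSC.**  For each observer mask a watertight triangle mesh is extracted by
marching cubes at the 0.5 iso-level of the binary field (no pre-smoothing;
one-voxel zero padding so boundary-touching masks still close).  ADSC is the
unweighted mean over triangles of the distance from the triangle barycenter
to the mask's voxel centroid.  "Its centroid" is read as the *structure's*
centroid — the only reading under which the quantity is a size/shape
descriptor.  Area weighting and vertex-based distances are exposed as
options; the default is the unweighted barycenter form.  For a sphere, ADSC
converges to the radius (within 1% at 1 mm resolution for r = 10 mm).

**Median surface.**  The 50% coverage volume keeps every voxel contained in
at least half of the observer masks (ties included, so 2-of-4 counts); its
marching-cubes surface is the median surface.  At threshold → 0⁺ the
coverage volume is the union, at 1.0 the intersection, and it is monotone in
between.

**SD_local.**  At each median-surface vertex, the signed perpendicular
distance to each observer surface is found as the smallest-|s| intersection
of the bidirectional ray `v + s·n` (n the outward vertex normal) with the
observer mesh, capped at 50 mm.  Signs are positive where the observer
surface lies outward of the median surface; signed distances are the
default (matching the coverage-probability methodology this follows), with
an unsigned option.  If a ray misses within the cap — possible on highly
irregular shapes — the code falls back to the nearest point on the observer
mesh, signed by the local orientation of the nearest triangle, and counts
the fallback (logged and reported; ~1% of vertices on typical phantoms).
SD_local is the n−1 SD of the per-observer distances at each vertex, stored
on the mesh as the `sd_local` vertex attribute (cm) for PLY export and
color-wash rendering.

For regional reporting the median surface is partitioned into the eight
octants of world axes translated to the mean of the observer-mask
centroids; the label convention `1 + [x<O_x] + 2[y<O_y] + 4[z<O_z]` (boundary
coordinates on the "≥" side) is declared, deterministic, and reported as
octants 1–8.  Octant numbering is not comparable across software — only the
per-octant values and the overall vertex mean are meaningful.  The overall
mean is over all vertices regardless of octant occupancy; empty octants are
reported as missing.

**Paired tests.**  Differences between delineation schemes are assessed by
the classic paired two-tailed t test on per-patient (or per-observer) metric
values: df = n−1, 95% CI = mean(d) ± t₀.₉₇₅,ₙ₋₁·SE(d), via `scipy.stats`.
Zero-variance differences are flagged degenerate (no p-value) instead of
being reported as significant.

## Ray casting and distances

The environment's mesh library needs an external spatial index for ray and
proximity queries, so the package carries a vectorized bidirectional
Möller–Trumbore intersector (all rays × all triangles, chunked; ~3k vertices
× ~6k triangles in well under a second).  Exact point-to-surface distances
in the observer simulator use nearest-centroid candidates from a KD-tree
(k = 24) refined by exact point-triangle distance; marching-cubes triangles
are at most about one voxel across, so the candidate set safely contains
the true nearest triangle.

## Synthetic phantom

`generate_phantom` builds a head-like study on a 128³ grid at 2 mm
(default; tests use 64³): a head ellipsoid (radii 80/95/85 mm) of brain
tissue (40 HU) wrapped in a 6 mm skull shell (1000 HU) in air (−1000 HU);
an ellipsoidal lesion (default radii 20/17/14 mm) at 60 HU; an MR-like
volume (brain 400 a.u., dark bone, lesion 450 a.u.) whose lesion rim
(outer 3 mm) is brightened by an enhancement factor 1.8, emulating
contrast enhancement; and a PET-like volume with background uptake 1.0 in
the head and a lesion at uptake ratio 4.  Additive Gaussian noise per
modality (defaults 15 HU CT, 15 a.u. MR, 0.05 PET) approximates acquisition
noise.  Contrast and noise levels were chosen once as representative of
contrast-enhanced brain imaging; everything is a dataclass field.  The
truth mask is the exact voxel-center digitization of the lesion ellipsoid.

Not emulated: PET point-spread/partial-volume blur, MR bias fields, CT beam
hardening, anatomy beyond one lesion.  Consequently, passing tests
demonstrate correctness of the *computational pipeline* (geometry,
statistics, determinism), not clinical realism of delineation behaviour.

**Observer simulation.**  Each simulated observer's mask is
`{x : sdist(x) ≤ margin_i + f_i(u(x))}` where `sdist` is the exact signed
distance to the truth's marching-cubes surface (positive outside, computed
in a band around the boundary — voxel-center distance transforms are too
quantized for sub-voxel contour placement), `u(x)` the direction from the
truth centroid, and `f_i` a band-limited random field on the sphere: real
orthonormal spherical harmonics of degree 1..L (default L = 4) with iid
N(0,1) coefficients, normalized analytically (pointwise variance
Σ(2l+1)/4π = (L²+2L)/4π by the addition theorem) to the requested radial SD
(default 2 mm).  This yields smooth, anatomically plausible disagreement
rather than voxel noise.  All randomness derives from one integer seed;
observer i uses sub-seed `seed + i`.

With an injected radial SD of 2 mm and three observers, the pipeline's mean
SD_local over the median surface recovers the injected value to well within
a factor of 1.5 across seeds (typically 2.0–2.4 mm); median-surface SD is a
biased estimator of the radial SD (the median surface itself adapts to the
perturbations), hence the documented tolerance.  Volume COV grows
monotonically with the perturbation SD.

## Numerical choices and degenerate inputs

- Marching cubes at iso 0.5, always padded by one voxel; meshes are
  re-oriented outward (positive enclosed volume).
- Ray-triangle tolerance 1e-9; a vertex lying on the observer surface
  reports distance 0 to coplanarity tolerance.
- Coverage threshold comparison uses `count ≥ threshold·N − 1e-12` so exact
  ties (2 of 4) are kept.
- COV with mean 0, paired tests with zero-variance differences, empty
  masks/meshes, and single-observer spread statistics are all flagged or
  raised explicitly rather than returning silent NaNs.
- Window normalization clips outside the window and is idempotent on
  normalized data under the unit window (level 0.5, width 1).

## Problem sizes

Default test and demonstration sizes: 64³ voxels at 2 mm for phantom-based
checks, 1 mm spacing for geometry oracles (sphere ADSC, concentric-shell
SD_local), 20 seeds for the stochastic recovery check, 10 seeds and
3 perturbation levels for COV monotonicity.  The full test suite runs in
about two minutes on one CPU; `scripts/acceptance.py` in under one.

## Known limitations

- Registration quality is assumed; only resampling under a given rigid
  transform is provided.
- SD_local depends on marching-cubes vertex normals; on very coarse grids
  normal direction noise inflates per-vertex values by a few percent.
- Octant labels are convention-bound (see above) and not comparable to
  other implementations' region numbering.
- The observer simulator perturbs a single closed structure radially; it
  cannot emulate topology changes (split/merged contours) or slice-wise
  human editing artifacts.
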