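# Methods

This note documents the model, the numerical choices, and what the
synthetic phantom does and does not establish.

## Spherical-harmonic representation

All angular quantities (FODs, TODs, atlases) are real, antipodally
symmetric functions on the sphere, represented in a real even-order SH
basis up to `lmax = 8` (45 coefficients). The basis is built from the
complex harmonics with Condon–Shortley phase as

- `m < 0`: `sqrt(2) * (-1)^m * Im Y_l^{|m|}`
- `m = 0`: `Y_l^0`
- `m > 0`: `sqrt(2) * (-1)^m * Re Y_l^m`

with storage order `j = l(l+1)/2 + m`, `l` even ascending, `m` ascending.
This basis is orthonormal; the test suite verifies the quadrature Gram
matrix is the identity to well below 1e-6. Files written by other
toolchains may place the `sqrt(2)` and sign factors differently for
`m != 0`; no silent conversion is attempted — users mixing toolchains must
check conventions themselves.

Key identities used throughout:

- spherical integral: `∫ T dΩ = sqrt(4π) · t_0` (all other basis functions
  integrate to zero);
- inner product: `∫ F·T dΩ = Σ_j f_j t_j` (orthonormality);
- truncation: two vectors of different `lmax` are truncated to the common
  band before the inner product; the discarded cross terms each pair a
  coefficient with an exact zero, so the retained contribution is exact.

## Orientation lobes and apodization

A streamline segment's orientation is encoded by the band-limited
projection of an orientation delta, `c_j = a_l · Y_j(u)`, damped by a
per-degree taper `a_l = exp(-σ² l(l+1))`. The default `σ = 0.17` keeps the
`l = 8` band at weight `exp(-0.17² · 72) ≈ 0.125` — high frequencies are
damped enough to suppress ringing, but the top band is not annihilated.
Because `a_0 = 1`, each lobe has unit spherical integral, so TOD mass
bookkeeping is exact: a voxel's spherical integral equals the streamline
length it contains, and the image total recovers the bundle arc length to
within the resampling discretization (tested at 0.5%).

## TOD mapping and density normalization

Streamlines are resampled to uniform arc-length steps of 0.25 × the
smallest voxel edge; each segment is assigned to the voxel containing its
midpoint. The midpoint rule converges to exact voxel traversal as the step
shrinks and keeps the implementation a single vectorized scatter-add.

Normalization divides each visited voxel by `sqrt(4π) t_0`, forcing unit
integral. "Visited" means `t_0 > 1e-8/(2√π)`: large enough to separate
accumulated float noise from a genuine visit, small enough that any real
segment (length ≫ 1e-8 mm) passes. Voxels with numerically negative mass
(possible in principle from apodization artefacts) are zeroed and counted
in a warning. Normalization makes the result invariant to streamline count
— duplicating every streamline k times changes nothing (tested to 1e-9) —
which is exactly what lets the atlas' first coefficient become a clean
subject-visitation fraction after averaging.

## Atlas averaging

The atlas is the plain arithmetic mean of normalized per-subject TODs on a
shared grid; inputs are validated to be normalized (voxel `t_0` equal to 0
or `1/sqrt(4π)` within 1e-6) and on identical grids — no implicit
resampling. The spatial prior `sqrt(4π) t_0` then equals the visitation
fraction, bounded by 1, with single-subject outliers damped to `1/n`.
Filtering statistics (original/retained streamline counts per hemisphere)
are reported with reduction percentages rounded half-up to two decimals.

## Affine transport and reorientation

Transport is pull-resampling through the world-to-world affine: target
voxel → target world → inverse affine → source world → source voxel, with
trilinear interpolation applied to each coefficient channel independently
(legitimate because coefficients are linear functionals of the underlying
function); nearest-neighbour is available for masks. Directional content
is reoriented by the rotation factor of the polar decomposition of the
affine's linear part — one global rotation, since an affine has a single
linear part and non-linear warps are out of scope. Reflections are folded
through `-I`, which acts as the identity on even-order functions. A flag
disables reorientation for comparison; it is on by default because the
transport contract (a rotated lobe image transports to a lobe image along
the rotated direction) requires it.

SH rotation itself is implemented as a least-squares refit on a Fibonacci
sphere design (≥ 4 × 45 points): rotation preserves the band limit, so the
refit is exact up to conditioning; the evaluation post-condition is met at
~1e-14, far below the 1e-6 contract.

## Tract map and binarization

The map is the voxel-wise coefficient dot product of FOD and registered
atlas. Negative values (band-limit ringing) are clamped to zero in the
default output ("pseudo-probability" semantics); raw values are available.
The binarization threshold uses strict `>` so a zero threshold on an empty
map yields an empty mask; 0.05 is the default for conventionally scaled
FODs and is exposed as a parameter, since FOD amplitude conventions vary
between CSD implementations.

## Segmentation metrics

Bundle distances use `scipy.ndimage.distance_transform_edt` with the
grid's voxel sizes (anisotropic grids supported), voxel-center to
voxel-center, and are cross-checked against an O(n²) all-pairs oracle in
the tests. Bundle distance of identical masks is defined as 0 (limit of
vanishing disagreement). Density correlation is computed over the union of
the two supports: correlating over the whole volume would be dominated by
the shared empty background, and support choice is reported in the metric
report. Default thresholds by map kind: tract map 0.05, streamline density
10, atlas prior 0.1, probability 0.5, reference tractography 0 — all
strict `>`.

The bundled worked-example mask pair (13- and 12-voxel masks overlapping
in 4) is a synthetic reconstruction: its voxel layout was found by search
so that the symmetric-difference distance multisets take the closed-form
sums `14 + 4√2 + 3√5` (unsigned) and `2 − 2√2 − √5` (signed) over 17
voxels, giving DSC 0.32, BD 1.55, BDs −0.18.

## The phantom: what it emulates, and what it does not

The phantom emulates a training cohort and a target subject for one tract:

- a curved tube (radius 3 mm around a 25 mm-radius, 60° circular arc in a
  40³ mm volume at 1 mm isotropic) so fibre orientation varies smoothly
  along the tract;
- 12 training subjects (custom atlases are practical from 10–20 training
  samples), each a 300-streamline bundle: per-streamline normal-plane
  offsets (σ = 2 mm, clipped at the tube radius, so bundles fill the
  tube) around a per-subject centerline perturbed by a small rigid motion
  (rotation σ of 2–4° per axis, sub-voxel shift) — the inter-subject
  geometric/orientational variability that atlas averaging is meant to
  absorb;
- a target subject whose tube is the template tube moved by a small affine
  (3° rotation + ~1 mm translation), recorded as the scene's registration
  transform; its FOD holds unit-peak single-fibre lobes along the local
  tangent, Gaussian coefficient noise (σ = 0.01), and, in the central 20%
  of arc length, an orthogonal second population at a 50/50 amplitude
  split;
- the ground truth is exactly the set of voxels whose centers lie within
  the tube.

All randomness flows from one `SeedSequence`; sub-seeds are spawned per
subject and for FOD noise, so scenes are bit-reproducible.

Under these conditions the full pipeline recovers the tube with DSC ≈ 0.97
(≥ 0.8 across seeds), in-tube map values typically 0.4–0.55 (median below
0.5), crossing voxels at ≈ 0.57 × the single-fibre level but ≥ 0.14 —
comfortably above the 0.05 threshold — and a deliberately 90°-mis-oriented
atlas collapses the in-tube mean to < 1% of the aligned case, showing the
orientation term does real work beyond spatial overlap.

What passing these tests does **not** show: robustness to real FOD
estimation noise and partial-volume effects (the phantom's lobes are clean
apodized deltas), to registration error (the scene transform is exact by
construction), to anatomically realistic fanning/branching geometry, or to
contamination of training bundles by orientational false positives (the
phantom's bundles are clean by construction; only the filtering *report*
arithmetic is implemented, not the filtering). Absolute map values — and
hence the 0.05 threshold — depend on the FOD amplitude convention of the
CSD implementation; the phantom uses unit-peak lobes, for which the
threshold is conservative.

## Problem sizes

Unit tests run on small grids (≤ 40³, 2–3 subjects, tens of streamlines);
the end-to-end acceptance checks use the full default scene (12 subjects ×
300 streamlines, 40³ grid) across five seeds, chosen so the whole suite
and the reproduction script each complete in minutes on a single CPU.

## Known limitations

- Non-linear warps, per-voxel Jacobian reorientation, and tumour
  deformation are out of scope; transport is affine with one global
  rotation.
- No FLIRT-matrix dialect conversion: transforms must be world-to-world
  RAS mm.
- The SH basis convention interoperates with other software only up to the
  sign/√2 placement documented above.
- Odd-order and complex SH (asymmetric ODFs) are unsupported.
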