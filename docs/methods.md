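# Methods

## Scope and model

`bonegrad` measures the spatial organisation of the cortical void network
— vascular-canal lumens and, at depth, the medullary cavity — in long-bone
shaft cortex, and relates it to apparent compressive stiffness. The
quantities are:

* **porosity** p = V_void / V_total inside a sampling window, with V_total
  counted over the bone *envelope* (everything inside the periosteal
  boundary);
* **canal diameter** via local thickness Th(x): the diameter of the
  largest sphere contained in the void phase that covers x (Hildebrand–
  Rüegsegger maximal inscribed sphere), summarised volume-weighted;
* **cortical thickness**: ray chord from the periosteal surface to the
  medullary cavity;
* **modulus 1 / modulus 2**: slopes of the first and second linear regions
  of the compressive stress–strain curve of a transverse slice, delimited
  by a continuous two-segment least-squares fit;
* **Pearson r** between position-matched structural and mechanical values,
  with p from the exact t transform (n − 2 degrees of freedom,
  two-tailed).

## Sampling scheme

Transverse slabs are taken every 1 mm from the distal end (z = 0); the
value at a position aggregates one full slab of voxels (single-plane mode
available). On the slab's central slice, rays run from the envelope
centroid along ±y and ±x; the labels anterior/posterior/lateral/medial are
a declared image-axis convention, not an anatomical registration. A window
of 500 µm (tangential) × 250 µm (radial) is anchored with its *inner* edge
at depth d ∈ {250, 500, 750, …} µm from the outer surface, so d = 250
covers the periosteal 0–250 µm band; the window footprint is the set of
voxels within half the tangential width of the continuous centroid, a
construction that is exactly symmetric under 90° rotations of the volume
(verified by a property test). Windows with no envelope voxels are
reported NA, never dropped silently. Direction-averaged values are the
arithmetic mean of available directions.

Surface detection ray-casts against the envelope rather than the raw bone
mask, so open surface pores do not produce early hits. The envelope is
built per slice by morphological closing (default disk radius 300 µm,
implemented with two Euclidean distance transforms) followed by hole
filling; the medullary cavity is the largest interior background component
of a slice. Porosity counts cavity void by default (deep windows then
approach p = 1, as deep cortex grades into the marrow space); diameter
statistics always exclude the cavity. A strict intracortical porosity mode
is available.

## Local thickness

Sphere radii come from the Euclidean distance transform of the void mask
(distance to the nearest background voxel centre); a sphere of squared
radius q centred at c covers voxels at squared offset strictly less than
q, so an isolated void voxel reports a thickness of two voxels. Painting
processes centres in descending radius order with a numba kernel; squared
distances are exact integers on the isotropic grid, so the result equals
an exhaustive every-centre oracle voxel for voxel (tested). Large volumes
run the distance transform in z-chunks with a 64-slice halo; the chunking
is verified exact at run time (no void farther than the halo from
background) and falls back to a full-volume transform otherwise.

The voxel-centred estimator carries a known negative bias on thin
cylinders: rim voxels not reached by the central sphere report roughly one
voxel less than the true diameter, giving about −0.7 voxel on the
volume-weighted mean (≈ −8 % for a 40 µm canal at 5.8 µm voxels, ≈ −4 %
at 80 µm). Recovery tests therefore bound the error at ±10 % for canals of
at least four voxels diameter; sub-25 µm canals at this voxel size should
not be interpreted quantitatively.

## Two-segment modulus fit

Strain is δ/t and stress F/A (engineering values; A is the supplied load
area — apparent footprint by default, since the choice between apparent
and net area is a user decision). The record is origin-shifted, restricted
to samples at or before the stress peak, and fit with
σ̂(ε) = a + m₁·min(ε, b) + m₂·max(ε − b, 0) for every candidate breakpoint
b on the interior grid of sample strains (the outer 10 % of pre-peak
points are excluded so both segments have support). The breakpoint with
minimal squared error wins; ties go to the smaller b, making the procedure
deterministic. Nested-model structure guarantees the two-segment error
never exceeds the single-line error; multiplying stress by c scales both
moduli and the strength by exactly c. Maximum strength is the sample
maximum of stress over the full record. No toe-region trimming is applied
by default (no preload is assumed); an optional minimum-strain cut exists.

## Synthetic phantoms

The generator emulates a shaft segment: a hollow cylinder (default outer
radius 1100 µm; wall 760 µm at the ends gaining 190 µm toward mid-shaft,
so the cavity narrows centrally and the thickness profile peaks at
mid-shaft) carrying straight, z-parallel canals. Defaults follow the
gradients reported for rabbit femoral cortex: target void fraction
0.05 at mid-shaft rising to 0.40 at the ends (at the 750 µm reference
depth, scaled down toward the surface), mean canal diameter 40 µm rising
to 110 µm, log-normal radii with CV 0.25, truncated below four voxels.
Intensities are bone 200 / void 20 (straddling the 80/255 segmentation
window with margin), optional Gaussian noise (0 for tests, 10 for demos).

Placement is rejection sampling of non-overlapping disks, confined per
1 mm longitudinal band to 250 µm depth cells until each cell reaches its
target void area. Canals persist across band boundaries as tracks (radius
rescaled to the local cell mean) and are born or die only where the target
changes, which both mimics the continuity of Haversian canals and avoids
spurious end-cap effects in the thickness map. A two-voxel bone gap is
enforced between canal surfaces so voxelization cannot pinch off bone
slivers smaller than the despeckle cutoff; with that, thresholding plus
despeckle reproduces the noise-free truth mask exactly. A voxel is void
iff its centre lies inside a canal, so per-canal voxel counts are exact
and total void volume is their sum — the basis of every recovery test.
Unreachable targets (packing limit) and canals below two voxels raise
explicit errors naming the band.

What the phantom does **not** model: oblique or branching canals,
trabecular rod–plate architecture at the metaphyses, lacuno-canalicular
porosity (below micro-CT resolution), scanner physics (noise is plain
Gaussian; no beam hardening or ring artifacts). Passing recovery tests
therefore demonstrates correctness of the measurement chain on geometry
of this class, not robustness to acquisition artifacts.

Synthetic compression curves are piecewise linear (modulus 1 to the
breakpoint strain, default 0.02; modulus 2 to the start of failure) with
an optional terminal stress drop over the final 5 % of the strain range
and additive Gaussian noise. The demo study derives each position's true
moduli from the phantom's deepest sampled true porosity through a linear
stiffness–porosity link (15 → 5 MPa and 1.4 → 0.7 MPa over void fractions
0.05 → 0.40, clipped positive), then re-fits them from the noisy curves.

## Problem sizes and determinism

The reference study runs a 5 mm × ⌀2.2 mm phantom at 5.8 µm voxels
(~1.3 × 10⁸ voxels, about two minutes on one CPU); the demo pipeline uses
a 4 mm × ⌀1.6 mm phantom with grayscale noise. Oracle-equivalence tests
run on random masks up to 32³ where exhaustive sphere fitting is
feasible. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; repeated runs are bit-identical, including
every CSV and JSON artifact of the pipeline (tested byte-for-byte).

## Numerical choices and edge cases

* Threshold bounds inclusive on both ends; "smaller than 25 pixels" is a
  strict inequality; despeckle uses 8-connectivity (4 available) and acts
  on bright speckles only by default.
* Histogram bins are right-open except the last (closed); values beyond
  the last edge count in the last bin so percentages always sum to 100.
* Empty inputs degrade to flagged NA (empty slices, windows without
  envelope voxels, empty thickness maps), not exceptions; genuinely
  invalid inputs (non-monotone displacement, zero-variance stress,
  out-of-tolerance slice thickness) raise with specifics.
* Position pairing: nearest neighbour within 0.5 mm; equal-distance ties
  to the smaller position; unmatched rows reported.
* No multiple-testing correction by default (a Holm option exists); a
  Spearman column is available as an extension for the visibly non-linear
  modulus–porosity relation.

## Known limitations

* The thickness estimator's sub-voxel bias (above) is inherent to the
  voxel-centred sphere convention; finer voxels are the only cure.
* Cortical thickness is a ray chord through the slice centroid, one of
  several defensible definitions (minimum-distance thickness would differ
  on oblique walls).
* Anatomical direction labels are conventional; results for real bones
  should be registered externally before directional interpretation.
* The stiffness–porosity link in the synthetic study is a deliberate
  one-factor simplification used to validate sign and ordering of the
  correlations, not a constitutive model.
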