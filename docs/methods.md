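# Methods

This note records the model behind each pipeline stage, the tunable
parameters and their defaults, the decisions taken where the design was
genuinely open, what the digital phantom does and does not emulate, and
the known limitations.

## Conventions

Volumes are arrays indexed `(slice, row, col)`; slice 0 is the most
superior slice, row 0 the anterior border, column 0 the image left (the
patient's right under radiological display).  Spacing is
`(slice_thickness, pixel_height, pixel_width)` in mm, and every mm- or
mm²-valued threshold is evaluated through the spacing — never assuming
isotropic 1 mm voxels.  The DICOM reader sorts slices by
ImagePositionPatient (descending z) to guarantee the superior-first
order; the NIfTI reader reorients through RAS+.

The "3×3 disk" structuring element used by all per-slice morphology is
the full 3×3 square: a disk of diameter 3 rasterizes to it (corner
distance √2 < 1.5).  The alternative reading (the 3×3 diamond) leaves
diagonal wall voxels of an airway uncovered by the wall-inclusion
dilation and was rejected for that reason.

## Body

Threshold window [−175, 750] HU, closed at both ends; 2D hole filling
(8-connected foreground, 4-connected background flood) so the lungs and
airways are part of the body; components with area strictly greater than
800 mm² are accepted, evaluated as pixel count × pixel area.  The order
is threshold → fill → area filter.

## Airway

*Seeding.* Within the body of the `n_top_slices = 5` most superior
slices, air is HU < −900.  3D components of at least 20 mm²-equivalent
footprint are scored by the distance of their in-plane centroid to the
body centroid, ties broken by larger volume — the trachea is central, so
distance is primary.  The seed is the rounded mean voxel location,
snapped to the nearest component voxel when the mean falls outside
(non-convex components).

*Adaptive region growing.* The 26-connected component of
{HU < threshold} containing the seed, threshold starting at −900 HU,
integer increments starting at 64 HU.  A candidate step whose volume
reaches twice the last accepted volume is leakage: the step is revoked
and the increment halves (integer division, floor 1).  Growth terminates
when leakage is detected at increment 1, returning the last accepted
mask; the compared volume is the cumulative region volume, not the
per-step gain.  A `max_threshold = 0` HU safety cap guards degenerate
inputs in which no leakage can ever occur (e.g. an all-air volume);
anatomical inputs always terminate on the doubling rule first, since
airway walls are far denser than the lumen.

*Wall inclusion.* One per-slice dilation of the lumen with the 3×3 disk.
This is intentionally a 2D operation: it recovers the in-plane wall ring
but not inter-slice wall voxels of oblique bronchi or the caps closing a
bronchus end — the main reason airway VOR on the phantom sits near 92 %
while the lungs exceed 99.9 %.

## Lungs

Rough fields are {HU < −300} inside the body.  After airway removal the
per-slice order is hole filling, then two closings with the 3×3 disk.
Correction removes 2D regions under 200 mm² and keeps the 26-connected
3D components meeting lung regions of the central slice, which removes
caudal bowel gas.

*Separation.* A slice separates when its widest lung component exceeds
half the body width.  The junction ROI is the middle third of the
component's columns and the upper half of its rows (integer floor
division).  The walk's start component is found inside the ROI among
non-lung pixels that have lung above them in their own column; without
that restriction the anterior chest wall — often 8-connected to the
mediastinum around a narrow fusion — is selected and the walk dies at
the ROI top.  The anterior line starts at the component pixel of
minimum row nearest the ROI centre column and repeatedly moves to the
upper neighbour (of three) with maximum HU, relabelling lung pixels as
non-lung until a non-lung pixel is reached; ties prefer the centre, then
the left column; steps are capped at the slice height.  The posterior
line mirrors it downward.  Left/right labels are assigned per slice to
4-connected components by centroid column against the body centroid
(patient right = image left): the cut is one pixel wide and drifts
between slices, so 3D connectivity across it is deliberately not used.

*Pathological-area inclusion.*  Interpolation labels, for every pixel
column, all slices between its first and last lung occurrence.
Propagation, per lung: candidates are non-lung pixels within the
in-slice 7×7 window of a border pixel; a candidate is admitted iff
strictly more than half (> 171 of 343) of its 7×7×7 neighbourhood is
lung; all admissions are synchronous per iteration and iteration runs to
the fixed point.  The candidate itself counts in the denominator but is
non-lung, and the neighbourhood is a voxel-count window, anisotropic in
mm on thick-slice data — both deliberate.  The final mask is
`lungs ∪ (interpolated ∩ propagated)`, so the stage only adds voxels; a
voxel claimed by both lungs (not observed in practice) would be assigned
to neither to keep them disjoint.  Geometrically, the propagation rule
fills concave pockets — tumour notches, nodule indentations — and halts
on flat or convex lung surfaces; surfaces smoother and larger than the
window (an idealized full sphere of curvature radius ≫ 7 voxels) are the
rule's blind spot, which is why the phantom's tumours are lumpy rather
than perfect spheres.

## Spine

Bone: {HU > 145} in the body, area > 25 mm², all pixels at least 10 px
from the body border (image edges count as border).  The vertebra ROI
spans CP.col ± 10 columns and CP.row − 50 to BB.bottom − 10 rows of the
body bounding box (offsets in pixels, as defined); every bone component
overlapping the ROI is vertebra.  Missing-part recovery adds pixels
8-adjacent to the vertebra with non-zero Sobel gradient **and HU ≥ 100**:
without the HU floor the rule swallows the one-pixel inner rim of the
canal on every slice (canal pixels adjacent to bone always sit on a
strong gradient), which alone would cost ~30 % of a 10 mm canal.  The
floor restricts recovery to partial-volume bone edges; it is
configurable (`vertebra_recovery_min_hu`).

Enclosure: inside the vertebra bounding box, non-bone components are
labelled with 4-connectivity (a diagonal gap counts as open); a
component touching no bounding-box border makes the slice enclosed, the
largest such component being the canal.  Enclosed slices take that
region directly and the fuzzy step is never invoked for them.  Remaining
slices are processed outward from the enclosed ones (a forward then a
backward sweep), each seeded with the rounded canal centroid of the
adjacent processed slice.  Fuzzy parameters: prior μ = 23 HU,
σ = 15 HU, k = 2.5 (selection window [−14.5, 60.5] HU), 11×11 seed
window, binarization threshold 0.5, 8-connected grayscale
reconstruction; a degenerate σ estimate (< 2 seed pixels or zero
spread) falls back to the prior σ.  Canal pixels are never bone.

## Evaluation metrics

VOR = 100·|A∩M|/|A∪M| on voxel counts (the voxel-volume factor cancels);
undefined and raised when both masks are empty.  Surface voxels have at
least one of their 18 neighbours (faces + edges) outside the structure,
with out-of-volume counting as outside.  Distances are Euclidean between
voxel centres with anisotropic spacing, computed by a distance transform
of each surface set; ASD and RMSD pool both directed distance sets, MSD
is the larger directed maximum.  The implementation is contract-tested
for equality with an O(N²) pairwise oracle.

## Digital phantom

The phantom rasterizes analytic solids on a 60×128×128 grid at
(2.5, 2.0, 2.0) mm spacing — a full-size ~230 mm thorax sampled 4×
coarser than a 512×512 scan, so clinically sized structures (820 cc
lungs, 18 mm trachea, 16.4–93.2 cc tumours) fit the grid.  Tissue means:
air −1000, soft tissue 30, lung −850, airway lumen −1000, airway wall
−100 (soft-tissue-like, above the −300 HU lung threshold as in real
scans), bone 300, canal 23, bowel gas −950 HU.  Noise is Gaussian per
tissue (soft 20, lung 30, bone 30, canal 5 HU SD), mildly spatially
correlated (Gaussian kernel, 0.8 px) because CT noise is not white; all
randomness derives from one seed.  Lungs are blunt-ended superellipsoids
(z-exponent 4; volume (8/5)·π·a·b·c): pointed ellipsoid ends would give
apex/base cross-sections under the method's own 200 mm² filter, which
real lungs do not have.  Bronchi run along the medial lung borders
(hilum), tapering, partly embedded and open to the mediastinum —
fully embedding a bronchus in lung would let hole filling relabel it as
lung, as it would in a real scan.  Tumours are spheres with a smooth
seeded radial perturbation (10 % relative amplitude), clipped to the
lung envelope; presets place a 16.4 cc and a 93.2 cc (nominal) tumour
against the lateral pleura and an 8 mm juxtapleural nodule.

What the phantom does **not** emulate: partial-volume averaging,
reconstruction-kernel texture, beam hardening, vessels, lobar fissures,
the couch, and anatomical variability.  Passing tests therefore
demonstrate algorithmic correctness under controlled geometry and
CT-like densities, not clinical accuracy; the degrees of freedom that
drive clinical failure (pathology morphology, contact with the
mediastinum, motion artefacts) are only coarsely represented.

## Numerical choices

Thresholds on HU windows are closed intervals; "greater than" filters
are strict.  Region-growing thresholds are integers.  Eq-style ROI
divisions floor to integers; centre points round to the nearest pixel.
Junction-walk ties prefer the centre column, then the left.  Membership
binarization keeps m ≥ 0.5.  The propagation neighbourhood count uses an
exact box filter with rounding to the nearest integer before the strict
comparison.  Problem sizes in the test suite and the acceptance script
(60×128×128 phantoms, ≤ 12³ oracle masks, 100 random metric pairs) were
chosen so each stage is exercised end-to-end at full fidelity.

## Known limitations

- The airway wall inclusion is per-slice; steep or oblique airway
  segments keep some 3D wall voxels out of the final airway label.
- Separation assumes the fused component is wider than half the body; a
  small anterior bridge on a slice whose lungs are otherwise narrow
  would not trigger it.
- The pathology stage cannot recover a lesion with no lung above or
  below it anywhere (interpolation never brackets it) or an ideal smooth
  sphere much larger than the propagation window.
- The fuzzy canal stage binarizes an unnormalized Gaussian at 0.5, which
  intrinsically keeps only |HU − μ_SP| ≤ σ_SP·√(2 ln 2); on very noisy
  canals the per-slice recovery is bounded by that selection.
- Vertebra recovery depends on an HU floor that assumes bone-like
  density for missing parts; severely osteoporotic vertebrae may fall
  below it.
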