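# Methods

## Coordinate and geometry conventions

All arrays are indexed `(z, y, x)`: axis 0 is the axial slice index
(superior–inferior), axis 1 anterior–posterior with the anterior side at low
index, axis 2 left–right. Voxel indices are 0-based; physical coordinates are
millimetres, with voxel centre `p` at `p · spacing + origin`. Readers
reorient NRRD/NIfTI files whose direction matrix is an axis permutation with
flips; genuinely oblique direction matrices are rejected rather than
resampled, because resampling would silently change every distance measured
downstream. An NRRD header without a spacing field is an error, never a
silent 1 mm default. Clinical exports that use a different anatomical
orientation must be permuted to this convention on load (the reader handles
any axis-aligned orientation); nothing else in the package depends on
patient handedness.

## Synthetic phantom: what it emulates and what it does not

`perfmap.phantom` emulates the anterior abdominal wall in a
contrast-enhanced CT: layered tissue along Y (air, 2 mm skin, subcutaneous
fat, 2 mm anterior rectus fascia at 26–28 mm depth, 20 mm rectus muscle
slab split by a 12 mm midline gap, posterior soft tissue), a Gaussian
umbilical skin indentation (4 mm deep, σ = 6 mm) at the midline, and
`n_vessels` perforator tubes of radius 1.5 mm at 400 HU against soft tissue
near 50 HU, with additive Gaussian noise (σ = 20 HU by default; the
contrast margin always exceeds 3 σ by construction). Default grid:
80 × 96 × 120 voxels at (1.0, 0.8, 0.8) mm — typical abdominal CTA
resolution. Layer depths are fixed in millimetres, so a geometry too small
for the stack is rejected.

Each vessel is a smooth parametric curve: it starts posterior to the muscle
(where the deep inferior epigastric artery runs), traverses the slab,
pierces the fascia and ends in the fat. Five archetypes cycle across lanes
on the two muscles — straight with a superior drift, sinusoidal, laterally
oblique, one full helix turn of radius 2.5 mm across the slab (arc length
`√((2πr)² + p²)` with pitch p = 20 mm, the closed-form oracle), and a steep
superior course whose intramuscular length always exceeds the 40 mm
threshold. Per-seed jitter on lane positions, axis offsets and slopes gives
each case its own anatomy while the helix keeps its analytic shape; one
seeded generator drives everything, so a case is bit-reproducible from its
seed.

Ground truth is analytic, not voxel-derived: intramuscular lengths come from
dense arc-length integration (0.01 mm steps; halving the step changes the
result by far less than 0.1 %) of the curve clipped to the analytic muscle
region, and the emergence point is the curve sample at the most anterior
fascia voxel-centre plane. Tubes are rasterised by the distance-to-curve ≤
radius rule on voxel centres.

Not emulated: partial-volume blur, beam hardening, contrast-timing
variation, vessel caliber change, branching vascular trees, and anatomical
pathology. Passing tests on phantoms therefore demonstrates the geometric
and statistical machinery, not clinical-grade segmentation of real CTA;
in particular the prompting assumptions (lumen is the local intensity
maximum; background just outside the vessel is darker) hold by construction
here and only approximately in patients.

## Anatomical priors

* **Vessel enhancement**: clip to an HU window (default 150–450) and rescale
  to [0, 1]; optional per-slice white top-hat for thin bright structures.
* **Skin**: first supra-threshold voxel along Y per (z, x) column (air
  threshold −500 HU).
* **Umbilicus**: depth map D(z, x) of the skin sheet; indentation =
  smooth(D, σ=1.5) − smooth(D, σ=8) within a midline band (±15 % of the
  x-extent). The light pre-smoothing removes the integer plateau of D so the
  peak sits at the dent centre; the final landmark is the indent-weighted
  centroid of the peak's half-height blob. Detection below a 2-voxel depth
  raises a landmark error, and a landmark file can always override — the
  horizontal coordinate of automatic umbilicus detection is the least robust
  quantity on real anatomy.
* **Fascia**: the anterior boundary layer of the muscle union, per column —
  `thickness_voxels` (default 2) voxels immediately anterior to the first
  muscle voxel, muscle excluded. Muscle masks are always inputs.
* **Candidates**: threshold the enhanced volume (default 0.5), restrict to
  the column-wise region between the skin and the posterior muscle surface
  plus a 12 mm posterior margin (perforators originate just behind the
  rectus), and remove 26-connected components below 30 voxels. Thresholding
  is monotone by construction: raising the threshold never adds voxels.

## Centerlines

Candidate components are thinned with 3D topology-preserving thinning
(subset of the input, component count preserved). Each skeleton component is
ordered as the graph-diameter path: 26-connectivity adjacency with physical
(mm) edge weights, geodesics between all degree-1 endpoints, the farthest
pair wins (ties go to the lexicographically smallest endpoint), side
branches are discarded. That deliberately reproduces the known failure mode
of diameter-path ordering at bifurcations — the straight-line endpoint
distance is reported alongside the path length precisely as the control for
it.

Thinning retracts the free end of a tube when a run is flat or of even voxel
width (observed retraction of an entire 20-voxel vessel ending), so
`extract_centerlines` re-extends each ordered path through its mask
component: mask voxels geodesically closest to a terminal path node form the
end's catchment region, and the geodesic to the region's farthest voxel is
appended. Paths start at their most posterior endpoint and are returned
sorted by descending length; components shorter than `min_length_mm`
(default 10 mm) are dropped.

`path_length_mm` is the literal sum of consecutive physical-point distances;
no resampling or smoothing is applied to it.

## Prompting and backends

For every axial slice a centerline traverses, its voxels in that slice
become positive prompts, each refined to the brightest voxel within a
5-voxel-radius ball. The refinement op itself defaults to a 3D ball (ties:
nearest to the seed, then lexicographic); *prompt building* refines within
the slice instead, because a 3D search can snap an oblique vessel's prompt
to a voxel that is bright one slice away but background in its own slice,
which starves the backend of valid positives. Negative prompts are sampled
deterministically on an in-plane ring (radii 4–8 voxels, 4 points,
angularly equispaced from +X, skipping angles without a qualifying voxel)
among voxels at most 0.6 × the positive's intensity — near, but outside,
the vessel. Duplicate positives are merged and colliding negatives dropped.

Backends implement `segment_slice(image_slice, prompt) -> binary mask`
(single-mask mode); slices are processed independently, so the stacked
result is invariant to processing order, and wall-clock time per centerline
is recorded for the ITpC metric. Shipped backends: `OracleBackend` (the
reference components containing a positive — pipeline validation) and
`ThresholdRegionGrowBackend` (8-connected growth above 0.6 × the positive's
intensity, components containing a negative discarded; intended for the
enhanced volume). GPU foundation models are out of scope by design; their
adapters would sit behind the same interface.

## Losses

Dice loss `1 − (2Σpg + ε)/(Σp + Σg + ε)` and binary cross-entropy with
probabilities clamped to [ε, 1−ε], ε = 1e−6 (clamping rather than adding ε
inside the log keeps interior probabilities exact: a uniform 0.5 prediction
costs exactly log 2 per voxel). Skeleton Recall Loss is the soft recall of
the prediction on the ground-truth skeleton dilated by 2 voxels and clipped
to the ground truth — without the clip a perfect prediction of a thin
structure would be penalised for the dilation halo. Empty ground truth
gives SRL 0 by convention. The compound loss is the weighted sum, linear in
the weights; the shipped optimised profile (Dice 0.5, skeleton recall 0.33,
CE 0.17, patch 96×192×192, batch 4, ≤150 epochs, patience 20) is metadata
for downstream training systems — no training loop lives here.

## Evaluation metrics and statistics

Overlap: DSC and IoU with the both-empty convention of 1. Boundary metrics
use surface voxels (foreground with a face-adjacent background neighbour;
the grid border counts as background); directed nearest-surface distances
are pooled over both directions; ASD is the pooled mean, HD the pooled
maximum (hence symmetric), HD95 the pooled 95th percentile with linear
interpolation (hence ≤ HD). Several ASD/HD conventions coexist in the
literature; this one is pinned and isolated in one function so alternates
can be swapped. An empty mask leaves the boundary metrics undefined and the
case flagged rather than aggregated. Error statistics are MAE, MdAE, RMSE
and the IQR of absolute errors, linear-interpolation percentiles.

Model comparison: one-way MANOVA on the metric vector (Wilks' λ with its F
approximation), per-metric one-way ANOVA, and Tukey HSD per metric at
family-wise α = 0.05 (unadjusted across metrics). When the between-group
SSCP is exactly zero the eigenproblem is empty and λ = 1, F = 0, p = 1 is
returned directly; zero-variance Tukey comparisons report p = 1. Note that
IoU is a deterministic transform of DSC for binary masks, so including both
in one MANOVA makes the error matrix singular — the acceptance script
compares backends on (DSC, ASD, HD, HD95).

## Clinical quantification

Intramuscular path length keeps the centerline points whose voxel lies in
the muscle mask, in order; excursions out of the mask are bridged by default
(surviving points treated as consecutive), with a strict split-at-gaps mode
behind a flag. Two discretisation corrections are applied by default, both
validated against the phantom's analytic truths (max per-vessel error
1.8 mm over 12 seeds, versus 4.1 mm for the literal voxel-step sum):

* chords are summed over every 3rd point — a digitised 26-connected path
  zig-zags around the true curve and step-by-step summation inflates length
  by up to ~20 % depending on obliquity, while 3-step chords suppress the
  staircase with negligible shortening of genuine curvature at vessel scale;
* the segment is extended half a step past the first/last in-muscle point,
  because the mask boundary lies midway between voxel centres and membership
  alone clips about half a voxel of true course at each muscle face.

Setting `chord_stride_points=1, boundary_extension=False` recovers the
literal definition.

The fascial emergence point is the most superficial (smallest Y) centerline
point inside the fascia; if the centerline never intersects it, the point
with the smallest column-wise |ΔY| to a fascia voxel qualifies when that
offset is at most 20 voxels — a closed bound: exactly 20 qualifies, 21 does
not. Umbilicus distances are pure axis differences, `|Δz|·s_z` vertically
and `|Δx|·s_x` horizontally, in mm — not the in-plane Euclidean distance.
Reports flag `length_ok` (< 40 mm intramuscular) and `central_ok`
(emergence within a configurable radius of the umbilicus, default 80 mm).
Vessel caliber is not measured; an externally supplied diameter can
accompany a report.

## Problem sizes and reproducibility

Defaults throughout target a desk-scale workload: the default phantom is
~0.9 M voxels and a full pipeline run takes a few seconds on one CPU; the
test suite runs in ~10 s and the acceptance script (8 phantoms × 2
backends) in ~10 s. Every run directory is self-describing (config echo +
seed), and reruns at a fixed seed are byte-identical. All tie-breaks
(refinement, path endpoints, negative-prompt angles) are deterministic and
documented above.

## Known limitations

* Diameter-path ordering discards side branches; true branching perforator
  trees are reported as their longest course. The straight-line control
  flags, but does not repair, branch-jump orderings.
* The umbilicus detector assumes a single dominant midline indentation.
* Phantom realism limits: no partial volume, no caliber variation, no
  branching; see above for what passing tests does and does not show.
* The fascia derivation assumes the anterior muscle surface is the fascia's
  posterior boundary per (z, x) column; strongly folded anatomy would need a
  real fascia segmentation as input.
* The 20-voxel emergence threshold is in voxel units by definition, so its
  physical meaning scales with the slice spacing of the study.
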