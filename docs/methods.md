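# Methods

`octrack` implements a classical analysis pipeline for time-lapse optical
coherence tomography (OCT) of organoid cultures: volume enhancement,
post-filtering of binary segmentation masks into labeled organoid
instances, per-organoid feature extraction, probabilistic multi-timepoint
tracking, parameter tuning, and growth analytics. Because real OCT organoid
datasets are rarely public, the package ships a synthetic phantom generator
that reproduces the statistical features the pipeline depends on, so every
stage can be validated end to end against known ground truth.

## Volume model and geometry

Volumes are 3-D scalar grids in `(z, y, x)` order with physical voxel
spacing `(dz, dy, dx)` in micrometers; the default spacing
`(2.68, 2.52, 2.52)` um matches a spectral-domain OCT system with 2.52 um
transverse step and 2.68 um axial resolution in tissue. The physical
coordinate of a voxel center is `index * spacing`. Acquired intensities are
16-bit unsigned counts; inside the enhancement chain the data are
double-precision reals on [0, 1].

## Enhancement chain

OCT speckle is well modeled as Poisson-distributed intensity noise, whose
variance grows with the mean. The chain is:

1. **Reference-histogram normalization.** A reference histogram is the
   elementwise sum of the luminance histograms of a set of reference
   volumes; its 95th percentile `p95_S` anchors the intensity scale. Each
   volume is scaled by `p95_S / p95(V)` so the 95th percentile of every
   normalized volume lands on the reference. Percentiles of integer
   histograms are computed as the smallest intensity whose cumulative mass
   strictly exceeds the target fraction (boundary ties round up; 100 voxels
   valued 0..99 give a 95th percentile of 95).
2. **Contrast stretch.** Affine map sending the 1st/99th percentiles to
   0/1, clipped to [0, 1]. Percentiles are computed over the whole volume,
   not per slice. A constant volume cannot be stretched; the chain then
   returns an all-zero volume with a warning rather than failing
   mid-pipeline.
3. **Variance stabilization.** Elementwise square root. For Poisson(λ)
   data the transformed noise is approximately Gaussian with variance 1/4
   independent of λ (checked at λ ∈ {10, 50, 100}), which makes the
   subsequent linear and rank filters behave uniformly across bright and
   dim regions.
4. **Unsharp sharpening** in the stabilized domain: `a1·V − a2·U` with
   `U` a Gaussian blur (σ = 3 voxels, kernel truncated at 4σ, normalized,
   reflective borders) and `(a1, a2) = (b/(2b−1), (1−b)/(2b−1))`. The
   coefficients satisfy `a1 − a2 = 1`, so constants are fixed points; the
   default `b = 2/3` gives the classical `2V − U`. Legal `b` is (0.5, 1]:
   outside that range the combination smooths instead of sharpens.
5. **Median denoising**, cubic kernel of edge 7, reflective borders.
6. **Inversion of the stabilization** by squaring, and quantization of
   [0, 1] to 0..255 with round-half-up.

Sharpening and median filtering deliberately run between the square root
and the squaring step — operating on Gaussianized noise is the purpose of
the stabilization.

## Segmentation boundary

The pipeline is agnostic about where binary masks come from; per-slice CNN
predictions are ingested as TIFF stacks. For self-contained testing a
baseline segmenter is included: global Otsu threshold plus morphological
opening with a ball of radius 1 voxel. The Otsu threshold is floored at
`median + 6·(1.4826·MAD)` because Otsu always splits a histogram — on an
object-free volume it would binarize background noise at its mean. The
robust floor uses background statistics that sparse bright foreground
cannot perturb, so it is inert on volumes that actually contain organoids.
The baseline is a test harness, not a claim of CNN-equivalent accuracy.

## Instance post-filtering

Per-slice detections are stitched into 3-D objects by connected-component
labeling, 26-neighbor adjacency by default (diagonal contacts across slices
connect); labels are assigned in scan order of each component's first
voxel. An object's physical volume is voxel count × voxel volume; objects
strictly smaller than the volume of a 25 um diameter sphere,
`(π/6)·25³ ≈ 8181.23 um³` (≤ 480 voxels at the default spacing), are
removed as sub-resolution debris. Equality survives ("smaller than" is
strict). The filter is idempotent and monotone in the diameter threshold.
No sphere fitting is involved — measured volume is compared to the
reference sphere's volume, equivalent to comparing equivalent-sphere
diameters.

## Features

Each labeled organoid yields: centroid (mean voxel-center coordinate, um),
volume (um³), a shape-descriptor vector, and its voxel occupancy set.
The descriptor vector is (sphericity, extent), both dimensionless in
[0, 1]. Sphericity is `π^(1/3)·(6V)^(2/3) / A`; the surface `A` is
estimated by counting exposed voxel faces weighted by their physical areas
and multiplying by 2/3, the standard stereological correction for the
staircase bias of axis-aligned face counting (which overestimates a smooth
isotropic surface by 3/2). The corrected estimator scores a large digital
ball near 1; values above 1 on coarse objects are clipped. IoU between two
organoids is computed on the shared voxel grid with no registration —
inter-day misregistration is absorbed by the matcher's gates and weights
rather than by aligning volumes.

## Dual-branch tracking

A reference day anchors the series. Organoids on the reference day seed
global identities; the ascending branch chains matches forward day by day
(each day's matched records become the next references), the descending
branch symmetrically backward. Unmatched evaluation-day organoids start new
tracks that extend only in that branch's direction; a track ends at its
first failed match (no gap bridging). Assignment is exclusive, so a fusion
event collapses to one surviving identity and terminates the other track.

For a candidate pair, hard gates reject implausible matches before scoring:
centroid distance above `theta_c` (default 30 um, sensible range 20–40),
or — ascending — a volume decrease beyond the fractional tolerance
`vol_tol` (default 10%, range 5–15%; any increase is expected growth), or
— descending — the mirrored rule for increases. Note the volume gate is
direction-aware: a series and its time reversal give mirrored tracking
results only when per-step volume changes stay inside the tolerance band.

Surviving pairs receive the composite similarity

    S = w_c·(1−D_c) + w_v·(1−D_v) + w_p·(1−D_p) + w_IoU·IoU

with `D_c = min(distance/theta_c, 1)`, `D_v = |ΔV| / max(V_ref, V_eval)`,
`D_p` the mean absolute shape-descriptor difference, all in [0, 1], and the
match probability is the logistic `P = 1/(1+exp(−S))`; gated pairs get
`P = 0`. Default weights are `w_c = 0.9`, `w_v = 0.6`, `w_p = 0`
(shape similarity off by default but supported), `w_IoU = 1`; a perfect
pair then scores `S = 2.5`, `P ≈ 0.924`.

Matches are drawn greedily from the probability matrix: select the global
maximum strictly above `p_min` (default 0.5), record the pair, zero its row
and column, repeat. Ties resolve to the smallest (ref, eval) index pair.
Greedy exclusive selection — rather than an optimal assignment — matches
the prioritize-and-exclude procedure the pipeline models; it is injective
both ways by construction and trivially auditable.

### Tuning

`tune_parameters` evaluates a grid of configurations (reference day,
centroid gate, volume tolerance, weights) by running the full tracker and
counting tracks that span the entire series; ties break to higher mean link
probability, then to the smaller centroid gate. `reference_day="auto"`
expands a candidate into one per observed day. The best reference day is a
property of the data (fusion timing, density), not a constant.

## Metrics and growth analytics

Segmentation scores are voxel-pooled per volume from confusion counts:
Dice `2TP/(2TP+FP+FN)`, accuracy, sensitivity `TP/(TP+FN)`, precision
`TP/(TP+FP)`; ratios with zero denominators report 1 when both masks are
empty, else 0. Tracking quality is measured on links (consecutive-day
identity assertions) after mapping detected labels to ground-truth ids by
majority voxel overlap: link precision and recall, full-track recall
(truth trajectories reproduced end-to-end by a single track), and the
fraction of reference-day organoids tracked across the whole series. The
growth curve reports per-day mean and standard error (sample SD/√n) of
tracked organoid volumes in mm³ (1 mm³ = 10⁹ um³); the growth rate is the
least-squares slope of mean volume versus day, matching the usual
mean-volume-trend presentation rather than a mean of per-organoid slopes.

## Synthetic phantom

The generator emulates exactly the features the pipeline depends on:

- Poisson speckle background (`lambda_bg`, default 20) and brighter
  Poisson organoid interiors (`lambda_org`, default 80) — matching the
  Poisson noise model that motivates the square-root stabilization and
  making that property directly testable;
- quasi-spherical organoids with initial diameters drawn uniformly from
  30–45 um — deliberately above the 25 um minimum-size filter, whose role
  is noise removal, so ground-truth objects are never legitimately
  deleted;
- growth by default volume-linear at 1500 um³/day (~10%/day initially; a
  radial-factor mode is also available) over days 1, 3, …, 13;
- rigid inter-timepoint misregistration: `drift_per_day` (default 5 um/day)
  times the day gap, in a seeded random direction per step;
- optional fusion, modeled as label merging into the lower id (no shape
  blending) — enough to exercise the tracker's termination behavior.

An organoid's voxel set on a given day is the `n` grid voxels nearest its
drifted center, with `n = round(V(t)/voxel volume)`, so the ground-truth
voxelized volume follows the analytic schedule to within half a voxel and
growth-rate recovery can be asserted tightly. Placement is by rejection
sampling with clearance covering the whole growth schedule plus drift
(fusion mode relaxes clearance to the initial day so growth can merge
neighbors); impossible configurations raise instead of looping forever.
Everything is deterministic given the seed.

What the phantom does *not* model: OCT point-spread and attenuation
physics, the gel-droplet geometry, non-spherical morphologies, organoid
birth after the first day, and appearance changes other than size. Passing
the end-to-end tests therefore demonstrates the correctness and internal
consistency of the algorithms under the stated noise and motion model, not
segmentation accuracy on real OCT volumes — the baseline segmenter in
particular makes no such claim.

## Problem sizes and numerical choices

The default phantom grid is 96×160×160 voxels; end-to-end test scenarios
use 64×128×128 (10 organoids, 7 timepoints), which the package processes
in well under a minute per stage. Grids are configurable up to the real
acquisition scale (698×1200×800). Internal arithmetic is double precision;
8-bit quantization rounds half up; Gaussian kernels truncate at 4σ; all
filters use reflective (symmetric) boundary handling; degenerate inputs
(constant volumes, empty masks, empty assignment matrices) are handled
explicitly as documented above.

## Known limitations

- No inter-day volumetric registration and no gap bridging across missed
  detections; a lost detection permanently truncates a track.
- Fused organoids are not split (no instance segmentation); the losing
  track simply ends.
- The tuner optimizes a single objective (full-series track count) with
  deterministic tie-breaks; it does not model accuracy/coverage trade-offs
  beyond that.
- The baseline segmenter is a global-threshold stand-in; on real, low
  contrast OCT data a trained segmentation model should supply the masks.
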