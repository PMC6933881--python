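# Methods

## The measurement chain

A micro-CT scan of one kernel is an isotropic 3D grayscale grid (8- or
16-bit, voxel size in μm; real benchtop scans of maize run at ~7 μm). The
pipeline turns it into the 28 structural parameters in four stages:
denoise → segment → measure → analyse. Each stage is pure given its
inputs, its configuration and one integer seed, so a full run is
reproducible byte for byte.

## Segmentation

* **Denoise** — median filter over a Euclidean ball (default radius
  1 voxel). The median preserves edges and never leaves the input
  intensity range. Radius 0 disables it; on noiseless input the filter is
  deliberately skipped because a rank filter rounds sharp corners of a
  piecewise-constant image.
* **Thresholds** — by default multi-class Otsu over four intensity
  classes (background, cavity, endosperm + coat, embryo; embryo is the
  brightest tissue in kernel CT, cavities nearly black). When class grey
  levels are known (phantom work, calibrated scans) fixed midpoint
  thresholds are used instead.
* **Foreground** — the largest 26-connected component above the material
  threshold; more than one large component is an error (one kernel per
  volume). Interior voids are recovered by hole filling with 6-connected
  background — the standard 26/6 duality, which stops corner-diagonal
  "tunnels" from opening a cavity to the outside.
* **Endosperm/embryo split** — region growing from high-confidence cores
  (morphological erosions of each side of the endosperm/embryo
  threshold); frontier voxels join a class when their grey value is
  within a tolerance (default 40 grey levels) of the class's running
  mean; leftovers fall back to the nearer class mean.
* **Seed coat** — segmented geometrically as the outer shell of the grain
  mask (default thickness 0.14 mm), because pericarp and endosperm are
  radiometrically indistinguishable at 8 bits. Parameters therefore pool
  coat with endosperm by default (`coat_separate=True` reverses this).
* **Cleanup** — connected components smaller than `min_object_vox`
  (default 27 voxels) take the majority label of their border; foreground
  never becomes background, so the cleanup only re-classes voxels and is
  idempotent.
* **Cavity localization** — per 26-connected cavity component, in order:
  embryo cavity if its one-voxel dilation overlaps embryo more than any
  other class; subcutaneous if the dilation touches the coat shell or the
  component lies within 2 voxels (plus coat) of the outer surface;
  endosperm cavity otherwise. Components are never split; an open pore
  (cavity touching background) warns and is classified by the same rules.

On a noiseless phantom with midpoint thresholds the whole chain
reproduces the truth labels exactly; this is a regression-tested
invariant, not an accident.

## Morphometry

* **Volumes** are voxel counts × (voxel size)³. Grain volume includes
  interior cavities (the solid hull): that is what an intact-kernel scan
  measures, and density DE = mass/Vg uses this cavity-inclusive volume.
  Cavity class volumes satisfy Vc = Vsc + Vemc + Venc exactly (same-voxel
  accounting).
* **Surface areas** are marching-cubes mesh areas of the 0.5-isosurface
  after Gaussian pre-smoothing of the binary mask (σ = 1.5 voxels).
  Smoothing matters: meshing the raw binary mask overestimates a smooth
  surface by ~9% (staircase artifact) and face counting by ~50%; with
  smoothing, a 4-mm sphere at 50 μm voxels is recovered to 0.02%. Objects
  so small that smoothing erases them fall back to the raw mesh; face
  counting survives as a `voxel_faces` reference mode.
* **Dimensions** L ≥ W ≥ T are grain-mask extents along its principal
  axes (PCA of voxel coordinates), not the bounding box, because a
  mounted kernel sits at an arbitrary orientation. One voxel is added to
  each extent so a box of n voxels measures n voxel-lengths.
* **Sphericity** SP = (36π V²)^(1/3)/SA; the mesh tolerance means
  voxelized spheres land within [0.98, 1.02].
* **Missing components** (e.g. a kernel segmented without an embryo)
  yield NaN for their fields, with a warning. NaN propagates through the
  ratio formulas; it is never silently replaced by 0.
* A note on the packaged reference cohort: its printed weight column is a
  bulk-sample mean and is **not** consistent with weight/Vg for the
  printed per-variety volumes (e.g. 346 mg / 285.9 mm³ ≈ 1.21 g cm⁻³
  against the printed density 1.278). This package always computes
  DE = mass/Vg from the actual inputs it is given and makes no attempt to
  reconcile that external inconsistency.

## Statistics

* Breakage rate BR = W_pan/(W_5mm + W_2mm + W_pan) is treated as a
  fraction in [0, 1] throughout; the published regression coefficients
  only reproduce on the fraction scale.
* The Spearman screen uses average ranks for ties and two-sided tests
  (0.05 "*", 0.01 "**"); constant columns are flagged as undefined.
* Stepwise selection is forward entry + backward removal with equal 5%
  entry and removal thresholds; termination is enforced by refusing to
  revisit a predictor set. The retained model is refit by plain OLS.
* Direct path coefficients are standardized OLS coefficients
  β_i = b_i·sd(x_i)/sd(y); indirect coefficients are r(Xi, Xj)·β_j. The
  identity total(i) = r(Xi, y) then holds algebraically for OLS with an
  intercept and is asserted to 10⁻⁶.
* The compact letter display uses pairwise Fisher's LSD on the pooled
  within-group mean square at 0.05 (Tukey HSD available), with
  insert-and-absorb letter assignment ordered by descending mean.

## The phantom generator

The phantom emulates the study conditions the statistics are meant for:

* body: superellipsoid, exponent 2.5 (a flattened ovoid; real kernels
  report only L/W/T ranges, not a shape law), default semi-axes
  7 × 4.2 × 2.25 mm — a 14 × 8.4 × 4.5 mm dent kernel;
* seed coat: erosion shell of 0.14 mm; embryo: half-ellipsoid lobe flush
  with one broad face, target fraction 10% of grain volume (real kernels:
  8–11%);
* cavities: spheres planted per location class — subcutaneous seated
  against the coat–endosperm interface, endosperm strictly interior,
  embryo inside the lobe — with default counts/radii giving per-class
  volumes of a few mm³, the range observed in air-dried kernels;
* grey levels 10/40/120/120/200 (background/cavity/endosperm/coat/embryo)
  with additive Gaussian noise (default σ = 8 on the 8-bit scale) clipped
  to [0, 255]; coat defaults to the endosperm grey because the two are
  indistinguishable in practice — the brightness ordering
  background < cavity < endosperm ≤ embryo is enforced;
* mass = apparent density × cavity-inclusive grain volume, so the
  phantom's true DE equals the configured density;
* all randomness flows from one integer seed through one generator.

Cohort simulation draws variety-level subcutaneous cavity volume
(1.3–5.9 mm³) and density (1.14–1.28 g cm⁻³) uniformly, scatters
replicates with 2% relative jitter, and generates
BR = 1.381 + 0.010·Vsc − 0.724·DE + ε with ε ~ N(0, 0.005) by default —
the magnitudes of the six-variety reference cohort. Breakage values
outside (0, 1) are flagged, never clipped. Nuisance columns (SSAg, SP by
default) are drawn independently of BR so selection procedures can be
scored against a known active set. `generate_cohort` additionally renders
one voxel phantom per kernel and computes BR from the *rendered* truth, so
the generating model holds exactly for the measured data;
`simulate_cohort_table` is the volume-free fast path used for
estimator-recovery experiments.

**What the phantom does not emulate:** reconstruction artifacts (beam
hardening, rings), partial-volume blur, the vitreous/floury endosperm
contrast, non-spherical cavity shapes, and kernel-surface texture (the
phantom's sphericity ≈ 0.79 versus ~0.51–0.57 for real dent kernels,
which have a crown dent and irregular surface). Passing phantom tests
therefore demonstrates correctness of the measurement chain, not
field-readiness for every scanner artifact.

## Problem sizes and numerical choices

Tests and the acceptance checks run phantoms at 70 μm voxels
(≈ 208 × 128 × 73 grid) and the sphere oracle at 50 μm (168³); end-to-end
cohort runs use 150 μm voxels with 6 varieties × 3 replicates. These sizes
were chosen so the full suite exercises every stage on kernel-shaped
geometry while remaining comfortable to run repeatedly; all thresholds
(Dice ≥ 0.95 at noise σ = 8, exact noiseless recovery, 1%/3%
volume/area oracles) are asserted at these sizes unchanged. Estimator
recovery uses 100 seeded cohorts of n = 60 (selection rate ≥ 90%) and
RMSE comparisons at n = 30/60/120.

Tie-breaks and degenerate inputs: stepwise prefers the smallest p-value
at entry and breaks exact ties by column order; rank-deficient designs
raise naming the collinear columns; empty masks return 0 area with a
warning; an all-background volume is a loud error, as is more than one
kernel per volume.

## Known limitations

* The coat/endosperm pooling convention means "endosperm" parameters are
  endosperm + pericarp unless `coat_separate=True`; the geometric shell
  is only as good as the configured thickness.
* Cavity localization is positional, per component; a cavity spanning the
  coat interface and the deep endosperm is assigned one class
  (subcutaneous, by the touch rule).
* With six cohort rows the regression on variety means is descriptive —
  the package reproduces it faithfully but the standard errors at n = 6
  mean the simulated-cohort tests, not the six-row fit, carry the
  statistical evidence for estimator correctness.
* The CLI `run` command simulates its cohort; segmenting a directory of
  real scans end to end is done with `segment`/`measure`/`stats` per
  kernel (no batch scheduler is included).
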