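# Methods

This note documents the models, estimators and numerical choices behind
`cect`, what the synthetic phantoms do and do not emulate, and the known
limitations.

## Data model and conventions

Volumes are 3D lattices of 8- or 16-bit gray values on an isotropic grid,
indexed `(z, y, x)` with slice files defining z in lexicographic order.
The gray convention follows attenuation reconstructions: 0 is air, the
dtype maximum is the densest material in view. All VOIs are half-open
and 0-based; spherical VOIs return a bounding box plus a congruent mask.
Reorientation (to put the coronal plane in xy) resamples on the same
grid with configurable spline order; exact quarter-turns about z in
nearest mode are executed as voxel permutations and are lossless.
Out-of-field voxels are filled with 0, the attenuation of air.

Quantitative analyses operate on the 16-bit data. The 8-bit conversion
(percentile windowing, default percentiles 0.1/99.9 for robustness to
hot pixels; linear map, clipped, rounded half-up) exists for export.

## Staining kinetics

An immersed specimen develops a bright stained shell that advances
inward. The specimen is deliberately approximated as a sphere — the
model the field uses because it turns two easily measured volumes into a
front depth:

- `R_e = (3 V_e / 4π)^(1/3)`, `r_u = (3 V_u / 4π)^(1/3)`, `r_p = R_e − r_u`;
- `r_p(t) = R_e (1 − e^(−kt))`, fitted by bounded nonlinear least squares
  (`scipy.optimize.least_squares`), initialised at `R_e = max r_p`,
  `k = 1/median(t)`, both parameters constrained positive with a rate
  cap of 10³/day. A fit is flagged unconverged when the optimiser fails,
  the rate pins at its cap, or the rate is unidentified (the curve is
  saturated to within 10⁻⁶ at the earliest observation, as with a
  constant depth series). The curve passes through the origin by
  construction.

Segmentation pipeline: threshold (Otsu or fixed) → largest 26-connected
component → 6-connected hole fill, with reference-material VOIs excluded
first. This replaces interactive lasso/brush editing so results are
reproducible. The stain threshold is the 1st percentile (configurable)
of tissue grays at the final, fully stained time point — a noise-robust
version of "the least attenuating tissue after complete staining". The
unstained core is segmented as sub-threshold tissue reduced to its
largest connected component with holes filled: with a percentile-based
threshold, a fixed fraction of stained voxels falls below the cutoff as
scattered speckle, and because radii go as the cube root of volume, even
1 % of speckle volume would bias late-time `r_p` by ~20 % if counted as
core. The cleanup is the automated counterpart of the manual speckle
removal interactive tools perform.

Total-volume change is reported relative to the first time point, in
percent, matching how swelling/shrinkage is usually plotted.

## Contrast-to-noise ratio and Otsu

`CNR = |μ₁ − μ₂| / ((σ₁+σ₂)/2)` with population SDs (divide by n; the
choice is documented and immaterial at ROI sizes of 10³–10⁵ voxels).
Degenerate conventions: zero noise with equal means → 0; zero noise with
different means → +∞. CNR is invariant under joint affine rescaling of
the grays, which ties it to the reference normalization: normalized
datasets give the same CNR as their raw counterparts.

Otsu binarization is implemented exactly as the classical 256-bin
between-class-variance maximisation over the VOI histogram, foreground
`gray ≥ threshold`, ties resolved to the lowest boundary; tests verify
equality with an exhaustive oracle.

## Reference normalization

`g_X = (G_X − G_E) / (G_B − G_E)` anchors tissue grays to the sample
tube (0) and a ceramic bead (1). Reference regions are supplied as VOIs
rather than auto-detected, since bead and tube geometry vary between
setups; the invariant `G_B > G_E ≥ G_air` is enforced to catch misplaced
VOIs. Whole-dataset rescaling maps each volume's (tube, air) pair —
falling back to (bead, tube) when air is unmeasured — onto an anchor
dataset's by the unique affine transform, rounded back to the input bit
depth.

## Structure-tensor white-matter metrics

**Tensor.** Gaussian-derivative gradients at scale σ_grad, per-voxel
outer products smoothed at σ_tensor, then again at the fiber scale
σ_fiber. Defaults (0.5, 0.5, 5) voxels are the mouse-brain settings: a
sub-voxel derivative scale resolves fiber walls, the 5-voxel smoothing
pools orientation over a bundle cross-section. Image gradients lie
perpendicular to fiber axes, so the fiber direction is the eigenvector
of the *smallest* eigenvalue.

**FA.** The standard DTI form on the sorted eigenvalues,
`FA = sqrt(3/2) · ‖λ − λ̄‖ / ‖λ‖`, clipped to [0, 1]; voxels whose trace
falls below an energy floor (default 10⁻⁶ of the maximum trace) carry no
orientation signal and get FA 0. The exact anisotropy estimator behind
commercial gradient-analysis tools is unpublished, so this definition is
the package's own, chosen for comparability with the DTI literature.

**Radial-diffusivity analog.** `(λ₂ + λ₃)/2` of the *trace-normalized*
eigenvalues (isotropic value 1/3). Raw structure-tensor eigenvalues
scale with squared image contrast, so the raw minor-eigenvalue mean
would *fall* when fibers lose contrast — the opposite of the diffusion
quantity the analog is named for. Normalizing by the trace makes it a
pure orientation-dispersion measure that rises as coherent fiber
contrast is lost, matching the DTI behaviour under demyelination.

**Volume fraction.** Fraction of VOI voxels on the fiber side of a fixed
threshold on a scale comparable across datasets (reference-matched
16-bit or the normalized scale); `hypo` counts `≤ threshold` (dark
fibers, anionic agents), `hyper` counts `≥` (cationic agents).

**Fiber detection.** Normalized cross-correlation of zero-mean
voxelized-cylinder templates over sampled orientations (default 30°
hemisphere sampling; explicit orientation lists supported), normalized
by the local window SD. The correlation peaks on the cylinder axis and
decays radially, so the object mask is reconstructed by stamping the
best-matching template footprint at every supra-cutoff voxel; this
covers a matching cylinder across its full cross-section while pure
noise produces essentially no detections at the default cutoff 0.5. The
template parameters of the commercial cylinder-correlation module are
not public; radius, length, angular step, polarity and cutoff are all
exposed.

**Labeling.** Markers are h-maxima regional-maxima regions of the
correlation map inside the mask (depth tolerance h = 0.1, so noise
ripples along one bundle's ridge do not fragment it), merged within a
configurable separation (default: the template radius); watershed of the
inverted correlation restricted to the mask assigns every detected voxel
to a bundle. Deterministic by construction.

**Thickness.** Local thickness = diameter of the largest inscribed
sphere through each voxel, computed from the Euclidean distance
transform by sweeping radii in descending order; per-bundle thickness is
the mean over the bundle, the headline number the median across bundles,
in µm. Verified against a brute-force inscribed-sphere oracle on small
grids. Thickness depends only on the labels, never on gray values.
Thickness measured on *detected* masks inherits the detection mask's
geometry (the stamped footprints slightly exceed the true cylinder), so
absolute values on detections are upper-biased by roughly one template
radius; comparisons between datasets processed identically are
unaffected, and thickness on ground-truth or threshold-based labels is
accurate to a voxel.

**Regional report.** Normalized mean gray per named VOI (canonically the
four corpus-callosum positions — caudal/rostral × medial/lateral — over
a 50-slice slab), with percent change versus a baseline dataset as the
demyelination proxy: `(g − g_base)/g_base × 100`.

## Phantoms

`make_scene` builds a quasi-spherical half-ellipsoid "hemisphere"
(default radii 1.50/1.35/1.20 mm) inside a tube annulus with a bright
bead and air, at 30 µm voxels on a 128³ grid so the whole scene fits a
desk-scale volume. The staining front advances inward along Euclidean-
distance contours of the true geometry, and its position at time t is
chosen so the unstained-core volume equals the spherical-model
prediction `V_u(t) = 4/3·π (R_e − r_p(t))³` — the front *shape* is
ellipsoidal (preserving the sphere approximation's model misfit) while
the front *position over time* realises the kinetic law, so the
generative `(R_e, k)` are exactly the quantities the analysis should
recover. Defaults emulate a fast, swelling-inducing anionic agent: rate
0.5/day (full staining within the nine-day window), +7 % total volume
change applied as a volume factor tracking staining progress, 1-voxel
front blur, Gaussian noise SD 1000 gray units (≈5 % of the
stained–unstained contrast), clipped to the 16-bit range with the
clipped fraction recorded.

`make_fiber_phantom` tiles parallel cylinders (default radius 30 µm,
hypointense by 8000 gray units) on a periodic lattice inside a centred
box; lattice counts and the box width are searched so the analytic
volume fraction `π r²/(s_y s_x)` matches the requested value (default
0.20) to well under the digitization error. A demyelination factor
d ∈ [0, 1] scales the fiber/background contrast by (1 − d), emulating
how demyelinated bundles admit more of a repelled anionic stain and
brighten. Reference materials sit in the margins so normalized-gray
analyses run end to end.

Determinism: a fixed spec seed yields bit-identical volumes; time series
use per-time-point seed streams so noise is independent across scans.

What the phantoms do *not* emulate: X-ray physics (beam hardening,
scatter, ring artifacts), diffusion-PDE concentration profiles (the
front is sharp with optional blur — the analysis model assumes a front),
anatomical heterogeneity, curved or dispersed fiber trajectories, and
partial-volume chemistry. Passing tests therefore demonstrate that the
estimators recover known geometric/statistical structure under realistic
noise, not that they are robust to every artifact of real scans.

## Problem sizes and runtime

The test and acceptance workloads use 128³ staining scenes (30 µm
voxels), ≤ 96³ fiber phantoms (6 µm voxels), 200-replicate Monte-Carlo
decay fits and 48³ tensor fields — sizes chosen so the entire validation
suite completes in a few minutes on a single CPU while keeping every
geometric feature several voxels wide.

## Known limitations

- The sphere approximation understates `r_p` for strongly aspherical
  specimens; the phantom manifests store both true ellipsoid radii and
  the sphere-equivalent radius so the misfit can be quantified.
- CNR on blurred-edge compartments is slightly below the nominal
  contrast/noise ratio because edge voxels mix compartments; the sharp-
  edge phantom recovers it to < 1 %.
- Cylinder-correlation detection assumes locally straight tubes at the
  template scale; strongly curved bundles fragment.
- Group-level inference (ANOVA, multiple comparisons) is out of scope;
  workflows report descriptive statistics that can be fed to any
  statistics package.
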