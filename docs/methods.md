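# Methods

This note records the models, parameter choices and numerical conventions
behind `calcquant`, and what its synthetic validation does and does not
establish.

## Volumes and resampling

A `ScalarVolume` is a 3-D intensity grid with per-axis spacing (mm), origin
and modality tag; voxel centers sit at `origin + index * spacing` and the
grid's physical extent counts a half-voxel margin per side. Before any
volumetry, volumes are rescaled to 0.5 mm isotropic resolution. "Bicubic"
interpolation is implemented as full separable cubic (tricubic) resampling
— volumetry is three-dimensional and clinical slices are anisotropic
(1.0–1.3 mm), so through-plane interpolation order matters as much as
in-plane. Output voxel centers are laid out in physical coordinates from
the input origin (half-voxel-center convention), which makes CT and MR
volumes comparable across different native grids; when the input is already
at the target spacing the map is an exact identity. Out-of-grid coordinates
take the nearest-edge value: a zero-padded edge would create artificial
dark voxels that the MR low-signal rule would happily call calcium.
Intensities are resampled first and thresholds applied afterwards.

Cubic spline interpolation is exact on constant and affine intensity fields
in the grid interior; near edges the nearest-edge extension perturbs the
spline prefilter, with a geometrically decaying influence (~0.27 per voxel)
into the interior. Tests therefore check affine exactness away from a
safety margin.

## Segmentation rules

* CT: strictly `> 560` HU within the ROI. The boundary is strict on both
  modalities so exact unit tests have a well-defined rule; a voxel at
  exactly 560 HU is background.
* MR: strictly `< μ − kσ`, k = 3 ilio-femoral / k = 2 aorto-iliac. The
  background region for (μ, σ) is the ROI itself; a single re-estimation
  pass excludes already-classified voxels and classifies once more. One
  re-pass (not iteration to convergence) keeps the estimator deterministic
  and order-free. If the ROI is degenerate (σ = 0) the mask is empty with a
  warning; if the *re-estimated* background is exactly constant the pass-1
  classification stands (the constructed constant-background case).
* σ uses the n−1 sample denominator.
* No connected-component or minimum-size filtering: the method is pure
  threshold volumetry, so on a calcium-free Gaussian ROI the k = 3 rule
  classifies ≈ Φ(−3) ≈ 0.135 % of voxels (slightly more after the re-pass,
  ≈ 0.146 %), a floor of ≈ 4–6 mm³ per 5-cm ROI that is itself tested.

An important operating constraint of an ROI-referenced rule: if calcium
occupies more than ~10 % of the ROI, the pass-1 threshold `μ − 3σ` of the
bimodal intensity mixture drops below the calcium signal level and detection
collapses. With the 5-cm, 5-mm-radius segment ROI (≈ 3 927 mm³) this bounds
reliable per-segment volumes at roughly ≤ 350 mm³. The synthetic cohorts are
generated inside this regime (below); for clinical use with larger plaque
burdens a background sample away from the vessel would be required.

ROIs are cylinders from an anatomical landmark (e.g. the femoral
bifurcation) with a 50 mm extent and a radius covering the vessel plus
margin — segments are localized by landmark and extent, not by lumen
segmentation.

Severity groups from the CTA volume: v < 100 mm³ → 1, 100 ≤ v < 300 → 2,
v ≥ 300 → 3 (half-open intervals so fractional volumes are always graded).

## Synthetic phantoms

`phantom.make_exam` builds paired CT/MR exams of parallel vessel tubes with
axis-aligned ellipsoidal calcium deposits whose analytic volumes
(4/3·π·abc) are known; ground truth is voxelized by center-inclusion on the
rendering grid.

CT model: piecewise-constant HU field (soft tissue 40, wall 60, lumen 300,
calcium 1000 HU) convolved with an isotropic Gaussian PSF, plus Gaussian
noise (default SD 20 HU). Blooming — the apparent enlargement of dense
calcium — emerges because the 560 HU threshold sits at only 37 % of the
calcium–lumen edge transition, so the blurred boundary crosses it outside
the true surface. The PSF FWHM is a free parameter (default 1.0 mm); no
quantitative blooming magnitude is modelled, so all blooming checks are
directional (sign of bias), not magnitude-matched.

MR model: uniform background (mean 100, optional smooth heterogeneity),
deposits rendered as dark cores at `calcium_fraction × mean` (default 0)
after shrinking each semi-axis by the surface-water layer thickness
(default 0.4 mm) — a one-parameter stand-in for the mobile water spins at a
calcification's surface that return signal and shrink its apparent size.
Erosion by semi-axis reduction is exact for ellipsoids (a 4-mm sphere with
a 0.5 mm layer leaves exactly the 3.5-mm core). Noise is Gaussian
(default SD 10 = 10 % of background): in proton-density imaging the
background sits far above the noise floor, where Rician ≈ Gaussian.

Generator regime (fixed study conditions):

* rendering grid = 0.5 mm isotropic, i.e. equal to the analysis grid. The
  mandatory resampling step then acts as an identity, so ground-truth voxel
  masks transfer exactly and parameter-recovery tests isolate the threshold
  rule rather than interpolation partial-volume error (resampling accuracy
  is validated separately on anisotropic grids);
* per-segment true volumes drawn from 60–350 mm³ across the three severity
  strata (40 % / 35 % / 25 %), spanning mild to severe disease while
  keeping every ROI's calcium fraction below ~9 % — inside the validity
  regime of the ROI-referenced rule derived above;
* 1–3 deposits per segment, semi-axes ≥ 1.5 mm (> the surface layer);
* cohorts split ~5:3 between 1.5 T and 3 T labels to mirror two-site
  recruitment (field strength is a stratification label only; no
  field-dependent susceptibility physics is modelled).

What passing phantom tests show: the thresholds, ROI bookkeeping and
statistics behave correctly, and the blooming/surface-layer mechanisms
reproduce the clinical bias *structure* (negative MR − CTA bias, regression
slope < 1, near-perfect correlation). What they do not show: clinical
accuracy on real anatomy — real plaque is irregular and eccentric, CT
blooming depends on kernel and dose, MR backgrounds drift, and the
phantom's bias magnitudes (slope ≈ 0.7, bias ≈ −70 mm³ at default
settings) are steeper than clinical values because the synthetic deposits
are smaller and more numerous per unit volume.

Reader-score generator: reader 1 draws from a categorical distribution over
the 5-point scale concentrated on scores 3–5 (mean 4.1); reader 2 repeats
the score with probability `agreement`, else moves to a uniformly chosen
adjacent category. Its population weighted κ has a closed form (enumerate
the joint pmf), which is inverted to choose `agreement` for a target κ —
the defaults target the clinically observed κ of 0.67 (ilio-femoral) and
0.80 (aorto-iliac).

## Agreement statistics

All estimators are implemented explicitly and checked against brute-force
formula oracles (and pingouin / scikit-learn where available):

* Pearson r with Fisher-z CI (SE = 1/√(n−3)); |r| within 1e−12 of 1 is
  snapped to ±1 with a degenerate CI.
* ICC(2,1): two-way random effects, single measurement, absolute agreement
  — chosen because "agreement" is reported as distinct from correlation, and
  absolute agreement penalizes systematic offsets that r ignores. CI by the
  standard F construction with Satterthwaite degrees of freedom. Note
  ICC(2,1) equals r for equal-moment measurement sets only asymptotically
  (finite-n ANOVA denominators differ).
* Bland–Altman: differences MR − CTA; bias ± 1.96 × SD (n−1).
* Weighted κ with linear weights `1 − |i−j|/4` over the full 5-category
  space (quadratic available); linear is the conventional default for
  ordinal Likert data. CI from the Fleiss–Cohen–Everitt large-sample
  variance.
* Interpretation scale implemented as half-open intervals
  [0.40, 0.60), [0.60, 0.75), ≥ 0.75 so every coefficient receives exactly
  one label.
* Strata with fewer than 3 pairs report n only.

Segments are treated as independent observations; CIs do not model
within-patient clustering of segments (the clinical analysis this mirrors
did the same, and the phantom generator draws segments independently).

## Projections

Thin-slab MinIP/MIP (4–15 mm typical; default 8 mm). Axis-aligned slabs
reduce voxels directly and are bit-exact, which the associativity and
monotonicity tests exploit; oblique normals resample planes by linear
interpolation first. A slab thinner than one voxel degrades to the nearest
single slice with a warning. Slab center defaults to the volume center;
callers may center on a segmented-calcium centroid.

## Stack-of-stars simulator

Hybrid model matching the physics at desk scale: exact non-uniform DFT of
radial spokes in-plane × Cartesian FFT across partitions; no gridding
approximation (the 64×64×16 default grid makes dense matrix products
cheap). Motion is rigid in-plane sinusoidal displacement of a feathered
sub-region, applied per line via the Fourier shift theorem — exact for the
feathered component. Reconstruction is the |k|-ramp density-compensated
adjoint (DC weight = Δk/4), with the inverse partition FFT applied first;
it depends only on each line's (view, partition) identity, so permuted
static schedules reconstruct identically to machine precision.

Scale choices: 64×64×16 grid; 101 views = ⌈π/2·64⌉, the full angular
sampling count for a 64 matrix — at 64 views the undersampling streak floor
is comparable to the motion artifact itself and obscures the ordering
comparison, just as a clinical 1200-view protocol fully samples its matrix.
Line time 5 ms. The default motion period (0.7 s, amplitude 3 mm) makes the
legacy ordering's partition-revisit interval (~0.5 s) comparable to the
motion period — the regime where the through-plane encode samples the
moving object in effectively uncorrelated states, reproducing at desk scale
the timing ratio of a multi-minute abdominal scan against multi-second
bowel/respiratory motion. The test phantom places its two "vessel" tubes
adjacent to the moving central "bowel" blob, as the iliac arteries are;
the blob is compact in z so its through-plane ghosts land outside its own
support. The artifact metric is ghost energy: Σ|recon|² outside the
2-voxel-dilated true-object support, normalized by the energy inside.
Under the defaults the legacy views-inner ordering yields ~2.7× the ghost
energy of the partitions-inner ordering and ~3–4× the vessel-region error;
with zero motion amplitude the two orderings agree to machine precision.
The comparison is a strict inequality, not a magnitude claim — no
quantitative artifact level is modelled.

## Problem sizes

Validation cohorts use 12 exams × 4 ilio-femoral segments (48 paired
measurements) at the 0.5 mm grid, 10⁵-voxel ROIs for false-positive rates,
and the 64×64×16 simulator grid; these sizes give stable statistics
(e.g. ±0.002 on r, factor-≪2 on tail fractions) while keeping a full run in
minutes on one CPU.

## Known limitations

* No CT projection physics (beam hardening, photon statistics, kernels):
  blooming is a single-parameter Gaussian PSF.
* No field-strength-dependent susceptibility/T2* model — 1.5 T vs 3 T is a
  labelling stratification only.
* No spatial registration between CT and MR; comparison is per-segment
  volume, never voxelwise.
* ROI-referenced MR background statistics break down above ~10 % ROI
  calcium fraction (see Segmentation rules).
* The rating generator's adjacent-category confusion is a minimal model of
  reader disagreement; it matches a target κ but not any particular reader
  psychology.
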