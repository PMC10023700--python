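# Methods notes

## Model and assumptions

The pipeline estimates regional lung ventilation from a pair of CT volumes
reconstructed at peak inspiration and peak expiration. It assumes:

* both volumes are on (or calibratable to) the Hounsfield scale, with the
  standard anchors air = −1000 HU, water = 0 HU;
* a binary lung mask is supplied for the inspiratory volume (and optionally
  the expiratory one) — segmentation is an input, not a stage;
* lung tissue density is a constant 1.065 g/ml, so the tissue specific
  volume is SV_tissue = 1/1.065 ≈ 0.939 ml/g and the voxel gas content is
  SVg = 1000/(HU + 1000) − SV_tissue (ml of gas per gram of tissue);
* spatial correspondence between the phases can be recovered by an
  intensity-driven deformable registration; ventilation is then the
  voxel-wise ΔSVg = SVg_insp − SVg_exp on the inspiratory grid.

A note on the HU convention: with the anchors above the SVg formula gives
water exactly 1 ml/g of total specific volume, which is the internal
consistency condition of the method. The `CalibrationSpec` lets a user
invert the anchors if their scanner export uses a different convention.

Functional classification is deliberately *cohort-relative*: the
thresholds α_I, α_E (5th percentile of inspiratory/expiratory SVg) and β
(25th percentile of ΔSVg) are recomputed from the pooled in-mask voxels of
the study's healthy control group, never shipped as constants. Fibrosis is
called only when *both* phases are dense (SVg below both α's); otherwise
the ΔSVg/β comparison separates low from normal ventilation.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| voxel spacing | 50 | µm | isotropic micro-CT reconstruction scale |
| SV_tissue | 0.939 | ml/g | 1/1.065, soft-tissue density |
| HU floor before SVg | −990 | HU | keeps 1000/(HU+1000) finite near pure air; clamped voxels are counted and logged |
| p_alpha, p_beta | 5, 25 | % | percentile levels defining α and β |
| pyramid levels | 4 | — | multiresolution Demons depth |
| iterations/level | 100, 100, 50, 25 | — | coarse → fine |
| field smoothing σ | 1.5 | voxels | Gaussian regularisation of the displacement field |
| histogram bins | 25 over [−1000, 500] | HU | density-histogram convention; configurable |

## Registration design

* The similarity is driven by Laplacian-filtered images (7-point stencil),
  because parenchymal HU changes with lung volume between phases while
  structural edges do not. The filter is applied once at full resolution,
  before pyramid construction; each pyramid level then gets the usual
  anti-alias Gaussian smoothing (σ = 0.5·shrink-factor voxels, and a light
  0.5-voxel smoothing at full resolution to keep the sparse edge maps
  differentiable).
* Both edge maps are normalised to zero mean / unit variance instead of
  histogram-matched. A Laplacian image is dominated by an atom at zero, so
  quantile-based matching is numerically unstable — in testing it flipped
  the registration between ~0.5-voxel and ~3-voxel mean field error on
  inputs differing only in a handful of voxels.
* The displacement field lives on the fixed (inspiratory) grid in physical
  µm and maps fixed point p to moving point p + u(p). Warping samples the
  moving image at those points with linear interpolation (nearest for
  masks), pads out-of-domain samples with the edge value, and reports the
  out-of-domain voxel count.
* Field application happens in HU space; SVg conversion follows warping.
  Interpolating HU avoids interpolating across the strongly nonlinear SVg
  scale near −1000 HU.
* TRE is the Euclidean landmark distance through the trilinearly
  interpolated field; the spread is the sample standard deviation
  (ddof = 1).

## Numerical choices

* Percentiles everywhere use linear interpolation between order statistics
  (quantile type 7), recorded in the threshold provenance.
* `classify` compares against thresholds with a guard tolerance of
  1e-9 ml/g. On noise-free synthetic data the control pools are atomic
  (piecewise-constant compartments) and a percentile lands exactly on the
  atom; without the guard, float round-off from interpolation would split
  the atom arbitrarily across the class boundary. The guard is six orders
  of magnitude below any physiological ΔSVg signal.
* Voxels passing exactly one of the two α margins are resolved by the
  ΔSVg rule (and counted as mixed-margin for QC), so the three classes
  always partition the lung.
* Region halves/thirds cut the mask's bounding extent along the chosen
  axis into equal slab counts, remainder to the cranial-most (or
  ventral-most) slabs. "Vertical" is cranio-caudal for upper/lower halves
  and ventral–dorsal for the histology-matched thirds; both axes are
  explicit options.
* Spearman p-values use the t-approximation on n−2 degrees of freedom; an
  exact permutation p-value is available for n ≤ 8.

## The phantom

The synthetic subject emulates: a soft-tissue torso (+40 HU) with two
ellipsoidal lungs; ventilated parenchyma at −550/−400 HU
(inspiration/expiration), low-ventilation lesions at −450/−420 HU,
fibrotic lesions at −100 HU in both phases; smooth seeded lesion blobs
biased toward the caudal half (confluent patches, 10% F and 15% LV of lung
volume by exact count); ten bright vessel-like markers whose centres form
exact landmark pairs; a smooth analytic expiration map (raised-cosine
cranio-caudal compression, zero at the apex and maximal 6 voxels at the
diaphragm, plus a 2% lateral scaling) that is analytically invertible, so
the expiratory volume is resampled anatomy, not an approximation; optional
additive Gaussian HU noise (added last); and re-encoding to raw grey
levels through a known linear calibration so the calibration stage is
exercised.

What it does *not* emulate: reconstruction texture and correlated noise,
beam hardening, gating artefacts, cardiac motion, airway trees, intra-
compartment heterogeneity (compartments are piecewise constant unless a
texture sd is set), or sliding motion at the pleura. Passing the phantom
checks therefore demonstrates the correctness of the computational chain
— calibration, registration convergence on edge structure, formula
composition, percentile construction, partitioning — not performance on
real scans.

Marker voxels carry their own HU (+100) in both phases; they are labelled
"normal ventilation" in the truth map and amount to ~0.2% of the lung, a
perturbation the recovery metrics ignore at the reported precision.

Problem sizes: unit tests run on 48–64-voxel cubes; the registration and
classification validations use the full 128-voxel cube at 50 µm, one
subject per condition and a three-phantom control cohort, which keeps a
full validation run in the minutes range on a single CPU.

## Validation design

Control-cohort ventilation maps used for threshold derivation are built by
warping the expiratory phase with the phantom's *known* analytic field;
the classified test subject always goes through the full Demons
registration. This isolates what each check measures: registration
accuracy is audited directly by landmark TRE on the registered pair, and
classification recovery is audited end-to-end on the subject. (Registering
the cohort as well mostly injects registration-error boundary blends into
the extreme percentiles of the control pool — the 5th-percentile α_E
collapses toward zero — which is a property of the synthetic crisp-edged
cohort, not of the method.)

Checks that need continuous value distributions — "the fraction of voxels
below a derived percentile equals its nominal level" and strict median
orderings between fibrotic and healthy subjects — run at a realistic 20 HU
noise level; noise-free compartments are degenerate atoms for which such
statements are ill-posed.

## Known limitations

* **Percentile-threshold circularity.** By construction, 25% of a healthy
  cohort's voxels lie below β. Any subject whose normally-ventilated
  parenchyma follows the same distribution as the control pool will
  therefore have ~25% of its truly normal voxels called "low ventilation"
  whenever the distributions are continuous (e.g. under measurement
  noise). With 15% true LV and 75% true NV lung, that bounds the
  achievable LV Dice near 0.62 regardless of implementation, and it is why
  the noisy-condition class recovery reports high Dice for F (protected by
  the two-sided α conjunction) and NV, but not LV. On noise-free
  piecewise-constant data the boundary rule (NV takes ΔSVg ≥ β) keeps the
  healthy atom on the normal side and recovery is limited only by
  partial-volume blend shells at lesion boundaries (LV Dice ≈ 0.87–0.88).
  Real studies should read the LV percentage as cohort-relative ("below
  the healthy 25th percentile"), not as a segmentation of pathology.
* Ventilation is a difference of specific gas volumes; no mass-conservation
  or Jacobian-based estimator is provided.
* The registration offers no diffeomorphic guarantee; invertibility is only
  verified on the phantom, where the truth map is invertible by
  construction.
* Histology colour rules (green-stain hue window, white threshold) are
  stain- and scanner-dependent and must be calibrated per laboratory; the
  defaults are sensible starting points, validated only on synthetic
  fixtures.
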