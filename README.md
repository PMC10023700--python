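# microvent

Quantitative ventilation mapping from paired inspiratory/expiratory
micro-CT of the mouse lung.

Longitudinal small-animal models of lung fibrosis (e.g. bleomycin-induced
fibrosis, with or without antifibrotic treatment) are usually read out by
terminal histology. Free-breathing micro-CT reconstructed at peak
inspiration and peak expiration offers a non-invasive alternative: the
voxel-wise change in gas content between the two respiratory phases is a
functional surrogate for regional ventilation. `microvent` implements that
image-analysis chain as a tested Python library plus CLI, together with a
fully synthetic paired-phase phantom so every stage can be validated
without animal data. It is aimed at preclinical imaging groups processing
their own phase-resolved reconstructions (lung masks are taken as inputs;
segmentation is out of scope).

## Method

1. **Calibration.** Raw grey levels are mapped linearly to Hounsfield
   units, anchored on air (−1000 HU) and water (0 HU).
2. **Deformable registration.** The expiratory volume is registered onto
   the inspiratory one with symmetric-forces Demons in a four-level
   multiresolution pyramid. Both volumes are Laplacian-filtered before the
   similarity-driven update so the forces follow structural edges rather
   than the global density shift between phases; the resulting displacement
   field is applied to the unfiltered HU volumes. Accuracy is audited as
   the target registration error (TRE) on paired anatomical landmarks.
3. **Ventilation map.** Each voxel's specific volume (ml/g) is
   `SV_total = 1000 / (HU + 1000)`; subtracting the tissue specific volume
   `SV_tissue = 1/1.065 ≈ 0.939 ml/g` gives the specific gas volume
   `SVg = SV_total − SV_tissue`. Ventilation is the voxel-wise difference
   `ΔSVg = SVg_insp − SVg_exp` on the inspiratory grid.
4. **Functional classification.** Thresholds are percentiles of a healthy
   (saline) cohort's pooled voxel values — α_I, α_E the 5th percentiles of
   inspiratory/expiratory SVg, β the 25th percentile of ΔSVg. A voxel is
   *fibrosis* (F) if both SVg values fall below their α, otherwise *low
   ventilation* (LV) if ΔSVg < β, otherwise *normal ventilation* (NV).
5. **Biomarkers.** Median, 75th percentile and IQR of HU and ΔSVg, and
   class volume percentages, per whole lung, cranio-caudal halves, or
   ventral/intermediate/dorsal thirds; group median histograms; Spearman
   rank correlation against histomorphometric endpoints (collagen and
   alveolar-air area fractions from colour-thresholded slide images).

## Worked example

Generate a synthetic healthy control and a fibrotic subject (20 HU noise),
derive cohort thresholds, register and classify the subject:

```python
import numpy as np
from microvent import (grey_to_hu, demons_register, warp, svg_map, ventilation_map,
                       derive_thresholds, classify, class_percentages)
from microvent.phantom import PhantomSpec, generate_phantom, evaluate_recovery

control = generate_phantom(PhantomSpec(noise_sd=20.0).saline(seed=1))
subject = generate_phantom(PhantomSpec(noise_sd=20.0, seed=7))

def svg_triplet(ph, field):
    cal = ph.truth.calibration
    hu_insp = grey_to_hu(ph.insp_raw, cal)
    hu_exp_warped = warp(grey_to_hu(ph.exp_raw, cal), field)
    svg_insp = svg_map(hu_insp, ph.mask_insp)
    svg_exp = svg_map(hu_exp_warped, ph.mask_insp)
    return svg_insp, svg_exp, ventilation_map(svg_insp, svg_exp, ph.mask_insp)

si, se, dv = svg_triplet(control, control.truth.field)
m = control.mask_insp.data
thr = derive_thresholds([si.data[m]], [se.data[m]], [dv.data[m]], cohort_id="saline-demo")
print(f"alpha_I = {thr.alpha_I:.3f} ml/g, alpha_E = {thr.alpha_E:.3f} ml/g, beta = {thr.beta:.3f} ml/g")

cal = subject.truth.calibration
field, report = demons_register(grey_to_hu(subject.insp_raw, cal),
                                grey_to_hu(subject.exp_raw, cal),
                                landmarks=subject.truth.landmarks)
print(f"TRE: {report.tre_before['mean_um']:.0f} um before -> "
      f"{report.tre_after['mean_um']:.0f} um after registration")

fmap = classify(*svg_triplet(subject, field), thr, subject.mask_insp)
f, lv, nv = class_percentages(fmap, subject.mask_insp)
print(f"class volumes: F {f:.1f}%  LV {lv:.1f}%  NV {nv:.1f}%")
print("Dice vs truth:", {k: round(v, 2) for k, v in
                         evaluate_recovery(subject.truth, fmap)["dice"].items()})
```

Output:

```
alpha_I = 1.129 ml/g, alpha_E = 0.549 ml/g, beta = 0.491 ml/g
TRE: 152 um before -> 17 um after registration
class volumes: F 10.8%  LV 33.1%  NV 56.1%
Dice vs truth: {'F': 0.96, 'LV': 0.6, 'NV': 0.86}
```

The subject was generated with 10% fibrotic and 15% low-ventilation lung;
the classifier recovers the fibrotic burden closely (10.8% vs 10%).
Registration reduces the mean landmark error from ~3 voxels to well under
one 50 µm voxel. The LV class is intrinsically over-called under noise:
by construction of the percentile threshold, 25% of healthy parenchyma
lies below β, which inflates LV at the expense of NV (see
`docs/methods.md`, Limitations).

The same chain is scriptable from the shell — `microvent phantom`,
`calibrate`, `register`, `ventilate`, `thresholds`, `classify`,
`biomarkers`, `histo`, or `microvent run-all --config study.yaml` for a
whole study manifest.

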