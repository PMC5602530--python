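# pdrkit

Analysis pipeline for the **perihematomal diffusion-restriction rim (PDR)**
in hyperacute intracerebral hemorrhage (IPH, ≤ 6 h from symptom onset).

In the first hours after an intraparenchymal bleed, a rim of restricted
water diffusion — hypointense on the ADC map, hyperintense on b1000
diffusion-weighted images, without corresponding FLAIR hyperintensity —
frequently appears adjacent to the outer border of the perihematomal
edema (PHE). `pdrkit` packages the full quantitative workflow needed to
study this finding:

* **Synthetic multimodal phantoms** (`pdrkit.phantom`): co-registered
  FLAIR / b1000 / ADC / T2* volumes with ground-truth clot, edema and
  rim masks. Compartment ADC is drawn from split-normal distributions
  whose medians/IQRs are the values observed in hyperacute patients
  (PDR 624.5 [598.5–670], IPH 789 [710–890], PHE 1030 [948–1110], all
  ×10⁻⁶ mm²/s), with ~20 % T2* "blooming" of the clot and a left–right
  symmetric background brain.
* **Automated ROI procedure** (`pdrkit.segmentation`): integer-shift
  registration, clot segmentation on T2* refined on FLAIR (removing the
  blooming margin), whole-lesion segmentation on FLAIR, PHE = lesion −
  IPH, a contralateral **mirror region** (lesion reflected across the
  midsagittal plane, auto-corrected), and rim detection by the
  mirror-referenced rule

  &nbsp;&nbsp;&nbsp;&nbsp;ADC ≤ median_mirror − 1.5 · SD_mirror &nbsp; AND &nbsp; b1000 ≥ median_mirror + 1.5 · SD_mirror

* **Quantification** (`pdrkit.quantify`): ROI volumes in cc, P25 / mean /
  median / P75 ADC, and relative ADC (rADC = ROI median / mirror median).
* **Cohort statistics** (`pdrkit.stats`): Pearson χ² (uncorrected),
  two-sided Fisher exact (point-probability ordering), Mann–Whitney U
  (exact for small samples), Kruskal–Wallis, Pearson correlation, and
  multivariate logistic regression by IRLS with Wald intervals — all
  implemented directly and cross-checked against independent oracles.
* **Synthetic cohorts** (`pdrkit.cohort`): 83-patient-style tables with
  PDR prevalence 56/83, Table-style marginals, and a log-linear
  PDR-volume/IPH-volume coupling (target r ≈ 0.65).

## Worked example

```python
from pdrkit import PhantomSpec, run_case, SegmentationParams, dice_coefficient
from pdrkit.phantom import PDR

case, seg, quant = run_case(PhantomSpec(), seed=42, params=SegmentationParams())
print(seg.pdr_positive, seg.pdr_volume_cc)
```

prints, for the default phantom (rim present):

```
PDR positive : True (7.27 cc)
ADC cutoff   : 796.9 - 1.5 x 62.8 = 702.7
IPH  median ADC   797.0  (10.4 cc)  rADC 1.000
PHE  median ADC  1022.8  (19.6 cc)  rADC 1.283
PDR  median ADC   618.8  (7.3 cc)  rADC 0.777
rim Dice vs truth: 0.915
```

The mirror region of healthy contralateral tissue gives an ADC cutoff of
702.7×10⁻⁶ mm²/s; the detected rim median (618.8) sits far below it and
its rADC (0.777) below the 0.90 bound that characterises the rim, while
the edema rADC (1.283) stays above 1.10 — the diffusion signature the
pipeline is built to measure. The rim overlaps the ground-truth rim with
Dice 0.915.

A shell interface wraps the same stages:

```sh
pdrkit simulate --n 10 --seed 7 --out sim/
pdrkit segment --flair sim/case_0000/flair.nii --adc sim/case_0000/adc.nii \
    --b1000 sim/case_0000/b1000.nii --t2star sim/case_0000/t2star.nii \
    --brain sim/case_0000/brain.nii --out seg/
pdrkit stats --cohort sim/cohort.csv --out report.json
pdrkit run --seed 7 --n 10 --out run/        # all stages + manifest
```

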