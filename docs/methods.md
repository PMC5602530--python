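# Methods

## The measurement problem

In hyperacute intracerebral hemorrhage (≤ 6 h from symptom onset) a rim
of restricted diffusion (PDR) is commonly found at the outer border of
the perihematomal edema (PHE): low ADC, bright b1000, no corresponding
FLAIR hyperintensity. Quantifying it requires a chain of ROI operations
— clot segmentation, edema segmentation by subtraction, a contralateral
reference region, and a mirror-referenced ADC threshold. `pdrkit`
implements that chain as reproducible code and supplies a synthetic
ground truth to validate every link.

## Phantom model

A phantom is a brain-shaped ellipsoid (default radii 56×56×36 mm on a
64×64×40 grid of 2 mm isotropic voxels) containing in one hemisphere:

* **IPH**: a solid ellipsoid (default radii 15×13×13 mm ≈ 10.6 cc,
  within the interquartile range of clot volumes seen clinically);
* **PHE**: a shell of constant Euclidean thickness (default 6 mm) around
  the clot, measured by the distance transform from the clot surface;
* **PDR** (optional): a 2 mm shell immediately outside the PHE border.
  No rim thickness is reported clinically; a one-voxel rim matches the
  "thin rim adjacent to the edema border" morphology. Note the full
  shell is ~7–9 cc, larger than typical measured rim volumes (~2 cc),
  because real rims are usually partial; detection and volumetry do not
  depend on this choice.

The first grid axis is left–right; the midsagittal plane is its central
plane and the background brain is symmetric about it, so the mirrored
lesion always samples statistically identical healthy tissue. Geometry
that leaves the brain or touches the midline is rejected.

### Signal model

Per-voxel ADC is drawn per compartment from a **split normal**: a
standard normal deviate scaled by (median − P25)/z₇₅ below zero and
(P75 − median)/z₇₅ above (z₇₅ ≈ 0.6745), so the population median and
both quartiles equal the printed compartment values exactly, including
their asymmetry. Defaults (×10⁻⁶ mm²/s): PDR 624.5 (598.5–670), IPH 789
(710–890), PHE 1030 (948–1110), background brain 800 (760–840).

FLAIR, b1000 and T2* are piecewise-constant unitless levels plus
Gaussian noise (no MR physics): edema markedly FLAIR-hyperintense (180
vs background 100), clot only mildly so (105, hyperacute blood), rim
not hyperintense (105); rim bright on b1000 (160); clot dark on T2*
(40) and dilated by 20 % of its volume (nearest-voxel dilation with
deterministic tie-breaks) to emulate susceptibility blooming. Per-
modality rigid offsets (whole voxels) model imperfect co-registration.
All randomness flows from one `numpy` generator per (spec, seed), so
regeneration is bit-identical.

What the phantom does **not** emulate: partial-volume averaging, bias
fields, anisotropic paper-style slice spacing by default (supported via
`voxel_spacing_mm`), irregular lesion shapes, partial rims, CSF/skull,
and pathology in the contralateral hemisphere. Passing tests therefore
demonstrate the correctness of the ROI arithmetic and thresholds under
the stated signal model, not reader-level performance on clinical scans.

## ROI procedure

1. **Registration**: exhaustive integer-shift search (default radius 3
   voxels) maximising normalised cross-correlation; ties broken by
   smallest shift, then lexicographically. Real 6-DOF registration is
   out of scope; translations are what the phantoms contain and are
   exactly testable.
2. **IPH**: largest 26-connected component of T2* below brain median −
   2 × robust SD (1.4826 × MAD, so the lesion itself cannot inflate the
   reference spread). The blooming margin is removed on FLAIR: marginal
   voxels whose FLAIR is closer to the surrounding (edema) level than to
   the clot-core level are dropped, provided the two reference levels are
   separated by > 3 × the local noise. Components below 0.1 cc yield a
   flagged empty mask.
3. **Lesion**: FLAIR-hyperintense components (> brain median + 2 ×
   robust SD, outside the clot, ≥ 0.1 cc) that touch the clot, united
   with the clot. **PHE = lesion − IPH** exactly.
4. **Mirror region**: the lesion reflected across the midsagittal plane
   (index i → N−1−i on axis 0), minus non-brain voxels and the lesion
   dilated by 2 voxels; fewer than 50 survivors is an error.
5. **PDR detection**: candidate region = PHE plus a 1-voxel outer shell
   (both sub-regions selectable), never inside the clot; a voxel is rim
   iff ADC ≤ mirror median − f·SD **and** b1000 ≥ mirror median + f_b·SD
   with f = f_b = 1.5 by default. The mirror SD is the sample SD of
   voxel values (not of per-slice medians). Components < 0.05 cc are
   discarded; positivity requires ≥ 0.1 cc. All thresholds are
   inclusive, logged with their computed values, and raising f can only
   shrink the detected rim (monotonicity holds by construction).

The "≤ 1.5 standard deviations of the median" rule is read as
cutoff = mirror median − 1.5 × mirror SD — the only reading that uses
both statistics. The b1000 criterion has no published numeric form; a
symmetric mirror-based rule with its own factor is used.

## Quantification

Volumes are voxel count × voxel volume / 1000 (cc); slice spacing
stands in for thickness+gap so volumetry matches the contiguous-grid
assumption of the ROI arithmetic. Quantiles use linear interpolation
between order statistics (no convention is published; this is the
`numpy` default and is tagged in the pipeline config). rADC = ROI
median / mirror median, reported as a fraction. When the detected rim
lies inside the PHE its voxels are excluded from PHE statistics by
default (configurable) so compartments do not mix.

## Cohort generator

Defaults mirror the 83-patient baseline: prevalence 56/83, age 65
(56–78), 54/83 male, IPH volume 12.9 (7.9–26.6) cc (log-split-normal),
NIHSS 11 (7–15) admission / 7 (3.5–11) discharge, onset bins
19/32/10/3/2/2 plus 15 wake-up cases, 66:15 deep:lobar, 2/83
infratentorial, 7/83 deaths, 4/83 removals. Because the rim occurs in
supratentorial hemorrhage only, infratentorial cases are allocated among
PDR-negatives at a rate preserving the configured marginal fraction.
Rim volume couples to clot volume through a log-linear link
(slope = ρ·σ_rim/σ_clot, default ρ = 0.70 giving raw-scale r ≈ 0.6–0.65);
the skewness of the clot-volume distribution shifts the realised rim
median slightly above the nominal 1.98 cc (~2.2 cc). Wake-up cases get
a latent onset drawn uniformly in (0, 6] h; their bin enters models as
3.0 h (window midpoint). NIHSS at admission and discharge are drawn
independently — a simplification; their joint distribution carries no
weight in any analysis here.

## Statistical battery

All tests are implemented directly; scipy supplies only distribution
functions, and scipy.stats / statsmodels serve as independent oracles in
the test suite.

* **Pearson χ²** without continuity correction (the convention that
  reproduces the printed gender statistic 1.430; Yates would not).
* **Fisher exact**, two-sided by point-probability ordering over the
  hypergeometric support (reproduces the printed 0.299 and 0.103;
  verified against exact-integer enumeration for every table with
  N ≤ 30). One printed mortality p (0.711) is *not* reproducible by
  this (or scipy's) convention — enumeration on the implied table gives
  1.0 — and is deliberately not asserted.
* **Mann–Whitney U** (reported as min(U₁,U₂)): exact two-sided p by the
  standard counting recurrence (equivalent to full rank-assignment
  enumeration) when the smaller sample has ≤ 8 observations and no
  ties; otherwise the normal approximation with tie and continuity
  corrections.
* **Kruskal–Wallis** with tie correction, χ² reference on k−1 df.
* **Pearson correlation** with the two-sided t-based p.
* **Logistic regression** by IRLS/Newton with step-halving; convergence
  at |Δ log-likelihood| < 1e−8, max 100 iterations; Wald 95 % intervals
  on the exp scale. Separation is flagged (`converged=False`, warning)
  rather than raised. The clinical source labels exponentiated
  coefficients "HR"; they are odds ratios and are labelled as such.
  The multivariate model uses male gender, age per 10 years,
  deep-vs-lobar location (infratentorial cases excluded, as the
  published coefficient is deep vs lobar), onset-to-MRI time in hours,
  admission NIHSS and log IPH volume. Significance is two-sided 0.05
  with no multiplicity correction, matching the source convention.

## Problem sizes and tolerances

The validation batches use 50 phantoms (25 with rim) on the default
64×64×40 grid — enough that pooled compartment medians are estimated to
±2×10⁻⁶ mm²/s and detection sensitivity/specificity to a few percent,
while the whole suite runs in well under a minute. Parameter-recovery
bands (±15×10⁻⁶ mm²/s on pooled medians, 10 % on mean logistic
coefficients at n = 500 over 20 seeds) reflect the Monte-Carlo error of
these sizes. Determinism is asserted byte-for-byte on full pipeline
re-runs.

## Known limitations

* Only integer-translation registration; rotations/scaling untested.
* Crisp compartment boundaries make segmentation Dice optimistic
  relative to clinical data.
* The rim is a complete shell; partial rims (the common clinical
  morphology) are not generated, so rim volumetry is not calibrated to
  printed rim volumes.
* The SPSS importer requires `pyreadstat` (optional) and an explicit
  column map, since the supplementary file layout is undocumented.
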