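# Methods

## The measurement model

A lesion is observed in four co-registered CT phases (PCP, CMP, NP, EP) as
voxel grids of Hounsfield units with anisotropic spacing (default 1.0 mm
slice thickness, 0.7 mm in-plane). All quantitation is ROI-based:

* **ROI(1)** (50–100 mm²) and **ROI(2)** (10–20 mm²) are circular ROIs
  centered on strongly enhancing tumor regions identified in the
  corticomedullary phase, where ccRCC's hypervascular patches are most
  conspicuous. Their geometry is defined once on CMP and copied to the
  other phases (similar-sized ROI at a similar level).
* **ROI(3)** covers the whole tumor on its largest cross-section, with
  every ROI pixel at least a safety margin (default 2.5 mm, the midpoint
  of the 2–3 mm rule) inside the tumor boundary. It is defined on EP —
  where the boundary is clearest — and the geometry copied exactly to the
  other phases. Whether radiologists re-draw or copy this ROI per phase is
  underdetermined by the protocol description; exact geometry copy is
  implemented, which on co-registered volumes makes the propagated and
  re-placed variants coincide.

Readings are averaged as a flat grand mean over enhancing regions × three
adjacent slices (the ROI's slice ± 1) × repeats (default 2; 3 for ROI(3))
× observers (default 2). The protocol text specifies per-level averaging
but not the nesting order; for balanced designs the flat mean is
equivalent. Observer/repeat variability is modeled as i.i.d. Gaussian
reading noise (default SD 1 HU) added to each reading.

Derived parameters: `NEV = AVT_phase − AVT_PCP` (HU),
`RER = AVT/AVC × 100` (%), `HDT = SD within ROI(3)` (HU),
`SHR = HDT/HDP × 100` (%). HDT uses the population SD (`ddof=0`,
configurable); at whole-tumor pixel counts the n vs n−1 distinction is
negligible. RER/SHR are reported to 2 decimals in presentation output
while full precision is kept internally.

### Enhancing-region detection

Candidate voxels are found on a lightly smoothed CMP grid (Gaussian,
σ = 0.8 mm) so single-voxel noise neither fragments a patch nor bridges
two. The threshold is the **maximum** of (a) the 90th percentile of
within-tumor smoothed intensity and (b) a robust noise floor,
median + 3 × 1.4826 × MAD. A pure percentile rule necessarily flags ~10%
of voxels even in a homogeneous tumor, so the floor is what makes "no
enhancing regions" a reachable outcome; both knobs are configurable.
Connected components smaller than 20 voxels are dropped. Components with a
length-to-width ratio above 3 are classed as intratumoral vessels and
excluded, mirroring the placement rule to avoid vessels; the ratio is
computed as `V/(π t²) / (2t)` with `t` the deepest inscribed distance
(EDT maximum), which stays large for curved tubes where principal-axis
moments would not. Voxels under a supplied cyst/calcification mask are
never included. If an ROI of the minimum area cannot be centered on a
region's intensity-weighted centroid, placement falls back to the largest
inscribed circle (recentered to the deepest support pixel when the
centroid lies in an excluded hole, e.g. a central cyst).

## Statistics

* Categorical variables: Pearson chi-square **without** continuity
  correction — this is the variant that reproduces the published cohort
  statistics exactly; Yates-corrected values do not.
* Quantitative variables: Lilliefors-corrected Kolmogorov–Smirnov (the
  common statistical-package behavior when mean/SD are estimated) at
  α = 0.05 in each class dispatches to the **equal-variance pooled** *t*
  test (again the variant that reproduces the published statistics; Welch
  does not) or to the Mann–Whitney U test reported as a tie-corrected
  normal *Z* without continuity correction. Groups with fewer than 4
  observations cannot be normality-tested and go to the rank test. For
  small tie-free samples (both n ≤ 8) the exact permutation p-value is
  used.
* Group sizes 74/31 are used when reproducing summary-statistic *t*
  values; the published quantitative table's header (57/28) is
  inconsistent with the cohort and with its own printed *t* statistics.
* Agreement: two-way random-effects, absolute-agreement, single-measures
  ICC — ICC(A,1) — with 0.75 as the good-agreement bar.
* ROC: rank-based AUC, oriented so the reported value is ≥ 0.5 (the
  direction flag records inverted markers), with Hanley–McNeil SE for the
  95% CI, clipped to [0, 1]. ccRCC is the positive class throughout.

## Logistic models

Published per-phase coefficient sets are shipped as a versioned JSON
resource and applied through the standard logistic link. Coding: male = 1,
morphology feature present = 1, ccRCC = 1; this map makes the published
coefficient signs consistent with the cohort's class compositions and
separates the worked example correctly. Classification threshold 0.5 (none
is published). The cystic-degeneration status of the worked-example
lesions is not stated; absent is assumed.

The published NP-model odds-ratio column disagrees with its own
coefficients (up to 34% relative), while the geometric means of its
printed CIs match exp(coefficient); the coefficients are therefore treated
as authoritative and the inconsistency is asserted explicitly in the test
suite. The published EP model carries an SHR_EP coefficient of 1.788 on a
percent-scale variable, which saturates the link for realistic values —
it is reproduced verbatim, and performance rates with empty denominators
(e.g. NPV when nothing is predicted negative) are reported as NaN.

Refits use maximum likelihood (statsmodels); (quasi-)complete separation —
where the MLE does not exist — raises an explicit diagnostic. Variable
screening restricts candidates to those univariately significant at
α = 0.05 and then runs **backward elimination by likelihood-ratio test**
(the selection algorithm is not named in the protocol; backward-LR is the
default, configurable). When the full candidate pool itself separates at
the cohort's sample size, the weakest univariate candidates are shed until
the MLE exists before elimination starts.

## What the synthetic generators emulate — and what they do not

The **tabular simulator** draws every quantitative column from its
published per-class normal marginal (means ± SD) and categoricals from the
published frequencies, with an optional single equicorrelation level
(default 0, since only marginals are published). Consequently NEV/RER/SHR
columns are *not* arithmetically linked to their AVT/HDT inputs in this
path — each is its own marginal — whereas the voxel pipeline produces
internally consistent records. Passing tests on such cohorts show that the
statistics and models behave correctly under the published calibration,
not that the generator reproduces real inter-feature covariance.

The **voxel phantom** is piecewise-constant tissue HU plus i.i.d. Gaussian
noise: tumor base HU per phase drawn from the whole-tumor-ROI class
marginals; compact enhancement patches near the margin (contrast scaled
1.0/0.4/0.25 into CMP/NP/EP, absent pre-contrast); arc-shaped vessel tubes;
non-enhancing 12 HU cysts; a thin hypoattenuating pseudocapsule rim; a
homogeneous cortex block whose HU is back-solved from the published
AVT/RER relation (≈ 188/148/137 HU in CMP/NP/EP); and a psoas cylinder
whose per-phase image noise reproduces the published heterogeneity
denominators (HDP ≈ 7.7–9.6 HU). In heterogeneous lesions roughly half of
the enhanced-phase HDT target is assigned to unstructured texture noise
and the rest arises from the structures; the split is a calibration
choice, so phantom HDT matches the published class *ordering* rather than
its exact magnitudes. No beam hardening, reconstruction kernels, partial
volume, registration error, or DICOM semantics are modeled; masks are
inputs, not segmentations.

Determinism: one integer seed governs each study; per-lesion generators
use spawned child seeds, so cohorts are reproducible and lesions
independent.

## Problem sizes

The shipped studies use sizes chosen for a single-CPU run: 200 calibrated
cohorts (74/31 each) for the refit phase-ordering comparison, 1000 null
cohorts for the dispatch type-I error, a 16-lesion phantom cohort for the
measurement study, 10 homogeneous phantoms for parameter recovery, and 50
replicates at n = 1000 for selection-consistency checks.

## Known limitations

* Phantom heterogeneity is stylized; HDT/SHR magnitudes on heterogeneous
  phantoms exceed the published means even though orderings reproduce.
* The tabular simulator's independent marginals understate the
  collinearity of real enhancement parameters, which flatters stepwise
  selection stability.
* In-sample AUC is used for refit comparisons (as in the reference
  analysis); no cross-validation or external validation is performed.
* The reduced CMP model without the subjective cystic flag is only
  qualitatively checkable (no published coefficients).
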