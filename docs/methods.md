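# Methods

## The detection model

Intraplaque hemorrhage (IPH) appears hyperintense on heavily T1-weighted
gradient-echo images (MP-RAGE) via the T1-shortening of methemoglobin. The
method detects and quantifies it per axial slice in four stages:

1. **Reference measurement.** Raw intensities vary across patients and
   slices because surface-coil sensitivity decays with depth. Each slice gets
   a scalar reference `R`:
   - `scm` — mean intensity inside the sternocleidomastoid contour,
     restricted to a 4 cm diameter circular ROI centred at the carotid lumen
     (the clipping limits how much superficial coil gain leaks into the
     reference). If the contour misses the ROI entirely the slice is flagged
     invalid for this reference and excluded, not errored.
   - `adjacent_muscle` — mean intensity inside a nearby deep-muscle contour
     drawn isointense with normal carotid wall; no ROI clipping, the region
     is already local.
   - `local_median` — median intensity inside the 4 cm ROI; fully automatic.
2. **Thresholding.** Inside a loose reviewer-drawn outer-wall contour,
   pixels with `I > t·R` (strict inequality) form the IPH mask. No
   morphology or connected-component post-processing is applied. Area is
   mask-pixel count × pixel area, using the slice's own (reconstructed)
   spacing. Presence is any supra-threshold pixel (a `min_area_mm2`
   parameter exists, default 0, because no minimum-lesion rule is part of the
   method). The slice score `max I/R` over the wall region reproduces the
   presence call at every threshold.
3. **Threshold selection.** ROC over the slice scores vs histology presence:
   candidate thresholds are midpoints between consecutive distinct scores
   plus sentinels beyond both extremes; sensitivity = P(score > t | IPH+),
   specificity = P(score ≤ t | IPH−); AUC by trapezoid, which at these
   candidates equals the tie-corrected Mann–Whitney concordance. The
   operating threshold maximizes Youden's J on a 0.1-spaced lattice
   (candidates snapped to the lattice, operating points re-evaluated there),
   ties broken toward the **larger** threshold — fewer false positives, the
   clinically preferred direction.
4. **Cross-validation.** Patient-level leave-one-out: for each patient the
   threshold is fitted on all other patients' included slices and applied to
   the held-out slices. Held-out predictions are pooled (micro-averaged)
   before computing sensitivity/specificity, because single-patient folds
   often lack one class. Fold-threshold spread (max − min) is reported as the
   robustness diagnostic.

### Histology fusion and subsets

Sections are matched to slices by signed distance to the carotid bifurcation:
nearest same-patient slice, within ±0.5 mm (half the 1 mm slice thickness;
configurable, since no tolerance is canonical). One slice may collect several
sections: presence is the **any** rule, truth area the **mean** over matched
sections, and the calcified fraction the IPH-area-weighted mean (weighting
preserves the fraction's meaning over the pooled area; the fusion rule for
this quantity is not canonical either and is a package choice).

Analysis subsets drop IPH-positive slices with truth area `< π(0.63·x)²` mm²
(x = 1 → 1.2469, printed clinically as 1.25; x = 1.5 → 2.8055, printed as
2.80 — the cutoff constant is pinned to the 0.63 mm *acquired* resolution, a
deliberate constant distinct from the reconstructed pixel size used for
areas) and/or heavily calcified slices (`calcified_fraction > 0.5`, strict).
IPH-absent slices are never dropped. Both comparisons are strict per the
table definitions; the two rules commute and the filter is idempotent.

### Correlation reporting

Pearson r between detected and truth areas is reported twice: over all
included slices and over truth-positive slices only. The all-slices value is
inflated by the many (0, 0) pairs from IPH-absent slices, so the
positive-only value is the primary column; which population underlies the
original clinical tables is ambiguous, and reporting both documents that.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `roi_diameter_mm` | 40 | mm | reference ROI centred at the lumen |
| grid step (`grid_step`) | 0.1 | ratio | thresholds are reported to one decimal clinically; a coarser lattice also stabilizes ties |
| `half_window_mm` | 0.5 | mm | half the 1 mm slice thickness: nearest-slab matching |
| area cutoffs | 0, 1.25, 2.80 | mm² | π(0.63·x)², x ∈ {1, 1.5} |
| `calcified_cutoff` | 0.5 | fraction | "heavily calcified" is >50 % of IPH area |
| `min_area_mm2` (detection) | 0 | mm² | no minimum-lesion rule is defined; any supra-threshold pixel counts |

## The phantom: what it emulates, and what a green test proves

Each synthetic slice contains, on a dim soft-tissue background (0.2× muscle):
an SCM ellipse near the top edge (skin side), a deep adjacent-muscle ellipse
beside the artery, and a vessel cross-section — lumen disk (0.1×, flowing
blood suppressed), wall annulus (1.0× muscle, i.e. isointense), with an IPH
disk painted inside the wall band at `iph_contrast_ratio`× muscle (default
1.6, the muscle-relative optimum regime) and, with probability
`calcified_probability`, a concentric hypointense (0.3×) calcified sub-disk.
The image is multiplied by an exponential coil field `exp(−depth/decay)`
(depth from the top edge; default decay ∞ = uniform coil, 60 mm when the
coil effect itself is under study), Gaussian noise of σ =
`noise_sigma_ratio`× muscle (default 5 %) is added, and the result clipped
at 0.

Cohort defaults mirror the clinical study's scale: 14 patients × 10 slices,
47 % slice-level prevalence, and `calcified_probability = 0.45` with the
calcified fraction uniform on (0.1, 0.9), which makes ≈22 % of positive
slices heavily (>0.5) calcified — the rate observed clinically. One named RNG
stream per patient makes cohorts reproducible and patients independent.

Geometry is circles and ellipses only, so every painted truth mask is an
exact pixel-centre rasterization with a closed-form area — the oracle for
the detection stage. Reference contours are polygons inscribed in the
painted ellipses, hence always interior to their tissue, so a noiseless
reference mean equals the tissue value exactly.

What the phantom does **not** emulate: MR physics (no T1/TI/TR signal
equation; contrast ratios are painted directly), Rician noise statistics
(Gaussian is second-order equivalent at these contrasts and keeps oracles
exact), partial-volume edges, motion/flow artifacts, irregular lesion and
vessel shapes, and histology shrinkage or registration error (phantom
"histology" is exact). A green pipeline test therefore establishes
correctness of the *computational* chain — rasterization, normalization,
thresholding, matching, ROC/Youden, LOOCV bookkeeping — not clinical
performance on real images.

Two deliberate consequences: (i) the phantom's local median sits on the dim
background, so median-referenced optimal thresholds are higher than the ≈2.2
seen in real necks, where the 4 cm ROI is mostly muscle-intense tissue — the
direction of all comparisons is unaffected; (ii) a heavily calcified IPH can
be *constructed* to be undetectable (its supra-threshold rim thinner than a
pixel), which is exactly the clinical failure mode — so "perfect detection"
statements are only meaningful on calcification-free noiseless cohorts, and
the degenerate-perfection test disables calcification.

## Numerical conventions

- **Coordinates:** mm, origin at the centre of pixel (0, 0), x along
  columns, y along rows; anisotropic spacing supported everywhere.
- **Pixel membership:** pixel-centre test (no area weighting). Polygons use
  even–odd ray casting with the half-open convention (a centre exactly on a
  lower/left edge is inside), so abutting polygons tile without double
  counting; circles use `distance ≤ radius`.
- **Median:** even counts → midpoint of the two central order statistics.
- **Strictness:** detection uses `>` ("exceeded"); the SCM exclusion is
  purely the empty-intersection condition with the 4 cm ROI (no separate
  distance test); subset rules use strict `<` (area) and `>` (calcification).
- **Ties in J:** broken toward the larger threshold; the lattice keeps score
  jitter from manufacturing spurious distinct optima.
- **Degenerate inputs:** single-class label sets, single-patient cohorts,
  empty ROIs and zero-variance correlations are hard errors or NaN-with-
  warning, never silently absorbed; invalid references are values, not
  exceptions, so exclusion counts are explicit.
- **Determinism:** every stochastic element derives from one integer seed;
  cohorts, CSVs and images regenerate byte-identically.

## Known limitations

- Slice-level analysis only: no within-slice localization scoring and no 3-D
  lesion linking across slices.
- Thresholds are optimized on presence/absence, not on area agreement; area
  correlation is a by-product (and is capped by noise at the threshold
  boundary and by calcified cores, as the worked example shows).
- No coil-sensitivity correction is implemented; the SCM reference's
  depth bias is demonstrated, not corrected.
- No confidence intervals on AUC or between-reference significance tests.
- Contours are inputs; the package neither draws nor QCs them beyond
  simplicity/containment validation.
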