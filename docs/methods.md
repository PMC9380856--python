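# Methods

## Measurement model

All measurements operate on a 2D axial slice: an intensity image, one
binary mask per LN side, a CSF mask, and a `MeasurementFrame` giving the
isotropic pixel spacing (mm/px) and the anterior–posterior reference line
position `x_ref` (mm). Selecting the slice and placing the reference line
on real MRI is a radiologist's step and is out of scope; the pipeline takes
both as inputs.

Conventions, chosen to mirror caliper measurements on a PACS workstation:

- **Chords are endpoint-to-endpoint extents**: per row (or reference
  column), `(last − first + 1) · spacing`. On convex ROIs this equals the
  in-mask run sum (a tested property); on ROIs with interior signal
  dropout the extent is robust, which is why it is the default. A
  `convention="run_sum"` switch exists for sensitivity analysis.
- **`x_ref` maps to the pixel column whose footprint contains it** (pixel
  centres at `(j + 0.5)·spacing`). Sub-pixel interpolation would be false
  precision at 0.5–0.8 mm spacing.
- **Intensity SD is the sample SD** (n−1), matching clinical ROI tools; a
  single-pixel ROI reports SD 0 with a warning.
- Public quantities are always mm / mm² / signal units, never pixels.

Raster accuracy (tested): chords within 2 px of the closed forms and area
within 3 % at 0.5 mm/px for LN-scale ellipses (LL 13–19 mm, area
100–200 mm²). The 3 % area bound degrades for much smaller ROIs, where the
boundary-pixel fraction grows.

## Index aggregation

Each subject carries 2 raters × 2 sides of raw measurements plus per-rater
CSF statistics. Plain indices average sides within rater, then raters.
`SLLr` averages the per-side ratios (each side's SL/LL first); the
alternative — dividing averaged SL by averaged LL — differs on asymmetric
subjects and is deliberately not used, because the ratio is defined per
sketched side. Corrected indices select a side from the *rater-mean* side
values: the smaller SL (cSL, with cSLLr using the same side's LL) and the
larger SIsd (cSIsd_LN). Exact ties select "left" and set a flag —
probability zero on continuous data, but determinism matters. nSIm
normalizes each side's SIm by the same rater's CSF mean
(`200·SIm/SIm_CSF`) before averaging.

Tested invariants: cSL ≤ SL and cSIsd_LN ≥ SIsd_LN per subject (min/mean
and max/mean ordering); all indices invariant under rater relabeling;
corrected values invariant under side relabeling (the side label flips);
nSIm invariant under global intensity rescaling. Partial records are
rejected, not imputed.

## Statistics

- **Group comparison** (per index, all groups jointly): if every group
  passes Shapiro–Wilk at α = 0.05, one-way ANOVA with Fisher's LSD
  pairwise comparisons — plain pairwise t-tests on the pooled within-group
  variance with df = N − k and *no* multiplicity correction, which is what
  LSD means. Otherwise pairwise two-sided Mann–Whitney U (exact for small
  untied samples, normal approximation with tie correction otherwise). A
  constant-valued group routes to the nonparametric path with a warning.
  One failing group forces the U test for all pairs of that index, so each
  index reports a single test type.
- **ICC(2,1)**: two-way random effects, absolute agreement, single
  measurement, from the mean squares of the subjects × raters table,
  computed on per-rater side-mean values. The variant is emitted in the
  result so alternatives can be compared; the choice is the standard one
  for inter-rater reliability of continuous measurements, and absolute
  agreement (not consistency) is the clinically relevant notion — a
  constant rater offset should and does degrade it. Bands: < 0.3 slight,
  0.3–0.7 moderate (boundaries inclusive), > 0.7 good.
- **ROC**: AUC from the rank (Mann–Whitney) statistic with midranks for
  ties — identical to the trapezoidal empirical ROC area. Orientation is
  chosen so the positive group lies on the positive side (AUC ≥ 0.5) and
  is reported. Candidate cutoffs are midpoints between adjacent sorted
  unique values plus sentinels outside the data range; the returned cutoff
  maximizes Youden's J, with ties broken toward higher sensitivity.
  Midpoint cutoffs give the same confusion matrices as observed-value
  cutoffs but do not depend on scanner units.
- **Full analysis**: comparisons for all 12 indices; ROC for every index
  with p < 0.05 between the positive group and each comparison group; ICC
  per index per group. No confidence intervals for AUC or ICC are
  computed, and no combined-index classifier is fit.

## Synthetic cohorts

The phantom generator emulates the study conditions: three groups (MSA-P,
PD, CG), 19 subjects each, with index distributions given by the shipped
`published_cohort_defaults` configuration (per-group means and SDs of cSL, LL, Area,
SIm_LN, cSIsd_LN, SIm_CSF, SIsd_CSF).

Key design choices:

- **Corrected-side anchoring.** The smaller-SL side is drawn from
  N(csl_mean, csl_sd); the other side adds a half-normal offset whose
  expectation is `asymmetry_delta`. Consequently the smaller-side mean is
  `csl_mean` and the side-mean SL is `csl_mean + asymmetry_delta/2` —
  both the corrected and plain group means are exact expectations of the
  generator, which independent left/right draws cannot achieve (the
  expected minimum of two independent normals sits below both means). The
  intensity SD anchors the *larger* side symmetrically. The asymmetry
  magnitudes are derived from the configured corrected-vs-plain mean gaps
  (`asymmetry_delta = 2·(SL − cSL)` per group: 1.70 / 1.06 / 0.96 mm),
  since no direct left–right difference is configured.
- **Truncation at zero by redraw** for all latent draws. For most indices
  the effect is negligible; for SIm_LN (mean 698, SD 434 in MSA-P, ~5 %
  negative mass) it raises the realized mean by ≈ 7 %. The convergence
  tests therefore compare cohort means against the analytic
  truncated-normal moments, which coincide with the plain ones wherever
  truncation is rare.
- **Geometry feasibility**: a drawn short line exceeding the long line is
  redrawn (100 attempts, then an error).
- **Rater noise** (tabular mode): additive zero-mean Gaussian per
  measurement, defaults 0.5 mm on lengths, 12 mm² on areas, 25 signal
  units on intensities — chosen to land the per-group ICCs of the length
  indices in the moderate-to-good range typical of two-reader caliper
  studies.
- **Image mode**: each subject is rendered as a 256×256 slice at
  0.5 mm/px (Gaussian texture inside ROIs, global noise SD 5, Rician
  noise not modelled — SNR at these magnitudes is high) and measured
  twice through the morphometry module; raters differ by reference-line
  jitter (SD = the length noise) and an independent 1-px mask erosion or
  identity. Dilation is not drawn: against the phantom's hard intensity
  step, a 1-px out-of-ROI ring would dominate the intensity-SD index in a
  way no real partial-volume boundary does.
- **Image-mode geometry**: side ellipses match LL (a = LL/2) and SL
  exactly (the reference line sits at 0.6·a, mirrored posteriorly between
  sides, with b sized so the chord there equals that side's SL). An
  ellipse cannot simultaneously match LL, SL *and* the configured area
  while keeping the reference chord away from its tip, so the rendered
  area is the geometric consequence πab; the tabular mode carries the
  full configured area distribution. Latent subjects whose smaller SL
  falls below 3 px (1.5 mm) are redrawn in image mode — a sub-pixel short
  line cannot be rendered or measured (~2 % of MSA-P draws). The CSF ROI
  is rendered on the same slice; measuring it on a separate slice would
  change nothing measurable.
- **Determinism**: subject *i* of a cohort uses seed `seed + i`, so any
  subject is individually reproducible; fixed seeds reproduce cohorts
  bit-for-bit.

What passing tests do *not* show about real data: the phantom is an
axis-aligned ellipse, not a lens-shaped LN (a shear parameter exists but
defaults to 0); boundary definition on real SWI is far harder than on a
hard-edged phantom, and the image-mode rater model (jitter + erosion)
understates inter-reader segmentation variability; image-mode measured
cSL sits ~0.5–0.8 mm below the latent truth because erosion and
rasterization both shorten chords — group orderings and discriminability
are preserved, absolute means are not. Published patient-level results
(e.g. per-group ICC values) depend on the unavailable raw measurements
and are not reproduction targets; the reproducible anchors are the
large-sample binormal AUCs implied by the group distributions.

## Problem sizes

Law-of-large-numbers checks use 10,000 subjects; binormal ROC simulations
10⁵ per group; ICC recovery 2,000 subjects × 2 raters; selection-stability
checks 100 repeated n = 19/19/19 cohorts. These sizes put Monte-Carlo
error well below the assertion tolerances while keeping the full suite
under half a minute.
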