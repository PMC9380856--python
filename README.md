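# lentimorph

Quantitative morphometry of the lentiform nucleus (LN) on axial
susceptibility-weighted MRI (SWI), and the statistics used to evaluate it as
a marker separating the parkinsonian subtype of multiple system atrophy
(MSA-P) from Parkinson's disease (PD) and controls (CG).

MSA-P narrows the posterior LN asymmetrically while iron deposition makes
its signal inhomogeneous. The measurement protocol captures this with a
handful of caliper-style indices per subject, measured on one axial slice
per side by two radiologists:

- **LL** — longest horizontal line of the sketched LN boundary (mm);
- **SL** — vertical "short line" at a fixed anterior–posterior reference
  position x_ref (mm), and the ratio **SLLr = SL/LL**;
- **Area** (mm²), **SIm_LN**, **SIsd_LN** — ROI area and in-ROI signal
  mean/SD;
- **nSIm** — LN intensity normalized so the CSF mean maps to 200:
  nSIm = 200·SIm_LN/SIm_CSF;
- **corrected indices**: cSL = min(SL_left, SL_right) (rater-mean per
  side), cSLLr = cSL/LL of the same side, cSIsd_LN = max(SIsd_left,
  SIsd_right) — the affected side carries the signal, so the extremum
  beats the bilateral mean.

Downstream statistics: Shapiro–Wilk-gated group comparisons (one-way ANOVA
with Fisher's LSD pairwise tests, or pairwise Mann–Whitney U), empirical
ROC with the cutoff at the maximum Youden index J = sensitivity +
specificity − 1, and two-rater ICC(2,1) (two-way random effects, absolute
agreement) with slight/moderate/good bands at 0.3 and 0.7.

Because clinical SWI data cannot be redistributed, the package ships a
phantom module that renders elliptical LN stand-ins with closed-form
ground truth (LL = 2a, SL(x) = 2b·√(1 − ((x−cx)/a)²), area = πab) and
generates whole three-group cohorts whose index distributions match the
published group means and SDs, including left–right asymmetry and
two-rater measurement noise.

## Worked example

```python
import lentimorph as lm

groups, noise = lm.published_cohort_defaults()          # MSA-P / PD / CG, n=19 each
records = lm.generate_cohort(groups, noise, mode="image", seed=7)
table = lm.indices_table(records)             # one row per subject
report = lm.run_full_analysis(table, lm.per_rater_table(records))
```

With seed 7 in image mode (each subject rendered as a 256×256 slice at
0.5 mm/px and measured twice through the morphometry module) this prints:

```
        cSL    SL  cSLLr  SIsd_LN  cSIsd_LN
group
CG     5.39  6.09   0.33   152.45    162.04
MSA-P  3.55  4.70   0.27   163.09    186.38
PD     6.32  6.93   0.39   128.48    135.07

cSL test: MannWhitneyU p(MSA-P vs PD) = 5e-05
cSL ROC MSA-P vs PD: AUC=0.885 cutoff=3.75 mm sens=0.632 spec=0.947 (lower_is_positive)
ICC(2,1) SL MSA-P 0.876 good
```

Reading: the synthetic MSA-P group shows the expected smaller corrected
short line (3.55 mm vs 6.32/5.39 mm) and larger corrected intensity SD;
cSL separates MSA-P from PD with AUC ≈ 0.89, classifying a subject as
MSA-P when its cSL falls below the 3.75 mm Youden cutoff.

The same pipeline is scriptable from the shell:

```bash
lentimorph report --seed 7 --mode image --outdir out/
# out/measurements.csv, indices.csv, per_rater.csv,
# report.json, comparisons.csv, icc.csv, roc.csv
```

`lentimorph simulate`, `measure`, `indices` and `stats` run the individual
stages; `measure` accepts a slice bundle (NIfTI or PNG + JSON sidecar
carrying pixel spacing and the per-side reference-line positions).

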