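# Methods

## Indices and classification

For a subject with complete anterior measurements, the anterior Bolton
ratio (ABR) is 100 times the sum of the six mandibular anterior
mesiodistal widths over the six maxillary ones; the simplified anterior
tooth ratio (SATR) is the same construction restricted to the lateral
incisors (FDI 32+42 over 12+22). Both are scale-invariant, strictly
increasing in any mandibular width and decreasing in any maxillary width.
Widths are carried in mm at full floating precision; ratios are displayed
as percent to 2 decimals.

Classification is against a normative range mean ± k·SD with k = 1 by
default, because the shipped decision thresholds are exactly one sample SD
from the mean (SATR: 85.69 ± 3.57 → 82.12/89.26; anterior Bolton norm:
78.8 ± 1.72 → 77.08/80.52). Bounds are inclusive to the normal category,
and the three labels are totally ordered (deficient < normal < excess) so
classification is monotone in the ratio. Two numerical guards apply:

- boundary comparisons carry a 1e-9 relative epsilon so a threshold stated
  in decimal (89.26 = 85.69 + 3.57) remains inclusive despite binary
  floating-point representation;
- a `strict` rounding mode first clamps a standard's mean and SD to two
  decimals, reproducing published tables exactly when a standard was
  estimated at higher precision. Whether historical cohorts were
  classified with rounded or unrounded thresholds is not knowable, so both
  modes exist; `full` is the default.

Sample SDs use the n−1 denominator throughout (the SPSS descriptive
convention). `establish_standard` on a constant list yields a degenerate
range {mean}; on fewer than two values it raises.

## Key-tooth derivation

Subjects are stratified by ABR into low (< 77.08%), normal
(77.08–80.52%, boundaries included) and high (> 80.52%). For each of the
six arch × tooth-type combinations, bilateral-mean widths are compared
between each pair of groups with an independent two-sample t-test — 18
tests, uncorrected for multiplicity, matching the historical workflow; a
Bonferroni/Holm option would be an extension, deliberately off by default.
The t statistic is computed from closed forms. The default variant is
`auto`: the pooled statistic when Levene's variance-homogeneity test
(mean-centred) has p > 0.05, Welch otherwise; the variant actually used is
recorded in every test row for audit. Degenerate inputs: two constant
samples with equal means give t = 0, p = 1; with unequal means the
statistic is undefined and raises.

The key tooth per arch is the type with p < α (default 0.05) in all three
comparisons. No qualifying type returns none; more than one raises an
ambiguity error rather than picking silently — with large cohorts
stratified on their own ratio, every component tooth correlates with the
grouping and secondary types can reach significance, and that situation
should be seen, not hidden.

## Association and prediction

Pearson's r and the simple OLS line relating SATR (x) to ABR (y) are
computed from the usual closed forms (r from centred cross-products, p
from t = r·√((n−2)/(1−r²)) on n−2 df; slope = cov/var, intercept from the
means). Regression operates on ratio fractions, not percents — a printed
equation of the form y = 0.503 + 0.328x is only dimensionally consistent
on fractions — and percent-scale inputs are converted (values with median
magnitude above 2 are treated as percents). Zero variance in either
variable raises. scipy's implementations are used in the test suite as
independent oracles, never as the computation path.

## Diagnostic evaluation

The screening diagnosis (SATR) is cross-tabulated against the gold
standard (ABR) over the three categories, then collapsed to 2×2 by pooling
deficient and excess into "abnormal". Sensitivity, specificity, PPV and
NPV are computed with **normal as the positive condition** — the published
2×2 (59, 15 / 17, 51) yields the published sensitivity 77.63% only under
this convention (59/76), so it is the default and a regression test pins
it; `positive="abnormal"` swaps sensitivity↔specificity and PPV↔NPV. A
zero denominator leaves that metric NaN and flagged, the others still
computed. Accuracy is deliberately not part of the standard report.

The "consistency" test is a Pearson chi-square, without continuity
correction, on the 2×3 table whose rows are the two methods' marginal
diagnosis distributions (df = 2). This is the one standard construction
that reproduces the published χ² = 2.59, p = 0.27 from the published 3×3
margins; the exact menu path originally used cannot be determined, so the
identification is stated here explicitly. Note this compares marginal
distributions, not paired agreement — Cohen's kappa, Bowker's symmetry
test and the Stuart–Maxwell marginal-homogeneity test are provided as
clearly separated extras for users who want paired statistics.

## Synthetic cohort generator

The generator emulates per-tooth-type width distributions of a
normal-ratio reference population (defaults in
`toothratio.simulate.TABLE_NORMAL_WIDTHS`) and a lateral-incisor-driven
mechanism of ratio deviation. For subject i and tooth t of type k:

```
w_it = μ_k + λ_k·Z_i + τ_k·D_ik + shift_k(scenario) + ε_it
```

with Z_i a standard-normal per-subject size factor shared across the
mouth, λ_k = σ_k·√s where s is `size_factor_sd_share` (default 0.5 — real
tooth sizes covary within a mouth, but no covariance data exist to
calibrate s), D_ik a per-subject per-type normal deviate, and ε_it
independent left–right asymmetry noise with SD `asymmetry_sd_mm`
(default 0.15 mm). τ_k is chosen so the three components sum to exactly
σ_k² per tooth, which requires asymmetry² ≤ (1−s)·σ_k² (validated at
construction). Generated widths are clipped to the 3.0–15.0 mm
plausibility window with a warning counter; clipping never occurs at the
default parameters.

Scenarios are named for the ratio category they plant: `lateral_deficient`
adds `lateral_shift_mm` to the upper laterals and subtracts it from the
lower ones (driving SATR and ABR down together), `lateral_excess` mirrors
it, `balanced` plants nothing, and `mixed` draws a scenario per subject
(default mix 30% deficient / 53% balanced / 17% excess, a
screening-clinic case mix). This sign convention matches the observed
pattern between extreme ratio groups — low-ratio patients have larger
upper and smaller lower laterals. The default shift of 0.35 mm per arch
(about 0.7 within-type SD) represents a clinically evident lateral-incisor
discrepancy and places the planted low/high group mean ABRs at ≈76.1% and
≈81.4%, clearly outside the 77.08–80.52% normal band.

`generate_three_group_study` assembles a derivation-style design — a
balanced normal group plus planted deficient and excess groups with
attached labels — and warns (not errors) if the configured shift fails to
separate the planted group means past the stratification bounds.

What the generator does **not** emulate: within-type left–right and
inter-arch width correlations beyond the single shared size factor. Real
lateral incisors are far more correlated across the midline and between
arches than independent draws, so the synthetic SATR distribution is wider
(SD ≈ 5–6 percentage points under `balanced`) than the published ±3.57
standard, and per-subject diagnostic agreement in synthetic cohorts is
correspondingly below the published sensitivity/specificity. Passing tests
therefore demonstrate the correctness of the computational pipeline and
the qualitative structure (positive SATR–ABR correlation, lateral-driven
group separation), not the empirical agreement level of real dentitions.
Peg-shaped and otherwise malformed teeth are excluded by design, mirroring
the eligibility criteria of normative samples.

## Pipeline, configuration, determinism

`AnteriorRatioStudy.fit()` runs the stages derive → associate → norm →
classify → evaluate. Stage prerequisites: derive/associate/norm/evaluate
need all 12 teeth per subject (evaluate can instead accept external
gold-standard labels, allowing lateral-only cohorts); classify needs only
the four laterals. The in-cohort standard (`norm`) is established by
default from subjects whose ABR classifies as normal, emulating a
reference subsample; `norm_source="all"` uses everyone. All thresholds and
conventions live in `PipelineConfig`, which serialises to YAML
idempotently and defaults to the published constants, so a default-config
evaluation applies the published decision rules verbatim. Every threshold
and variant actually used is logged. All randomness flows from explicit
integer seeds through `numpy.random.default_rng`; identical seeds give
bit-identical cohorts and reports.

## Problem sizes used in the checks

The statistical acceptance checks use: 1000 seeded replicates at 40
subjects/group for the null rejection rate of the 18 tests (observed
≈5%); 200 replicates at 80/group for the key-tooth selection rate under
the default shift (observed ≈99%); n = 2000 for generator moment recovery
(errors < 0.02 mm); n = 240 mixed subjects for the SATR–ABR association
(r ≈ 0.67–0.71 across seeds). These sizes give Monte-Carlo standard
errors comfortably inside the asserted bands while keeping a full run in
tens of seconds.

## Known limitations

- Only the 12 permanent anterior teeth are modelled; posterior teeth and
  the overall (12-tooth-per-arch) Bolton ratio are out of scope.
- Missing teeth make a record ineligible for the affected ratio; no
  imputation is attempted.
- The marginal chi-square tests distributional consistency, not paired
  agreement; use the kappa/Stuart–Maxwell extras for the latter.
- Published reference quantities that depend on unavailable raw data
  (e.g. the exact correlation or t statistics of the original cohorts)
  anchor the structure of the pipeline, not reproducible values; the
  synthetic generator substitutes cohorts with known ground truth.
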