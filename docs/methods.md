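# Methods

This note documents the statistical machinery in `mstriage`: the scoring
model, the ROC cut-off estimation, the reliability and validity statistics,
the synthetic-data model behind the tests, and the numerical and design
choices made where more than one reasonable option existed.

## Instrument model

An instrument is an ordered set of sections (`disease_activity`,
`symptoms`, `impacts`), each holding items with consecutive integer
response levels starting at 0 (0 = absent) and a non-negative weight per
level.  Scoring is sum-and-rescale: raw section score = Σ weight(item,
level); standardized total = 100 × (pooled raw sum) / (pooled attainable
maximum).  An alternative equal-section-weight pooling (mean of per-section
fractions) is exposed as `normalize_sections` but is off by default: the
published description of the instrument rescales the pooled raw sum, and
the default follows it.

The EDSS enters as a derived item: when the with-EDSS variant is active,
the patient's EDSS value (0–10 in half steps) is mapped to a 21-level item
whose default weights equal the raw EDSS value, so it contributes up to 10
raw points to disease activity.  Under the without-EDSS variant the item is
removed from both the numerator and the attainable maximum, which is what
makes the two variants' totals comparable on the same 0–100 scale.  The
timed 25-foot walk is carried as a passthrough covariate and never scored;
no published scoring rule exists for it.

Default weights are unit ordinal (none/mild/moderate/severe = 0/1/2/3,
relapse count capped at 3).  The deployed instrument's weights are
proprietary; the default is a documented stand-in and everything is
overridable through the YAML/JSON config.  Missing responses on required
items are a hard error; items may be declared `optional`, in which case a
missing response scores 0 with a logged warning.

Zone classification is boundary-inclusive on both sides (total ≤ lower →
RRMS zone, total ≥ upper → SPMS zone), matching the instrument's stated
"equal or above the upper cut-off" / "lower or equal to the lower cut-off"
rules.  Totals are kept at full precision internally; CSV/JSON writers
round scores to 1 decimal and sens/spec/AUC to 2 decimals at serialization
time only.

## ROC analysis

* **Candidate thresholds** are midpoints between consecutive distinct
  observed scores plus sentinels one unit beyond each extreme, so the curve
  always reaches (sens = 1) and (spec = 1).  Midpoints are invariant to
  monotone jitter; observed-value thresholds are available via
  `threshold_grid="observed"` for instruments whose reported cut-offs are
  data values.
* **AUC** is the normalized Mann-Whitney U with ties counted ½ (identical
  to the trapezoidal area under the empirical curve — an equivalence the
  test suite verifies exactly against exhaustive pair counting).  The 95%
  CI uses the Hanley–McNeil standard error by default (DeLong behind
  `ci_method="delong"`), clamped to [0, 1].
* **Cut-off criteria**: Youden's J (maximized) and the squared distance to
  the (1, 1) corner (minimized), both weighting sensitivity and
  specificity equally.  Criterion ties are broken deterministically by the
  smallest threshold on the *oriented* scale, which makes the selected
  operating point invariant under negating scores and flipping the
  orientation.
* **Dual cut-offs**: upper from SPMS (positive) vs pooled RRMS +
  transitioning; lower from RRMS vs pooled transitioning + SPMS.  For the
  lower comparison the reported sensitivity/specificity depend on which
  class is called positive and the source analysis does not say; the
  default treats non-RRMS as positive (higher scores positive) and
  `lower_positive="rrms"` flips the convention (same thresholds, sens/spec
  roles exchanged) so both readings can be reported.  A derived pair with
  lower ≥ upper is flagged with a warning and refused by
  `cutoff_pair()` — never silently reordered.  Empirically, under the
  calibrated model the two criteria coincide for most seeds on the upper
  comparison, while Youden occasionally selects a markedly lower upper
  threshold when the criterion surface is flat — qualitatively the same
  divergence the original analysis saw on its without-EDSS run.
* **Sample size**: smallest total n for a one-sided normal test of
  H0: AUC = 0.5 against a target AUC, using the Hanley–McNeil variance
  under both hypotheses; allocation ratio configurable, default 1:1.  The
  default α = .025 reflects a Bonferroni split of .05 across the two
  planned comparisons; α is taken as given, not re-derived.  At the design
  point (AUC 0.68, power 0.90) the formula returns n ≈ 104, consistent
  with a prespecified recruitment target of "more than 150".

## Psychometrics

ICC(2,1) — two-way random effects, absolute agreement, single measure — is
computed from the crossed-ANOVA mean squares, with the standard F-based
confidence interval (Satterthwaite df for the absolute-agreement
denominator).  It matches `pingouin`'s ICC(A,1) to numerical precision in
the cross-check tests; interpretation bands are ≥ 0.75 excellent, 0.40–0.75
fair to good, < 0.40 poor.  Grids with missing cells are rejected (no
imputation); a grid with zero between-subject variance reports ICC 0 with
a warning.  Per-section ICCs are supported by scoring each section
separately, but only the total-score rater model is calibrated.

Known-groups contrasts use Welch's t by default (Student's pooled test
behind `equal_var=True`) with pooled-SD Cohen's d; the EDSS banding for the
disability contrast is [1, 4.5] vs (4.5, 9.5), scores outside both bands
excluded.  Item validity uses Spearman correlations with average-rank ties
against the ordinal diagnosis coding RRMS = 0 < transitioning = 1 <
SPMS = 2 (the natural severity order); a constant item is reported as
undefined (NaN), not 0.  No multiplicity correction is applied to these
descriptive contrasts; the Bonferroni adjustment belongs to the design-time
sample-size calculation only.

## Synthetic data: what it emulates, and what it does not

The default cohort spec encodes the published validation-study structure:

| group | n | total score | EDSS | age | P(relapse 6 mo) |
|---|---|---|---|---|---|
| RRMS | 89 | N(38.1, 12.5²) | N(2.6, 1.0²) | N(38.1, 11.3²) | 30/89 |
| transitioning | 47 | N(55.2, 11.1²) | N(4.3, 1.1²) | N(46.2, 10.7²) | 10/47 |
| SPMS | 62 | N(69.6, 12.0²) | N(5.6, 1.4²) | N(53.4, 10.7²) | 9/62 |

Totals are *truncated* (not clipped) normals on [0, 100], avoiding point
masses at the boundaries that would distort ROC thresholds; EDSS is clipped
to [0, 10] and rounded to the half-point grid.  The published total-score
SDs are treated as the with-EDSS algorithm's distribution (consistent with
its reported AUC ≈ 0.91 under a normal model); no without-EDSS score
distribution was published, so the without-EDSS cut-offs are not a
simulation target.  By closed-form mixture-of-normals computation this
model implies SPMS-vs-rest AUC ≈ 0.91, RRMS-vs-rest AUC ≈ 0.91, and
sens ≈ 0.81 / spec ≈ 0.84 at the fixed 58.9 cut-off — which is why
reproducing those numbers stochastically is an informative check of the
pipeline.

Item-level mode draws per-item presence from per-group Bernoulli
prevalences and, conditional on presence, a severity level from a baseline
mild/moderate/severe distribution (0.50/0.35/0.15) exponentially tilted
toward higher levels by a per-group shift (0 / 0.6 / 1.2); the published
account says impacts were more severe in transitioning/SPMS patients
without giving numbers, so the tilt magnitudes are documented assumptions.
Items with published per-group prevalence counts use them exactly; the
rest (fatigue, sensory, hobbies/leisure, work, daily activities) use
counts chosen to match the published overall totals and qualitative
ordering.  In summary mode no explicit EDSS–total correlation is imposed
(none was published); item-level mode induces one implicitly through group
membership.

The rater-study model is additive — score(s, r) = true(s) + rater bias +
residual — with defaults of two vignette subjects (true scores 40 and 70,
an RRMS-like and an SPMS-like presentation), 20 raters, bias SD 2.5 and
residual SD 4.0, whose implied ICC(2,1) ≈ 0.95 mirrors the reported
reliability of the instrument.

What passing the simulation-based tests shows: the scoring, ROC, cut-off
and reliability machinery is correct and the published group-level numbers
are mutually consistent.  What it does not show: anything about real
patient-level response patterns — inter-item correlations, missingness,
site and country effects, and longitudinal change are all absent from the
generator.

## Reproducibility and problem sizes

A single integer seed drives every stream through
`numpy.random.SeedSequence` spawning (one child per diagnosis group, in
group order), so any group or stage is reproducible in isolation, and the
full pipeline (`run_validation`) serializes to byte-identical JSON under a
fixed seed (timestamps live only in the run log).  The stochastic
reproduction checks use 500 replicate cohorts of 198 patients (Monte-Carlo
SE of the mean AUC ≈ 0.001), 1000 replicate rater studies of 40 subjects ×
6 raters for the ICC recovery check, and 300 replicates for the
known-groups significance rate; these sizes make the Monte-Carlo error
comfortably smaller than every tolerance tested while keeping the whole
suite in the tens of seconds.

## Known limitations

* Default item weights are a stand-in; absolute totals from item-level
  scoring are not comparable to the published score distributions (the
  summary-score mode exists precisely for distribution-calibrated work).
* The Hanley–McNeil interval is approximate for extreme AUCs near 1 at
  small n; DeLong is available where that matters.
* The ICC confidence interval is exact under the two-way normal model
  only; with 2 subjects it is extremely wide, as in the original study.
* `sample_size_auc` treats the published design reference as
  Hanley–McNeil-based since no formula was printed; other variance models
  (e.g. Obuchowski) would shift the result modestly.
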