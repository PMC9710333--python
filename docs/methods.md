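# Methods

## The classification problem

Adults presenting acutely with infection in much of sub-Saharan Africa have
no documented pre-illness creatinine, so AKI — defined as a ≥1.5-fold
creatinine rise over baseline — can only be diagnosed against an *estimated*
baseline. The package implements four estimation strategies and propagates
each through the full KDIGO classification so their effect on prevalence is
measurable:

1. **MDRD_G100** (primary): invert the 4-parameter MDRD equation at an
   assumed GFR of 100 mL/min/1.73 m².
2. **MDRD_G75**: as above at 75 mL/min/1.73 m² (a more conservative healthy
   kidney assumption → larger baseline estimate → fewer AKI diagnoses; the
   prevalence ordering G75 ≤ G100 is a mathematical consequence and is
   enforced as a test property).
3. **FAS_BACKCALC**: invert the full-age-spectrum equation, whose baseline
   falls with age above 40 — it flags more older adults than MDRD.
4. **LOWEST_INPATIENT**: lowest measured creatinine during admission; it
   cannot flag participants whose creatinine never falls, so it misses
   severe-but-static impairment.

Equation variants: MDRD uses coefficient 186 (non-IDMS-traceable assays;
175 behind `idms_traceable=True`), and both MDRD and CKD-EPI 2009 exclude
the race coefficient by default, because ethnicity adjustment factors
overestimate GFR in Black populations and underdiagnose CKD. The FAS sex
medians are Q = 0.70 (female) / 0.90 (male) mg/dL, and the FAS inversion
assumes the same GFR 100 target as the primary MDRD analysis. MDRD and FAS
invert in closed form; CKD-EPI by Brent root finding on the bracket
[0.05, 25] mg/dL (the assay-reportable range with margin); round-trip error
is bounded below 10⁻⁶. The chronic-disease decision value is the arithmetic
mean of the MDRD and CKD-EPI estimates ("combined" eGFR); both components
are retained so either equation can be applied alone. Body surface area,
where needed, is Du Bois: `0.007184 · kg^0.425 · cm^0.725`.

Creatinine is mg/dL everywhere internally; conversion (×88.42 to µmol/L)
exists only at the I/O boundary, and the CSV reader hard-rejects creatinine
values above 25 mg/dL as probable unit errors.

### Decision rules and tie-breaks

* Stage boundaries are half-open with boundaries joining the higher stage:
  [1.5, 2.0), [2.0, 3.0), [3.0, ∞). This is the only reading that
  reconciles printed ranges like "1.5–1.9×" with continuous ratios.
* The incident-AKI rise and the recovery fall both use the KDIGO absolute
  0.3 mg/dL criterion, compared with a 10⁻⁹ tolerance so exact boundary
  values (e.g. 3.0 → 2.7) count.
* AKD is a disjunction over all its criteria (any-criterion definition);
  its eGFR terms use the combined eGFR for consistency with the CKD rule.
  At 3 months AKD rests on creatinine/eGFR criteria only — dipstick testing
  is an admission-only measurement.
* The "normal creatinine" recovery threshold (1.3 mg/dL) is applied
  sex-independently.
* CKD returns *indeterminate*, not "no", when admission eGFR ≥ 60
  (chronicity unproven) or the 3-month value is missing; the CKD
  denominator is survivors with a 3-month creatinine.
* Missing data are handled complete-case per endpoint: a participant
  missing the 48-h creatinine drops out of 48-h endpoints only.

## Synthetic cohort generator

The generator (`synth`) draws cohorts with the structure the analysis
assumes, plus per-participant ground truth, so classifier fidelity and
parameter recovery are testable end to end. Defaults are the study
conditions the package targets: n = 101; age log-normal matched to median
38 (IQR 29–48), clipped to [18, 88]; 47 % male; HIV prevalence 60 % with
~16 % of statuses missing completely at random; AKI prevalence 33 % with a
21/24/55 % stage split; recovery probability 0.55; 30 % mortality by
~92-day follow-up with a designed HIV hazard ratio of 3.97; 48-h and
3-month creatinine missing at the observed study rates; 7 % lost to
follow-up.

Mechanics, in sampling order:

* **Vitals** (SBP, DBP, respiratory rate, GCS) are drawn from truncated
  normals/mixtures chosen to give a realistic qSOFA distribution; DBP is
  N(75, 12) so the model profile value of 75 mm Hg is its centre.
* **AKI** is Bernoulli from a logistic model with designed odds ratios:
  HIV 4.0, age 2.0/decade, qSOFA 1.8/point, DBP 1.01/mm Hg; the intercept
  is root-found per cohort so the mean designed risk equals the target
  prevalence. Because the fitted adjusted model nests the generating model
  (the spline basis contains the linear age term), the HIV coefficient is
  recoverable without bias.
* **True baseline GFR** is exactly 100 for non-chronic participants, so
  their true baseline creatinine coincides with the classifier's estimate
  and, with noise off, classification equals truth. Real cohorts have
  between-subject baseline spread; the generator deliberately omits it, so
  a passing noise-free fidelity test says the *rules* are implemented
  exactly, not that real-data misclassification is zero.
* **Latent CKD** (default marginal prevalence 0.10) is drawn *inside* the
  designed-AKI group (acute-on-chronic presentation, true GFR uniform on
  [25, 45]). This is forced by arithmetic: eGFR < 60 at presentation
  implies a creatinine ≥ (100/60)^(1/1.154) ≈ 1.56× the GFR-100 baseline,
  so a low-GFR subject cannot present AKI-negative. Chronic creatinines are
  nudged so the combined eGFR stays below 60 at both timepoints (and
  non-chronic 3-month values stay above), keeping latent state and
  classifier output in exact correspondence.
* **Creatinine trajectories**: AKI fold multipliers are uniform within the
  designed stage's interval; non-AKI folds U(0.85, 1.30) (acute-illness
  wobble, below the 1.5 threshold); recovered participants return to
  baseline by 48 h; non-recovered non-chronic ones settle at 1.25–1.45×
  baseline by 3 months. A small fraction (4 %) of non-AKI participants
  develop incident AKI by 48 h.
* **Survival** is exponential with covariate log-hazards (HIV ln 3.97, age
  ln 1.5/decade, qSOFA ln 1.7/point), baseline hazard calibrated so the
  designed death probability by censoring equals the target; censoring is
  uniform on [80, 100] days. Deaths force the corresponding creatinine
  values missing; MCAR missingness is applied last.
* **Noise** is multiplicative log-normal with CV 5 % (typical enzymatic
  creatinine imprecision), applied after truth labels are computed on the
  noiseless record.

Everything is driven by one `numpy` generator seeded from the config, so a
seed reproduces a cohort byte-for-byte.

## Statistical layer

* **Group comparisons**: Shapiro-Wilk at α = 0.05 in each group gates
  t-test versus Wilcoxon rank-sum for continuous variables; Fisher's exact
  test for binary ones; complete-case per variable; constants are skipped
  with a note.
* **Logistic model**: age enters as a restricted (natural) cubic spline
  with 3 knots at the 10th/50th/90th age percentiles (order-statistic
  quantiles, so replicating rows leaves the fit unchanged). Two adjusted
  covariate sets are selectable: the default "profile" set
  (age spline + HIV + qSOFA + diastolic BP — the set consistent with the
  fixed prediction profile used for the age curve) and a leaner
  "age_hiv" set; neither is asserted to be *the* canonical model.
* **Age OR curve**: odds at age *a* (fixed profile qSOFA = 2, HIV+,
  DBP = 75) divided by odds at the reference age 40; percentile-bootstrap
  95 % CIs from 1000 participant-level resamples with the knots held fixed;
  non-converging replicates are dropped and the curve fails if more than
  5 % drop. OR(40) ≡ 1 with a degenerate interval.
* **Survival**: Cox PH (lifelines, Efron ties) with exposure + age +
  qSOFA; losses to follow-up censored at last contact; Kaplan-Meier curves
  per exposure group exported as plain coordinate tables.
* **Minimal detectable OR**: solves for the exposed-group probability p₂ at
  which a two-group test attains the requested power, then reports
  [p₂/(1−p₂)]/[p₁/(1−p₁)]. The default machinery is **exact Fisher power**:
  the two-sided Fisher rejection region over all (x₁, x₂) outcomes is
  enumerated once and power is the exact binomial sum; pooled- and
  unpooled-variance z approximations are selectable. Fisher-exact is the
  default because it is the appropriate exact calculation at these sample
  sizes and matches the behaviour of the standard desktop power calculators
  for small two-group designs; the z approximations give systematically
  smaller ORs (unpooled ≈ 3.44, pooled ≈ 3.67 versus Fisher ≈ 3.74 for the
  35/53, p₁ = 0.23 design). The root is located to power error < 10⁻⁹.

## Problem sizes used in the test suite

Parameter-recovery checks run at n = 20 000 (sampling error ≲ 3 % on the
designed OR/HR); null-calibration checks use 100 permutation seeds at
n = 101; prevalence reproduction pools 200 seeds of the n = 101 default
cohort and compares against binomial 95 % bands; the Fisher oracle
enumerates all 46 376 2×2 tables with grand total ≤ 30.

## Known limitations

* The generator's baseline-GFR degeneracy (above) means synthetic fidelity
  results do not quantify real-world misclassification from unknown true
  baselines — the central caveat of baseline back-calculation itself.
* Urine-output AKI criteria are not implemented (not assessed in the
  target setting); no multiple imputation (complete-case by design); no
  competing-risks model; cystatin-C and 2021 CKD-EPI equations are out of
  scope.
* The latent-CKD mechanism ties chronic disease to acute presentation;
  community CKD in participants who never meet AKI criteria is not
  simulated.
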