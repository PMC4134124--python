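# Methods

This note records the scientific model behind `ibdclaims`, the defaults and
why they are what they are, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Case ascertainment

**Code mapping.** ICD-9 stems 555 / 556 and ICD-10 stems K50 / K51 map to CD
and UC. Matching is prefix-based on the portion of the code before any
decimal point and case-insensitive, so `556.9`, `5569` (claims feeds often
omit the decimal) and `k51` all map; unknown codes are silently non-target
rather than errors, since claims streams are full of unrelated diagnoses.

**Gate.** Entry to the IBD cohort requires ≥1 hospital discharge or ≥4
physician claims with IBD-mapped codes inside a rolling window. The window
is half-open, `[t, t + 730 days)`, anchored at each event date, and 730 days
regardless of leap years: this makes the arithmetic exactly reproducible and
"two years" is not defined more precisely in the underlying case definition.
The qualifying date is the earliest date at which either arm completes (the
k-th event of the first qualifying window); a scan over anchors in date
order finds it because the completion index is monotone in the anchor.
Claims on the same date count individually — the definition gives no
distinct-date rule — and the gate is monotone: adding encounters can never
un-qualify a person.

**Washout.** Any IBD-mapped encounter in a calendar year inside the washout
span (inclusive) excludes the person as prevalent. Washout is checked before
the gate. The default profile has the washout span (1991–1995) abut the
study start (1996), so retained persons' first IBD contact is necessarily
on/after the study start. Washout is inherently leaky for onsets very late
in the washout span whose first coded contact happens after it; that leakage
is a property of the design being modelled, not a bug, and the washout
soundness guarantee is stated at the encounter level: no ascertained case
has any IBD-coded encounter inside the span.

**Diagnosis date and classification window.** The diagnosis date is the
first IBD-mapped contact on/after the study start (first medical contact
dating), even when the gate completes later; the incidence year is its
calendar year, and persons whose diagnosis year falls outside the study span
are dropped. The cumulative score accumulates IBD-mapped encounters from the
first contact through first contact + 730 days by default — the same
two-year horizon as the gate, keeping the classification bounded and
deterministic. Scoring over all available follow-up is supported
(`classification_window_days=None`); with long follow-up it shifts borderline
patients out of IBDU, and the bounded default was chosen because an
incident-case label should reflect presentation-era coding, not a decade of
subsequent care.

**Score and partition.** Claims score ±1 and discharges ±2 (UC positive, CD
negative); UC iff score > +2, CD iff score < −2, IBDU for scores in
[−2, +2]. Every integer score receives exactly one label, and swapping all
CD codes for UC codes negates the score and swaps the CD/UC labels.

## Incidence estimation

Denominators are annual registry counts by year, age group and sex — not
person-days — matching how annual rates are reported from insurance
registries. Age at diagnosis is calendar-year age (diagnosis year minus
birth year), consistent with those denominators. Crude rates are
`1e5 × cases / N`; `0/0` cells are reported as rate 0 with an `undefined`
flag, while cases against a zero denominator raise an error.

The ASR is the dot product of age-specific rates with standard weights, a
convex combination, so it always lies between the minimum and maximum
age-specific rate and equals the common rate when rates are flat. The
sexes-combined ASR standardizes pooled-sex age-specific rates with the same
(both-sex) weights, because sex-specific standard weights are not part of
this reporting tradition. The IBD ASR standardizes summed CD+UC+IBDU counts;
with shared weights this equals the sum of the component ASRs, which the
code asserts as a property rather than assuming.

The bundled standard is the 2006 Canadian census population by five-year age
band (provenance in `standards.py`); weights for any requested grouping are
aggregated from those bands, which requires bin boundaries at multiples of
five. Published census counts are rounded to the nearest 5 by the source;
since only normalized weights enter any computation this is immaterial.

## Trend model

Per stratum the model is Poisson with log link, offset `log N`, and calendar
year as a categorical factor with the first study year as reference; the
age-adjusted rows add an age-group factor. One summary per stratum is
reported: the final-year-vs-reference contrast `100(exp β_final − 1)` with a
Wald 95% CI — the model is categorical in year, so a single-number summary
must pick a contrast, and the endpoint contrast is the natural "change over
the study period". All per-year contrasts are also emitted
(`trend_by_year.csv`) for anyone wanting a different summary.

The fitter is IRLS/Newton scoring with the observed-information covariance
(identical to expected information under the canonical log link),
convergence at score inf-norm < 1e-8, cap 100 iterations, and the intercept
initialized at the log of the pooled empirical rate. In a single stratum
with year-only factors the model is saturated and the fitted rates equal the
observed rates exactly, which serves as a closed-form oracle; the
implementation is cross-checked against an independent GLM implementation in
the tests. Plain Poisson is used deliberately — no overdispersion
correction — matching the standard GENMOD-style analysis this reproduces.
Cells with zero population are dropped from the likelihood with a logged
warning; a factor level whose total count is zero has no finite MLE and is
reported as non-estimable (NaN estimates, `estimable=False`) instead of
crashing, and a zero-count reference year makes the whole stratum
non-estimable.

## Synthetic-data generator

The generator emulates a closed, universally covered provincial population
observed through claims:

- **Registry.** `n_persons` baseline residents aged by `age_distribution` at
  the first calendar year (uniform age within bin; the open top bin spans 15
  years), sex Bernoulli(`sex_ratio`), covered from max(birth, span start) to
  the span end. By default newborn cohorts enter each subsequent year at the
  rate implied by the youngest bin's density (`replenish_births`); without
  them a closed cohort simply ages and the youngest bins empty over a
  14-year study, which would make standardization against fixed census
  weights degenerate. Ages advance by calendar year.
- **Onsets.** At most one disease per person; in year *y* a disease-free
  person acquires disease *d* with hazard
  `baseline[d, age, sex]/1e5 × trend_d^(y − first_year)`, onset date uniform
  within the year. The default baseline surfaces peak in young adulthood
  (CD) and early middle age (UC) and integrate to roughly 27 and 21 per
  100,000 — a high-incidence population — with default trends 0.97 (CD) and
  0.978 (UC) per year, i.e. declines of ~33% and ~25% over 14 years.
- **Care contact.** Per post-onset calendar year: Poisson(4) claims and a
  Bernoulli(0.15) hospitalization by default, dated uniformly in the
  post-onset part of the year and coded for the true disease, flipped to the
  other disease's code with probability `code_noise_prob` (default 0.1).
  ICD-9 is emitted before the cutover year (default 2001), ICD-10 from it —
  a hard cutover; only the code sets matter downstream. Background non-IBD
  encounters are Poisson(`background_encounter_rate`) per covered person-year
  from a small fixed list of non-target codes; they exercise the code filter
  and are otherwise inert. No published care-contact intensities exist for
  this population, so the contact defaults are illustrative: high enough
  that gate sensitivity is near 1 (Poisson(8) claims over the two-year
  window), which is the regime in which label accuracy can be meaningfully
  validated against ground truth.

What it does **not** emulate: migration in or out, deaths, remission or cure
affecting coding, multi-code discharge abstracts (readers must explode those
to one row per code), comorbidity coding realism, fee codes, or clustering
of care by provider. Consequently a passing suite demonstrates that the
pipeline recovers known data-generating parameters under honest coding and
steady contact — not that any particular real-world sensitivity or
specificity is achieved. One visible artefact of the simple noise model: per-
encounter flips with many contacts rarely leave a cumulative score inside
[−2, +2], so the synthetic IBDU share (a few percent) is smaller than the
mixed-coding shares seen in real databases.

Determinism: each stage draws from `SeedSequence([seed, stage])`, so
identical configs give byte-identical outputs and stages are individually
reproducible.

## Problem sizes in the checks

The routine suite uses cohorts of 8,000–40,000 persons, where every
distributional check is placed within 3 Monte-Carlo standard errors of its
expectation. The trend-recovery check uses twenty replicates of a
200,000-person cohort with a flat CD baseline of 25/100,000 and trend 0.97
under noiseless coding, asking the combined-sex age-adjusted 95% CI to cover
the analytic endpoint change `100(0.97¹³ − 1) ≈ −32.7%` in at least 18 of
20 replicates; at ~50 cases in the reference year the interval is wide, so
this checks calibration, not precision. Interval coverage of the fitter
itself is checked separately at moderate counts (300 replicates, nominal
95%, accepted range 90–99%).

## Known limitations

- Annual-count denominators ignore within-year person-time; rates for
  partially covered years (birth years) are slightly biased relative to
  exact person-time, consistently with the reporting convention emulated.
- The endpoint contrast uses only the reference and final years' relative
  level; a year with atypical counts at either end moves it. The per-year
  contrasts are emitted for joinpoint-style follow-up analyses, which are
  out of scope.
- Wald intervals on sparse strata (expected counts near zero) are known to
  be erratic; such strata are usually flagged non-estimable here, but thin
  positive counts still yield very wide, asymmetric intervals.
- The washout guarantee is encounter-level; person-level exclusion of every
  washout-era onset additionally requires that each onset leaves a coded
  encounter before the span ends.
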