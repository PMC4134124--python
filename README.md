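# ibdclaims

Case ascertainment and incidence-trend analysis for inflammatory bowel
disease (IBD) from administrative health-claims data, together with a
synthetic single-payer claims simulator so the whole pipeline can be
developed and tested without access to confidential health databases.

The package is aimed at epidemiologists working with physician-billing and
hospital-discharge streams from a universal-coverage system, where incident
Crohn's disease (CD), ulcerative colitis (UC) and undifferentiated IBD
(IBDU) must be identified from diagnosis codes alone.

## The method

**Case definition.** Encounters carrying ICD-9 codes 555.x / 556.x or ICD-10
codes K50.x / K51.x are mapped to CD / UC respectively. A patient enters the
IBD cohort if they have at least one hospital discharge, or at least four
physician claims, with such codes within a rolling two-year (730-day)
window. Patients with any IBD-coded encounter during a pre-study washout
span (1991–1995 by default) are treated as prevalent and excluded. The
diagnosis date is the first IBD-coded contact on/after the study start, and
the incidence year is the year of that date.

**Subtype score.** Each physician claim scores +1 (UC code) or −1 (CD code);
each hospital discharge scores +2 or −2. With cumulative score *S*:

- *S* > +2 → UC
- *S* < −2 → CD
- −2 ≤ *S* ≤ +2 → IBDU

So one UC-coded discharge plus one UC-coded claim gives (+2) + (+1) = +3 → UC.

**Rates.** Incident cases are cross-tabulated by year, age group and sex
against annual population denominators; crude rates are `1e5 * cases / N`
and the direct age-standardized rate (ASR) is `Σ_a w_a r_a` with `w_a` the
age weights of the 2006 Canadian census population (bundled; any standard
can be supplied as CSV).

**Trend.** For each stratum (disease × sex × age level) a log-linear Poisson
model is fitted to yearly counts with the log population as offset and
calendar year as a categorical factor (first study year as reference):

    log E[count_y] = log N_y + α + β_y      (+ γ_agegroup when age-adjusting)

The reported change over the study period is `100 (exp(β_final) − 1)` with a
Wald 95% CI. Fitting is by IRLS (Newton scoring) to a score norm below
1e-8; year levels with zero total count are reported as non-estimable.

**Simulator.** The `synthetic_claims` module draws a covered registry with a
configurable age/sex structure, assigns at most one disease per person from
age-sex-specific baseline incidence (per 100,000 person-years) with a
multiplicative per-year trend, and generates post-onset Poisson claims,
Bernoulli hospitalizations, code noise that mixes CD/UC coding, a hard
ICD-9→10 cutover year and non-IBD background encounters — all deterministic
given a seed, with ground truth retained for validation.

## Worked example

```python
import ibdclaims as ic
from ibdclaims.incidence_estimation import regroup_population

cfg = ic.SimulationConfig(seed=1, n_persons=150_000, background_encounter_rate=0.5)
cohort = ic.simulate_cohort(cfg)
cases = ic.ascertain_cases(cohort.persons, cohort.encounters)

years = list(range(1996, 2010))
cube = ic.tabulate_cases(cases, cohort.persons, ic.DECADE_BINS, years=years)
pop = cohort.population[cohort.population["year"].isin(years)]
rates = ic.build_rate_tables(cube, pop, ic.canada_2006_weights(ic.DECADE_BINS), ic.DECADE_BINS)

tcube = ic.tabulate_cases(cases, cohort.persons, ic.TREND_BINS, years=years)
tpop = regroup_population(pop, ic.DECADE_BINS, ic.TREND_BINS)
summary = ic.trend_summary(ic.run_trend_suite(tcube, tpop, reference_year=1996), 2009)
```

prints, after formatting:

```
incident cases: 795
by category: {'CD': 411, 'UC': 366, 'IBDU': 18}
CD ASR per 100,000:  1996: 25.8   2009: 12.5
UC ASR per 100,000:  1996: 14.0   2009: 11.4
IBD ASR per 100,000:  1996: 39.8   2009: 24.6
CD change 2009 vs 1996 (age-adjusted): -50.3% (95% CI -70.7, -15.6)
UC change 2009 vs 1996 (age-adjusted): -11.3% (95% CI -50.9, 60.2)
```

The generator's defaults encode a high-incidence population whose CD rate
declines 3% per year (0.97¹³ ≈ −33% over 14 years) and UC 2.2% per year;
the fitted contrasts recover those declines within their (wide, at ~30
cases/year) confidence intervals. The CD ASR falls from ~26 to ~13 per
100,000 while UC drifts down more gently — the qualitative pattern the
pipeline is designed to detect.

The same run is available from the shell:

```bash
ibdclaims all --config examples/demo_config.yaml --out scratch/demo
```

which writes `data/` (registry, truth, encounters, population CSVs) and
`results/` (cases.csv, rates.csv, table2.csv, table3.csv, trend.csv,
figure_data/*.csv, run.log, run_manifest.json). The individual stages are
also exposed as `ibdclaims simulate|ascertain|rates|trend|report`.

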