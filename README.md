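# organclock

Multi-organ biological-age clocks from routine clinical biomarkers, and
two-wave change analysis of how lifestyle shifts relate to the pace of
aging.

People with the same chronological age (CA) can age at different rates, and
different organ systems within one person can age differently. This package
implements a complete, tested pipeline for studying that heterogeneity in a
two-wave cohort: it builds Klemera–Doubal biological ages (a comprehensive
15-marker clock plus cardiopulmonary, metabolic, liver, renal and immune
clocks), scores a five-factor Healthy Lifestyle Index (HLI), validates each
clock against organ-mapped diseases, and estimates the effect of lifestyle
*change* on biological-age acceleration with fixed-effects panel models and
quantile G-computation. A seeded synthetic-cohort generator with known
ground truth makes every stage testable without restricted data.

It is written for epidemiologists and biostatisticians who have (or want to
simulate) person × wave tables of clinical biomarkers, lifestyle
questionnaire fields and disease flags.

## The models

**Klemera–Doubal biological age.** Within each sex stratum, each biomarker
*j* is regressed on age, x_j = q_j + k_j·CA, with residual SD s_j. The
uncorrected biological age of a person with marker vector x is the
precision-weighted average of per-marker inverse-regression estimates

    BA_E = Σ_j (x_j − q_j) k_j / s_j²  ÷  Σ_j (k_j / s_j)²

and the CA-anchored estimator shrinks it toward chronological age,

    BA_EC = ( Σ_j (x_j − q_j) k_j / s_j² + CA/s_BA² ) ÷ ( Σ_j (k_j/s_j)² + 1/s_BA² ),

where s_BA² is the population variance of true biological age about CA,
estimated from the variance of BA_E − CA minus the model-implied estimator
dispersion. **BA acceleration** is BA − CA; positive values mean faster
aging.

**Healthy Lifestyle Index.** Five binary indicators — never smoking,
drinking less than once a week, diet quality at or above the population
median of a modified (alcohol-free, 7-component, range 7–35) alternate
Mediterranean diet score, leisure exercise at least 1–2 times a week, and
7–8 hours of sleep — summed to 0–5 and dichotomised at 4–5 = healthy.

**Change inference.** With two waves the fixed-effects (within) estimator
equals first-difference OLS: Δ(acceleration) is regressed on Δ(exposures)
and Δ(time-varying covariates), with time-invariant covariates and baseline
CA as level terms; robust (HC1) standard errors; Cochran's Q for subgroup
heterogeneity at α = 0.1. Quantile G-computation regresses the same
differenced outcome on quantile-scored exposures: the mixture effect ψ is
the sum of the exposure coefficients and each factor's relative
contribution is its share of the summed same-sign coefficients.

## Worked example

```python
from organclock.synthetic import CohortConfig, generate_cohort
from organclock.lifestyle import build_hli_records, categorize_change
from organclock.kdm import fit_kdm_all, score_dataset
from organclock.validation import validate_panels

data, truth = generate_cohort(CohortConfig(seed=1))   # 8396 persons, 2 waves
hli = build_hli_records(data)
ba = score_dataset(data, fit_kdm_all(data))
table, validated, unvalidatable = validate_panels(data, ba, hli)
print(validated, unvalidatable)
```

prints

```
['comprehensive', 'cardiopulmonary', 'metabolic', 'liver'] ['renal']
```

i.e. the cardiopulmonary, metabolic and liver clocks are retained alongside
the comprehensive clock because their per-SD acceleration is associated
with their mapped diseases (for this seed, e.g. diabetes OR 3.01 per SD of
metabolic acceleration, 95% CI 2.72–3.34; chronic hepatitis OR 1.36 per SD
of liver acceleration, CI 1.20–1.53), the immune clock fails (its mapped
disease carries no signal in the generator, OR 0.93, CI 0.81–1.05), and the
renal clock has no mapped disease to validate against.

The numbered scripts under `analysis/` run the full narrative on the same
cohort — `01_simulate_cohort.py` (change frequencies: smoking 98% and
alcohol 96% unchanged, diet changing in 38% of people, HLI score changing
in 61%), `02_fit_bioages.py` (clock fits and validation above),
`03_change_effects.py` (fixed-effects change estimates with subgroup and
sensitivity suites), `04_mixture_contributions.py` (QGC contributions, plus
calibrated scenarios in which diet carries 24% of the protective mixture
for the comprehensive profile and smoking 55% for the metabolic profile;
the mean recovered weights over 20 seeds are 0.239 and 0.543), and
`05_demo_pipeline.py` (end-to-end run on a high-signal demonstration
cohort, where all five estimated factor effects come out negative, as
simulated). Each writes its tables under `results/`.

There is also a CLI: `organclock simulate|score|fit-kdm|score-ba|validate|
fem|qgc|run-all --help`.

## Layout

- `src/organclock/` — the library: `synthetic` (cohort generator),
  `lifestyle` (aMED/HLI scoring), `kdm` (the clocks), `validation`,
  `fem` (change inference), `qgc`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and acceptance suites.
- `docs/methods.md` — modelling assumptions, parameter choices, limitations.
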