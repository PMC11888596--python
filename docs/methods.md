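# Methods

This note records the models implemented in `organclock`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
cohort does and does not emulate. Every number quoted here is produced by
the test suite, the analysis scripts or the acceptance script; none is
asserted from outside the code.

## The Klemera–Doubal clocks

Biological age (BA) is estimated per sex stratum from per-marker linear
age regressions. For marker *j*: x_j = q_j + k_j·CA + e_j, e_j ~ N(0, s_j²),
fitted by OLS on baseline-wave records. The uncorrected estimate BA_E is
the (k_j/s_j)²-weighted average of the inverse-regression estimates
(x_j − q_j)/k_j, hence always between their minimum and maximum (a tested
invariant). The CA-anchored estimate BA_EC adds CA as a pseudo-marker with
variance s_BA²:

    BA_EC = (Σ_j (x_j − q_j) k_j/s_j² + CA/s_BA²) / (Σ_j (k_j/s_j)² + 1/s_BA²).

s_BA² — the variance of true biological age about CA — is estimated as
mean[(BA_E − CA)²] minus the dispersion term
(1 − r_char²)/r_char² · (age range)²/(12·m), where m is the number of
markers and r_char is the characteristic marker–age correlation, floored
at 0.01 years². We take r_char as the mean |marker–age correlation|
weighted by each marker's share of the estimator information, (k_j/s_j)²
normalised; the weighting rule is a free choice in this family of
estimators and only moves s_BA, not BA_E. Residual SDs are floored at 1e-8
so noiseless markers remain usable; with noiseless markers and no latent
aging the whole pipeline returns BA = CA to 1e-8 years (tested end to end).

Both waves are scored with baseline-fitted parameters so that within-person
change in acceleration is not contaminated by parameter drift between
waves; the training wave is an argument. BA acceleration is BA − CA. The
anchored estimator is the headline output; `use_ca_anchor=False` switches
to BA_E. Anchoring is a shrinkage: E[BA_EC − CA | true acceleration a] =
λ·a with λ = s_BA²·Σ(k/s)² / (1 + s_BA²·Σ(k/s)²). This matters for
interpretation (see "power and attenuation" below).

Panels: comprehensive (15 markers: SBP, WHR, PEF, GGT, ALB, LDL-CH,
HDL-CH, TG, AST, Cr, ALP, urea, MCV, HBA1C, PLT), cardiopulmonary
{SBP, PEF}, metabolic {LDL-CH, HDL-CH, HBA1C, TG, WHR}, liver
{AST, GGT, ALP, ALB}, renal {Cr, urea}, immune {PLT, MCV}. Marker
screening keeps candidates with missingness below 30% and |age
correlation| ≥ 0.10 with a consistent sign in both sex strata; the
correlation threshold is configurable and the screen can be bypassed by
specifying panels explicitly (the shipped panels are the defaults). Marker
units are taken as given; no transformation is applied by default.

## Lifestyle scoring

The five binary criteria: never smoking; drinking less than 1.0
occasion/week (strict inequality); modified-aMED diet score at or above
the population median (inclusive), with the median computed over the
analysis population of the record's own wave, pooled across sexes;
exercise at least 1–2 times/week; sleep in the closed interval [7, 8]
hours. HLI is the sum (0–5), dichotomised at ≥ 4.

The modified aMED removes the alcohol item (alcohol is its own HLI
factor), leaving 7 components scored 1–5 by quintile within a reference
population — hence the attainable range 7–35, which the acceptance script
recomputes. The implemented component list is vegetables, legumes, fruits,
nuts, whole grains, fish, and red/processed meat (reverse-scored); the
list is configuration. Quintile ranks use a mid-rank empirical CDF with
right-closed bins at 0.2/0.4/0.6/0.8, so ties are symmetric and a
degenerate (constant) component scores 3 for everyone; scoring is
invariant to strictly monotone re-expressions of an intake scale (tested).
Records missing any component are excluded (complete case).

Between-wave change per factor is healthier / unchanged / unhealthier by
flag transition; HLI (range) change compares scores, HLI (category) change
compares the dichotomy. The categorisation is antisymmetric under swapping
waves (tested). Alternative criteria for the sensitivity suite (one factor
swapped at a time) ship in `data/definitions.yaml`: never-or-former
smoking, < 3 occasions/week, diet top 40%, exercise ≥ 3 times/week, sleep
6–9 h.

## Clock validation

Cross-sectional on baseline records. Each clock's acceleration is
standardized against the baseline population and cut at ±1 (on the z scale
by default; the cut scale is switchable to raw years) into low/mid/high,
with mid the reference; the cardiopulmonary clock is never categorised
because its accelerations are an order of magnitude smaller than the
others'. Logistic regressions of each mapped disease on the continuous
(per-SD) and categorical terms adjust for the five lifestyle flags plus
the standard covariates. Menopausal status is coded with peri- and
post-menopausal indicators only (reference: premenopausal women and men);
full dummy coding would be exactly collinear with sex. Newton fits that
fail to converge are retried with BFGS and flagged if still unconverged —
never silent NaNs. Wald 95% CIs; no multiple-testing correction, matching
the study design this pipeline operationalises.

A panel passes validation iff its continuous per-SD odds ratio exceeds 1
with a CI excluding 1 for at least one mapped disease. The disease map:
comprehensive → {CVD, diabetes, cancer}; cardiopulmonary → {CVD, chronic
bronchitis}; metabolic → {CVD, diabetes}; liver → {chronic hepatitis or
cirrhosis}; immune → {rheumatoid arthritis}; renal has no mapped disease
and is reported as unvalidatable.

## Change inference

For two waves the fixed-effects estimator is identical to first-difference
OLS, and the implementation exploits that: Δ(acceleration) on Δ(exposures)
and Δ(time-varying covariates). The primary variant also enters
time-invariant covariates (sex, ethnicity, urbanicity, education) and
baseline CA as level terms in the differenced equation — equivalent to
covariate × wave interactions, which is the only way adjustment for a
time-constant covariate can have any effect in a within-person design. The
"standard FEM" sensitivity variant drops them, leaving the pure within
estimator; first-difference and within estimates agree to 1e-10 (tested).
Categorical time-varying covariates are dummy-coded with pooled levels
before differencing. Columns that difference to zero are dropped with a
warning; an exposure with no within-person variation raises a rank error
naming it. SEs are HC1; the short-horizon effect of change is assumed
linear. Exposure modes: the five factor deltas jointly, ΔHLI, or
Δ(HLI category). Subgroup analyses refit per stratum (dropping the
stratifier from the covariates) and compare strata with Cochran's
Q = Σ w_i (β_i − β̄_w)², w_i = 1/se_i², against χ²(k−1), significant at
α = 0.1.

Quantile G-computation runs on the same person-level differenced design so
that ψ and the fixed-effects joint model answer the same estimand: with
the ordinal change exposures passing through quantisation untouched, ψ
equals the sum of the joint-model exposure coefficients to 1e-10 (tested).
Continuous exposures are quantile-binned 0..q−1 (q = 4 default,
right-closed empirical breaks). Weights are |coefficient| divided by the
summed |coefficients| of the same sign; the protective (negative) weights
are the headline output and positive weights are reported separately. The
ψ CI is Wald (HC1) by default or a seeded person-level nonparametric
bootstrap.

## The synthetic cohort

Each person has a shared frailty g_i ~ N(0, 2.5²) years, organ-specific
frailties o_i ~ N(0, 1.5²), and a lifestyle burden Σ_f β_f(1 − healthy_f)
that changes when flags change between waves; markers follow their
sex-specific age lines evaluated at CA + organ acceleration plus N(0, s_j²)
noise. Default effect magnitudes β_f (years of acceleration while
unhealthy) are smoking 0.13, alcohol 0.17, diet 0.15, exercise 0.16, sleep
0.02 — a profile whose protective mixture gives diet a 24% share; a
metabolic profile (smoking 0.54, alcohol 0.18, diet 0.18, exercise 0.09,
sleep −0.01) gives smoking 55%. These shares are what the QGC recovery
suite checks at n = 8000 over 20 seeds (recovered means 0.239 and 0.543).

Baseline ages are uniform on 30–76 with a truncated-normal wave gap
(mean 2.0, SD 0.25, bounds [1, 3] years), keeping all ages within 30–79.
Wave-0 healthy flags are Bernoulli (smoking and alcohol strongly
sex-patterned); wave-1 flags follow per-factor transition probabilities
whose defaults reproduce the emulated change profile: smoking and alcohol
> 90% unchanged, diet and sleep changing in over a third of people,
exercise near 30%, and > 60% of people changing HLI score. Raw
questionnaire fields are generated consistently with the flags; diet runs
through a latent quality variable mapped monotonically into the seven
intake components (small log-scale noise, SD 0.12), so the re-derived
median-split flag agrees with the intended one for ~96% of records.
Covariate distributions (education, occupation, menopausal status by age,
energy intake declining at the repeat wave, etc.) are fixed multinomials
and serve only as adjustment noise.

Diseases are logistic in the baseline acceleration of their mapped organ.
By default the driving acceleration is the *biomarker-implied* one — the
exact inverse-regression composite of the generated marker values under
the true marker model — because diseases are caused by measured physiology
(glycaemia drives diabetes, blood pressure drives CVD), and that is
precisely why a biomarker clock can validate against disease. A config
switch (`disease_driver="latent"`) links them to the latent acceleration
instead; with realistic marker noise that regime flattens every
association toward the null, which is informative for stress-testing but
is not how clinical diseases relate to clinical markers. Rheumatoid
arthritis has a null link by construction so the immune clock fails
validation; no disease maps to the renal clock. Under the defaults the
validation stage retains comprehensive, cardiopulmonary, metabolic and
liver, as intended.

Missingness is injected completely at random per marker (the analysis is
complete-case); attrition between waves is not modelled. The generator
makes no attempt to match any real cohort's joint covariate distribution,
survey weights or ethnic composition, so passing tests demonstrate
estimator correctness and pipeline behaviour, not real-world effect sizes.

## Power, attenuation, and the two cohort profiles

The anchored clock shrinks individual accelerations by λ (above). With
study-condition marker noise, λ for the comprehensive clock is roughly
0.2–0.3, so a true 0.15-year change effect surfaces as ~0.04 years against
differenced-outcome noise of a few years — below the two-wave detection
floor at n ≈ 8000. For this reason: (1) the estimator-recovery suites
(fixed effects and QGC) generate the differenced outcome directly from the
ground-truth change model, Δy = Σ β_f Δflag_f + N(0, σ), with σ = 1–2
years and a 0.25 change probability per factor so every coefficient is
precisely identified — these tests check the estimators, not the
measurement chain; and (2) end-to-end sign demonstrations use a separate
`demo_config` profile (2000 persons, marker noise × 0.2, effects of 1–2
years, disease slopes rescaled to the compressed driver) under which all
five estimated factor effects come out negative with CIs excluding zero.
The study-condition profile remains the default everywhere else.

## Numerical and design choices

- Quintile and quantile bins are right-closed on mid-rank/empirical
  percentiles; degenerate inputs give the middle score (aMED) or all
  zeros with a warning (QGC).
- Sleep interval closed [7, 8]; diet median inclusive (≥); alcohol strict
  (< 1.0/week).
- s_j floored at 1e-8, s_BA² at 0.01 years²; λ limits (s_BA → 0 gives
  BA = CA, s_BA → ∞ gives BA_E) are tested.
- CIs are symmetric Wald (β ± 1.96·se) throughout.
- All randomness flows through `numpy.random.default_rng(seed)`;
  identical config + seed reproduces byte-identical CSVs (tested).
- Cohort simulations in the test suite use 300–8396 persons depending on
  the statistical precision each check needs; the recovery criteria run at
  the full design size of 8000–10000.

## Known limitations

- Two waves only; no random-effects/hybrid models, no attrition, no
  time-to-event outcomes.
- The validation pass rule is an operationalisation (per-SD OR > 1 with CI
  excluding 1 for ≥ 1 mapped disease); other defensible rules exist.
- Marker parameters (q, k, s) are plausible configuration values, not
  population estimates; absolute clock values on synthetic data have no
  clinical meaning.
- The immune panel has only two markers and, as in real panels of this
  kind, limited information; its failure to validate here is by
  construction, not evidence about immune aging.
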