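# Methods

This note documents the models and procedures implemented in `capstew`,
the assumptions behind them, and the judgement calls made where a
published definition leaves room for interpretation.

## Adherence classification

### Initial regimen and combination window

The initial empirical regimen is the set of antibacterial agents whose
first administration falls within 3 h (inclusive) of the earliest
administration; later agents are treated as a therapy switch, not
combination therapy. The window is a parameter of
`build_initial_regimen`; enlarging it can only grow the agent set, and
the regimen is invariant to the order events are supplied in. Dose and
route appropriateness are out of scope — only the choice of agents is
classified.

### CRB-65

The standard clinical definition is used: one point each for confusion,
respiratory rate ≥ 30/min, systolic blood pressure < 90 mmHg or diastolic
≤ 60 mmHg, and age ≥ 65 years. Patients are banded low (0–2,
mild/moderate) or high (≥ 3, severe). Scores are expected as inputs where
available; the `Crb65Inputs` path recomputes them from vitals.

### Empirical-choice rules

Rules are declarative: an ordered list of conditions over
(CRB-65 band, penicillin allergy, eGFR band, ICU status), each carrying
one or more *regimen patterns*. A pattern is a list of components (an
agent set or a whole pharmacological class, with min/max multiplicities);
a regimen satisfies a pattern when its agents can be assigned to
components within those bounds. Matching is **strict** by default: every
administered agent must be accounted for, so adding any agent outside the
pattern renders an otherwise-adherent regimen non-adherent. This reflects
the adherence definitions used for stewardship audits, where an
unprompted extra agent is itself a deviation; strictness is configurable
per rule.

Rule selection is first-match in file order, so the more specific
high-band conditions (ICU, then eGFR < 30 — strictly below 30) precede the
band default. The packaged Norwegian rule set covers:

| Band | Allergy | Adherent patterns |
|---|---|---|
| ≤ 2 | no  | any combination of benzylpenicillin, phenoxymethylpenicillin, ampicillin, amoxicillin |
| ≤ 2 | yes | any single macrolide |
| ≥ 3 | no  | (benzylpenicillin or ampicillin) + (gentamicin or tobramycin) |
| ≥ 3, eGFR < 30 | no | cefotaxime or ceftriaxone |
| ≥ 3, ICU | no | (cefotaxime, ceftriaxone or piperacillin/tazobactam) + a quinolone |
| ≥ 3 | yes | clindamycin + a quinolone |

The ICU recommendation text is grammatically ambiguous about whether the
quinolone is required with all three beta-lactam options or only with
piperacillin/tazobactam. The default applies it to all three (the
conjoint reading); `default_ruleset(icu_reading="pip_tazo_only")` selects
the alternative. Neither reading is asserted as authoritative.

Whether a macrolide *combined* with another agent counts as adherent for
allergic low-band patients is likewise unstated in the source guidance;
strict semantics (single macrolide only) are used and configurable.

Agent names are normalized through a packaged synonym table (generic
names, common brand names, unambiguous ATC codes). Unknown names degrade
to class `other` with the raw name preserved — under strict matching they
classify as non-adherent rather than crashing a cohort run.

### Duration rules

Total therapy time is the union of in-hospital administration intervals
(combination therapy counts calendar time once) plus the sum of planned
post-discharge course lengths. Durations use a 24-h day and closed
intervals. Adherence: duration ≤ recommended days × 24 + 24-h margin,
i.e. ≤ 144 h for the low band and ≤ 192 h for the high band, both
inclusive at the boundary.

## Cohort cascades

Empirical-choice cohort, in order: (1) no antibiotic therapy; (2) first
administration more than 48 h after admission (a start at exactly 48 h is
retained — "within 48 h" is read inclusively); (3) initial choice guided
by microbiology results.

Duration cohort, in order: (1) no therapy; (2) discharge diagnosis other
than CAP or COPD exacerbation; (3) therapy < 24 h; (4) therapy > 480 h
(exactly 20 days is retained); (5) death before the recommended duration
for the band elapsed, operationalized as death time ≤ 144 h (low band) or
≤ 192 h (high); (6) length of stay exceeding the band threshold — the
proxy for failure to stabilize; (7) discharge to a nursing home or other
institution without a documented clinically stable observation (afebrile
< 37.6 °C, respiratory rate ≤ 24/min, SpO₂ > 90% on ambient air, able to
eat — a missing or partial observation is unassessable and conservatively
treated as not stable). The step order is configurable because a patient
can satisfy several exclusion reasons and published flow diagrams do not
fully pin the order; the audit trail records whichever rule fired. Each
excluded patient carries a machine-readable reason, counts chain exactly,
and re-filtering the included set is a fixed point.

## Statistical layer

**Modified Poisson regression.** Non-adherence is a common outcome
(~80% in duration cohorts), so odds ratios would badly overstate effects;
risk ratios are estimated directly with a log-link Poisson model applied
to the 0/1 outcome, fitted by IRLS, with a cluster-robust (HC0-type)
sandwich variance. With one observation per cluster and independence
working correlation this is mathematically the same estimator as a
Poisson GEE; the simpler GLM-with-sandwich form is implemented. On a
saturated single-covariate layout the exponentiated coefficient equals
the 2×2 risk ratio exactly, which the tests exploit as an oracle.
Suspected separation (|coefficient| > 15 on the log scale) raises rather
than returning a misleading estimate.

**2×2 effect measures.** Risk ratios use the Katz log-method 95% CI,
`exp(ln RR ± 1.96 √(1/a − 1/(a+b) + 1/c − 1/(c+d)))`; a zero-event arm
falls back to adding 0.5 to every cell and flags the estimate. P-values
come from Pearson's chi-squared without continuity correction (Yates
correction available by flag). The Wilcoxon rank-sum test uses exact
enumeration for combined n ≤ 10 without ties and the tie-corrected normal
approximation otherwise; fully tied data returns p = 1 with a warning.

**Binarization.** Multivariate models take binary covariates. Shipped
cutoffs: CRP > 100 mg/L, length of stay > 2 days, Clinical Frailty Scale
> 4, CRB-65 > 2, SOFA ≥ 2, NEWS2 > 4, PSI > 90. Continuous covariates
without an established cutoff are cut at their observed median
(direction: strictly greater); a constant column under the median rule is
an error rather than a silent all-zero covariate.

**Population attributable fractions.** The case-load (Miettinen) form
PAF = p_c (RR − 1)/RR, with p_c the exposure prevalence among cases and
RR the adjusted risk ratio. Published PAFs in this literature are not
always reproducible from printed RRs and exposure tables, so the method
tag travels with every estimate. Confidence intervals bootstrap the full
pipeline — resample rows, refit the regression, recompute p_c — with
percentile bounds; degenerate replicates (empty cells, separation) are
dropped, and the estimate fails loudly if fewer than half survive. A RR
below 1 yields a negative PAF, flagged as protective.

**Spline curves.** Probability-of-outcome curves over a continuous
predictor use a natural cubic spline basis (internal knots at equally
spaced quantiles, boundary knots at the data range) inside a binomial
GLM, with pointwise Wald CIs on the linear predictor transformed to the
probability scale. Default 4 degrees of freedom; quasi-separation is
flagged on the returned object.

**Medians and proportions.** Median differences use a seeded bootstrap
percentile CI plus a permutation p-value; proportion differences use the
Wald CI. Bootstrap/permutation defaults are 2000 replicates in the
stats layer (the pipeline uses 500 for PAF CIs to keep a full run under
a minute); all stochastic routines are bit-reproducible under a seed.

## Imputation

Missing numeric covariates are filled by chained predictive mean
matching: variables are visited in order of increasing missingness; each
round regresses the target on all other numeric columns (random forest by
default, k-NN as a cheap alternative, or any scikit-learn regressor
factory), and each missing cell receives the *observed* value of a donor
drawn uniformly from the k = 5 observed rows with the nearest
predictions. Iteration stops when the imputed matrix stabilizes or after
max_iter = 10 rounds (with stochastic donor draws exact stabilization is
rare; the last round is returned and flagged). Observed cells are never
altered; imputed values always lie in the observed support, so flags stay
binary and counts integral. This is single imputation — downstream
standard errors carry no between-imputation variance, matching the
analysis design it supports. Missingness above 50% warns; an all-missing
column is an error.

## Synthetic cohorts

The generator exists so that the full pipeline — classification,
cascades, regression, PAF, splines, imputation — can be exercised and
validated without patient data. Defaults encode the study conditions:

* n = 523; age from a reflected gamma, `age = 89.03 − Gamma(1.91, 10.11)`
  floored at 18, calibrated so median/IQR ≈ 73 (63–80) — the family is a
  modelling choice, not a claim about the real cohort;
* sex 43% female; comorbidity prevalences (COPD 41%, CKD 9.4% of which a
  fifth stage 4/5, immunodeficiency 9.8%, …); antibiotic allergy 9.9%
  with penicillin allergy 6%; CRB-65 band probabilities
  0.24/0.54/0.20/0.027, realized through component vitals consistent with
  the drawn age so the recorded score always recomputes from the record;
* CRP and length of stay log-normal (medians 120 mg/L and 60 h);
  missingness injected MCAR at the published per-variable rates (SOFA
  9.0%, PSI 10.5%, NEWS2 0.4%, CFS 0.6%).

Non-adherence is multiplicative on the risk scale: each patient's
probability is a baseline (0.10 empirical, 0.58 duration) times the true
RR of every exposure they carry (empirical: penicillin allergy 4.9,
CRB-65 ≥ 3 3.9, nursing-home admission 2.3, CKD 1.8, recent antibiotics
1.8; duration: CRP > 100 mg/L 1.37, stay > 2 days 1.22), truncated at
0.99 with a flag in the truth table. The realized state is then
*constructed*, not merely labelled: adherent patients draw regimens from
rule-satisfying menus and durations below their band threshold,
non-adherent patients from violating menus and longer durations, with
small fractions of late starts, micro-guided choices, < 24 h and > 20 d
courses to exercise every cascade step. Classifying the generated events
through the rule engine therefore reproduces the latent states with 100%
agreement — any disagreement is a bug in the generator or the engine, and
a test enforces this round trip.

What the generator does **not** emulate: correlation between covariates
(comorbidities, CRP and severity are drawn independently except for the
mechanical couplings noted above), therapy switches after the initial
regimen, longitudinal vitals, temporal trends, or site effects. Passing
tests therefore demonstrate that the estimators recover known mechanisms
under clean conditions — unbiasedness and calibration — not that the
pipeline is robust to confounding structures it has never seen.

## Validation problem sizes

Parameter recovery uses 200 replicates of n = 5000 single-exposure
cohorts (recovered mean RR within ±0.05 of the generating 1.37 and 1.22);
Wald-test type-I error uses 1000 null replicates at n = 500 (rejection
rate within 5% ± 2 points); sandwich standard errors are checked against
a 2000-replicate nonparametric bootstrap on a 200-row fixture (within
10%); marginal fidelity is checked at the cohort's own n = 523 within
binomial sampling error. These sizes make the Monte-Carlo error
comfortably smaller than the tolerances they guard.

## Known limitations

* The rule engine classifies only the initial regimen; de-escalation and
  switch appropriateness are out of scope.
* PSI, NEWS2 and SOFA are consumed as given numbers, never recomputed
  from raw observations.
* The PAF estimator is one defensible choice among several; comparisons
  against published PAFs computed with unknown estimators are not valid
  ground truth.
* Multivariate coefficients from any real cohort depend on that cohort's
  joint covariate distribution; the synthetic generator's independence
  assumption means its fitted multivariate models validate the machinery,
  not any published coefficient table.
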