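# capstew

Guideline-adherence analysis for antibiotic therapy in hospitalized adults
with suspected community-acquired pneumonia (CAP).

Antimicrobial stewardship programmes need to know *where* and *why*
prescribing deviates from national guidelines. For CAP there are two
distinct stewardship targets: the **choice of empirical therapy** (does the
initial regimen match the recommendation for the patient's CRB-65 severity
band, penicillin-allergy status, kidney function and ICU status?) and the
**duration of therapy** (does the total course — in-hospital plus planned
post-discharge treatment — stay within the recommended days?). `capstew`
implements the full analysis for both targets as a tested, reusable
pipeline for epidemiologists and stewardship teams:

* a declarative **rule engine** that normalizes antibiotic names, builds
  the initial regimen (agents started within 3 h of the first dose count
  as combination therapy), computes CRB-65, and classifies choice and
  duration adherence against a YAML-configurable rule set. The packaged
  default encodes the Norwegian national recommendations (low severity
  5 days → ≤ 144 h adherent, high severity 7 days → ≤ 192 h, each with a
  24-h margin);
* the two **cohort filter cascades** (48-h empirical window and
  microbiology-guided exclusions; the seven-step duration cascade with a
  discharge-status proxy for clinical stability), each with an exclusion
  audit trail that reconciles exactly;
* a **statistical layer** built around modified Poisson regression: a
  log-link Poisson model for the binary non-adherence outcome with
  cluster-robust sandwich variance (equivalently, a Poisson GEE with
  independence working correlation), which estimates risk ratios (RR)
  directly. Around it: 2×2 risk ratios with Katz log-scale confidence
  intervals, Pearson chi-squared and Wilcoxon rank-sum tests, covariate
  binarization, population attributable fractions
  PAF = p_c (RR − 1)/RR with full-pipeline bootstrap CIs, natural-spline
  logistic probability curves, and bootstrap median / Wald proportion
  differences;
* **chained predictive-mean-matching imputation** for missing covariates
  (random-forest or k-NN regressors; imputed values are always observed
  donor values);
* a **synthetic cohort generator** whose defaults reproduce the published
  cohort marginals (n = 523, age median 73 IQR 63–80, antibiotic allergy
  9.9%, CRB-65 ≥ 3 in 2.7%) and whose latent non-adherence mechanism is
  multiplicative on the risk scale with configurable true risk ratios —
  so every stage is testable without access to patient data.

## Worked example

Run both analyses end-to-end on the default synthetic scenario:

```python
from capstew import SyntheticScenario, PipelineConfig, run_pipeline

cfg = PipelineConfig(
    seed=42,
    scenario=SyntheticScenario(seed=42),
    out_dir="example_run",
    paf_n_boot=200,
)
bundle = run_pipeline(cfg)
emp, dur = bundle["empirical"], bundle["duration"]
print(f"empirical cohort: {len(emp['included'])} patients, "
      f"adherence {emp['adherence_rate']:.1%}")
print(f"duration cohort:  {len(dur['included'])} patients, "
      f"adherence {dur['adherence_rate']:.1%}")
reg = dur["regression"].to_frame().set_index("term")
for term in ("crp_max_mg_L", "length_of_stay_h"):
    row = reg.loc[term]
    print(f"{term}: RR {row.rr:.2f} (95% CI {row.ci_low:.2f}, {row.ci_high:.2f}), "
          f"p = {row.p:.3g}")
```

prints

```
empirical cohort: 481 patients, adherence 84.0%
duration cohort:  392 patients, adherence 24.2%
crp_max_mg_L: RR 1.36 (95% CI 1.20, 1.54), p = 2.04e-06
length_of_stay_h: RR 1.41 (95% CI 1.24, 1.61), p = 3.63e-07
```

Read: of the 523 generated admissions, 481 enter the empirical-choice
cohort and 84% received a guideline-concordant initial regimen, while only
24% of the duration cohort stayed within the recommended course length —
the generator's mechanism (baseline non-adherence risk 0.58, true RRs 1.37
for CRP > 100 mg/L and 1.22 for stay > 2 days) drives duration
non-adherence, and the fitted risk ratios recover effects of that order at
this single-cohort sample size. Result tables (filter traces, univariate
comparisons, regression tables, PAFs, spline curves) are written under
`out_dir`, each stamped with the seed and a configuration hash.

The same pipeline runs from the shell on delimited text tables:

```bash
capstew simulate --seed 42 --n 523 --out-dir cohort/
capstew classify --patients cohort/patients.csv --events cohort/events.csv --out verdicts.csv
capstew analyze --patients cohort/patients.csv --events cohort/events.csv --out-dir results/
capstew report --out-dir results/
```

## Documentation

See `docs/methods.md` for the statistical model, the generator's
assumptions and what passing tests do and do not demonstrate about real
cohorts.
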