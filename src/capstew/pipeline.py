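"""End-to-end analysis pipeline for the two stewardship targets.

``run_pipeline`` wires the stages together: read (or simulate) tables ->
impute missing covariates -> build initial regimens and durations ->
apply the two cohort filter cascades -> classify adherence -> univariate
comparison tables -> binarize covariates -> modified Poisson regression
-> population attributable fractions -> natural-spline probability
curves.  Every output file carries the run seed and a hash of the
configuration, and all stochastic steps derive their seeds from the one
configured seed, so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import stats as stats_mod
from .agents import load_default_taxonomy
from .guideline import (
    GuidelineRuleSet,
    NoTherapyError,
    build_initial_regimen,
    classify_duration,
    classify_empirical,
    default_ruleset,
    load_ruleset,
    total_therapy_duration_h,
)
from .imputation import impute_chained_pmm
from .io import events_from_frame, read_tables, write_table
from .synthetic import SyntheticScenario, generate_cohort, inject_missingness

#: default covariate lists (patient-table columns, binarized before the fit)
EMPIRICAL_MODEL_COVARIATES = (
    "age_years",
    "sex_male",
    "clinical_frailty_scale",
    "admitted_from_nursing_home",
    "antibiotics_prior_month",
    "copd",
    "ckd",
    "immunodeficiency",
    "antibiotics_ongoing_at_admission",
    "any_antibiotic_allergy",
    "sofa",
    "crb65_score",
)

DURATION_MODEL_COVARIATES = (
    "age_years",
    "sex_male",
    "immunodeficiency",
    "copd",
    "systemic_steroids",
    "length_of_stay_h",
    "clinical_frailty_scale",
    "charlson_index",
    "sofa",
    "ventilatory_support",
    "icu_admission",
    "crp_max_mg_L",
    "bacteria_detected",
    "virus_detected",
    "hi_mcat",
    "enterobacterales_nonfermenter",
)


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run (file paths or a scenario)."""

    seed: int = 0
    analysis: Literal["empirical", "duration", "both"] = "both"
    patient_table: str | None = None
    event_table: str | None = None
    rules_config: str | None = None
    scenario: SyntheticScenario | None = None
    out_dir: str = "capstew_out"
    empirical_covariates: Sequence[str] = EMPIRICAL_MODEL_COVARIATES
    duration_covariates: Sequence[str] = DURATION_MODEL_COVARIATES
    binarization_overrides: Sequence[stats_mod.BinarizationRule] = ()
    paf_n_boot: int = 500
    spline_df: int = 4
    significance_level: float = 0.05
    impute_regressor: str = "random_forest"
    impute_max_iter: int = 5

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # output location does not affect results
        payload["binarization_overrides"] = [
            (r.variable, r.cutoff, r.direction) for r in self.binarization_overrides
        ]
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _prepare_tables(cfg: PipelineConfig, rules: GuidelineRuleSet):
    if cfg.scenario is not None:
        patients, events, truth = generate_cohort(cfg.scenario, rules)
        if cfg.scenario.missingness_rates:
            patients = inject_missingness(
                patients, cfg.scenario.missingness_rates, seed=cfg.scenario.seed + 1
            )
        return patients, events, truth
    if not (cfg.patient_table and cfg.event_table):
        raise PipelineError("read", "need either a scenario or both input tables")
    patients, events, report = read_tables(cfg.patient_table, cfg.event_table)
    if not report.ok:
        raise PipelineError("read", "; ".join(report.errors))
    return patients, events, None


def _univariate_table(
    data: pd.DataFrame, outcome: pd.Series, covariates: Sequence[str]
) -> pd.DataFrame:
    """Adherent-vs-non-adherent comparison per covariate: chi-squared for
    binary variables, Wilcoxon rank-sum for continuous ones."""
    rows = []
    for cov in covariates:
        values = data[cov]
        complete = values.notna()
        v, o = values[complete], outcome[complete]
        if v.dropna().isin([0, 1, True, False]).all():
            t = stats_mod.two_by_two(v.astype(bool), o.astype(bool))
            try:
                _, p = stats_mod.pearson_chisq(t)
            except ValueError:
                p = np.nan
            rows.append(
                {
                    "variable": cov,
                    "type": "binary",
                    "nonadherent_summary": f"{t.a}/{t.a + t.b}",
                    "adherent_summary": f"{t.c}/{t.c + t.d}",
                    "p_value": p,
                }
            )
        else:
            x = v[o.astype(bool)]
            y = v[~o.astype(bool)]
            if len(x) == 0 or len(y) == 0:
                continue
            _, p = stats_mod.wilcoxon_ranksum(x, y)
            rows.append(
                {
                    "variable": cov,
                    "type": "continuous",
                    "nonadherent_summary": f"median {np.median(x):.1f}",
                    "adherent_summary": f"median {np.median(y):.1f}",
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def _fit_analysis(
    data: pd.DataFrame,
    outcome_col: str,
    covariates: Sequence[str],
    cfg: PipelineConfig,
    seed: int,
):
    rules = list(stats_mod.DEFAULT_BINARIZATION_RULES) + list(cfg.binarization_overrides)
    continuous = [
        c
        for c in covariates
        if not data[c].dropna().isin([0, 1, True, False]).all()
    ]
    binar, applied = stats_mod.binarize(data, rules, median_for=continuous)
    X = binar[list(covariates)].astype(float)
    y = binar[outcome_col].astype(int)
    fit = stats_mod.modified_poisson(y.to_numpy(), X)

    model_data = pd.concat([X, y.rename(outcome_col)], axis=1)
    pafs = []
    for term, est in fit.estimates.items():
        if term == "const" or est.p_value >= cfg.significance_level:
            continue
        cases = model_data[model_data[outcome_col] == 1]
        p_c = float(cases[term].mean()) if len(cases) else 0.0
        source = stats_mod.paf_bootstrap_source(model_data, outcome_col, term, [c for c in covariates if c != term])
        est_paf = stats_mod.paf(
            est.rr, p_c, resample_source=source, n_boot=cfg.paf_n_boot, seed=seed
        )
        pafs.append(
            {
                "term": term,
                "rr": est.rr,
                "p_c": p_c,
                "paf": est_paf.paf,
                "ci_low": est_paf.ci_low,
                "ci_high": est_paf.ci_high,
                "method": est_paf.method,
                "n_boot": est_paf.n_boot,
            }
        )
    return fit, applied, pd.DataFrame(pafs)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured analyses; returns a bundle of result frames
    and writes them under ``cfg.out_dir``."""
    out_dir = Path(cfg.out_dir)
    chash = cfg.config_hash()
    seed = cfg.seed
    taxonomy = load_default_taxonomy()
    rules = load_ruleset(cfg.rules_config) if cfg.rules_config else default_ruleset()

    log: list[str] = [f"seed={seed}", f"config_hash={chash}"]
    bundle: dict = {}

    patients, events_frame, truth = _prepare_tables(cfg, rules)
    log.append(f"patients read: {len(patients)}")
    events = events_from_frame(events_frame, taxonomy)

    # imputation of missing numeric covariates
    try:
        imputable = [
            c
            for c in patients.columns
            if pd.api.types.is_numeric_dtype(patients[c])
            and patients[c].isna().any()
            and c not in ("death_time_h",)
        ]
        patients_complete, imp_report = impute_chained_pmm(
            patients,
            columns=imputable,
            predictor_model=cfg.impute_regressor,
            max_iter=cfg.impute_max_iter,
            seed=seed + 11,
        )
        log.append(
            f"imputed columns: {imputable} in {imp_report.iterations} iterations"
        )
    except (ValueError, TypeError) as exc:
        raise PipelineError("impute", str(exc))

    # per-patient regimen, duration, verdicts
    verdict_rows = []
    for row in patients_complete.itertuples(index=False):
        pid = row.patient_id
        evs = events.get(pid, [])
        rec: dict = {"patient_id": pid}
        try:
            regimen = build_initial_regimen(evs)
            v = classify_empirical(
                regimen,
                int(row.crb65_score),
                bool(row.penicillin_allergy),
                float(row.egfr),
                bool(row.icu_admission),
                rules,
            )
            rec.update(
                empirical_adherent=v.adherent,
                empirical_rule_id=v.rule_id,
                empirical_rationale=v.rationale,
            )
            duration_h = total_therapy_duration_h(evs)
            dv = classify_duration(duration_h, int(row.crb65_score), rules)
            rec.update(
                total_duration_h=duration_h,
                duration_adherent=dv.adherent,
                duration_rationale=dv.rationale,
            )
        except NoTherapyError:
            rec.update(
                empirical_adherent=None,
                empirical_rule_id=None,
                empirical_rationale="no antibiotic therapy",
                total_duration_h=np.nan,
                duration_adherent=None,
                duration_rationale="no antibiotic therapy",
            )
        verdict_rows.append(rec)
    verdicts = pd.DataFrame(verdict_rows)
    merged = patients_complete.merge(verdicts, on="patient_id")
    merged["sex_male"] = (merged["sex"] == "male").astype(int)
    bundle["verdicts"] = verdicts

    analyses = (
        ("empirical", "duration")
        if cfg.analysis == "both"
        else (cfg.analysis,)
    )
    out_dir.mkdir(parents=True, exist_ok=True)

    if "empirical" in analyses:
        included, trace = cohort_mod.filter_empirical_cohort(merged, events)
        sub = merged[merged["patient_id"].isin(included)].copy()
        sub["nonadherent"] = (~sub["empirical_adherent"].astype(bool)).astype(int)
        rate = float(sub["empirical_adherent"].mean()) if len(sub) else np.nan
        log.append(
            f"empirical cohort: {len(sub)} included, adherence rate {rate:.3f}"
        )
        uni = _univariate_table(sub, sub["nonadherent"], cfg.empirical_covariates)
        fit, applied, pafs = _fit_analysis(
            sub, "nonadherent", cfg.empirical_covariates, cfg, seed + 21
        )
        bundle["empirical"] = {
            "trace": trace,
            "included": included,
            "adherence_rate": rate,
            "univariate": uni,
            "regression": fit,
            "paf": pafs,
        }
        write_table(cohort_mod.summarize_flow(trace), out_dir / "empirical_flow.csv", seed, chash)
        write_table(uni, out_dir / "empirical_univariate.csv", seed, chash)
        write_table(fit.to_frame(), out_dir / "empirical_regression.csv", seed, chash)
        write_table(pafs, out_dir / "empirical_paf.csv", seed, chash)
        write_table(applied, out_dir / "empirical_binarization.csv", seed, chash)

    if "duration" in analyses:
        included, trace = cohort_mod.filter_duration_cohort(merged, events, rules)
        sub = merged[merged["patient_id"].isin(included)].copy()
        sub["nonadherent"] = (~sub["duration_adherent"].astype(bool)).astype(int)
        rate = float(sub["duration_adherent"].mean()) if len(sub) else np.nan
        log.append(
            f"duration cohort: {len(sub)} included, adherence rate {rate:.3f}"
        )
        uni = _univariate_table(sub, sub["nonadherent"], cfg.duration_covariates)
        fit, applied, pafs = _fit_analysis(
            sub, "nonadherent", cfg.duration_covariates, cfg, seed + 22
        )
        curves = {}
        for var in ("crp_max_mg_L", "length_of_stay_h"):
            if sub[var].nunique() > cfg.spline_df and len(sub) >= 50:
                curves[var] = stats_mod.spline_logistic_curve(
                    sub[var].to_numpy(), sub["nonadherent"].to_numpy(), df=cfg.spline_df
                )
        bundle["duration"] = {
            "trace": trace,
            "included": included,
            "adherence_rate": rate,
            "univariate": uni,
            "regression": fit,
            "paf": pafs,
            "spline_curves": curves,
        }
        write_table(cohort_mod.summarize_flow(trace), out_dir / "duration_flow.csv", seed, chash)
        write_table(uni, out_dir / "duration_univariate.csv", seed, chash)
        write_table(fit.to_frame(), out_dir / "duration_regression.csv", seed, chash)
        write_table(pafs, out_dir / "duration_paf.csv", seed, chash)
        write_table(applied, out_dir / "duration_binarization.csv", seed, chash)
        for var, curve in curves.items():
            write_table(curve.to_frame(), out_dir / f"duration_spline_{var}.csv", seed, chash)

    if truth is not None:
        write_table(truth, out_dir / "truth_table.csv", seed, chash)
        bundle["truth"] = truth
    (out_dir / "run_log.txt").write_text("\n".join(log) + "\n")
    bundle["log"] = log
    bundle["config_hash"] = chash
    return bundle
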