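"""Synthetic admission cohorts with a known adherence mechanism.

No patient-level CAP adherence dataset is publicly deposited, so every
pipeline stage is exercised on generated cohorts whose covariate marginals
are calibrated to the published baseline table of the study population
(n = 523; age median 73, IQR 63-80; antibiotic allergy 9.9%; CRB-65 band
frequencies 24/54/20/2.7%) and whose outcome mechanism is explicit:

* each patient's probability of *non-adherence* (separately for empirical
  choice and therapy duration) is a baseline risk multiplied by the true
  risk ratio of every exposure they carry, truncated below 1;
* the realized adherence state is then *materialized as antibiotic events*
  drawn from rule-satisfying or rule-violating regimen menus and duration
  targets, so the guideline engine recovers the latent state exactly;
* a truth table records every latent quantity for recovery tests.

Covariates are generated independently of each other (apart from the
mechanical couplings: CRB-65 uses the drawn age, eGFR follows CKD stage,
exposures feed the risk model); no between-comorbidity correlation is
claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .guideline import GuidelineRuleSet, crb65_band, default_ruleset

# reflected-gamma age model: age = offset - Gamma(shape, scale), floored at
# 18; calibrated numerically to median 73 with IQR (63, 80)
AGE_OFFSET = 89.028
AGE_SHAPE = 1.9069
AGE_SCALE = 10.1064

#: regimen menus per empirical rule id: options satisfying the default
#: Norwegian rule set, and violating options (beta-lactams / clindamycin /
#: tetracyclines for allergic low-band patients, monotherapy or wrong class
#: for severe disease).
ADHERENT_MENUS: dict[str, tuple[tuple[str, ...], ...]] = {
    "low_band_no_allergy": (
        ("benzylpenicillin",),
        ("phenoxymethylpenicillin",),
        ("amoxicillin",),
        ("ampicillin",),
        ("benzylpenicillin", "amoxicillin"),
    ),
    "low_band_allergy": (("erythromycin",), ("azithromycin",), ("clarithromycin",)),
    "high_band_standard": (
        ("benzylpenicillin", "gentamicin"),
        ("ampicillin", "gentamicin"),
        ("benzylpenicillin", "tobramycin"),
    ),
    "high_band_low_egfr": (("cefotaxime",), ("ceftriaxone",)),
    "high_band_icu": (
        ("cefotaxime", "ciprofloxacin"),
        ("piperacillin_tazobactam", "ciprofloxacin"),
        ("ceftriaxone", "levofloxacin"),
    ),
    "high_band_allergy": (
        ("clindamycin", "ciprofloxacin"),
        ("clindamycin", "levofloxacin"),
    ),
}

VIOLATING_MENUS: dict[str, tuple[tuple[str, ...], ...]] = {
    "low_band_no_allergy": (
        ("cefotaxime",),
        ("piperacillin_tazobactam",),
        ("doxycycline",),
        ("cefuroxime",),
        ("benzylpenicillin", "gentamicin"),
    ),
    "low_band_allergy": (
        ("benzylpenicillin",),
        ("cefotaxime",),
        ("cefuroxime",),
        ("clindamycin",),
        ("doxycycline",),
    ),
    "high_band_standard": (
        ("benzylpenicillin",),
        ("cefotaxime",),
        ("erythromycin",),
    ),
    "high_band_low_egfr": (("benzylpenicillin", "gentamicin"), ("cefuroxime",)),
    "high_band_icu": (("cefotaxime",), ("benzylpenicillin", "gentamicin")),
    "high_band_allergy": (("clindamycin",), ("ciprofloxacin",), ("cefotaxime",)),
}


@dataclass
class SyntheticScenario:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int
    n_patients: int = 523

    # demographic / clinical marginals
    sex_female: float = 0.43
    crb65_band_probs: tuple[float, float, float, float] = (0.24, 0.54, 0.20, 0.027)
    comorbidity_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {
            "copd": 0.41,
            "ckd": 0.094,
            "immunodeficiency": 0.098,
            "hypertension": 0.37,
            "chf": 0.16,
            "diabetes": 0.13,
            "cancer": 0.096,
            "cognitive_impairment": 0.029,
        }
    )
    ckd_stage45_given_ckd: float = 0.20
    any_allergy_prevalence: float = 0.099
    penicillin_allergy_prevalence: float = 0.060
    icu_prevalence: float = 0.03
    nursing_home_admission_prevalence: float = 0.05
    antibiotics_prior_month_prevalence: float = 0.22
    antibiotics_ongoing_prevalence: float = 0.20
    micro_guided_prevalence: float = 0.025
    late_start_fraction: float = 0.06
    no_therapy_fraction: float = 0.0
    crp_median_mg_L: float = 120.0
    crp_log_sigma: float = 0.9
    los_median_h: float = 60.0
    los_log_sigma: float = 0.7
    discharge_destination_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "home": 0.93,
            "nursing_home_or_institution": 0.06,
            "died": 0.01,
        }
    )
    discharge_diagnosis_probs: Mapping[str, float] = field(
        default_factory=lambda: {"cap": 0.80, "copd_exacerbation": 0.14, "other": 0.06}
    )
    stable_at_discharge: float = 0.90
    short_course_fraction: float = 0.025
    long_course_fraction: float = 0.05

    # adherence mechanism (risk scale, multiplicative)
    empirical_baseline_risk: float = 0.10
    empirical_rrs: Mapping[str, float] = field(
        default_factory=lambda: {
            "penicillin_allergy": 4.9,
            "crb65_high": 3.9,
            "ckd": 1.8,
            "admitted_from_nursing_home": 2.3,
            "antibiotics_prior_month": 1.8,
        }
    )
    duration_baseline_risk: float = 0.58
    duration_rrs: Mapping[str, float] = field(
        default_factory=lambda: {"crp_gt100": 1.37, "los_gt2d": 1.22}
    )
    risk_cap: float = 0.99

    missingness_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "sofa": 0.090,
            "psi": 0.105,
            "news2": 0.004,
            "clinical_frailty_scale": 0.006,
        }
    )

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in (
            "comorbidity_prevalence",
            "empirical_rrs",
            "duration_rrs",
            "missingness_rates",
            "discharge_destination_probs",
            "discharge_diagnosis_probs",
        ):
            d[key] = dict(d[key])
        return d


def _draw_ages(n: int, rng: np.random.Generator) -> np.ndarray:
    ages = AGE_OFFSET - rng.gamma(AGE_SHAPE, AGE_SCALE, size=n)
    while np.any(ages < 18):
        bad = ages < 18
        ages[bad] = AGE_OFFSET - rng.gamma(AGE_SHAPE, AGE_SCALE, size=int(bad.sum()))
    return ages


def _draw_crb65_scores(
    ages: np.ndarray, band_probs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample total CRB-65 scores whose marginal matches ``band_probs``
    while staying consistent with the age point (age >= 65).

    The score distribution is split into conditionals given the age point
    so the unconditional frequencies still hit the targets: young patients
    absorb all the zero scores, elderly patients the top scores.
    """
    p = band_probs / band_probs.sum()
    old = ages >= 65
    q = float(old.mean())
    if q in (0.0, 1.0):
        return rng.choice(4, size=ages.size, p=p)
    p_young = np.array([min(1.0, p[0] / (1 - q)), 0, 0, 0])
    p_young[1] = 1 - p_young[0]
    p_old = np.array(
        [
            0.0,
            max(0.0, (p[1] - (1 - q) * p_young[1]) / q),
            min(1.0, p[2] / q),
            min(1.0, p[3] / q),
        ]
    )
    p_old = p_old / p_old.sum()
    scores = np.empty(ages.size, dtype=int)
    scores[~old] = rng.choice(4, size=int((~old).sum()), p=p_young)
    scores[old] = rng.choice(4, size=int(old.sum()), p=p_old)
    return scores


def _vitals_for_score(
    score: int, age_point: bool, rng: np.random.Generator
) -> dict:
    """Choose CRB-65 components summing to ``score`` and emit consistent
    vital signs."""
    needed = score - int(age_point)
    needed = int(np.clip(needed, 0, 3))
    which = rng.permutation(3)[:needed]  # 0=confusion, 1=resp rate, 2=BP
    confusion = 0 in which
    rr_point = 1 in which
    bp_point = 2 in which
    return {
        "confusion": confusion,
        "respiratory_rate_per_min": float(
            rng.uniform(30, 40) if rr_point else rng.uniform(12, 28)
        ),
        "systolic_bp_mmHg": float(
            rng.uniform(70, 88) if bp_point else rng.uniform(95, 150)
        ),
        "diastolic_bp_mmHg": float(
            rng.uniform(40, 58) if bp_point else rng.uniform(62, 90)
        ),
    }


def _bernoulli(rng: np.random.Generator, p: float, n: int) -> np.ndarray:
    return rng.random(n) < p


def _multiplicative_risk(
    base: float, exposures: Mapping[str, np.ndarray], rrs: Mapping[str, float], cap: float
) -> tuple[np.ndarray, np.ndarray]:
    risk = np.full(next(iter(exposures.values())).size, base, dtype=float)
    for name, rr in rrs.items():
        risk = risk * np.where(exposures[name], rr, 1.0)
    truncated = risk > cap
    return np.minimum(risk, cap), truncated


def generate_cohort(
    scenario: SyntheticScenario, rules: GuidelineRuleSet | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (patient table, event table, truth table).

    The truth table carries every latent state (per-patient non-adherence
    probabilities, realized states, generating rule id, truncation flags)
    and is kept separate so analyses can run blind.
    """
    rng = np.random.default_rng(scenario.seed)
    rules = rules or default_ruleset()
    n = scenario.n_patients
    s = scenario

    ages = _draw_ages(n, rng)
    scores = _draw_crb65_scores(ages, np.asarray(s.crb65_band_probs, float), rng)
    female = _bernoulli(rng, s.sex_female, n)

    comorb = {k: _bernoulli(rng, p, n) for k, p in s.comorbidity_prevalence.items()}
    ckd45 = comorb["ckd"] & _bernoulli(rng, s.ckd_stage45_given_ckd, n)
    egfr = np.where(
        ckd45,
        rng.uniform(8, 29, n),
        np.where(
            comorb["ckd"],
            rng.uniform(32, 55, n),
            np.clip(rng.normal(78, 15, n), 35, 130),
        ),
    )

    pen_allergy = _bernoulli(rng, s.penicillin_allergy_prevalence, n)
    extra = (s.any_allergy_prevalence - s.penicillin_allergy_prevalence) / max(
        1e-12, 1 - s.penicillin_allergy_prevalence
    )
    any_allergy = pen_allergy | _bernoulli(rng, max(0.0, extra), n)
    icu = _bernoulli(rng, s.icu_prevalence, n)
    nursing_home = _bernoulli(rng, s.nursing_home_admission_prevalence, n)
    abx_month = _bernoulli(rng, s.antibiotics_prior_month_prevalence, n)
    abx_ongoing = _bernoulli(rng, s.antibiotics_ongoing_prevalence, n)
    micro_guided = _bernoulli(rng, s.micro_guided_prevalence, n)

    crp = np.exp(rng.normal(np.log(s.crp_median_mg_L), s.crp_log_sigma, n))
    los_draw = np.exp(rng.normal(np.log(s.los_median_h), s.los_log_sigma, n))

    destinations = rng.choice(
        list(s.discharge_destination_probs),
        size=n,
        p=np.asarray(list(s.discharge_destination_probs.values())) /
        sum(s.discharge_destination_probs.values()),
    )
    diagnoses = rng.choice(
        list(s.discharge_diagnosis_probs),
        size=n,
        p=np.asarray(list(s.discharge_diagnosis_probs.values())) /
        sum(s.discharge_diagnosis_probs.values()),
    )

    # therapy timing
    no_therapy = _bernoulli(rng, s.no_therapy_fraction, n)
    late = _bernoulli(rng, s.late_start_fraction, n) & ~no_therapy
    t0 = np.where(late, rng.uniform(48.5, 120, n), rng.uniform(0.0, 36.0, n))
    los = np.maximum(los_draw, t0 + 2.0)

    # latent non-adherence states
    emp_expo = {
        "penicillin_allergy": pen_allergy,
        "crb65_high": scores >= 3,
        "ckd": comorb["ckd"],
        "admitted_from_nursing_home": nursing_home,
        "antibiotics_prior_month": abx_month,
    }
    p_emp, emp_trunc = _multiplicative_risk(
        s.empirical_baseline_risk, emp_expo, s.empirical_rrs, s.risk_cap
    )
    emp_nonadh = rng.random(n) < p_emp

    dur_expo = {"crp_gt100": crp > 100.0, "los_gt2d": los > 48.0}
    p_dur, dur_trunc = _multiplicative_risk(
        s.duration_baseline_risk, dur_expo, s.duration_rrs, s.risk_cap
    )
    dur_nonadh_latent = rng.random(n) < p_dur

    short_course = _bernoulli(rng, s.short_course_fraction, n) & ~no_therapy
    long_course = _bernoulli(rng, s.long_course_fraction, n) & ~no_therapy & ~short_course

    patient_rows = []
    event_rows = []
    truth_rows = []
    for i in range(n):
        pid = f"P{i:05d}"
        vit = _vitals_for_score(int(scores[i]), ages[i] >= 65, rng)
        # recompute the realized score from the constructed components
        realized = (
            int(vit["confusion"])
            + int(vit["respiratory_rate_per_min"] >= 30)
            + int(
                vit["systolic_bp_mmHg"] < 90 or vit["diastolic_bp_mmHg"] <= 60
            )
            + int(ages[i] >= 65)
        )
        band = crb65_band(realized)
        thr = rules.duration_rules[band].threshold_h

        stable = rng.random() < s.stable_at_discharge
        if stable:
            stab = {
                "stability_temperature_C": float(rng.uniform(36.0, 37.5)),
                "stability_respiratory_rate": float(rng.uniform(12, 24)),
                "stability_spo2_percent": float(rng.uniform(91, 99)),
                "stability_able_to_eat": True,
            }
        else:
            stab = {
                "stability_temperature_C": float(rng.uniform(37.6, 39.5)),
                "stability_respiratory_rate": float(rng.uniform(25, 34)),
                "stability_spo2_percent": float(rng.uniform(80, 90)),
                "stability_able_to_eat": bool(rng.random() < 0.5),
            }

        death_time = np.nan
        if destinations[i] == "died":
            death_time = float(rng.uniform(48, 600))

        patient_rows.append(
            {
                "patient_id": pid,
                "age_years": float(ages[i]),
                "sex": "female" if female[i] else "male",
                **vit,
                "crb65_score": realized,
                "penicillin_allergy": bool(pen_allergy[i]),
                "any_antibiotic_allergy": bool(any_allergy[i]),
                "egfr": float(egfr[i]),
                "icu_admission": bool(icu[i]),
                **{k: bool(v[i]) for k, v in comorb.items()},
                "ckd_stage45": bool(ckd45[i]),
                "clinical_frailty_scale": int(np.clip(round(rng.normal(3.7, 1.8)), 1, 9)),
                "charlson_index": int(rng.poisson(3.8)),
                "sofa": int(rng.poisson(2.0)),
                "news2": int(np.clip(round(rng.normal(5.2, 2.6)), 0, 17)),
                "psi": int(np.clip(round(rng.normal(88, 32)), 10, 220)),
                "crp_max_mg_L": float(crp[i]),
                "length_of_stay_h": float(los[i]),
                "discharge_destination": destinations[i],
                "discharge_diagnosis": diagnoses[i],
                "death_time_h": death_time,
                "prior_hospitalization_14d": False,
                "antibiotics_prior_month": bool(abx_month[i]),
                "antibiotics_ongoing_at_admission": bool(abx_ongoing[i]),
                "admitted_from_nursing_home": bool(nursing_home[i]),
                "initial_choice_guided_by_micro": bool(micro_guided[i]),
                "bacteria_detected": bool(rng.random() < 0.50),
                "virus_detected": bool(rng.random() < 0.44),
                "gram_positive": bool(rng.random() < 0.24),
                "hi_mcat": bool(rng.random() < 0.34),
                "enterobacterales_nonfermenter": bool(rng.random() < 0.11),
                "covid_vaccinated": bool(rng.random() < 0.77),
                "pneumococcal_vaccine_5y": bool(rng.random() < 0.40),
                "influenza_vaccine_season": bool(rng.random() < 0.54),
                "ventilatory_support": bool(rng.random() < 0.12),
                "systemic_steroids": bool(rng.random() < 0.15),
                **stab,
            }
        )

        rule_id = None
        total_h = np.nan
        if not no_therapy[i]:
            rule = rules.select_empirical_rule(
                realized, bool(pen_allergy[i]), float(egfr[i]), bool(icu[i])
            )
            rule_id = rule.rule_id
            menu = (
                VIOLATING_MENUS[rule_id] if emp_nonadh[i] else ADHERENT_MENUS[rule_id]
            )
            agents = menu[rng.integers(0, len(menu))]

            if short_course[i]:
                total_h = float(rng.uniform(6, 23))
            elif long_course[i]:
                total_h = float(rng.uniform(481, 700))
            elif dur_nonadh_latent[i]:
                total_h = float(rng.uniform(thr + 6, 478))
            else:
                total_h = float(rng.uniform(84, thr))

            inpat = float(np.clip(los[i] - t0[i], 1.0, total_h))
            plan = total_h - inpat
            start = float(t0[i])
            max_offset = min(2.8, inpat - 0.5)  # keep stop after start
            for j, code in enumerate(agents):
                offset = 0.0 if j == 0 else float(rng.uniform(0.2, max_offset))
                event_rows.append(
                    {
                        "patient_id": pid,
                        "event_id": f"{pid}-E{j}",
                        "agent": code,
                        "start_time_h": start + offset,
                        "stop_time_h": start + inpat,
                        "route": "iv",
                        "setting": "inpatient",
                        "planned_duration_h": np.nan,
                    }
                )
            if plan > 1e-9:
                event_rows.append(
                    {
                        "patient_id": pid,
                        "event_id": f"{pid}-ED",
                        "agent": agents[0],
                        "start_time_h": start + inpat,
                        "stop_time_h": np.nan,
                        "route": "oral",
                        "setting": "discharge_plan",
                        "planned_duration_h": plan,
                    }
                )

        truth_rows.append(
            {
                "patient_id": pid,
                "empirical_rule_id": rule_id,
                "p_empirical_nonadherence": float(p_emp[i]),
                "empirical_nonadherent": bool(emp_nonadh[i]),
                "p_duration_nonadherence": float(p_dur[i]),
                "duration_nonadherent_latent": bool(dur_nonadh_latent[i]),
                "duration_nonadherent": bool(total_h > thr) if not np.isnan(total_h) else None,
                "total_duration_h": total_h,
                "band_threshold_h": thr,
                "risk_truncated_empirical": bool(emp_trunc[i]),
                "risk_truncated_duration": bool(dur_trunc[i]),
                "no_therapy": bool(no_therapy[i]),
                "short_course": bool(short_course[i]),
                "long_course": bool(long_course[i]),
            }
        )

    patients = pd.DataFrame(patient_rows)
    events = pd.DataFrame(
        event_rows,
        columns=[
            "patient_id",
            "event_id",
            "agent",
            "start_time_h",
            "stop_time_h",
            "route",
            "setting",
            "planned_duration_h",
        ],
    )
    truth = pd.DataFrame(truth_rows)
    return patients, events, truth


def inject_missingness(
    table: pd.DataFrame,
    rates: Mapping[str, float],
    mechanism: str = "MCAR",
    seed: int = 0,
) -> pd.DataFrame:
    """Mask cells completely at random at the per-variable rates."""
    if mechanism != "MCAR":
        raise ValueError("only MCAR masking is implemented")
    rng = np.random.default_rng(seed)
    out = table.copy()
    for col, rate in rates.items():
        if not 0 <= rate < 1:
            raise ValueError(f"rate for {col!r} must be in [0, 1)")
        if rate == 0:
            continue
        mask = rng.random(len(out)) < rate
        out[col] = out[col].astype("float64")
        out.loc[mask, col] = np.nan
    return out


def simulate_binary_risk_cohort(
    n: int,
    exposure_prevalence: float,
    baseline_risk: float,
    true_rr: float,
    rng: np.random.Generator | int,
    exposure_name: str = "exposure",
) -> pd.DataFrame:
    """Minimal cohort for parameter-recovery experiments: one binary
    exposure, outcome risk = baseline * RR^exposure."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    risk_exposed = baseline_risk * true_rr
    if risk_exposed >= 1:
        raise ValueError("baseline_risk * true_rr must stay below 1")
    exposure = rng.random(n) < exposure_prevalence
    risk = np.where(exposure, risk_exposed, baseline_risk)
    outcome = rng.random(n) < risk
    return pd.DataFrame(
        {exposure_name: exposure.astype(int), "outcome": outcome.astype(int)}
    )
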