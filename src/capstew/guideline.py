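"""Rule engine for guideline adherence of empirical antibiotic therapy.

The engine answers two questions for one hospital admission with suspected
community-acquired pneumonia (or COPD exacerbation):

* **choice** — does the *initial* regimen (all agents started within a
  short combination window of the first administration) match the national
  recommendation for the patient's CRB-65 severity band, penicillin-allergy
  status, kidney function (eGFR band) and ICU status?
* **duration** — is the total therapy duration (union of in-hospital
  treatment intervals plus planned post-discharge days) within the
  recommended number of days plus a 24-hour margin?

Rules are declarative (:class:`GuidelineRuleSet`) and load from a YAML
config; the packaged default encodes the Norwegian recommendations
(low severity 5 days -> 144 h threshold, high severity 7 days -> 192 h).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Sequence

import yaml

from .agents import AgentTaxonomy, AntibioticAgent, load_default_taxonomy

COMBINATION_WINDOW_H = 3.0


# ---------------------------------------------------------------------------
# events and regimens


@dataclass(frozen=True)
class AntibioticEvent:
    """One timed administration (inpatient) or discharge prescription."""

    patient_id: str
    agent: AntibioticAgent
    start_time_h: float
    route: Literal["iv", "oral"] = "iv"
    setting: Literal["inpatient", "discharge_plan"] = "inpatient"
    stop_time_h: float | None = None
    planned_duration_h: float | None = None
    event_id: str | None = None

    def __post_init__(self) -> None:
        if self.setting == "inpatient":
            if self.stop_time_h is None:
                raise ValueError(f"inpatient event {self.event_id or ''} lacks stop_time_h")
            if self.stop_time_h < self.start_time_h:
                raise ValueError("stop_time_h precedes start_time_h")
        elif self.setting == "discharge_plan":
            if self.planned_duration_h is None or self.planned_duration_h <= 0:
                raise ValueError("discharge_plan event needs planned_duration_h > 0")


class NoTherapyError(ValueError):
    """Raised when an operation that needs antibiotic events receives none.

    Downstream cohort filters catch this and exclude the patient rather
    than failing the run.
    """


@dataclass(frozen=True)
class Regimen:
    """The initial empirical regimen: agents started within the window."""

    agents: frozenset[AntibioticAgent]
    t0_h: float
    member_event_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.agents:
            raise ValueError("regimen must contain at least one agent")

    @property
    def codes(self) -> frozenset[str]:
        return frozenset(a.code for a in self.agents)


def build_initial_regimen(
    events: Sequence[AntibioticEvent], window_h: float = COMBINATION_WINDOW_H
) -> Regimen:
    """Group agents started within ``window_h`` of the first administration.

    Agents whose first dose starts later than ``t0 + window_h`` represent a
    therapy switch, not combination therapy, and are excluded.  The window
    boundary is inclusive.
    """
    if not events:
        raise NoTherapyError("no antibiotic therapy recorded")
    ordered = sorted(events, key=lambda e: e.start_time_h)
    t0 = ordered[0].start_time_h
    members = [e for e in ordered if e.start_time_h <= t0 + window_h]
    return Regimen(
        agents=frozenset(e.agent for e in members),
        t0_h=t0,
        member_event_ids=tuple(e.event_id for e in members if e.event_id is not None),
    )


def total_therapy_duration_h(events: Sequence[AntibioticEvent]) -> float:
    """Total therapy time: union of inpatient intervals + planned days.

    Overlapping inpatient intervals are merged first, so combination
    therapy counts calendar time once rather than per drug.  Planned
    post-discharge courses are additive (they happen after discharge).
    """
    if not events:
        raise NoTherapyError("no antibiotic therapy recorded")
    intervals = sorted(
        (e.start_time_h, e.stop_time_h) for e in events if e.setting == "inpatient"
    )
    union = 0.0
    cur_lo: float | None = None
    cur_hi = 0.0
    for lo, hi in intervals:
        if cur_lo is None or lo > cur_hi:
            if cur_lo is not None:
                union += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    if cur_lo is not None:
        union += cur_hi - cur_lo
    planned = sum(
        e.planned_duration_h for e in events if e.setting == "discharge_plan"
    )
    return union + planned


# ---------------------------------------------------------------------------
# CRB-65


@dataclass(frozen=True)
class Crb65Inputs:
    """Inputs to the CRB-65 severity score, measured at admission."""

    confusion: bool
    respiratory_rate_per_min: float
    systolic_bp_mmHg: float
    diastolic_bp_mmHg: float
    age_years: float

    def __post_init__(self) -> None:
        if self.respiratory_rate_per_min < 0:
            raise ValueError("respiratory rate must be >= 0")
        if self.age_years < 18:
            raise ValueError("adult cohort: age must be >= 18")
        if self.systolic_bp_mmHg <= 0 or self.diastolic_bp_mmHg <= 0:
            raise ValueError("blood pressures must be positive")


def crb65_score(v: Crb65Inputs) -> int:
    """CRB-65: one point each for Confusion, RR >= 30/min, SBP < 90 or
    DBP <= 60 mmHg, and age >= 65 years (0-4 points)."""
    score = 0
    score += int(v.confusion)
    score += int(v.respiratory_rate_per_min >= 30)
    score += int(v.systolic_bp_mmHg < 90 or v.diastolic_bp_mmHg <= 60)
    score += int(v.age_years >= 65)
    return score


def crb65_band(score: int) -> str:
    """Severity band: 'low' for 0-2 (mild/moderate), 'high' for >= 3."""
    if not 0 <= score <= 4:
        raise ValueError(f"CRB-65 score out of range: {score}")
    return "high" if score >= 3 else "low"


# ---------------------------------------------------------------------------
# declarative rules


@dataclass(frozen=True)
class PatternComponent:
    """One slot of a regimen pattern: a set of codes or a whole class.

    ``min_count``/``max_count`` bound how many administered agents may fill
    the slot; 'Benzylpenicillin AND Gentamicin' is two components with
    min 1 each, 'any single macrolide' is one component with max 1.
    """

    codes: frozenset[str] | None = None
    agent_class: str | None = None
    min_count: int = 1
    max_count: int | None = None

    def admits(self, agent: AntibioticAgent) -> bool:
        if self.codes is not None:
            return agent.code in self.codes
        return agent.agent_class == self.agent_class


@dataclass(frozen=True)
class RegimenPattern:
    components: tuple[PatternComponent, ...]

    def matches(self, regimen: Regimen, strict: bool = True) -> bool:
        """True when the agents can be assigned to components.

        Strict semantics: every administered agent must be accounted for
        by a component — one extra agent outside the pattern makes the
        regimen non-adherent.  Non-strict allows unassigned extras.
        Search is exhaustive; regimens are tiny (1-3 agents).
        """
        agents = sorted(regimen.agents, key=lambda a: a.code)
        slots: list[list[int | None]] = []
        for agent in agents:
            admitted = [i for i, c in enumerate(self.components) if c.admits(agent)]
            if not admitted:
                if strict:
                    return False
                admitted = [None]
            elif not strict:
                admitted = admitted + [None]
            slots.append(admitted)
        for assignment in itertools.product(*slots):
            counts = [0] * len(self.components)
            for idx in assignment:
                if idx is not None:
                    counts[idx] += 1
            ok = all(
                c.min_count <= n and (c.max_count is None or n <= c.max_count)
                for c, n in zip(self.components, counts)
            )
            if ok:
                return True
        return False


@dataclass(frozen=True)
class RuleCondition:
    """Condition under which an empirical rule applies.

    ``None`` fields match any value (e.g. the low-band rules apply
    regardless of ICU status and kidney function).
    """

    crb65_band: Literal["low", "high"]
    penicillin_allergy: bool
    egfr_band: Literal["lt30"] | None = None
    icu: bool | None = None

    def matches(self, band: str, allergy: bool, egfr: float, icu: bool) -> bool:
        if self.crb65_band != band or self.penicillin_allergy != allergy:
            return False
        if self.egfr_band == "lt30" and not egfr < 30:
            return False
        if self.icu is not None and self.icu != icu:
            return False
        return True


@dataclass(frozen=True)
class EmpiricalRule:
    rule_id: str
    condition: RuleCondition
    patterns: tuple[RegimenPattern, ...]
    description: str = ""
    strict: bool = True


@dataclass(frozen=True)
class DurationRule:
    crb65_band: Literal["low", "high"]
    recommended_days: float
    margin_h: float = 24.0

    @property
    def threshold_h(self) -> float:
        return self.recommended_days * 24.0 + self.margin_h


@dataclass
class GuidelineRuleSet:
    """Ordered empirical rules plus per-band duration rules.

    Rule matching is first-match in file order, so more specific
    conditions (ICU, low eGFR) must precede the band's default rule.
    """

    name: str
    empirical_rules: list[EmpiricalRule]
    duration_rules: dict[str, DurationRule]

    def __post_init__(self) -> None:
        for band in ("low", "high"):
            if band not in self.duration_rules:
                raise ValueError(f"duration rule missing for band {band!r}")
            if self.duration_rules[band].recommended_days <= 0:
                raise ValueError("recommended_days must be > 0")
            if self.duration_rules[band].margin_h < 0:
                raise ValueError("margin_h must be >= 0")
        for band in ("low", "high"):
            for allergy in (False, True):
                if not any(
                    r.condition.crb65_band == band
                    and r.condition.penicillin_allergy == allergy
                    for r in self.empirical_rules
                ):
                    raise ValueError(
                        f"no empirical rule for band={band}, allergy={allergy}"
                    )

    def select_empirical_rule(
        self, crb65: int, penicillin_allergy: bool, egfr: float, icu: bool
    ) -> EmpiricalRule:
        band = crb65_band(crb65)
        for rule in self.empirical_rules:
            if rule.condition.matches(band, penicillin_allergy, egfr, icu):
                return rule
        raise LookupError(
            "no empirical rule matches condition "
            f"(crb65_band={band}, allergy={penicillin_allergy}, egfr={egfr}, icu={icu})"
        )


@dataclass(frozen=True)
class AdherenceVerdict:
    """Adherent/non-adherent with the fired rule and a human rationale."""

    adherent: bool
    rule_id: str
    rationale: str
    inputs_echo: dict

    def __post_init__(self) -> None:
        if not self.rationale:
            raise ValueError("rationale must be non-empty")


# ---------------------------------------------------------------------------
# classification


def classify_empirical(
    regimen: Regimen,
    crb65: int,
    penicillin_allergy: bool,
    egfr: float,
    icu: bool,
    rules: GuidelineRuleSet,
) -> AdherenceVerdict:
    """Classify the initial regimen against the matching empirical rule."""
    rule = rules.select_empirical_rule(crb65, penicillin_allergy, egfr, icu)
    adherent = any(p.matches(regimen, strict=rule.strict) for p in rule.patterns)
    agent_names = ", ".join(sorted(a.display_name for a in regimen.agents))
    rationale = (
        f"regimen [{agent_names}] {'matches' if adherent else 'does not match'} "
        f"rule '{rule.rule_id}'"
        + (f" ({rule.description})" if rule.description else "")
    )
    return AdherenceVerdict(
        adherent=adherent,
        rule_id=rule.rule_id,
        rationale=rationale,
        inputs_echo={
            "crb65": crb65,
            "penicillin_allergy": penicillin_allergy,
            "egfr": egfr,
            "icu": icu,
            "agents": sorted(regimen.codes),
        },
    )


def classify_duration(
    duration_h: float, crb65: int, rules: GuidelineRuleSet
) -> AdherenceVerdict:
    """Adherent iff total duration <= recommended days * 24 + margin.

    Thresholds are inclusive: 144.0 h (low band) and 192.0 h (high band)
    are adherent under the default rules.
    """
    if duration_h <= 0:
        raise ValueError("duration_h must be > 0")
    band = crb65_band(crb65)
    rule = rules.duration_rules[band]
    adherent = duration_h <= rule.threshold_h
    rationale = (
        f"total therapy {duration_h:.1f} h "
        f"{'within' if adherent else 'exceeds'} the {band}-severity limit "
        f"{rule.threshold_h:.0f} h ({rule.recommended_days:g} d + {rule.margin_h:g} h margin)"
    )
    return AdherenceVerdict(
        adherent=adherent,
        rule_id=f"duration_{band}",
        rationale=rationale,
        inputs_echo={"duration_h": duration_h, "crb65": crb65},
    )


# ---------------------------------------------------------------------------
# loading


def _parse_component(raw: dict, taxonomy: AgentTaxonomy) -> PatternComponent:
    codes = raw.get("codes")
    agent_class = raw.get("agent_class")
    if (codes is None) == (agent_class is None):
        raise ValueError("component needs exactly one of 'codes' or 'agent_class'")
    if codes is not None:
        for code in codes:
            if code not in taxonomy:
                raise ValueError(f"pattern references unknown agent code {code!r}")
        codes = frozenset(codes)
    return PatternComponent(
        codes=codes,
        agent_class=agent_class,
        min_count=int(raw.get("min", 1)),
        max_count=(None if raw.get("max") is None else int(raw["max"])),
    )


def ruleset_from_dict(cfg: dict, taxonomy: AgentTaxonomy | None = None) -> GuidelineRuleSet:
    taxonomy = taxonomy or load_default_taxonomy()
    strict_default = bool(cfg.get("strict", True))
    rules = []
    for raw in cfg["empirical_rules"]:
        cond = raw["condition"]
        patterns = tuple(
            RegimenPattern(
                components=tuple(
                    _parse_component(c, taxonomy) for c in p["components"]
                )
            )
            for p in raw["patterns"]
        )
        rules.append(
            EmpiricalRule(
                rule_id=raw["rule_id"],
                condition=RuleCondition(
                    crb65_band=cond["crb65_band"],
                    penicillin_allergy=bool(cond["penicillin_allergy"]),
                    egfr_band=cond.get("egfr_band"),
                    icu=cond.get("icu"),
                ),
                patterns=patterns,
                description=" ".join(str(raw.get("description", "")).split()),
                strict=bool(raw.get("strict", strict_default)),
            )
        )
    duration = {
        d["crb65_band"]: DurationRule(
            crb65_band=d["crb65_band"],
            recommended_days=float(d["recommended_days"]),
            margin_h=float(d.get("margin_h", 24.0)),
        )
        for d in cfg["duration_rules"]
    }
    return GuidelineRuleSet(
        name=str(cfg.get("name", "custom")), empirical_rules=rules, duration_rules=duration
    )


def load_ruleset(path, taxonomy: AgentTaxonomy | None = None) -> GuidelineRuleSet:
    """Load a rule set from a YAML file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return ruleset_from_dict(cfg, taxonomy)


def default_ruleset(
    taxonomy: AgentTaxonomy | None = None,
    icu_reading: Literal["conjoint", "pip_tazo_only"] = "conjoint",
) -> GuidelineRuleSet:
    """The packaged Norwegian CAP rule set.

    ``icu_reading`` resolves an ambiguity in the ICU recommendation text:
    'conjoint' (default) requires a quinolone with any of the three
    beta-lactam options; 'pip_tazo_only' requires the quinolone only with
    piperacillin/tazobactam and accepts cefotaxime/ceftriaxone monotherapy.
    """
    taxonomy = taxonomy or load_default_taxonomy()
    with resources.files("capstew.data").joinpath("rules_cap_norway.yaml").open() as fh:
        cfg = yaml.safe_load(fh)
    if icu_reading == "pip_tazo_only":
        for raw in cfg["empirical_rules"]:
            if raw["rule_id"] == "high_band_icu":
                raw["patterns"] = [
                    {"components": [{"codes": ["cefotaxime", "ceftriaxone"], "max": 1}]},
                    {
                        "components": [
                            {"codes": ["piperacillin_tazobactam"]},
                            {"agent_class": "quinolone"},
                        ]
                    },
                ]
    elif icu_reading != "conjoint":
        raise ValueError(f"unknown icu_reading {icu_reading!r}")
    return ruleset_from_dict(cfg, taxonomy)
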