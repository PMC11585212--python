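"""Sub-cohort selection cascades with a full exclusion audit trail.

Two analysis cohorts are carved out of the admitted population:

* the **empirical-choice** cohort — everyone who started antibiotics
  within 48 h of admission and whose initial choice was not guided by
  microbiology results (otherwise the therapy is not empirical);
* the **duration** cohort — patients with a respiratory discharge
  diagnosis who received a plausible full course (24 h to 20 days), did
  not die before the recommended duration could elapse, and were
  clinically stable by the discharge proxy (length of stay within the
  recommended duration; institution-discharged patients additionally
  require a documented stability assessment).

Every exclusion is logged to a :class:`FilterTrace` whose step counts
must reconcile exactly, so a flow diagram can be rendered and audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import pandas as pd

from .guideline import (
    AntibioticEvent,
    GuidelineRuleSet,
    crb65_band,
    total_therapy_duration_h,
)

EMPIRICAL_START_LIMIT_H = 48.0
MIN_DURATION_H = 24.0
MAX_DURATION_H = 480.0  # 20 days


@dataclass(frozen=True)
class StabilityObservation:
    """Clinical-stability snapshot at discharge (the stability proxy)."""

    temperature_C: float
    respiratory_rate_per_min: float
    spo2_percent_ambient_air: float
    able_to_eat: bool

    def __post_init__(self) -> None:
        if not 25 <= self.temperature_C <= 45:
            raise ValueError("implausible temperature")
        if not 0 <= self.respiratory_rate_per_min <= 80:
            raise ValueError("implausible respiratory rate")
        if not 50 <= self.spo2_percent_ambient_air <= 100:
            raise ValueError("implausible SpO2")


def is_clinically_stable(obs: StabilityObservation | None) -> bool:
    """Stable iff afebrile (< 37.6 C), RR <= 24/min, SpO2 > 90 % on
    ambient air, and able to eat.  A missing observation is unassessable
    and treated as not stable."""
    if obs is None:
        return False
    return (
        obs.temperature_C < 37.6
        and obs.respiratory_rate_per_min <= 24
        and obs.spo2_percent_ambient_air > 90
        and obs.able_to_eat
    )


@dataclass(frozen=True)
class FilterStep:
    step_id: str
    description: str
    n_before: int
    n_excluded: int
    excluded_ids: tuple[str, ...]


@dataclass
class FilterTrace:
    """Ordered exclusion log; counts must chain exactly."""

    cohort_name: str
    steps: list[FilterStep] = field(default_factory=list)

    def validate(self) -> None:
        for step in self.steps:
            if step.n_excluded != len(step.excluded_ids):
                raise ValueError(f"step {step.step_id}: count != id list length")
        for prev, nxt in zip(self.steps, self.steps[1:]):
            if nxt.n_before != prev.n_before - prev.n_excluded:
                raise ValueError(
                    f"trace broken between {prev.step_id} and {nxt.step_id}"
                )

    @property
    def n_input(self) -> int:
        return self.steps[0].n_before if self.steps else 0

    @property
    def n_included(self) -> int:
        if not self.steps:
            return 0
        last = self.steps[-1]
        return last.n_before - last.n_excluded

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step_id": [s.step_id for s in self.steps],
                "description": [s.description for s in self.steps],
                "n_before": [s.n_before for s in self.steps],
                "n_excluded": [s.n_excluded for s in self.steps],
                "excluded_ids": ["|".join(s.excluded_ids) for s in self.steps],
            }
        )

    def exclusion_reasons(self) -> dict[str, str]:
        """Machine-readable map from excluded patient id to step id."""
        return {pid: s.step_id for s in self.steps for pid in s.excluded_ids}


EventsMap = Mapping[str, Sequence[AntibioticEvent]]


def _run_cascade(
    patients: pd.DataFrame,
    steps: Sequence[tuple[str, str, Callable[[pd.Series], bool]]],
    cohort_name: str,
) -> tuple[list[str], FilterTrace]:
    trace = FilterTrace(cohort_name=cohort_name)
    remaining = patients
    for step_id, description, exclude in steps:
        if remaining.empty:
            mask = pd.Series(False, index=remaining.index, dtype=bool)
        else:
            mask = remaining.apply(exclude, axis=1).astype(bool)
        excluded = tuple(remaining.loc[mask, "patient_id"])
        trace.steps.append(
            FilterStep(
                step_id=step_id,
                description=description,
                n_before=len(remaining),
                n_excluded=len(excluded),
                excluded_ids=excluded,
            )
        )
        remaining = remaining.loc[~mask]
    trace.validate()
    return list(remaining["patient_id"]), trace


def filter_empirical_cohort(
    patients: pd.DataFrame, events: EventsMap
) -> tuple[list[str], FilterTrace]:
    """Select the empirical-choice analysis cohort.

    Steps: (1) no antibiotic therapy; (2) therapy initiated more than
    48 h after admission (boundary inclusive: a start at exactly 48 h is
    kept); (3) initial choice guided by microbiology results.
    """

    def first_start(row: pd.Series) -> float:
        return min(e.start_time_h for e in events[row["patient_id"]])

    steps = [
        (
            "no_therapy",
            "did not receive antibiotic therapy",
            lambda row: len(events.get(row["patient_id"], ())) == 0,
        ),
        (
            "late_start",
            f"antibiotic therapy initiated > {EMPIRICAL_START_LIMIT_H:.0f} h after admission",
            lambda row: first_start(row) > EMPIRICAL_START_LIMIT_H,
        ),
        (
            "micro_guided",
            "initial antibiotic choice guided by microbiology results",
            lambda row: bool(row["initial_choice_guided_by_micro"]),
        ),
    ]
    return _run_cascade(patients, steps, "empirical_choice")


_DURATION_STEP_IDS = (
    "no_therapy",
    "other_diagnosis",
    "short_course",
    "long_course",
    "died_early",
    "long_stay",
    "unstable_institution",
)


def _stability_from_row(row: pd.Series) -> StabilityObservation | None:
    cols = (
        "stability_temperature_C",
        "stability_respiratory_rate",
        "stability_spo2_percent",
        "stability_able_to_eat",
    )
    if any(c not in row or pd.isna(row[c]) for c in cols):
        return None
    return StabilityObservation(
        temperature_C=float(row["stability_temperature_C"]),
        respiratory_rate_per_min=float(row["stability_respiratory_rate"]),
        spo2_percent_ambient_air=float(row["stability_spo2_percent"]),
        able_to_eat=bool(row["stability_able_to_eat"]),
    )


def filter_duration_cohort(
    patients: pd.DataFrame,
    events: EventsMap,
    rules: GuidelineRuleSet,
    order: Sequence[str] | None = None,
) -> tuple[list[str], FilterTrace]:
    """Select the therapy-duration analysis cohort.

    Default step order: (1) no therapy; (2) discharge diagnosis other
    than CAP / COPD exacerbation; (3) therapy < 24 h; (4) therapy > 20
    days (exactly 480 h is retained); (5) died before the recommended
    duration for the severity band elapsed; (6) length of stay exceeding
    the band's duration threshold (stability proxy); (7) discharged to a
    nursing home or institution without documented clinical stability.
    ``order`` may reorder the steps (all seven ids must appear once).
    """

    durations: dict[str, float] = {}

    def duration(row: pd.Series) -> float:
        pid = row["patient_id"]
        if pid not in durations:
            durations[pid] = total_therapy_duration_h(events[pid])
        return durations[pid]

    def band_threshold(row: pd.Series) -> float:
        return rules.duration_rules[crb65_band(int(row["crb65_score"]))].threshold_h

    def died_early(row: pd.Series) -> bool:
        death = row.get("death_time_h")
        return death is not None and not pd.isna(death) and float(death) <= band_threshold(row)

    def unstable_institution(row: pd.Series) -> bool:
        if row["discharge_destination"] != "nursing_home_or_institution":
            return False
        return not is_clinically_stable(_stability_from_row(row))

    catalogue = {
        "no_therapy": (
            "did not receive antibiotic therapy",
            lambda row: len(events.get(row["patient_id"], ())) == 0,
        ),
        "other_diagnosis": (
            "discharge diagnosis other than CAP or COPD exacerbation",
            lambda row: row["discharge_diagnosis"] not in ("cap", "copd_exacerbation"),
        ),
        "short_course": (
            f"treated with antibiotics for < {MIN_DURATION_H:.0f} h",
            lambda row: duration(row) < MIN_DURATION_H,
        ),
        "long_course": (
            f"treated with antibiotics for > {MAX_DURATION_H:.0f} h (20 days)",
            lambda row: duration(row) > MAX_DURATION_H,
        ),
        "died_early": (
            "died before the recommended therapy duration elapsed",
            died_early,
        ),
        "long_stay": (
            "length of stay exceeds the recommended duration threshold (stability proxy)",
            lambda row: float(row["length_of_stay_h"]) > band_threshold(row),
        ),
        "unstable_institution": (
            "discharged to nursing home/institution without documented clinical stability",
            unstable_institution,
        ),
    }
    if order is None:
        order = _DURATION_STEP_IDS
    if sorted(order) != sorted(_DURATION_STEP_IDS):
        raise ValueError(f"order must be a permutation of {_DURATION_STEP_IDS}")
    if order[0] != "no_therapy":
        raise ValueError("the no-therapy step must run first (durations need events)")
    steps = [(sid, catalogue[sid][0], catalogue[sid][1]) for sid in order]
    return _run_cascade(patients, steps, "therapy_duration")


def summarize_flow(trace: FilterTrace) -> pd.DataFrame:
    """Render a flow-diagram style counts report; totals must reconcile."""
    trace.validate()
    frame = trace.to_frame().drop(columns="excluded_ids")
    frame["n_after"] = frame["n_before"] - frame["n_excluded"]
    return frame
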