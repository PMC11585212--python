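"""Delimited-text I/O with schema validation.

Patient and antibiotic-event tables travel as comma-separated UTF-8 text
with a mandatory header row (ISO decimal point).  The column dictionary
lives in the package docs; readers validate mandatory columns, report
per-column missingness, and quarantine records with range violations
(negative stay, under-age patients, invalid enums) rather than failing
the run.  Output writers stamp a ``# capstew`` header comment carrying
the seed and config hash so every result file is traceable to its run.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import AgentTaxonomy, load_default_taxonomy
from .guideline import AntibioticEvent

MANDATORY_PATIENT_COLUMNS = (
    "patient_id",
    "age_years",
    "sex",
    "crb65_score",
    "penicillin_allergy",
    "egfr",
    "icu_admission",
    "length_of_stay_h",
    "discharge_destination",
    "discharge_diagnosis",
    "initial_choice_guided_by_micro",
)

MANDATORY_EVENT_COLUMNS = (
    "patient_id",
    "agent",
    "start_time_h",
    "setting",
)

_DESTINATIONS = {"home", "nursing_home_or_institution", "died"}
_DIAGNOSES = {"cap", "copd_exacerbation", "other"}


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    missingness: dict[str, float] = field(default_factory=dict)
    quarantined_ids: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _check_mandatory(frame: pd.DataFrame, mandatory, label: str, report: ValidationReport):
    missing = [c for c in mandatory if c not in frame.columns]
    if missing:
        report.errors.append(f"{label} table missing mandatory columns: {missing}")


def read_tables(
    patient_path: str | Path,
    event_path: str | Path,
    taxonomy: AgentTaxonomy | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, ValidationReport]:
    """Read and validate the patient and antibiotic-event tables.

    Returns typed frames and a validation report.  Schema violations
    (missing mandatory columns) are hard errors; range violations
    quarantine the offending patient and are listed in the report.
    """
    report = ValidationReport()
    patients = pd.read_csv(patient_path, comment="#")
    events = pd.read_csv(event_path, comment="#")
    _check_mandatory(patients, MANDATORY_PATIENT_COLUMNS, "patient", report)
    _check_mandatory(events, MANDATORY_EVENT_COLUMNS, "event", report)
    if report.errors:
        raise ValueError("; ".join(report.errors))

    patients["patient_id"] = patients["patient_id"].astype(str)
    events["patient_id"] = events["patient_id"].astype(str)

    for col in patients.columns:
        frac = float(patients[col].isna().mean())
        if frac > 0:
            report.missingness[col] = frac

    bad = pd.Series(False, index=patients.index)
    checks = [
        ("length_of_stay_h", patients["length_of_stay_h"] < 0, "negative length of stay"),
        ("age_years", patients["age_years"] < 18, "age below 18"),
        (
            "discharge_destination",
            ~patients["discharge_destination"].isin(_DESTINATIONS),
            "invalid discharge destination",
        ),
        (
            "discharge_diagnosis",
            ~patients["discharge_diagnosis"].isin(_DIAGNOSES),
            "invalid discharge diagnosis",
        ),
        ("crb65_score", ~patients["crb65_score"].between(0, 4), "CRB-65 out of range"),
    ]
    for col, mask, why in checks:
        mask = mask.fillna(False)
        for pid in patients.loc[mask, "patient_id"]:
            report.warnings.append(f"patient {pid}: {why}; record quarantined")
        bad |= mask
    report.quarantined_ids = list(patients.loc[bad, "patient_id"])
    patients = patients.loc[~bad].reset_index(drop=True)
    return patients, events, report


def events_from_frame(
    events: pd.DataFrame, taxonomy: AgentTaxonomy | None = None
) -> dict[str, list[AntibioticEvent]]:
    """Convert the event table to per-patient event objects, normalizing
    agent names through the taxonomy."""
    taxonomy = taxonomy or load_default_taxonomy()
    out: dict[str, list[AntibioticEvent]] = {}
    bad: list[str] = []
    for row in events.itertuples(index=False):
        try:
            stop = getattr(row, "stop_time_h", np.nan)
            plan = getattr(row, "planned_duration_h", np.nan)
            if pd.isna(row.start_time_h):
                raise ValueError("missing start_time_h")
            if row.setting == "inpatient" and pd.isna(stop):
                raise ValueError("inpatient event missing stop_time_h")
            ev = AntibioticEvent(
                patient_id=str(row.patient_id),
                agent=taxonomy.normalize(str(row.agent)),
                start_time_h=float(row.start_time_h),
                route=getattr(row, "route", "iv"),
                setting=row.setting,
                stop_time_h=None if pd.isna(stop) else float(stop),
                planned_duration_h=None if pd.isna(plan) else float(plan),
                event_id=str(getattr(row, "event_id", "") or "") or None,
            )
        except (ValueError, TypeError) as exc:
            bad.append(f"{getattr(row, 'event_id', row.patient_id)}: {exc}")
            continue
        out.setdefault(ev.patient_id, []).append(ev)
    if bad:
        raise ValueError("events with missing/invalid fields: " + "; ".join(bad))
    return out


def write_table(
    frame: pd.DataFrame, path: str | Path, seed: int | None = None, config_hash: str = ""
) -> None:
    """Write a result table with a traceability header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    buf.write(f"# capstew seed={seed} config_hash={config_hash}\n")
    frame.to_csv(buf, index=False)
    path.write_text(buf.getvalue())
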