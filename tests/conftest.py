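import numpy as np
import pandas as pd
import pytest

from capstew.agents import load_default_taxonomy
from capstew.guideline import AntibioticEvent, Regimen, default_ruleset


@pytest.fixture(scope="session")
def taxonomy():
    return load_default_taxonomy()


@pytest.fixture(scope="session")
def rules(taxonomy):
    return default_ruleset(taxonomy)


@pytest.fixture(scope="session")
def make_regimen(taxonomy):
    def _make(*codes, t0=0.0):
        return Regimen(agents=frozenset(taxonomy.get(c) for c in codes), t0_h=t0)

    return _make


@pytest.fixture(scope="session")
def make_event(taxonomy):
    def _make(
        code,
        start,
        stop=None,
        pid="P1",
        setting="inpatient",
        planned=None,
        event_id=None,
    ):
        if setting == "inpatient" and stop is None:
            stop = start + 24.0
        return AntibioticEvent(
            patient_id=pid,
            agent=taxonomy.normalize(code),
            start_time_h=start,
            stop_time_h=stop,
            setting=setting,
            planned_duration_h=planned,
            event_id=event_id,
        )

    return _make


def patient_row(pid, **overrides):
    """A complete patient record with innocuous defaults; tests override
    the fields a filter step keys on."""
    row = {
        "patient_id": pid,
        "age_years": 70.0,
        "sex": "male",
        "crb65_score": 1,
        "penicillin_allergy": False,
        "any_antibiotic_allergy": False,
        "egfr": 80.0,
        "icu_admission": False,
        "length_of_stay_h": 60.0,
        "discharge_destination": "home",
        "discharge_diagnosis": "cap",
        "death_time_h": np.nan,
        "initial_choice_guided_by_micro": False,
        "stability_temperature_C": 36.8,
        "stability_respiratory_rate": 18.0,
        "stability_spo2_percent": 96.0,
        "stability_able_to_eat": True,
    }
    row.update(overrides)
    return row


@pytest.fixture
def patient_frame():
    def _make(rows):
        return pd.DataFrame([patient_row(**r) for r in rows])

    return _make
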