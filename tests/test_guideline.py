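import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capstew.guideline import (
    Crb65Inputs,
    NoTherapyError,
    build_initial_regimen,
    classify_duration,
    classify_empirical,
    crb65_score,
    default_ruleset,
    total_therapy_duration_h,
)


# ---------------------------------------------------------------------------
# initial regimen / combination window


def test_agents_within_three_hours_form_combination_therapy(make_event):
    events = [make_event("benzylpenicillin", 0.0), make_event("gentamicin", 2.5)]
    reg = build_initial_regimen(events)
    assert reg.codes == {"benzylpenicillin", "gentamicin"}
    assert reg.t0_h == 0.0


def test_single_event_gives_singleton_regimen(make_event):
    reg = build_initial_regimen([make_event("amoxicillin", 5.0)])
    assert reg.codes == {"amoxicillin"}


def test_agent_after_window_is_a_switch_not_combination(make_event):
    events = [make_event("benzylpenicillin", 0.0), make_event("gentamicin", 3.01)]
    assert build_initial_regimen(events).codes == {"benzylpenicillin"}
    # boundary is inclusive
    events = [make_event("benzylpenicillin", 0.0), make_event("gentamicin", 3.0)]
    assert build_initial_regimen(events).codes == {"benzylpenicillin", "gentamicin"}


def test_empty_event_list_signals_no_therapy():
    with pytest.raises(NoTherapyError):
        build_initial_regimen([])


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    starts=st.lists(
        st.floats(min_value=0, max_value=48, allow_nan=False), min_size=1, max_size=6
    ),
    window=st.floats(min_value=0.5, max_value=6.0),
)
def test_regimen_matches_brute_force_grouping(make_event, starts, window):
    """Oracle: agents whose start lies within window of the earliest start."""
    codes = ["benzylpenicillin", "gentamicin", "erythromycin", "cefotaxime",
             "ciprofloxacin", "doxycycline"]
    events = [make_event(codes[i], t) for i, t in enumerate(starts)]
    reg = build_initial_regimen(events, window_h=window)
    t0 = min(starts)
    expected = {codes[i] for i, t in enumerate(starts) if t <= t0 + window}
    assert reg.codes == expected


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    starts=st.lists(
        st.floats(min_value=0, max_value=12, allow_nan=False), min_size=1, max_size=5
    ),
    w1=st.floats(min_value=0.5, max_value=3.0),
    extra=st.floats(min_value=0.0, max_value=3.0),
)
def test_enlarging_window_never_shrinks_regimen(make_event, starts, w1, extra):
    codes = ["benzylpenicillin", "gentamicin", "erythromycin", "cefotaxime",
             "ciprofloxacin"]
    events = [make_event(codes[i], t) for i, t in enumerate(starts)]
    small = build_initial_regimen(events, window_h=w1).codes
    large = build_initial_regimen(events, window_h=w1 + extra).codes
    assert small <= large


def test_regimen_is_invariant_to_event_order(make_event):
    events = [
        make_event("benzylpenicillin", 0.0),
        make_event("gentamicin", 2.0),
        make_event("erythromycin", 1.0),
    ]
    forward = build_initial_regimen(events)
    backward = build_initial_regimen(events[::-1])
    assert forward.codes == backward.codes and forward.t0_h == backward.t0_h


# ---------------------------------------------------------------------------
# CRB-65


@pytest.mark.parametrize(
    "confusion, rr, sbp, dbp, age, expected",
    [
        (False, 18, 120, 80, 50, 0),
        (True, 32, 85, 55, 73, 4),
        # each threshold exactly at its boundary
        (False, 29, 90, 61, 65, 1),   # only the age point fires
        (False, 30, 120, 80, 50, 1),  # RR boundary inclusive
        (False, 18, 89, 80, 50, 1),   # SBP < 90
        (False, 18, 120, 60, 50, 1),  # DBP <= 60 inclusive
        (True, 18, 120, 80, 50, 1),
        (False, 18, 90, 61, 64, 0),   # all just on the harmless side
    ],
)
def test_crb65_point_thresholds(confusion, rr, sbp, dbp, age, expected):
    v = Crb65Inputs(
        confusion=confusion,
        respiratory_rate_per_min=rr,
        systolic_bp_mmHg=sbp,
        diastolic_bp_mmHg=dbp,
        age_years=age,
    )
    assert crb65_score(v) == expected


# ---------------------------------------------------------------------------
# empirical classification


@pytest.mark.parametrize(
    "codes, crb65, allergy, egfr, icu, expected",
    [
        # low band, no allergy: penicillins alone or combined
        (("benzylpenicillin",), 1, False, 80, False, True),
        (("phenoxymethylpenicillin",), 0, False, 80, False, True),
        (("benzylpenicillin", "amoxicillin"), 2, False, 80, False, True),
        (("cefotaxime",), 1, False, 80, False, False),
        (("benzylpenicillin", "gentamicin"), 1, False, 80, False, False),
        # low band, allergy: any single macrolide
        (("erythromycin",), 0, True, 80, False, True),
        (("azithromycin",), 2, True, 80, False, True),
        (("benzylpenicillin",), 1, True, 80, False, False),
        (("erythromycin", "azithromycin"), 1, True, 80, False, False),
        (("doxycycline",), 1, True, 80, False, False),
        # high band standard: penicillin + aminoglycoside
        (("benzylpenicillin", "gentamicin"), 3, False, 80, False, True),
        (("ampicillin", "tobramycin"), 4, False, 80, False, True),
        (("benzylpenicillin",), 3, False, 80, False, False),
        (("cefotaxime",), 3, False, 80, False, False),
        # high band, eGFR < 30: third-generation cephalosporin
        (("ceftriaxone",), 3, False, 25, False, True),
        (("cefotaxime",), 3, False, 29.9, False, True),
        (("benzylpenicillin", "gentamicin"), 3, False, 25, False, False),
        # high band ICU: beta-lactam option plus quinolone
        (("cefotaxime", "ciprofloxacin"), 3, False, 80, True, True),
        (("piperacillin_tazobactam", "ciprofloxacin"), 4, False, 80, True, True),
        (("ceftriaxone", "levofloxacin"), 3, False, 80, True, True),
        (("cefotaxime",), 3, False, 80, True, False),
        # high band, allergy: clindamycin + quinolone
        (("clindamycin", "ciprofloxacin"), 3, True, 80, False, True),
        (("clindamycin",), 3, True, 80, False, False),
        (("ciprofloxacin",), 4, True, 80, False, False),
    ],
)
def test_empirical_rule_rows(rules, make_regimen, codes, crb65, allergy, egfr, icu, expected):
    verdict = classify_empirical(make_regimen(*codes), crb65, allergy, egfr, icu, rules)
    assert verdict.adherent is expected
    assert verdict.rationale


def test_verdict_echoes_rule_and_inputs(rules, make_regimen):
    v = classify_empirical(make_regimen("benzylpenicillin"), 1, False, 80, False, rules)
    assert v.rule_id == "low_band_no_allergy"
    assert v.inputs_echo["crb65"] == 1


def test_condition_grid_totality(rules, make_regimen):
    """Every (score, allergy, egfr band, icu) cell selects exactly one rule."""
    reg = make_regimen("benzylpenicillin")
    for crb65 in range(5):
        for allergy in (False, True):
            for egfr in (20.0, 60.0):
                for icu in (False, True):
                    v = classify_empirical(reg, crb65, allergy, egfr, icu, rules)
                    assert isinstance(v.adherent, bool)


def test_extra_agent_breaks_low_band_adherence(rules, make_regimen, taxonomy):
    """Strict matching: any agent outside the pattern flips the verdict."""
    adherent_sets = {
        (1, False): ("benzylpenicillin",),
        (0, True): ("erythromycin",),
    }
    extras = ["cefotaxime", "doxycycline", "gentamicin", "ciprofloxacin"]
    for (crb65, allergy), codes in adherent_sets.items():
        assert classify_empirical(
            make_regimen(*codes), crb65, allergy, 80, False, rules
        ).adherent
        for extra in extras:
            spoiled = make_regimen(*codes, extra)
            assert not classify_empirical(
                spoiled, crb65, allergy, 80, False, rules
            ).adherent


def test_icu_reading_switch_changes_cephalosporin_monotherapy_verdict(make_regimen):
    conjoint = default_ruleset(icu_reading="conjoint")
    alt = default_ruleset(icu_reading="pip_tazo_only")
    mono = make_regimen("cefotaxime")
    assert not classify_empirical(mono, 3, False, 80, True, conjoint).adherent
    assert classify_empirical(mono, 3, False, 80, True, alt).adherent
    # piperacillin/tazobactam still needs the quinolone under both readings
    pip = make_regimen("piperacillin_tazobactam")
    assert not classify_empirical(pip, 3, False, 80, True, conjoint).adherent
    assert not classify_empirical(pip, 3, False, 80, True, alt).adherent


# ---------------------------------------------------------------------------
# therapy duration


def test_duration_adds_inpatient_and_planned_courses(make_event):
    events = [
        make_event("benzylpenicillin", 0.0, 70.0),
        make_event("amoxicillin", 70.0, setting="discharge_plan", planned=120.0, stop=None),
    ]
    assert total_therapy_duration_h(events) == pytest.approx(190.0)


def test_overlapping_inpatient_intervals_count_once(make_event):
    events = [
        make_event("benzylpenicillin", 0.0, 48.0),
        make_event("gentamicin", 24.0, 72.0),
    ]
    assert total_therapy_duration_h(events) == pytest.approx(72.0)


def test_abutting_intervals_and_plan(make_event):
    events = [
        make_event("benzylpenicillin", 0.0, 24.0),
        make_event("benzylpenicillin", 24.0, 48.0),
        make_event("amoxicillin", 48.0, 50.0),
        make_event("amoxicillin", 50.0, setting="discharge_plan", planned=96.0, stop=None),
    ]
    assert total_therapy_duration_h(events) == pytest.approx(146.0)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    intervals=st.lists(
        st.tuples(
            st.integers(min_value=0, max_value=200),
            st.integers(min_value=1, max_value=100),
        ),
        min_size=1,
        max_size=8,
    )
)
def test_interval_union_matches_hour_grid_brute_force(make_event, intervals):
    """Oracle: mark covered half-hours on a fine grid and count."""
    events = [
        make_event("benzylpenicillin", float(lo), float(lo + length))
        for lo, length in intervals
    ]
    grid = np.zeros(2 * 400, dtype=bool)  # half-hour resolution
    for lo, length in intervals:
        grid[2 * lo : 2 * (lo + length)] = True
    assert total_therapy_duration_h(events) == pytest.approx(grid.sum() / 2.0)


@pytest.mark.parametrize(
    "duration_h, crb65, expected",
    [
        (144.0, 1, True),
        (145.0, 2, False),
        (192.0, 3, True),
        (193.0, 3, False),
        (144.5, 0, False),
        (192.0, 2, False),
    ],
)
def test_duration_thresholds_inclusive(rules, duration_h, crb65, expected):
    assert classify_duration(duration_h, crb65, rules).adherent is expected


def test_duration_adherence_flips_exactly_once(rules):
    """For fixed severity, adherence is non-increasing in duration."""
    for crb65 in (1, 3):
        verdicts = [
            classify_duration(h, crb65, rules).adherent
            for h in np.arange(1.0, 500.0, 0.5)
        ]
        flips = sum(a and not b for a, b in zip(verdicts, verdicts[1:]))
        assert flips == 1
        assert not any(not a and b for a, b in zip(verdicts, verdicts[1:]))
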