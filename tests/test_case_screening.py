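"""Risk windows, encounter classification (with brute-force precedence
oracle), and case screening."""

import itertools
from datetime import date, timedelta

import pytest

from pedopitox.case_screening import (
    DEFAULT_PRECEDENCE,
    ScreeningError,
    build_windows,
    classify_encounter,
    screen,
)
from pedopitox.claims_model import (
    Child,
    ClaimsBundle,
    ClaimsValidationError,
    DeathRecord,
    Encounter,
    EnrollmentSpan,
    PrescriptionFill,
)
from pedopitox.cohort_builder import CohortSpec, build_cohort

SPEC = CohortSpec(study_start=date(1999, 1, 1), study_end=date(2011, 12, 31))


def _fill(day, supply, child="kid"):
    return PrescriptionFill(child, day, "opioid", supply)


# --- risk windows -----------------------------------------------------------


@pytest.mark.parametrize(
    "fill_date,supply,supply_end,early_cutoff,window_end",
    [
        # fill day is supply day 1; endpoints inclusive
        (date(2005, 3, 1), 1, date(2005, 3, 1), date(2005, 3, 8), date(2005, 3, 15)),
        (date(2005, 3, 1), 10, date(2005, 3, 10), date(2005, 3, 17), date(2005, 3, 24)),
        (date(2005, 12, 28), 7, date(2006, 1, 3), date(2006, 1, 10), date(2006, 1, 17)),
    ],
)
def test_window_date_arithmetic(fill_date, supply, supply_end, early_cutoff, window_end):
    (w,) = build_windows([_fill(fill_date, supply)])
    assert (w.supply_end, w.early_cutoff, w.window_end) == (supply_end, early_cutoff, window_end)


def test_overlapping_fills_keep_both_windows():
    windows = build_windows([_fill(date(2005, 3, 1), 10), _fill(date(2005, 3, 5), 10)])
    assert len(windows) == 2


def test_nonpositive_days_supply_rejected():
    with pytest.raises(ClaimsValidationError):
        _fill(date(2005, 3, 1), 0)


def test_stratum_boundaries():
    (w,) = build_windows([_fill(date(2005, 3, 1), 10)])
    assert w.stratum(date(2005, 3, 1)) == "early"
    assert w.stratum(date(2005, 3, 17)) == "early"  # supply_end + 7
    assert w.stratum(date(2005, 3, 18)) == "late"  # supply_end + 8
    assert w.stratum(date(2005, 3, 24)) == "late"
    with pytest.raises(ScreeningError):
        w.stratum(date(2005, 3, 25))


# --- encounter classification ----------------------------------------------

# Representative codes per (category, sub-group) in the default registry.
TRIGGERS = {
    ("intentional_overdose", "A"): "E9500",
    ("intentional_overdose", "B"): "E9501",
    ("intentional_overdose", "C"): "E9505",
    ("unintentional_overdose", "A"): "E8502",
    ("unintentional_overdose", "B"): "E8511",
    ("unintentional_overdose", "C"): "E8589",
    ("adverse_effect_therapeutic", "A"): "E9352",
    ("adverse_effect_therapeutic", "B"): "E9300",
    ("adverse_effect_therapeutic", "C"): "E9479",
}
SYMPTOM_TRIGGERS = {"cns": "78001", "respiratory": "78603"}
ECODE_CATS = ("intentional_overdose", "unintentional_overdose", "adverse_effect_therapeutic")


def _encounter(dx=("4659",), ecodes=(), setting="emergency"):
    return Encounter("e1", "kid", date(2005, 3, 3), setting, tuple(dx), tuple(ecodes))


def precedence_oracle(states, cns, resp):
    """Independent re-derivation of the category rule from trigger-group
    presence: per category fire iff (A or C) present and B absent; then take
    the first firing category in precedence order, else symptoms."""
    for cat in ECODE_CATS:
        a, b, c = states[cat]
        if (a or c) and not b:
            return cat
    if cns or resp:
        return "symptom_only"
    return None


def test_classification_matches_precedence_oracle(registry):
    """Exhaustive check over every combination of triggered sub-groups."""
    per_cat = list(itertools.product([False, True], repeat=3))  # (A, B, C)
    checked = 0
    for s1, s2, s3, cns, resp in itertools.product(
        per_cat, per_cat, per_cat, [False, True], [False, True]
    ):
        states = dict(zip(ECODE_CATS, (s1, s2, s3)))
        ecodes = [
            TRIGGERS[(cat, grp)]
            for cat in ECODE_CATS
            for grp, on in zip("ABC", states[cat])
            if on
        ]
        dx = ["4659"]
        if cns:
            dx.append(SYMPTOM_TRIGGERS["cns"])
        if resp:
            dx.append(SYMPTOM_TRIGGERS["respiratory"])
        got = classify_encounter(_encounter(dx=dx, ecodes=ecodes), registry)
        expected = precedence_oracle(states, cns, resp)
        if expected is None:
            assert got is None
        elif expected == "symptom_only":
            sub = "both" if (cns and resp) else ("cns" if cns else "respiratory")
            assert got == ("symptom_only", sub)
        else:
            assert got == (expected, None)
        checked += 1
    assert checked == 8 ** 3 * 4


def test_unspecified_poisoning_vetoed_by_specific_non_opioid(registry):
    """A Group C (unspecified medication) poisoning code plus a Group B
    specific non-opioid code yields no category."""
    enc = _encounter(ecodes=["E8589", "E8511"])
    assert classify_encounter(enc, registry) is None


def test_overdose_plus_symptom_resolves_to_overdose(registry):
    enc = _encounter(dx=["78001"], ecodes=["E8502"])
    assert classify_encounter(enc, registry) == ("unintentional_overdose", None)


def test_primary_and_secondary_positions_equivalent(registry):
    first = _encounter(dx=["78001", "4659"])
    second = _encounter(dx=["4659", "78001"])
    assert classify_encounter(first, registry) == classify_encounter(second, registry)


def test_outpatient_encounter_is_precondition_error(registry):
    with pytest.raises(ScreeningError, match="outpatient"):
        classify_encounter(_encounter(setting="outpatient"), registry)


# --- screening --------------------------------------------------------------


def _screen_bundle(registry, encounters=(), deaths=(), fills=None):
    fills = fills if fills is not None else [_fill(date(2005, 3, 1), 10)]
    bundle = ClaimsBundle(
        children=(Child("kid", date(1995, 6, 1)),),
        enrollment_spans=(EnrollmentSpan("kid", date(2003, 1, 1), date(2006, 12, 31)),),
        fills=tuple(fills),
        encounters=tuple(encounters),
        deaths=tuple(deaths),
    )
    cohort = build_cohort(bundle, SPEC, registry)
    return screen(cohort, bundle, registry)


def test_encounter_before_window_not_screened(registry):
    enc = Encounter("e1", "kid", date(2005, 2, 28), "emergency", ("4659",), ("E8502",))
    assert _screen_bundle(registry, encounters=[enc]) == []


def test_death_in_window_screens_regardless_of_causes(registry):
    cases = _screen_bundle(registry, deaths=[DeathRecord("kid", date(2005, 3, 20), ())])
    assert len(cases) == 1
    assert cases[0].category == "death_any_cause"
    assert cases[0].time_stratum == "late"


def test_death_outside_window_not_screened(registry):
    assert _screen_bundle(registry, deaths=[DeathRecord("kid", date(2005, 5, 1), ())]) == []


def test_overlapping_windows_attribute_to_most_recent_fill(registry):
    fills = [_fill(date(2005, 3, 1), 10), _fill(date(2005, 3, 5), 10)]
    enc = Encounter("e1", "kid", date(2005, 3, 8), "emergency", ("4659",), ("E8502",))
    cases = _screen_bundle(registry, encounters=[enc], fills=fills)
    assert len(cases) == 1
    assert cases[0].window.fill_date == date(2005, 3, 5)


def test_one_case_per_child_and_date(registry):
    encs = [
        Encounter("e1", "kid", date(2005, 3, 3), "emergency", ("4659",), ("E9352",)),
        Encounter("e2", "kid", date(2005, 3, 3), "inpatient", ("4659",), ("E9500",)),
    ]
    cases = _screen_bundle(registry, encounters=encs)
    assert len(cases) == 1
    assert cases[0].category == "intentional_overdose"  # highest precedence wins


def test_shrinking_window_never_adds_cases(registry):
    """Cases screened under a 3-day supply are a subset of those under 10."""
    encs = [
        Encounter("e1", "kid", date(2005, 3, 3), "emergency", ("4659",), ("E8502",)),
        Encounter("e2", "kid", date(2005, 3, 20), "emergency", ("4659",), ("E9352",)),
    ]
    wide = {c.case_id for c in _screen_bundle(registry, encounters=encs,
                                              fills=[_fill(date(2005, 3, 1), 10)])}
    narrow = {c.case_id for c in _screen_bundle(registry, encounters=encs,
                                                fills=[_fill(date(2005, 3, 1), 3)])}
    assert narrow <= wide
    assert len(narrow) < len(wide)


def test_partition_one_category_one_stratum(registry, small_simulation):
    """Every screened case carries exactly one category and one stratum, and
    stratified counts sum to the overall count."""
    _, bundle, *_ = small_simulation
    cohort = build_cohort(bundle, SPEC, registry)
    cases = screen(cohort, bundle, registry)
    assert cases
    by_cat = {}
    by_stratum = {}
    for c in cases:
        by_cat[c.category] = by_cat.get(c.category, 0) + 1
        by_stratum[c.time_stratum] = by_stratum.get(c.time_stratum, 0) + 1
        assert c.time_stratum in ("early", "late")
        assert c.window.fill_date <= c.event_date <= c.window.window_end
    assert sum(by_cat.values()) == len(cases)
    assert sum(by_stratum.values()) == len(cases)
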