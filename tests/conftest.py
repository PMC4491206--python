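"""Shared fixtures: the default registry, small synthetic runs, and a
hand-built claims fixture that realizes the published validation-table counts
(category totals, symptom subtypes, time strata, record availability) exactly,
for end-to-end reproduction tests."""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import pytest

from pedopitox.adjudication_engine import ChartAbstraction
from pedopitox.claims_model import (
    Child,
    ClaimsBundle,
    DeathRecord,
    Encounter,
    EnrollmentSpan,
    PrescriptionFill,
)
from pedopitox.codesets import load_registry
from pedopitox.cohort_builder import CohortSpec

FILL_DATE = date(2005, 3, 1)
DAYS_SUPPLY = 5  # supply_end 2005-03-05, early cutoff 03-12, window_end 03-19
EARLY_EVENT = date(2005, 3, 3)
LATE_EVENT = date(2005, 3, 14)

# One representative triggering code per screening category (all present in
# the bundled default registry).
CATEGORY_CODES = {
    "intentional_overdose": ((), ("E9500",)),
    "unintentional_overdose": ((), ("E8502",)),
    "adverse_effect_therapeutic": ((), ("E9352",)),
    "cns": (("7800",), ()),
    "respiratory": (("78603",), ()),
}

# (category-or-subtype, early_total, early_confirmed, late_total, late_confirmed)
# chosen so the margins reproduce the published tables:
#   categories 30/15, 31/25, 58/33, symptoms 47/12 (CNS 32/9, resp 15/3),
#   deaths 2/0; strata 121/69 early, 47/16 late; overall 168/85.
TABLE_LAYOUT = [
    ("intentional_overdose", 23, 12, 7, 3),
    ("unintentional_overdose", 26, 23, 5, 2),
    ("adverse_effect_therapeutic", 43, 25, 15, 8),
    ("cns", 20, 7, 12, 2),
    ("respiratory", 7, 2, 8, 1),
    ("death", 2, 0, 0, 0),
]
N_NOT_FOUND = 23
N_NO_INFORMATION = 4


@dataclass
class TableFixture:
    bundle: ClaimsBundle
    abstractions: dict = field(default_factory=dict)  # case_id -> {reviewer: abstraction}
    availability: dict = field(default_factory=dict)  # case_id -> state
    cohort_spec: CohortSpec = field(
        default_factory=lambda: CohortSpec(
            study_start=date(1999, 1, 1), study_end=date(2011, 12, 31)
        )
    )


def _confirmed_abstraction(case_id: str, use_group1: bool) -> ChartAbstraction:
    if use_group1:
        return ChartAbstraction(
            case_id=case_id,
            signs_symptoms_compatible=True,
            physician_attributed_to_opioid=True,
            ed_primary_reason=True,
            intent_evidence="therapeutic",
            source_evidence="own_prescription",
        )
    return ChartAbstraction(
        case_id=case_id,
        signs_symptoms_compatible=True,
        temporal_sequence_consistent=True,
        ed_primary_reason=True,
        intent_evidence="therapeutic",
        source_evidence="own_prescription",
    )


def build_table_fixture() -> TableFixture:
    """Claims bundle + abstractions realizing the published table counts."""
    children, spans, fills, encounters, deaths = [], [], [], [], []
    fx = TableFixture(bundle=ClaimsBundle())
    seq = 0

    def add_case(kind: str, event_date: date, confirmed: bool, state: str) -> None:
        nonlocal seq
        seq += 1
        child_id = f"T{seq:04d}"
        children.append(Child(child_id=child_id, birth_date=date(1995, 6, 1)))
        spans.append(
            EnrollmentSpan(child_id=child_id, start_date=date(2004, 1, 1),
                           end_date=date(2005, 12, 31))
        )
        fills.append(
            PrescriptionFill(child_id=child_id, fill_date=FILL_DATE,
                             drug_class="opioid", days_supply=DAYS_SUPPLY)
        )
        case_id = f"{child_id}:{event_date.isoformat()}"
        if kind == "death":
            deaths.append(DeathRecord(child_id=child_id, death_date=event_date))
        else:
            dx, ecodes = CATEGORY_CODES[kind]
            encounters.append(
                Encounter(
                    encounter_id=f"ENC{seq:04d}", child_id=child_id, date=event_date,
                    setting="emergency", dx_codes=dx or ("4659",), ecodes=ecodes,
                )
            )
        if state != "adjudicable":
            fx.availability[case_id] = state
            return
        fx.availability[case_id] = "adjudicable"
        if confirmed:
            abstraction = _confirmed_abstraction(case_id, use_group1=seq % 2 == 0)
        else:
            abstraction = ChartAbstraction(case_id=case_id)  # nothing compatible
        fx.abstractions[case_id] = {"r1": abstraction, "r2": abstraction}

    for kind, early_n, early_conf, late_n, late_conf in TABLE_LAYOUT:
        for i in range(early_n):
            add_case(kind, EARLY_EVENT, confirmed=i < early_conf, state="adjudicable")
        for i in range(late_n):
            add_case(kind, LATE_EVENT, confirmed=i < late_conf, state="adjudicable")
    for _ in range(N_NOT_FOUND):
        add_case("adverse_effect_therapeutic", EARLY_EVENT, False, "not_found")
    for _ in range(N_NO_INFORMATION):
        add_case("adverse_effect_therapeutic", EARLY_EVENT, False, "no_information")

    fx.bundle = ClaimsBundle(
        children=tuple(children), enrollment_spans=tuple(spans), fills=tuple(fills),
        encounters=tuple(encounters), deaths=tuple(deaths),
    ).validate()
    return fx


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def table_fixture() -> TableFixture:
    return build_table_fixture()


@pytest.fixture(scope="session")
def small_simulation():
    """A 2000-child synthetic population shared by read-only tests."""
    from pedopitox.synthetic_claims import SimulationParams, generate

    params = SimulationParams(n_children=2000, rng_seed=12345)
    bundle, abstractions, committee, truth = generate(params)
    return params, bundle, abstractions, committee, truth
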