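"""Synthetic claims generator with planted, recoverable ground truth.

Emulates a pediatric Medicaid-like population: children aged 2-17 (ages drawn
from a truncated normal, mean 11.3 / SD 5.0 years), opioid prescription fills
with realistic days-supply, and ED/inpatient encounters.  A configurable
fraction of children receives one *planted* toxicity event: an encounter (or
death) inside a fill's risk window whose codes — drawn from the active
code-set registry, never hard-coded — trigger exactly one intended screening
category.  Each planted case carries a latent confirmation status drawn with
its category's confirmation probability, realized as a pair of reviewer chart
abstractions that the adjudication engine maps to the intended Group 1/2/3
labels.  Decoy encounters (triggering codes outside every window; in-window
encounters with inert codes; outpatient visits) exercise the negative space.

The generator is a validation harness, not an epidemiology simulator: planted
event rates are deliberately far above real-world incidence so that stratified
PPV estimates have useful statistical resolution at moderate population sizes.
Ground truth never leaks into the claims files themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np

from .adjudication_engine import (
    GROUP1,
    GROUP2,
    GROUP3,
    GROUPS,
    AdjudicationResult,
    ChartAbstraction,
    adjudicate_full,
)
from .case_screening import DEATH_CATEGORY, EARLY_TAIL_DAYS, WINDOW_TAIL_DAYS
from .claims_model import (
    Child,
    ClaimsBundle,
    DeathRecord,
    Encounter,
    EnrollmentSpan,
    PrescriptionFill,
)
from .codesets import CodeSetRegistry, load_registry
from .cohort_builder import age_at

__all__ = ["GroundTruthRecord", "SimulationParams", "generate", "generate_rater_pair"]

log = logging.getLogger(__name__)

# Inert diagnosis codes used as filler/decoys; none matches any default
# screening or exclusion group (asserted at generation time against the
# active registry).
FILLER_DX = ("4659", "5589", "84200", "07999", "4661")

_SYMPTOM_KEYS = {"cns": "symptom_cns", "respiratory": "symptom_respiratory"}


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one synthetic population.

    Category mix, confirmation probabilities, early/late window split,
    record-availability rates and the reviewer agreement default to the
    validation study's observed values, so a generated population produces a
    recognizably calibrated validation report.  All knobs are overridable.
    """

    n_children: int = 1000
    rng_seed: int = 0
    age_mean_years: float = 11.3
    age_sd_years: float = 5.0
    female_fraction: float = 0.57
    study_start: date = date(1999, 1, 1)
    study_end: date = date(2011, 12, 31)
    extra_fills_mean: float = 0.5  # Poisson mean for fills beyond the first
    days_supply_choices: tuple[int, ...] = (3, 5, 7, 10, 14)
    days_supply_weights: tuple[float, ...] = (0.35, 0.30, 0.20, 0.10, 0.05)
    #: Per-child probability of one planted case of each category.
    planted_rates: dict = field(
        default_factory=lambda: {
            "intentional_overdose": 0.30 * 30 / 168,
            "unintentional_overdose": 0.30 * 31 / 168,
            "adverse_effect_therapeutic": 0.30 * 58 / 168,
            "symptom_only": 0.30 * 47 / 168,
            DEATH_CATEGORY: 0.30 * 2 / 168,
        }
    )
    #: P(confirmed | stratum); symptom cases keyed by subtype.
    confirmation_probs: dict = field(
        default_factory=lambda: {
            "intentional_overdose": 15 / 30,
            "unintentional_overdose": 25 / 31,
            "adverse_effect_therapeutic": 33 / 58,
            "symptom_cns": 9 / 32,
            "symptom_respiratory": 3 / 15,
            DEATH_CATEGORY: 0.0,
        }
    )
    symptom_cns_share: float = 32 / 47
    early_fraction: float = 121 / 168
    #: Confirmation odds tilt by window position.  Defaults reproduce the
    #: early/late PPV split while preserving every per-category confirmation
    #: probability exactly, because early_fraction * early + late_fraction *
    #: late = 1 by construction.
    stratum_confirmation_multipliers: dict = field(
        default_factory=lambda: {
            "early": (69 / 121) / (85 / 168),
            "late": (16 / 47) / (85 / 168),
        }
    )
    group1_share_of_confirmed: float = 0.5
    not_found_rate: float = 23 / 195
    no_information_rate: float = 4 / 195
    reviewer_agreement: float = 0.917
    decoy_encounter_rate: float = 0.25  # inert in-window encounter, non-planted children
    pre_window_trigger_rate: float = 0.10  # triggering encounter before any window
    severity_weights: dict = field(
        default_factory=lambda: {"high": 27 / 85, "intermediate": 52 / 85, "low": 6 / 85}
    )
    source_weights: dict = field(
        default_factory=lambda: {
            "own_prescription": 76 / 85,
            "other_person": 4 / 85,
            "unspecified": 5 / 85,
        }
    )

    def __post_init__(self) -> None:
        if self.n_children < 1:
            raise ValueError("n_children must be >= 1")
        probs = [
            *self.planted_rates.values(),
            *self.confirmation_probs.values(),
            self.symptom_cns_share,
            self.early_fraction,
            self.reviewer_agreement,
            self.not_found_rate,
            self.no_information_rate,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if any(m < 0 for m in self.stratum_confirmation_multipliers.values()):
            raise ValueError("stratum confirmation multipliers must be >= 0")
        if sum(self.planted_rates.values()) > 1.0:
            raise ValueError("planted rates must sum to at most 1")


@dataclass(frozen=True)
class GroundTruthRecord:
    """What was planted for one case; never written into the claims files."""

    case_id: str
    child_id: str
    event_date: date
    category: str
    symptom_subtype: str | None
    window_position: str  # early / late
    confirmed: bool
    group: str
    availability: str  # adjudicable / no_information / not_found


def _weighted_choice(rng: np.random.Generator, table: dict) -> str:
    labels = list(table)
    weights = np.asarray([table[k] for k in labels], dtype=float)
    return labels[rng.choice(len(labels), p=weights / weights.sum())]


def _truncated_normal_age(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(1000):
        value = rng.normal(mean, sd)
        if 2.0 <= value < 18.0:
            return value
    return float(np.clip(rng.normal(mean, sd), 2.0, 17.99))


def _abstraction_for_group(
    rng: np.random.Generator,
    case_id: str,
    group: str,
    params: SimulationParams,
    category: str,
    is_death: bool,
) -> ChartAbstraction:
    """Build a chart abstraction that the rule engine maps to *group*."""
    intent = {
        "intentional_overdose": {"self_harm": 1.0},
        "unintentional_overdose": {"unintentional_overdose": 0.7, "recreational": 0.3},
        "adverse_effect_therapeutic": {"therapeutic": 0.90, "withdrawal": 0.02,
                                       "unspecified": 0.08},
        "symptom_only": {"therapeutic": 0.85, "unspecified": 0.15},
        DEATH_CATEGORY: {"unspecified": 1.0},
    }[category]
    kwargs: dict = {
        "case_id": case_id,
        "intent_evidence": _weighted_choice(rng, intent),
        "source_evidence": _weighted_choice(rng, params.source_weights),
        "death": is_death,
    }
    if group in (GROUP1, GROUP2):
        severity = "death" if is_death else _weighted_choice(rng, params.severity_weights)
        if severity == "high":
            kwargs["hospitalization_or_escalation"] = True
        elif severity == "intermediate":
            kwargs["ed_primary_reason"] = True
        elif severity == "low":
            kwargs["incidental_mention"] = True
    if group == GROUP1:
        kwargs["signs_symptoms_compatible"] = True
        kwargs["physician_attributed_to_opioid"] = True
        if rng.random() < 0.3:  # escalation arm of the Group 1 definition
            kwargs["escalation_for_opioid_toxicity"] = True
            kwargs["hospitalization_or_escalation"] = True
    elif group == GROUP2:
        kwargs["signs_symptoms_compatible"] = True
        kwargs["temporal_sequence_consistent"] = True
    else:
        scenario = rng.integers(3)
        if scenario == 0:  # attributed to another cause
            kwargs["signs_symptoms_compatible"] = True
            kwargs["other_cause_implicated"] = True
            kwargs["other_cause_attributed"] = True
        elif scenario == 1:  # compatible but no temporal sequence
            kwargs["signs_symptoms_compatible"] = True
        # scenario 2: nothing compatible at all — all defaults
    return ChartAbstraction(**kwargs)


def _trigger_codes(
    rng: np.random.Generator, registry: CodeSetRegistry, category: str, subtype: str | None
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """(dx_codes, ecodes) that trigger exactly *category* under *registry*."""
    filler = FILLER_DX[rng.integers(len(FILLER_DX))]
    if category == "symptom_only":
        group = registry.symptom_group(_SYMPTOM_KEYS[subtype])
        pattern = group.patterns[rng.integers(len(group.patterns))]
        return (pattern.pattern, filler), ()
    pool = registry.group(category, "A").patterns + registry.group(category, "C").patterns
    pattern = pool[rng.integers(len(pool))]
    if pattern.pattern.startswith("E"):
        return (filler,), (pattern.pattern,)
    return (pattern.pattern, filler), ()


def _assert_inert_fillers(registry: CodeSetRegistry) -> None:
    for code in FILLER_DX:
        for category, groups in registry.categories.items():
            for group in groups.values():
                if group.matches(code):
                    raise ValueError(
                        f"filler code {code} matches {category}/{group.label} in the "
                        "active registry; choose different fillers"
                    )
        for name, group in registry.exclusions.items():
            if group.matches(code):
                raise ValueError(f"filler code {code} matches exclusion group {name}")


def generate(
    params: SimulationParams,
    registry: CodeSetRegistry | None = None,
) -> tuple[
    ClaimsBundle,
    dict[str, dict[str, ChartAbstraction]],
    dict[str, AdjudicationResult],
    list[GroundTruthRecord],
]:
    """Generate a claims bundle plus reviewer abstractions and ground truth.

    Returns ``(bundle, abstractions, committee, truth)``: per-case reviewer
    abstractions keyed ``{case_id: {"r1": ..., "r2": ...}}`` (absent for cases
    whose records are planted as unavailable), committee adjudications for
    resolving reviewer disagreements, and one ground-truth record per planted
    case.  Deterministic given ``params.rng_seed``.
    """
    registry = registry if registry is not None else load_registry()
    _assert_inert_fillers(registry)
    rng = np.random.default_rng(params.rng_seed)

    categories = list(params.planted_rates)
    rates = np.asarray([params.planted_rates[c] for c in categories], dtype=float)
    cum = np.cumsum(rates)

    children: list[Child] = []
    spans: list[EnrollmentSpan] = []
    fills: list[PrescriptionFill] = []
    encounters: list[Encounter] = []
    deaths: list[DeathRecord] = []
    abstractions: dict[str, dict[str, ChartAbstraction]] = {}
    committee: dict[str, AdjudicationResult] = {}
    truth: list[GroundTruthRecord] = []

    span_days = (params.study_end - params.study_start).days
    enc_seq = 0

    for i in range(params.n_children):
        child_id = f"C{i:06d}"
        anchor = params.study_start + timedelta(
            days=int(rng.integers(400, max(span_days - 60, 401)))
        )
        age_years = _truncated_normal_age(rng, params.age_mean_years, params.age_sd_years)
        birth = anchor - timedelta(days=int(age_years * 365.25))
        # day-count truncation can push the calendar age across the 2/17 bounds
        while age_at(birth, anchor) > 17:
            birth += timedelta(days=7)
        while age_at(birth, anchor) < 2:
            birth -= timedelta(days=7)
        sex = "F" if rng.random() < params.female_fraction else "M"
        race = "caucasian" if rng.random() < 0.59 else "other"
        children.append(Child(child_id=child_id, birth_date=birth, sex=sex, race=race))

        n_fills = 1 + int(rng.poisson(params.extra_fills_mean))
        ds_weights = np.asarray(params.days_supply_weights, dtype=float)
        fill_dates = [anchor]
        for _ in range(n_fills - 1):
            fill_dates.append(fill_dates[-1] + timedelta(days=int(rng.integers(45, 200))))
        supplies = [
            int(rng.choice(params.days_supply_choices, p=ds_weights / ds_weights.sum()))
            for _ in fill_dates
        ]
        for d, ds in zip(fill_dates, supplies):
            fills.append(
                PrescriptionFill(child_id=child_id, fill_date=d, drug_class="opioid",
                                 days_supply=ds)
            )
        last_window_end = max(
            d + timedelta(days=ds - 1 + WINDOW_TAIL_DAYS) for d, ds in zip(fill_dates, supplies)
        )
        spans.append(
            EnrollmentSpan(
                child_id=child_id,
                start_date=max(birth, anchor - timedelta(days=400)),
                end_date=last_window_end + timedelta(days=120),
            )
        )

        u = rng.random()
        planted_idx = int(np.searchsorted(cum, u, side="right"))
        planted = categories[planted_idx] if planted_idx < len(categories) else None

        if planted is None:
            # Negative space: inert in-window encounters, pre-window encounters
            # carrying triggering codes, and outpatient visits that must all be
            # ignored by screening.
            if rng.random() < params.decoy_encounter_rate:
                offset = int(rng.integers(0, supplies[0] + WINDOW_TAIL_DAYS))
                enc_seq += 1
                encounters.append(
                    Encounter(
                        encounter_id=f"E{enc_seq:07d}", child_id=child_id,
                        date=anchor + timedelta(days=offset),
                        setting="emergency" if rng.random() < 0.8 else "inpatient",
                        dx_codes=(FILLER_DX[rng.integers(len(FILLER_DX))],),
                    )
                )
            if rng.random() < params.pre_window_trigger_rate:
                cat = categories[int(rng.integers(len(categories) - 1))]
                sub = "cns" if rng.random() < params.symptom_cns_share else "respiratory"
                dx, ec = _trigger_codes(rng, registry, cat, sub)
                enc_seq += 1
                encounters.append(
                    Encounter(
                        encounter_id=f"E{enc_seq:07d}", child_id=child_id,
                        date=anchor - timedelta(days=int(rng.integers(20, 300))),
                        setting="emergency", dx_codes=dx, ecodes=ec,
                    )
                )
            if rng.random() < 0.05:  # outpatient visit with a triggering code
                cat = categories[int(rng.integers(len(categories) - 1))]
                dx, ec = _trigger_codes(rng, registry, cat, "cns")
                enc_seq += 1
                encounters.append(
                    Encounter(
                        encounter_id=f"E{enc_seq:07d}", child_id=child_id,
                        date=anchor + timedelta(days=2),
                        setting="outpatient", dx_codes=dx, ecodes=ec,
                    )
                )
            continue

        # Plant one case on the first fill's window.
        supply_end = anchor + timedelta(days=supplies[0] - 1)
        early = rng.random() < params.early_fraction
        if early:
            lo, hi = 0, (supply_end - anchor).days + EARLY_TAIL_DAYS
        else:
            lo = (supply_end - anchor).days + EARLY_TAIL_DAYS + 1
            hi = (supply_end - anchor).days + WINDOW_TAIL_DAYS
        event_date = anchor + timedelta(days=int(rng.integers(lo, hi + 1)))
        case_id = f"{child_id}:{event_date.isoformat()}"

        subtype = None
        if planted == DEATH_CATEGORY:
            deaths.append(DeathRecord(child_id=child_id, death_date=event_date))
        else:
            if planted == "symptom_only":
                subtype = "cns" if rng.random() < params.symptom_cns_share else "respiratory"
            dx, ec = _trigger_codes(rng, registry, planted, subtype)
            enc_seq += 1
            encounters.append(
                Encounter(
                    encounter_id=f"E{enc_seq:07d}", child_id=child_id, date=event_date,
                    setting="emergency" if rng.random() < 0.7 else "inpatient",
                    dx_codes=dx, ecodes=ec,
                )
            )

        conf_key = _SYMPTOM_KEYS[subtype] if subtype else planted
        tilt = params.stratum_confirmation_multipliers["early" if early else "late"]
        confirmed = rng.random() < min(1.0, params.confirmation_probs[conf_key] * tilt)
        if confirmed:
            group = GROUP1 if rng.random() < params.group1_share_of_confirmed else GROUP2
        else:
            group = GROUP3

        avail_u = rng.random()
        if avail_u < params.not_found_rate:
            availability = "not_found"
        elif avail_u < params.not_found_rate + params.no_information_rate:
            availability = "no_information"
        else:
            availability = "adjudicable"

        if availability == "adjudicable":
            a1 = _abstraction_for_group(
                rng, case_id, group, params, planted, planted == DEATH_CATEGORY
            )
            if rng.random() < params.reviewer_agreement:
                group2 = group
            else:
                group2 = [g for g in GROUPS if g != group][int(rng.integers(2))]
            a2 = _abstraction_for_group(
                rng, case_id, group2, params, planted, planted == DEATH_CATEGORY
            )
            abstractions[case_id] = {"r1": a1, "r2": a2}
            committee[case_id] = adjudicate_full(a1)

        truth.append(
            GroundTruthRecord(
                case_id=case_id, child_id=child_id, event_date=event_date,
                category=planted, symptom_subtype=subtype,
                window_position="early" if early else "late",
                confirmed=confirmed, group=group, availability=availability,
            )
        )

    bundle = ClaimsBundle(
        children=tuple(children),
        enrollment_spans=tuple(spans),
        fills=tuple(fills),
        encounters=tuple(encounters),
        deaths=tuple(deaths),
    ).validate()
    log.info(
        "generated %d children, %d fills, %d encounters, %d deaths, %d planted cases",
        len(children), len(fills), len(encounters), len(deaths), len(truth),
    )
    return bundle, abstractions, committee, truth


def generate_rater_pair(
    truth_groups: list[str], agreement: float, seed: int
) -> tuple[list[str], list[str]]:
    """Two reviewer label sequences: rater 1 reproduces the truth, rater 2
    agrees with probability *agreement* and otherwise picks a different group
    uniformly."""
    if not (0.0 <= agreement <= 1.0):
        raise ValueError("agreement must be in [0, 1]")
    rng = np.random.default_rng(seed)
    r1 = list(truth_groups)
    r2 = []
    for g in r1:
        if rng.random() < agreement:
            r2.append(g)
        else:
            others = [x for x in GROUPS if x != g]
            r2.append(others[int(rng.integers(len(others)))])
    return r1, r2
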