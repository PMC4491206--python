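"""Per-prescription risk windows, encounter classification, case screening.

Follow-up for each opioid fill runs from the fill date through 14 days after
the end of the dispensed days of supply.  The fill day counts as supply day 1,
so ``supply_end = fill_date + days_supply - 1`` and all window endpoints are
inclusive.  Within a window, qualifying ED/inpatient encounters are classified
into mutually exclusive screening categories in precedence order

    intentional_overdose > unintentional_overdose
        > adverse_effect_therapeutic > symptom_only

and any death is screened in regardless of its cause-of-death codes.  Each
case also gets a time stratum: *early* (through 7 days after supply end) or
*late* (days 8-14 after supply end).
"""

from __future__ import annotations

import csv
import logging
from collections import defaultdict
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path

from .claims_model import ClaimsBundle, Encounter, PrescriptionFill
from .codesets import ECODE_CATEGORIES, CodeSetRegistry, normalize_code
from .cohort_builder import CohortMember

__all__ = [
    "DEFAULT_PRECEDENCE",
    "PotentialCase",
    "RiskWindow",
    "ScreeningError",
    "build_windows",
    "classify_encounter",
    "read_potential_cases",
    "screen",
    "write_potential_cases",
]

log = logging.getLogger(__name__)

WINDOW_TAIL_DAYS = 14
EARLY_TAIL_DAYS = 7

#: Mutually exclusive screening categories, in default precedence order.
DEFAULT_PRECEDENCE = (
    "intentional_overdose",
    "unintentional_overdose",
    "adverse_effect_therapeutic",
    "symptom_only",
)
DEATH_CATEGORY = "death_any_cause"
CASE_CATEGORIES = DEFAULT_PRECEDENCE + (DEATH_CATEGORY,)


class ScreeningError(ValueError):
    """Precondition violation during screening."""


@dataclass(frozen=True)
class RiskWindow:
    """Inclusive follow-up interval anchored at one opioid fill."""

    child_id: str
    fill_date: date
    supply_end: date
    early_cutoff: date
    window_end: date

    def contains(self, day: date) -> bool:
        return self.fill_date <= day <= self.window_end

    def stratum(self, day: date) -> str:
        if not self.contains(day):
            raise ScreeningError(f"{day} outside window {self.fill_date}..{self.window_end}")
        return "early" if day <= self.early_cutoff else "late"


@dataclass(frozen=True)
class PotentialCase:
    """One screened event: an in-window qualifying encounter or death."""

    child_id: str
    event_date: date
    category: str
    window: RiskWindow
    time_stratum: str
    encounter_id: str | None = None  # None for death-review cases
    symptom_subtype: str | None = None  # cns / respiratory / both; symptom_only

    def __post_init__(self) -> None:
        if self.category not in CASE_CATEGORIES:
            raise ScreeningError(f"unknown category {self.category!r}")
        if (self.symptom_subtype is not None) != (self.category == "symptom_only"):
            raise ScreeningError("symptom_subtype present iff category is symptom_only")

    @property
    def case_id(self) -> str:
        return f"{self.child_id}:{self.event_date.isoformat()}"


def build_windows(fills: list[PrescriptionFill]) -> list[RiskWindow]:
    """Construct one risk window per opioid fill (no merging of overlaps)."""
    windows = []
    for f in fills:
        if f.days_supply < 1:
            raise ScreeningError(f"days_supply {f.days_supply} < 1 for {f.child_id!r}")
        supply_end = f.fill_date + timedelta(days=f.days_supply - 1)
        windows.append(
            RiskWindow(
                child_id=f.child_id,
                fill_date=f.fill_date,
                supply_end=supply_end,
                early_cutoff=supply_end + timedelta(days=EARLY_TAIL_DAYS),
                window_end=supply_end + timedelta(days=WINDOW_TAIL_DAYS),
            )
        )
    return windows


def classify_encounter(
    encounter: Encounter,
    registry: CodeSetRegistry,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> tuple[str, str | None] | None:
    """Assign an ED/inpatient encounter to at most one screening category.

    For each external-cause category the trigger is: any code in group A
    (opioid/unspecified analgesic) or group C (unspecified medication), with
    no code in group B (a specific non-opioid drug) anywhere on the
    encounter.  Symptom screening fires on the CNS/respiratory diagnosis
    lists alone, with no external-cause code required.  The first category in
    *precedence* whose trigger holds wins; an encounter triggering nothing
    returns ``None``.

    Returns ``(category, symptom_subtype)``; the subtype is non-None only for
    ``symptom_only``.
    """
    if encounter.setting not in ("emergency", "inpatient"):
        raise ScreeningError(
            f"encounter {encounter.encounter_id!r} has setting {encounter.setting!r}; "
            "screening is restricted to emergency and inpatient encounters"
        )
    codes = [normalize_code(c) for c in (*encounter.dx_codes, *encounter.ecodes)]

    def ecode_trigger(category: str) -> bool:
        a = registry.group(category, "A")
        b = registry.group(category, "B")
        c = registry.group(category, "C")
        if b.matches_any(codes):
            return False
        return a.matches_any(codes) or c.matches_any(codes)

    cns = registry.symptom_group("symptom_cns").matches_any(codes)
    resp = registry.symptom_group("symptom_respiratory").matches_any(codes)

    for category in precedence:
        if category in ECODE_CATEGORIES:
            if ecode_trigger(category):
                return category, None
        elif category == "symptom_only":
            if cns or resp:
                subtype = "both" if (cns and resp) else ("cns" if cns else "respiratory")
                return "symptom_only", subtype
        else:  # pragma: no cover - guarded by module constants
            raise ScreeningError(f"unknown category in precedence: {category!r}")
    return None


def _attribute_window(windows: list[RiskWindow], day: date) -> RiskWindow | None:
    """Most recent qualifying fill on or before *day* whose window covers it."""
    containing = [w for w in windows if w.contains(day)]
    if not containing:
        return None
    return max(containing, key=lambda w: w.fill_date)


def screen(
    cohort: list[CohortMember],
    bundle: ClaimsBundle,
    registry: CodeSetRegistry,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> list[PotentialCase]:
    """Screen all in-window events of cohort members into potential cases.

    One potential case per (child, event date): when several qualifying
    encounters share a date the highest-precedence category wins, and a death
    on that date supersedes any encounter-based case.  Outpatient encounters
    never screen in.
    """
    windows_by_child = {
        m.child_id: build_windows(list(m.qualifying_fills)) for m in cohort
    }
    encounters_by_child = defaultdict(list)
    for e in bundle.encounters:
        if e.setting in ("emergency", "inpatient"):
            encounters_by_child[e.child_id].append(e)

    cases: dict[tuple[str, date], PotentialCase] = {}
    rank = {c: i for i, c in enumerate(precedence)}
    for member in cohort:
        windows = windows_by_child[member.child_id]
        for enc in sorted(encounters_by_child[member.child_id], key=lambda e: (e.date, e.encounter_id)):
            window = _attribute_window(windows, enc.date)
            if window is None:
                continue
            result = classify_encounter(enc, registry, precedence)
            if result is None:
                continue
            category, subtype = result
            case = PotentialCase(
                child_id=member.child_id,
                event_date=enc.date,
                category=category,
                window=window,
                time_stratum=window.stratum(enc.date),
                encounter_id=enc.encounter_id,
                symptom_subtype=subtype,
            )
            key = (member.child_id, enc.date)
            prior = cases.get(key)
            if prior is None or rank[category] < rank.get(prior.category, len(rank)):
                cases[key] = case

    for death in bundle.deaths:
        windows = windows_by_child.get(death.child_id, [])
        window = _attribute_window(windows, death.death_date)
        if window is None:
            continue
        key = (death.child_id, death.death_date)
        cases[key] = PotentialCase(
            child_id=death.child_id,
            event_date=death.death_date,
            category=DEATH_CATEGORY,
            window=window,
            time_stratum=window.stratum(death.death_date),
            encounter_id=None,
            symptom_subtype=None,
        )

    result = sorted(cases.values(), key=lambda c: (c.child_id, c.event_date))
    log.info("screened %d potential cases from %d cohort members", len(result), len(cohort))
    return result


# ---------------------------------------------------------------------------
# CSV interchange

_CASE_COLUMNS = [
    "case_id", "child_id", "event_date", "category", "symptom_subtype",
    "time_stratum", "encounter_id", "fill_date", "supply_end", "early_cutoff",
    "window_end",
]


def write_potential_cases(cases: list[PotentialCase], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CASE_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for c in cases:
            writer.writerow(
                {
                    "case_id": c.case_id,
                    "child_id": c.child_id,
                    "event_date": c.event_date.isoformat(),
                    "category": c.category,
                    "symptom_subtype": c.symptom_subtype or "",
                    "time_stratum": c.time_stratum,
                    "encounter_id": c.encounter_id or "",
                    "fill_date": c.window.fill_date.isoformat(),
                    "supply_end": c.window.supply_end.isoformat(),
                    "early_cutoff": c.window.early_cutoff.isoformat(),
                    "window_end": c.window.window_end.isoformat(),
                }
            )
    return path


def read_potential_cases(path: str | Path) -> list[PotentialCase]:
    cases = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            window = RiskWindow(
                child_id=row["child_id"],
                fill_date=date.fromisoformat(row["fill_date"]),
                supply_end=date.fromisoformat(row["supply_end"]),
                early_cutoff=date.fromisoformat(row["early_cutoff"]),
                window_end=date.fromisoformat(row["window_end"]),
            )
            cases.append(
                PotentialCase(
                    child_id=row["child_id"],
                    event_date=date.fromisoformat(row["event_date"]),
                    category=row["category"],
                    window=window,
                    time_stratum=row["time_stratum"],
                    encounter_id=row["encounter_id"] or None,
                    symptom_subtype=row["symptom_subtype"] or None,
                )
            )
    return cases
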