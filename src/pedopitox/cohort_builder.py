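"""Cohort selection: eligible opioid fills with 12-month lookback exclusions.

The study population is children aged 2-17 with a filled opioid prescription.
To avoid confounding by symptoms of serious underlying disease, a fill is
dropped when any medical encounter in the year before it carries a code from
an exclusion group (serious illness, organ transplant, institutional
residence, drug abuse).  Exclusions anchor at the fill date, because each fill
initiates its own follow-up; a child keeps only the fills that individually
pass, and is dropped entirely when none survive.  Naloxone receipt is
deliberately *not* an exclusion.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from datetime import date, timedelta

from .claims_model import ClaimsBundle, PrescriptionFill
from .codesets import CodeGroup, CodeSetRegistry, normalize_code

__all__ = ["CohortMember", "CohortSpec", "age_at", "build_cohort"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortSpec:
    """Eligibility parameters for cohort entry.

    Ages are inclusive bounds in completed years, evaluated at each fill date.
    ``lookback_days`` is the pre-fill window scanned for exclusion codes;
    0 disables history exclusions.  ``exclusion_groups`` names the registry
    exclusion groups to apply; ``None`` means all groups in the registry.
    ``require_continuous_enrollment`` additionally demands an enrollment span
    covering the full lookback (off by default).
    """

    study_start: date
    study_end: date
    min_age_years: int = 2
    max_age_years: int = 17
    lookback_days: int = 365
    exclusion_groups: tuple[str, ...] | None = None
    require_continuous_enrollment: bool = False

    def __post_init__(self) -> None:
        if self.min_age_years >= self.max_age_years:
            raise ValueError("min_age_years must be < max_age_years")
        if self.lookback_days < 0:
            raise ValueError("lookback_days must be >= 0")
        if self.study_start > self.study_end:
            raise ValueError("study_start must be <= study_end")


@dataclass(frozen=True)
class CohortMember:
    child_id: str
    qualifying_fills: tuple[PrescriptionFill, ...]


def age_at(birth_date: date, on_date: date) -> int:
    """Completed years of age on *on_date* (birthday counts as completed)."""
    if on_date < birth_date:
        raise ValueError(f"on_date {on_date} precedes birth_date {birth_date}")
    years = on_date.year - birth_date.year
    if (on_date.month, on_date.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def _encounter_codes(encounter) -> list[str]:
    return [normalize_code(c) for c in (*encounter.dx_codes, *encounter.ecodes)]


def build_cohort(
    bundle: ClaimsBundle,
    spec: CohortSpec,
    registry: CodeSetRegistry,
) -> list[CohortMember]:
    """Apply eligibility and lookback exclusions, returning retained members.

    A fill qualifies when it is an opioid fill inside the study window, the
    child is aged within the spec's bounds on the fill date, the fill date
    lies in an enrollment span, and no encounter in the ``lookback_days``
    before the fill (exclusive of the fill date itself) carries an exclusion
    code.  Output is sorted by child_id and independent of input row order.
    """
    bundle.validate()
    group_names = (
        spec.exclusion_groups
        if spec.exclusion_groups is not None
        else tuple(sorted(registry.exclusions))
    )
    groups: list[tuple[str, CodeGroup]] = [(n, registry.exclusions[n]) for n in group_names]

    births = {c.child_id: c.birth_date for c in bundle.children}
    spans = defaultdict(list)
    for s in bundle.enrollment_spans:
        spans[s.child_id].append(s)
    encounters_by_child = defaultdict(list)
    for e in bundle.encounters:
        encounters_by_child[e.child_id].append(e)
    fills_by_child = defaultdict(list)
    for f in bundle.fills:
        fills_by_child[f.child_id].append(f)

    exclusion_counts: Counter[str] = Counter()
    members: list[CohortMember] = []
    for child_id in sorted(births):
        kept: list[PrescriptionFill] = []
        for fill in sorted(
            fills_by_child[child_id], key=lambda f: (f.fill_date, f.days_supply)
        ):
            if fill.drug_class != "opioid":
                continue
            if not (spec.study_start <= fill.fill_date <= spec.study_end):
                exclusion_counts["outside_study_window"] += 1
                continue
            age = age_at(births[child_id], fill.fill_date)
            if not (spec.min_age_years <= age <= spec.max_age_years):
                exclusion_counts["age_out_of_range"] += 1
                continue
            if not any(s.start_date <= fill.fill_date <= s.end_date for s in spans[child_id]):
                exclusion_counts["not_enrolled_at_fill"] += 1
                continue
            lookback_start = fill.fill_date - timedelta(days=spec.lookback_days)
            if spec.require_continuous_enrollment and spec.lookback_days > 0:
                if not any(
                    s.start_date <= lookback_start and fill.fill_date <= s.end_date
                    for s in spans[child_id]
                ):
                    exclusion_counts["lookback_enrollment_gap"] += 1
                    continue
            flagged = None
            if spec.lookback_days > 0:
                for enc in encounters_by_child[child_id]:
                    if not (lookback_start <= enc.date < fill.fill_date):
                        continue
                    codes = _encounter_codes(enc)
                    for name, group in groups:
                        if any(group.matches(c) for c in codes):
                            flagged = name
                            break
                    if flagged:
                        break
            if flagged:
                exclusion_counts[flagged] += 1
                continue
            kept.append(fill)
        if kept:
            members.append(CohortMember(child_id=child_id, qualifying_fills=tuple(kept)))

    log.info(
        "cohort: %d members retained from %d children; exclusions by reason: %s",
        len(members), len(births), dict(exclusion_counts),
    )
    return members
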