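"""Deterministic adjudication rules: Group 1/2/3, severity, intent, source.

Chart review classifies each screened episode into mutually exclusive groups:

* **Group 1 (definite/probable)** — signs and symptoms compatible with opioid
  toxicity, attributed by the treating physician to an opioid, with no other
  process implicated; *or* direct intervention / escalation of care because of
  potential opioid toxicity.
* **Group 2 (possible)** — compatible signs or symptoms not clearly attributed
  to the opioid but not attributed to another cause either, with a temporal
  sequence that makes opioid causation plausible.
* **Group 3 (excluded)** — everything else: symptoms attributed to another
  cause, no supporting temporal sequence, or no compatible findings at all.

The engine is a pure function of a structured chart abstraction; the clinical
judgment lives in producing the abstraction, which this package does not
automate.  Two independent reviews are combined by :func:`consensus`, which
never auto-resolves a disagreement — a committee label must be supplied.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "AdjudicationError",
    "AdjudicationResult",
    "ChartAbstraction",
    "GROUPS",
    "INTENTS",
    "SEVERITIES",
    "SOURCES",
    "adjudicate",
    "adjudicate_full",
    "classify_exposure",
    "classify_severity",
    "consensus",
    "read_abstractions",
    "write_adjudications",
]

log = logging.getLogger(__name__)

GROUP1 = "group1_definite_probable"
GROUP2 = "group2_possible"
GROUP3 = "group3_excluded"
GROUPS = (GROUP1, GROUP2, GROUP3)
CONFIRMED_GROUPS = (GROUP1, GROUP2)

#: Severity in strict dominance order.
SEVERITIES = ("death", "high", "intermediate", "low")
INTENTS = (
    "self_harm",
    "recreational",
    "unintentional_overdose",
    "therapeutic",
    "withdrawal",
    "unspecified",
)
SOURCES = ("own_prescription", "other_person", "illegal", "unspecified")


class AdjudicationError(ValueError):
    """Contract violation in the adjudication workflow."""


@dataclass(frozen=True)
class ChartAbstraction:
    """Minimal structured summary of one chart review.

    Boolean fields mirror the adjudication criteria; ``intent_evidence`` and
    ``source_evidence`` are closed vocabularies recorded as documented, never
    imputed.
    """

    case_id: str
    signs_symptoms_compatible: bool = False
    physician_attributed_to_opioid: bool = False
    other_cause_implicated: bool = False
    other_cause_attributed: bool = False
    escalation_for_opioid_toxicity: bool = False
    temporal_sequence_consistent: bool = False
    hospitalization_or_escalation: bool = False
    ed_primary_reason: bool = False
    incidental_mention: bool = False
    intent_evidence: str = "unspecified"
    source_evidence: str = "unspecified"
    death: bool = False

    def __post_init__(self) -> None:
        if self.intent_evidence not in INTENTS:
            raise AdjudicationError(f"unknown intent_evidence {self.intent_evidence!r}")
        if self.source_evidence not in SOURCES:
            raise AdjudicationError(f"unknown source_evidence {self.source_evidence!r}")
        if (
            not self.hospitalization_or_escalation
            and self.ed_primary_reason
            and self.incidental_mention
        ):
            raise AdjudicationError(
                "ed_primary_reason and incidental_mention are mutually exclusive "
                "for non-hospitalized encounters"
            )


@dataclass(frozen=True)
class AdjudicationResult:
    case_id: str
    group: str
    severity: str | None = None
    intent: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise AdjudicationError(f"unknown group {self.group!r}")
        confirmed = self.group in CONFIRMED_GROUPS
        if confirmed != (self.severity is not None):
            raise AdjudicationError("severity present iff group is confirmed")
        if (self.intent is not None) != (self.severity is not None):
            raise AdjudicationError("intent/source present iff severity present")

    @property
    def confirmed(self) -> bool:
        return self.group in CONFIRMED_GROUPS


def adjudicate(a: ChartAbstraction) -> str:
    """Map a chart abstraction to its adjudication group (total function)."""
    if (
        a.signs_symptoms_compatible
        and a.physician_attributed_to_opioid
        and not a.other_cause_implicated
    ) or a.escalation_for_opioid_toxicity:
        return GROUP1
    if (
        a.signs_symptoms_compatible
        and not a.physician_attributed_to_opioid
        and not a.other_cause_attributed
        and a.temporal_sequence_consistent
    ):
        return GROUP2
    return GROUP3


def classify_severity(a: ChartAbstraction, group: str) -> str:
    """Severity of a confirmed case, by dominance death > high > intermediate > low."""
    if group not in CONFIRMED_GROUPS:
        raise AdjudicationError("severity is only defined for Group 1/2 cases")
    if a.death:
        return "death"
    if a.hospitalization_or_escalation:
        return "high"
    if a.ed_primary_reason:
        return "intermediate"
    return "low"


def classify_exposure(a: ChartAbstraction) -> tuple[str, str]:
    """Circumstances of exposure and opioid source, passed through unchanged."""
    if a.intent_evidence not in INTENTS:
        raise AdjudicationError(f"unknown intent {a.intent_evidence!r}")
    if a.source_evidence not in SOURCES:
        raise AdjudicationError(f"unknown source {a.source_evidence!r}")
    return a.intent_evidence, a.source_evidence


def adjudicate_full(a: ChartAbstraction) -> AdjudicationResult:
    """Group plus severity/intent/source (the latter only for confirmed cases)."""
    group = adjudicate(a)
    if group not in CONFIRMED_GROUPS:
        return AdjudicationResult(case_id=a.case_id, group=group)
    intent, source = classify_exposure(a)
    return AdjudicationResult(
        case_id=a.case_id,
        group=group,
        severity=classify_severity(a, group),
        intent=intent,
        source=source,
    )


def consensus(
    r1: AdjudicationResult,
    r2: AdjudicationResult,
    committee: AdjudicationResult | None = None,
) -> tuple[AdjudicationResult, bool]:
    """Combine two independent reviews; disagreements require a committee label.

    Returns ``(final_result, disagreement_flag)``.  On agreement the first
    reviewer's full result stands (the group, which is what agreement is
    judged on, is identical).
    """
    if r1.case_id != r2.case_id:
        raise AdjudicationError(f"case mismatch: {r1.case_id!r} vs {r2.case_id!r}")
    if r1.group == r2.group:
        return r1, False
    if committee is None:
        raise AdjudicationError(
            f"case {r1.case_id!r}: reviewers disagree ({r1.group} vs {r2.group}) "
            "and no committee adjudication was supplied"
        )
    if committee.case_id != r1.case_id:
        raise AdjudicationError("committee label is for a different case")
    return committee, True


# ---------------------------------------------------------------------------
# CSV interchange

_ABSTRACTION_BOOLS = [
    "signs_symptoms_compatible", "physician_attributed_to_opioid",
    "other_cause_implicated", "other_cause_attributed",
    "escalation_for_opioid_toxicity", "temporal_sequence_consistent",
    "hospitalization_or_escalation", "ed_primary_reason", "incidental_mention",
    "death",
]
_ABSTRACTION_COLUMNS = ["case_id", "reviewer", *_ABSTRACTION_BOOLS,
                        "intent_evidence", "source_evidence"]


def read_abstractions(path: str | Path) -> dict[str, dict[str, ChartAbstraction]]:
    """Load per-reviewer abstractions keyed as ``{case_id: {reviewer: abstraction}}``."""
    out: dict[str, dict[str, ChartAbstraction]] = {}
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            a = ChartAbstraction(
                case_id=row["case_id"],
                intent_evidence=row["intent_evidence"],
                source_evidence=row["source_evidence"],
                **{k: row[k].strip().lower() in ("1", "true", "yes") for k in _ABSTRACTION_BOOLS},
            )
            out.setdefault(row["case_id"], {})[row["reviewer"]] = a
    return out


def write_abstractions(
    abstractions: dict[str, dict[str, ChartAbstraction]], path: str | Path
) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_ABSTRACTION_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for case_id in sorted(abstractions):
            for reviewer in sorted(abstractions[case_id]):
                a = abstractions[case_id][reviewer]
                row = {"case_id": case_id, "reviewer": reviewer,
                       "intent_evidence": a.intent_evidence,
                       "source_evidence": a.source_evidence}
                row.update({k: str(getattr(a, k)).lower() for k in _ABSTRACTION_BOOLS})
                writer.writerow(row)
    return path


def write_adjudications(results: list[AdjudicationResult], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["case_id", "group", "severity", "intent", "source"],
            lineterminator="\n",
        )
        writer.writeheader()
        for r in results:
            writer.writerow(
                {"case_id": r.case_id, "group": r.group,
                 "severity": r.severity or "", "intent": r.intent or "",
                 "source": r.source or ""}
            )
    return path


def read_adjudications(path: str | Path) -> list[AdjudicationResult]:
    out = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                AdjudicationResult(
                    case_id=row["case_id"], group=row["group"],
                    severity=row["severity"] or None, intent=row["intent"] or None,
                    source=row["source"] or None,
                )
            )
    return out
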