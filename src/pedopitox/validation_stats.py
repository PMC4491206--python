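"""Validation statistics: record availability, stratified PPV, agreement, kappa.

The positive predictive value (PPV) of a screening stratum is the fraction of
its adjudicable potential cases confirmed as Group 1 or Group 2 toxicity,
with an exact (Clopper-Pearson) binomial 95% confidence interval.  Cases whose
records could not be found, or held too little information to adjudicate, are
removed from every denominator.  Inter-rater reliability between the two
independent reviewers is summarised as percent observed agreement, expected
(chance) agreement from the raters' marginal label frequencies, and Cohen's
kappa = (po - pe) / (1 - pe).
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from statsmodels.stats.proportion import proportion_confint

from .adjudication_engine import GROUPS, AdjudicationResult
from .case_screening import DEFAULT_PRECEDENCE, DEATH_CATEGORY, PotentialCase

__all__ = [
    "Availability",
    "PPVCell",
    "Reliability",
    "ValidationError",
    "ValidationReport",
    "build_report",
    "cohens_kappa",
    "kappa_from_agreement",
    "ppv",
]

log = logging.getLogger(__name__)

AVAILABILITY_STATES = ("adjudicable", "no_information", "not_found")


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class PPVCell:
    """PPV of one screening stratum; undefined (None) when the stratum is empty."""

    stratum: str
    n_total: int
    n_confirmed: int
    ppv_percent: float | None
    ci95: tuple[float, float] | None

    @property
    def ppv_rounded(self) -> float | None:
        return None if self.ppv_percent is None else round(self.ppv_percent, 1)

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "n_total": self.n_total,
            "n_confirmed": self.n_confirmed,
            "ppv_percent": self.ppv_rounded,
            "ci95": None if self.ci95 is None else [round(x, 1) for x in self.ci95],
        }


def ppv(n_confirmed: int, n_total: int, stratum: str = "") -> PPVCell:
    """Exact-binomial PPV cell; ``n_total = 0`` yields an undefined cell."""
    if n_confirmed < 0 or n_total < 0 or n_confirmed > n_total:
        raise ValidationError(f"invalid counts confirmed={n_confirmed}, total={n_total}")
    if n_total == 0:
        return PPVCell(stratum, 0, 0, None, None)
    lo, hi = proportion_confint(n_confirmed, n_total, alpha=0.05, method="beta")
    return PPVCell(
        stratum=stratum,
        n_total=n_total,
        n_confirmed=n_confirmed,
        ppv_percent=100.0 * n_confirmed / n_total,
        ci95=(100.0 * lo, 100.0 * hi),
    )


@dataclass(frozen=True)
class Availability:
    n_screened: int
    n_no_information: int
    n_not_found: int

    @property
    def n_adjudicable(self) -> int:
        return self.n_screened - self.n_no_information - self.n_not_found


@dataclass(frozen=True)
class Reliability:
    n_pairs: int
    observed_agreement: float
    expected_agreement: float
    kappa: float | None


def kappa_from_agreement(po: float, pe: float) -> float:
    """Cohen's kappa from observed and expected agreement proportions."""
    if not (0.0 <= pe < 1.0):
        raise ValidationError(f"expected agreement pe={pe} must be in [0, 1)")
    if not (0.0 <= po <= 1.0):
        raise ValidationError(f"observed agreement po={po} must be in [0, 1]")
    return (po - pe) / (1.0 - pe)


def cohens_kappa(labels_r1, labels_r2) -> Reliability:
    """Unweighted Cohen's kappa between two raters' label sequences.

    ``kappa`` is ``None`` (undefined) when both raters are constant and
    identical, so that chance agreement is 1.
    """
    r1, r2 = list(labels_r1), list(labels_r2)
    if not r1 or len(r1) != len(r2):
        raise ValidationError("label sequences must be equal-length and non-empty")
    n = len(r1)
    po = sum(a == b for a, b in zip(r1, r2)) / n
    m1, m2 = Counter(r1), Counter(r2)
    labels = set(m1) | set(m2)
    pe = sum((m1[l] / n) * (m2[l] / n) for l in labels)
    if math.isclose(pe, 1.0):
        return Reliability(n_pairs=n, observed_agreement=po, expected_agreement=pe, kappa=None)
    return Reliability(
        n_pairs=n,
        observed_agreement=po,
        expected_agreement=pe,
        kappa=kappa_from_agreement(po, pe),
    )


@dataclass(frozen=True)
class ValidationReport:
    """All validation tables for one screening + adjudication run."""

    availability: Availability
    overall: PPVCell
    by_category: dict[str, PPVCell]
    by_symptom_subtype: dict[str, PPVCell]
    by_time_stratum: dict[str, PPVCell]
    severity_table: dict[str, int]
    intent_table: dict[str, int]
    source_table: dict[str, int]
    reliability: Reliability | None
    codeset_version: str = "unversioned"

    def to_dict(self) -> dict:
        rel = None
        if self.reliability is not None:
            rel = {
                "n_pairs": self.reliability.n_pairs,
                "observed_agreement_percent": round(100 * self.reliability.observed_agreement, 1),
                "expected_agreement_percent": round(100 * self.reliability.expected_agreement, 1),
                "kappa": None
                if self.reliability.kappa is None
                else round(self.reliability.kappa, 3),
            }
        return {
            "codeset_version": self.codeset_version,
            "availability": {
                "n_screened": self.availability.n_screened,
                "n_no_information": self.availability.n_no_information,
                "n_not_found": self.availability.n_not_found,
                "n_adjudicable": self.availability.n_adjudicable,
            },
            "overall": self.overall.to_dict(),
            "by_category": {k: v.to_dict() for k, v in self.by_category.items()},
            "by_symptom_subtype": {k: v.to_dict() for k, v in self.by_symptom_subtype.items()},
            "by_time_stratum": {k: v.to_dict() for k, v in self.by_time_stratum.items()},
            "severity": self.severity_table,
            "intent": self.intent_table,
            "source": self.source_table,
            "reliability": rel,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path

    def format_text(self) -> str:
        """Plain-text tables mirroring the report, for console output."""
        lines = [
            f"Code-set version: {self.codeset_version}",
            f"Screened: {self.availability.n_screened}   "
            f"no information: {self.availability.n_no_information}   "
            f"not found: {self.availability.n_not_found}   "
            f"adjudicable: {self.availability.n_adjudicable}",
            "",
            "PPV by screening stratum (confirmed = Group 1 or Group 2)",
            f"{'stratum':<34}{'n':>6}{'confirmed':>11}{'PPV %':>8}  95% CI",
        ]

        def row(cell: PPVCell) -> str:
            if cell.ppv_percent is None:
                return f"{cell.stratum:<34}{cell.n_total:>6}{cell.n_confirmed:>11}{'--':>8}"
            lo, hi = cell.ci95
            return (
                f"{cell.stratum:<34}{cell.n_total:>6}{cell.n_confirmed:>11}"
                f"{cell.ppv_rounded:>8.1f}  ({lo:.1f}, {hi:.1f})"
            )

        lines.append(row(self.overall))
        for table in (self.by_category, self.by_symptom_subtype, self.by_time_stratum):
            lines.append("")
            lines.extend(row(c) for c in table.values())
        for name, table in (
            ("Severity", self.severity_table),
            ("Intent", self.intent_table),
            ("Source", self.source_table),
        ):
            lines.append("")
            lines.append(f"{name} (confirmed cases)")
            total = sum(table.values())
            for label, count in table.items():
                pct = f"{100 * count / total:.1f}" if total else "--"
                lines.append(f"  {label:<28}{count:>5}  {pct}%")
        if self.reliability is not None:
            r = self.reliability
            kappa = "undefined" if r.kappa is None else f"{r.kappa:.3f}"
            lines += [
                "",
                f"Inter-rater reliability over {r.n_pairs} pairs: "
                f"observed agreement {100 * r.observed_agreement:.1f}%, "
                f"expected {100 * r.expected_agreement:.1f}%, kappa {kappa}",
            ]
        return "\n".join(lines) + "\n"


def build_report(
    cases: list[PotentialCase],
    final_results: dict[str, AdjudicationResult],
    availability: dict[str, str] | None = None,
    reliability: Reliability | None = None,
    codeset_version: str = "unversioned",
) -> ValidationReport:
    """Assemble the full validation report.

    ``availability`` maps case_id to one of ``adjudicable`` / ``no_information``
    / ``not_found``; missing ids default to adjudicable.  Every adjudicable
    case must have a final adjudication in ``final_results``.
    """
    availability = availability or {}
    for case_id, state in availability.items():
        if state not in AVAILABILITY_STATES:
            raise ValidationError(f"unknown availability state {state!r} for {case_id!r}")

    adjudicable: list[PotentialCase] = []
    n_noinfo = n_notfound = 0
    for case in cases:
        state = availability.get(case.case_id, "adjudicable")
        if state == "no_information":
            n_noinfo += 1
        elif state == "not_found":
            n_notfound += 1
        else:
            adjudicable.append(case)

    confirmed_ids = set()
    for case in adjudicable:
        result = final_results.get(case.case_id)
        if result is None:
            raise ValidationError(f"adjudicable case {case.case_id!r} has no final adjudication")
        if result.confirmed:
            confirmed_ids.add(case.case_id)

    def cell(stratum: str, subset: list[PotentialCase]) -> PPVCell:
        return ppv(
            sum(c.case_id in confirmed_ids for c in subset), len(subset), stratum=stratum
        )

    categories = list(DEFAULT_PRECEDENCE) + [DEATH_CATEGORY]
    by_category = {
        cat: cell(cat, [c for c in adjudicable if c.category == cat]) for cat in categories
    }
    symptom_cases = [c for c in adjudicable if c.category == "symptom_only"]
    by_subtype = {
        sub: cell(sub, [c for c in symptom_cases if c.symptom_subtype in (sub, "both")])
        for sub in ("cns", "respiratory")
    }
    by_stratum = {
        s: cell(s, [c for c in adjudicable if c.time_stratum == s]) for s in ("early", "late")
    }

    severity = Counter()
    intent = Counter()
    source = Counter()
    for case in adjudicable:
        result = final_results[case.case_id]
        if result.confirmed:
            severity[result.severity] += 1
            intent[result.intent] += 1
            source[result.source] += 1

    report = ValidationReport(
        availability=Availability(len(cases), n_noinfo, n_notfound),
        overall=cell("overall", adjudicable),
        by_category=by_category,
        by_symptom_subtype=by_subtype,
        by_time_stratum=by_stratum,
        severity_table=dict(sorted(severity.items())),
        intent_table=dict(sorted(intent.items())),
        source_table=dict(sorted(source.items())),
        reliability=reliability,
        codeset_version=codeset_version,
    )
    assert sum(c.n_total for c in by_category.values()) == report.overall.n_total
    assert sum(c.n_total for c in by_stratum.values()) == report.overall.n_total
    return report
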