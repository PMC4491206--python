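"""Domain types for administrative claims data and delimited-file round-trip I/O.

The pipeline consumes one *claims bundle*: five linked tables describing a
pediatric insured population — children (demographics), enrollment spans,
pharmacy fills, medical encounters (ED / inpatient / outpatient with ordered
ICD-9-CM diagnosis codes and external-cause codes), and death records.  All
dates are whole calendar days, matching the daily granularity of claims
extracts.  Files are comma-delimited UTF-8 with a header row and ISO-8601
dates; multi-valued code fields are semicolon-joined with the first diagnosis
code primary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import pandas as pd

__all__ = [
    "Child",
    "ClaimsBundle",
    "ClaimsValidationError",
    "DeathRecord",
    "Encounter",
    "EnrollmentSpan",
    "PrescriptionFill",
    "read_bundle",
    "write_bundle",
]

log = logging.getLogger(__name__)

SEXES = frozenset({"F", "M", "unknown"})
SETTINGS = frozenset({"emergency", "inpatient", "outpatient"})

BUNDLE_FILES = {
    "children": ("children.csv", ["child_id", "birth_date", "sex", "race"]),
    "enrollment": ("enrollment.csv", ["child_id", "start_date", "end_date"]),
    "fills": ("fills.csv", ["child_id", "fill_date", "drug_class", "days_supply"]),
    "encounters": (
        "encounters.csv",
        ["encounter_id", "child_id", "date", "setting", "dx_codes", "ecodes"],
    ),
    "deaths": ("deaths.csv", ["child_id", "death_date", "cause_codes"]),
}


class ClaimsValidationError(ValueError):
    """A bundle or one of its rows violates a structural invariant."""


@dataclass(frozen=True)
class Child:
    child_id: str
    birth_date: date
    sex: str = "unknown"
    race: str = "unknown"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ClaimsValidationError(f"unknown sex {self.sex!r} for child {self.child_id!r}")


@dataclass(frozen=True)
class EnrollmentSpan:
    child_id: str
    start_date: date
    end_date: date

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ClaimsValidationError(
                f"enrollment span for {self.child_id!r} has start {self.start_date} "
                f"after end {self.end_date}"
            )


@dataclass(frozen=True)
class PrescriptionFill:
    child_id: str
    fill_date: date
    drug_class: str  # "opioid" or "other"; NDC mapping happens upstream
    days_supply: int

    def __post_init__(self) -> None:
        if self.days_supply < 1:
            raise ClaimsValidationError(
                f"fill for {self.child_id!r} on {self.fill_date} has days_supply "
                f"{self.days_supply}; must be >= 1"
            )
        if self.drug_class not in ("opioid", "other"):
            raise ClaimsValidationError(f"unknown drug_class {self.drug_class!r}")


@dataclass(frozen=True)
class Encounter:
    encounter_id: str
    child_id: str
    date: date
    setting: str
    dx_codes: tuple[str, ...]  # ordered; first entry is the primary diagnosis
    ecodes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise ClaimsValidationError(
                f"encounter {self.encounter_id!r} has unknown setting {self.setting!r}"
            )
        if not self.dx_codes:
            raise ClaimsValidationError(f"encounter {self.encounter_id!r} has no diagnosis codes")


@dataclass(frozen=True)
class DeathRecord:
    child_id: str
    death_date: date
    cause_codes: tuple[str, ...] = ()


@dataclass(frozen=True)
class ClaimsBundle:
    """The five linked claims tables for one study population."""

    children: tuple[Child, ...] = ()
    enrollment_spans: tuple[EnrollmentSpan, ...] = ()
    fills: tuple[PrescriptionFill, ...] = ()
    encounters: tuple[Encounter, ...] = ()
    deaths: tuple[DeathRecord, ...] = ()

    def validate(self) -> "ClaimsBundle":
        """Check referential integrity and cross-table invariants; return self."""
        ids = [c.child_id for c in self.children]
        known = set(ids)
        if len(ids) != len(known):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ClaimsValidationError(f"duplicate child_id(s): {dupes}")
        missing: set[str] = set()
        for table in (self.enrollment_spans, self.fills, self.encounters, self.deaths):
            missing.update(r.child_id for r in table if r.child_id not in known)
        if missing:
            raise ClaimsValidationError(
                f"child_id(s) referenced but not in children table: {sorted(missing)}"
            )
        births = {c.child_id: c.birth_date for c in self.children}
        for f in self.fills:
            if f.fill_date < births[f.child_id]:
                raise ClaimsValidationError(
                    f"fill on {f.fill_date} precedes birth of {f.child_id!r}"
                )
        for e in self.encounters:
            if e.date < births[e.child_id]:
                raise ClaimsValidationError(
                    f"encounter {e.encounter_id!r} precedes birth of {e.child_id!r}"
                )
        death_ids = [d.child_id for d in self.deaths]
        if len(death_ids) != len(set(death_ids)):
            dupes = sorted({i for i in death_ids if death_ids.count(i) > 1})
            raise ClaimsValidationError(f"multiple death records for child_id(s): {dupes}")
        return self

    def sorted(self) -> "ClaimsBundle":
        """Canonical row order: child_id, then date, then remaining fields."""
        return ClaimsBundle(
            children=tuple(sorted(self.children, key=lambda c: c.child_id)),
            enrollment_spans=tuple(
                sorted(self.enrollment_spans, key=lambda s: (s.child_id, s.start_date, s.end_date))
            ),
            fills=tuple(
                sorted(self.fills, key=lambda f: (f.child_id, f.fill_date, f.days_supply))
            ),
            encounters=tuple(
                sorted(self.encounters, key=lambda e: (e.child_id, e.date, e.encounter_id))
            ),
            deaths=tuple(sorted(self.deaths, key=lambda d: (d.child_id, d.death_date))),
        )


# ---------------------------------------------------------------------------
# Delimited-file I/O


def _parse_date(value: str, *, file: str, row: int) -> date:
    try:
        return date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise ClaimsValidationError(f"{file}, row {row}: unparseable date {value!r}") from exc


def _split_codes(value) -> tuple[str, ...]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or str(value) == "":
        return ()
    return tuple(part for part in str(value).split(";") if part)


def _read_csv(directory: Path, key: str) -> pd.DataFrame:
    filename, columns = BUNDLE_FILES[key]
    path = directory / filename
    if not path.exists():
        raise FileNotFoundError(f"missing bundle file: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    got = list(frame.columns)
    if got != columns:
        raise ClaimsValidationError(f"{filename}: expected columns {columns}, found {got}")
    return frame


def read_bundle(directory: str | Path) -> ClaimsBundle:
    """Load and validate a claims bundle from its five CSV files."""
    directory = Path(directory)
    frames = {key: _read_csv(directory, key) for key in BUNDLE_FILES}

    children = tuple(
        Child(
            child_id=r.child_id,
            birth_date=_parse_date(r.birth_date, file="children.csv", row=i + 2),
            sex=r.sex,
            race=r.race,
        )
        for i, r in enumerate(frames["children"].itertuples(index=False))
    )
    spans = tuple(
        EnrollmentSpan(
            child_id=r.child_id,
            start_date=_parse_date(r.start_date, file="enrollment.csv", row=i + 2),
            end_date=_parse_date(r.end_date, file="enrollment.csv", row=i + 2),
        )
        for i, r in enumerate(frames["enrollment"].itertuples(index=False))
    )
    fills = tuple(
        PrescriptionFill(
            child_id=r.child_id,
            fill_date=_parse_date(r.fill_date, file="fills.csv", row=i + 2),
            drug_class=r.drug_class,
            days_supply=int(r.days_supply),
        )
        for i, r in enumerate(frames["fills"].itertuples(index=False))
    )
    encounters = tuple(
        Encounter(
            encounter_id=r.encounter_id,
            child_id=r.child_id,
            date=_parse_date(r.date, file="encounters.csv", row=i + 2),
            setting=r.setting,
            dx_codes=_split_codes(r.dx_codes),
            ecodes=_split_codes(r.ecodes),
        )
        for i, r in enumerate(frames["encounters"].itertuples(index=False))
    )
    deaths = tuple(
        DeathRecord(
            child_id=r.child_id,
            death_date=_parse_date(r.death_date, file="deaths.csv", row=i + 2),
            cause_codes=_split_codes(r.cause_codes),
        )
        for i, r in enumerate(frames["deaths"].itertuples(index=False))
    )

    bundle = ClaimsBundle(children, spans, fills, encounters, deaths).validate()
    log.info(
        "read bundle from %s: %d children, %d spans, %d fills, %d encounters, %d deaths",
        directory, len(children), len(spans), len(fills), len(encounters), len(deaths),
    )
    return bundle


def write_bundle(bundle: ClaimsBundle, directory: str | Path) -> list[Path]:
    """Write a validated bundle to five CSV files in deterministic order."""
    bundle = bundle.validate().sorted()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    tables: dict[str, list[dict]] = {
        "children": [
            {"child_id": c.child_id, "birth_date": c.birth_date.isoformat(),
             "sex": c.sex, "race": c.race}
            for c in bundle.children
        ],
        "enrollment": [
            {"child_id": s.child_id, "start_date": s.start_date.isoformat(),
             "end_date": s.end_date.isoformat()}
            for s in bundle.enrollment_spans
        ],
        "fills": [
            {"child_id": f.child_id, "fill_date": f.fill_date.isoformat(),
             "drug_class": f.drug_class, "days_supply": f.days_supply}
            for f in bundle.fills
        ],
        "encounters": [
            {"encounter_id": e.encounter_id, "child_id": e.child_id,
             "date": e.date.isoformat(), "setting": e.setting,
             "dx_codes": ";".join(e.dx_codes), "ecodes": ";".join(e.ecodes)}
            for e in bundle.encounters
        ],
        "deaths": [
            {"child_id": d.child_id, "death_date": d.death_date.isoformat(),
             "cause_codes": ";".join(d.cause_codes)}
            for d in bundle.deaths
        ],
    }
    written = []
    for key, rows in tables.items():
        filename, columns = BUNDLE_FILES[key]
        path = directory / filename
        pd.DataFrame(rows, columns=columns).to_csv(path, index=False, lineterminator="\n")
        written.append(path)
    return written
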