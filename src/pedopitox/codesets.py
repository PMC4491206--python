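"""ICD-9-CM screening code sets: normalization, matching, and registry loading.

Potential opioid-toxicity cases are screened with four categories of codes on
ED/inpatient encounters — external-cause codes for intentional (self-harm) and
unintentional medication poisoning/overdose, external-cause codes for adverse
effects in therapeutic use, and diagnosis codes for the cardinal symptoms of
serious toxicity (CNS and respiratory depression).  Within each external-cause
category the codes divide into sub-groups: A (opioid or unspecified analgesic),
B (a specific drug that is *not* an opioid), and C (unspecified medication).
An encounter flags a category when an A or C code is present, unless a B code
attributes the event to a specific non-opioid drug.

Code lists live in a versioned YAML config, not in source, so that users can
swap in their own lists.  The bundled default (``data/default_codesets.yaml``)
is a reconstruction from the standard ICD-9-CM families — it is documented as
such and should be replaced with a study-specific list for real analyses.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "CATEGORIES",
    "CodeGroup",
    "CodePattern",
    "CodeSetError",
    "CodeSetRegistry",
    "default_registry_path",
    "load_registry",
    "match_code",
    "normalize_code",
]

log = logging.getLogger(__name__)

#: Screening categories that use external-cause codes with A/B/C sub-groups.
ECODE_CATEGORIES = (
    "intentional_overdose",
    "unintentional_overdose",
    "adverse_effect_therapeutic",
)
#: Symptom categories hold plain diagnosis-code patterns (single group).
SYMPTOM_CATEGORIES = ("symptom_cns", "symptom_respiratory")
CATEGORIES = ECODE_CATEGORIES + SYMPTOM_CATEGORIES

GROUP_LABELS = ("A", "B", "C")

_VALID_RAW = re.compile(r"^[0-9EVev.\s]*[0-9EVev][0-9EVev.\s]*$")
_VALID_NORMALIZED = re.compile(r"^[0-9EV]+$")


class CodeSetError(ValueError):
    """Raised for malformed codes or code-set configuration."""


def normalize_code(raw: str) -> str:
    """Canonicalize an ICD-9-CM code: uppercase, trimmed, dot removed.

    >>> normalize_code("965.00")
    '96500'
    >>> normalize_code(" e850.2 ")
    'E8502'
    """
    if raw is None or str(raw).strip() == "":
        raise CodeSetError("empty code")
    text = str(raw)
    if not _VALID_RAW.match(text):
        raise CodeSetError(f"invalid ICD-9-CM code {raw!r}")
    code = re.sub(r"[\s.]", "", text).upper()
    if not _VALID_NORMALIZED.match(code):
        raise CodeSetError(f"invalid ICD-9-CM code {raw!r}")
    return code


@dataclass(frozen=True)
class CodePattern:
    """A normalized code (``exact``) or code-family prefix (``prefix``)."""

    pattern: str
    match_mode: str = "prefix"

    def __post_init__(self) -> None:
        if self.match_mode not in ("exact", "prefix"):
            raise CodeSetError(f"unknown match_mode {self.match_mode!r}")
        if not _VALID_NORMALIZED.match(self.pattern):
            raise CodeSetError(f"pattern {self.pattern!r} is not a normalized code")

    def matches(self, code: str) -> bool:
        if self.match_mode == "exact":
            return code == self.pattern
        return code.startswith(self.pattern)


@dataclass(frozen=True)
class CodeGroup:
    label: str
    patterns: tuple[CodePattern, ...]

    def matches(self, code: str) -> bool:
        return any(p.matches(code) for p in self.patterns)

    def matches_any(self, codes) -> bool:
        return any(self.matches(c) for c in codes)


@dataclass(frozen=True)
class CodeSetRegistry:
    """Named code groups per screening category, plus named exclusion groups.

    ``categories`` maps each of the five screening categories to its groups:
    the three external-cause categories carry groups labelled A/B/C (B and C
    may be empty), the two symptom categories carry a single unlabeled group.
    ``exclusions`` maps cohort-exclusion reasons (serious illness, transplant,
    institutional residence, drug abuse, ...) to code groups.
    """

    categories: dict[str, dict[str, CodeGroup]]
    exclusions: dict[str, CodeGroup]
    version: str

    def group(self, category: str, label: str) -> CodeGroup:
        return self.categories[category].get(label, CodeGroup(label, ()))

    def symptom_group(self, category: str) -> CodeGroup:
        return self.categories[category]["dx"]


def match_code(code: str, group: CodeGroup) -> bool:
    """True iff *code* (already normalized) matches any pattern in *group*."""
    return group.matches(code)


def _parse_pattern(entry, *, where: str) -> CodePattern:
    if isinstance(entry, str):
        return CodePattern(normalize_code(entry), "prefix")
    if isinstance(entry, dict):
        try:
            raw = entry["pattern"]
        except KeyError as exc:
            raise CodeSetError(f"{where}: pattern entry missing 'pattern' key") from exc
        return CodePattern(normalize_code(raw), entry.get("match_mode", "prefix"))
    raise CodeSetError(f"{where}: malformed pattern entry {entry!r}")


def _parse_group(label: str, entries, *, where: str) -> CodeGroup:
    patterns: list[CodePattern] = []
    seen = set()
    for entry in entries or []:
        pat = _parse_pattern(entry, where=where)
        if pat in seen:
            log.warning("%s: duplicate pattern %s ignored", where, pat.pattern)
            continue
        seen.add(pat)
        patterns.append(pat)
    return CodeGroup(label, tuple(patterns))


def default_registry_path() -> Path:
    """Path of the bundled default code-set config."""
    return Path(resources.files("pedopitox").joinpath("data/default_codesets.yaml"))


def load_registry(config: str | Path | None = None) -> CodeSetRegistry:
    """Load a :class:`CodeSetRegistry` from a YAML config file.

    With no argument the bundled default reconstruction is loaded.  Every one
    of the five screening categories must be present; a missing category is a
    configuration error, not an empty group.
    """
    path = Path(config) if config is not None else default_registry_path()
    if not path.exists():
        raise CodeSetError(f"code-set config not found: {path}")
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict) or "categories" not in doc:
        raise CodeSetError(f"{path}: config must be a mapping with a 'categories' section")

    raw_categories = doc["categories"]
    categories: dict[str, dict[str, CodeGroup]] = {}
    for category in CATEGORIES:
        if category not in raw_categories:
            raise CodeSetError(f"{path}: missing screening category {category!r}")
        section = raw_categories[category] or {}
        where = f"{path}:{category}"
        if category in ECODE_CATEGORIES:
            groups = {
                label: _parse_group(label, section.get(label), where=f"{where}/{label}")
                for label in GROUP_LABELS
            }
            if not groups["A"].patterns:
                raise CodeSetError(f"{where}: group A must have at least one pattern")
        else:
            entries = section.get("dx", section if isinstance(section, list) else None)
            groups = {"dx": _parse_group("dx", entries, where=where)}
            if not groups["dx"].patterns:
                raise CodeSetError(f"{where}: symptom category must have at least one pattern")
        categories[category] = groups

    exclusions = {
        name: _parse_group(name, entries, where=f"{path}:exclusions/{name}")
        for name, entries in (doc.get("exclusions") or {}).items()
    }
    version = str(doc.get("version", "unversioned"))
    registry = CodeSetRegistry(categories=categories, exclusions=exclusions, version=version)
    log.info("loaded code-set registry %s (version %s)", path, version)
    return registry
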