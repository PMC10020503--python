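"""Diagnosis-code pattern matching and bundled code sets.

A :class:`CodeSet` holds ICD-9-CM style patterns.  Each pattern is either a
bare prefix (``"013"``, ``"054.3"``, ``"003.21"``) or an inclusive range of
3-digit rubrics written as ``"042-044"``.  Matching is prefix-based at the
rubric level, the convention of claims-database studies: a listed 3-digit
code includes all of its sub-rubrics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .errors import ConfigurationError, DataError

_PATTERN_RE = re.compile(r"^\d+(\.\d+)?$")
_RANGE_RE = re.compile(r"^(\d{3})-(\d{3})$")


@dataclass(frozen=True)
class CodeSet:
    """A named list of diagnosis-code patterns.

    Parameters
    ----------
    name:
        Label used in error messages and reports.
    entries:
        Patterns: bare prefixes and/or ``"lo-hi"`` rubric ranges.
    """

    name: str
    entries: tuple[str, ...]
    _prefixes: tuple[str, ...] = field(init=False, repr=False, compare=False)
    _ranges: tuple[tuple[int, int], ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        prefixes: list[str] = []
        ranges: list[tuple[int, int]] = []
        for entry in self.entries:
            entry = str(entry).strip()
            if not entry:
                raise ConfigurationError(f"code set {self.name!r}: empty pattern")
            m = _RANGE_RE.match(entry)
            if m:
                lo, hi = int(m.group(1)), int(m.group(2))
                if lo > hi:
                    raise ConfigurationError(
                        f"code set {self.name!r}: range {entry!r} has low > high"
                    )
                ranges.append((lo, hi))
            elif _PATTERN_RE.match(entry):
                prefixes.append(entry)
            else:
                raise ConfigurationError(
                    f"code set {self.name!r}: malformed pattern {entry!r}"
                )
        object.__setattr__(self, "_prefixes", tuple(prefixes))
        object.__setattr__(self, "_ranges", tuple(ranges))


def _rubric(code: str) -> int:
    head = code.split(".", 1)[0]
    if not head.isdigit():
        raise DataError(f"malformed diagnosis code {code!r}: non-numeric rubric")
    return int(head)


def match_code(code: str, cs: CodeSet) -> bool:
    """Return True if ``code`` belongs to the code set.

    A code matches when it equals a pattern, extends a dotted pattern
    (``"054.30"`` extends ``"054.3"``), shares the 3-digit rubric of a bare
    pattern (``"013.1"`` matches ``"013"``), or its rubric lies inside a
    listed range.
    """
    if not code:
        raise DataError("empty diagnosis code")
    code = str(code).strip()
    rub = _rubric(code)
    for pat in cs._prefixes:
        if "." in pat:
            if code == pat or code.startswith(pat):
                return True
        else:
            if code.split(".", 1)[0] == pat:
                return True
    for lo, hi in cs._ranges:
        if lo <= rub <= hi:
            return True
    return False


# ---------------------------------------------------------------------------
# Bundled code sets

def _read_yaml(name: str) -> dict:
    ref = resources.files("herbsurv").joinpath("data", "codesets", name)
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_codeset(name: str) -> CodeSet:
    """Load one of the bundled flat code sets by file stem."""
    doc = _read_yaml(f"{name}.yaml")
    return CodeSet(doc["name"], tuple(str(e) for e in doc["entries"]))


def load_neuro_codesets() -> dict[str, CodeSet]:
    """The four neurological-disease subtype code sets, keyed by subtype."""
    return {
        "cns_infection": load_codeset("neuro_cns_infection"),
        "cognitive": load_codeset("neuro_cognitive"),
        "vasculopathy": load_codeset("neuro_vasculopathy"),
        "peripheral_neuropathy": load_codeset("neuro_peripheral_neuropathy"),
    }


def load_oi_codesets() -> dict[str, CodeSet]:
    """The six opportunistic-infection flag code sets."""
    doc = _read_yaml("opportunistic_infections.yaml")
    return {
        key: CodeSet(key, tuple(str(e) for e in entries))
        for key, entries in doc["sets"].items()
    }


@dataclass(frozen=True)
class CharlsonMap:
    """Quan's ICD-9-CM Charlson enumeration with weights and hierarchy."""

    categories: dict[str, CodeSet]
    weights: dict[str, int]
    hierarchy: tuple[tuple[str, str], ...]


def load_charlson_map() -> CharlsonMap:
    doc = _read_yaml("charlson_quan_icd9.yaml")
    cats: dict[str, CodeSet] = {}
    weights: dict[str, int] = {}
    for label, spec in doc["categories"].items():
        cats[label] = CodeSet(label, tuple(str(e) for e in spec["entries"]))
        weights[label] = int(spec["weight"])
    hierarchy = tuple((a, b) for a, b in doc.get("hierarchy", []))
    return CharlsonMap(cats, weights, hierarchy)


# ---------------------------------------------------------------------------
# Cause-of-death chapters (ICD-9 numeric and ICD-10 alphanumeric ranges)

_ICD10_RE = re.compile(r"^([A-Z])(\d{2})")
_ICD10_RANGE_RE = re.compile(r"^([A-Z])(\d{2})-([A-Z])(\d{2})$")

CAUSE_CATEGORIES = (
    "infections_parasites",
    "circulatory",
    "endocrine_metabolic",
    "hepatitis_liver",
    "respiratory",
    "genitourinary",
    "neoplasms",
    "other",
)


def _icd10_key(letter: str, num: int) -> tuple[str, int]:
    return (letter, num)


class CauseMap:
    """Ordered chapter-level mapping of death-cause codes to categories."""

    def __init__(self) -> None:
        doc = _read_yaml("cause_categories.yaml")
        self._order: list[tuple[str, CodeSet, list[tuple[tuple, tuple]]]] = []
        for cat in doc["categories"]:
            icd9 = CodeSet(cat["label"] + "_icd9", tuple(cat["icd9"]))
            icd10_ranges = []
            for rng in cat["icd10"]:
                m = _ICD10_RANGE_RE.match(rng)
                if m is None:
                    raise ConfigurationError(f"bad ICD-10 range {rng!r}")
                icd10_ranges.append(
                    (
                        _icd10_key(m.group(1), int(m.group(2))),
                        _icd10_key(m.group(3), int(m.group(4))),
                    )
                )
            self._order.append((cat["label"], icd9, icd10_ranges))

    def categorize(self, code: str, icd_version: int) -> str:
        """Map a cause-of-death code to a category; unknown codes -> 'other'."""
        code = str(code).strip()
        if not code:
            return "other"
        if icd_version == 9:
            try:
                for label, icd9, _ in self._order:
                    if match_code(code, icd9):
                        return label
            except DataError:
                return "other"
            return "other"
        m = _ICD10_RE.match(code.upper())
        if m is None:
            return "other"
        key = _icd10_key(m.group(1), int(m.group(2)))
        for label, _, ranges in self._order:
            for lo, hi in ranges:
                if lo <= key <= hi:
                    return label
        return "other"
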