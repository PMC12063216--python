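"""In-memory model of a healthcare-semantics workbook.

A dataset workbook describes clinical *concepts* (classes) and their
*composedOf* attributes (properties) in a fixed tabular layout, together
with schema-level metadata and the external coding systems (terminologies)
the concepts bind to.  The types here are the typed, row-anchored form of
the three tabs the forge consumes: ``Metadata``, ``Coding System and
Version`` and ``Concepts``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Tuple, Union


class _Unbounded:
    """Upper cardinality bound ``n`` — compares greater than any integer."""

    _instance: Optional["_Unbounded"] = None

    def __new__(cls) -> "_Unbounded":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNBOUNDED"

    def __gt__(self, other: object) -> bool:
        return not isinstance(other, _Unbounded)

    def __ge__(self, other: object) -> bool:
        return True

    def __lt__(self, other: object) -> bool:
        return False

    def __le__(self, other: object) -> bool:
        return isinstance(other, _Unbounded)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _Unbounded)

    def __hash__(self) -> int:
        return hash("UNBOUNDED")


UNBOUNDED = _Unbounded()

Bound = Union[int, _Unbounded]
Cardinality = Tuple[int, Bound]


def format_cardinality(card: Cardinality) -> str:
    """Render a bound pair back into its cell form, e.g. ``(0, UNBOUNDED)`` -> ``"0:n"``."""
    lo, hi = card
    return f"{lo}:{'n' if isinstance(hi, _Unbounded) else hi}"


@dataclass(frozen=True)
class MetadataRecord:
    """Schema-level metadata from the ``Metadata`` tab."""

    prefix: str
    title: str
    description: str
    version: str
    copyright: str
    license: str
    canonical_iri: str
    versioned_iri: str
    prior_version: Optional[str] = None


@dataclass(frozen=True)
class CodeValidity:
    """Per-code release-validity metadata for a versioned terminology."""

    code: str
    valid_from: Optional[str] = None
    valid_to: Optional[str] = None
    meaning_changed: bool = False
    meaning_derivable: bool = False


@dataclass(frozen=True)
class CodingSystemRecord:
    """One external terminology referenced by ``standard`` / value-set cells."""

    name: str
    namespace: str
    version: str
    rdf_available: bool
    root_node: Optional[str] = None
    code_validity: Tuple[CodeValidity, ...] = ()

    def code_iri(self, code: str) -> str:
        return self.namespace + code


#: Parsed forms a ``value set or subset`` cell can take.
VALUE_SET_DESCENDANT = "descendant_of"
VALUE_SET_CODES = "codes"
VALUE_SET_LABELS = "labels"


@dataclass(frozen=True)
class ValueSet:
    """A value-set expression: enumerated labels, enumerated codes, or a subtree."""

    kind: str  # one of VALUE_SET_*
    values: Tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in (VALUE_SET_DESCENDANT, VALUE_SET_CODES, VALUE_SET_LABELS):
            raise ValueError(f"unknown value-set kind: {self.kind!r}")


@dataclass
class AttributeRow:
    """A ``composedOf`` (or ``inherited``) row belonging to one concept."""

    concept_reference: str
    row_kind: str  # "composedOf" | "inherited"
    name: str
    general_description: str
    value_type: str
    row_number: int
    excluded_type_descendants: Tuple[str, ...] = ()
    standard: Optional[str] = None
    value_set: Optional[ValueSet] = None
    cardinality: Cardinality = (0, UNBOUNDED)
    sensitive: bool = False
    active: bool = True
    #: set by resolve_inheritance: name of the ancestor concept defining this row
    inherited_from: Optional[str] = None

    @property
    def min_card(self) -> int:
        return self.cardinality[0]

    @property
    def max_card(self) -> Bound:
        return self.cardinality[1]


@dataclass
class ConceptRow:
    """A ``concept`` row plus its attribute rows, as laid out in the workbook."""

    name: str
    general_description: str
    row_number: int
    parent: Optional[str] = None
    semantic_type: str = ""
    meaning_binding: Optional[Tuple[str, str]] = None  # (coding-system name, code)
    excluded_type_descendants: Tuple[str, ...] = ()
    card_admin_case: Optional[Cardinality] = None
    card_subject_pseudo_id: Optional[Cardinality] = None
    card_source_system: Optional[Cardinality] = None
    active: bool = True
    attributes: list = field(default_factory=list)

    def active_attributes(self) -> Iterator[AttributeRow]:
        return (a for a in self.attributes if a.active)


@dataclass
class DatasetModel:
    """The validated in-memory form of the three consumed tabs."""

    metadata: MetadataRecord
    coding_systems: list = field(default_factory=list)
    concepts: list = field(default_factory=list)
    #: row-anchored problems found while reading the workbook itself
    read_report: "ValidationReport" = field(default_factory=lambda: ValidationReport())

    def coding_system(self, name: str) -> Optional[CodingSystemRecord]:
        for cs in self.coding_systems:
            if cs.name == name:
                return cs
        return None

    def concept(self, name: str) -> Optional[ConceptRow]:
        for c in self.concepts:
            if c.name == name:
                return c
        return None

    def active_concepts(self) -> Iterator[ConceptRow]:
        return (c for c in self.concepts if c.active)

    def copy(self) -> "DatasetModel":
        concepts = []
        for c in self.concepts:
            cc = replace(c)
            cc.attributes = [replace(a) for a in c.attributes]
            concepts.append(cc)
        return DatasetModel(
            metadata=self.metadata,
            coding_systems=list(self.coding_systems),
            concepts=concepts,
            read_report=ValidationReport(list(self.read_report)),
        )


# ---------------------------------------------------------------------------
# Row-anchored validation reporting
# ---------------------------------------------------------------------------

SEVERITY_ERROR = "error"
SEVERITY_WARNING = "warning"


@dataclass(frozen=True)
class DatasetError:
    """One row-anchored problem found while reading or validating a workbook."""

    code: str
    tab_name: str
    row_number: int
    column_name: str
    message: str
    severity: str = SEVERITY_ERROR


class ValidationReport:
    """Ordered collection of dataset errors/warnings, sorted by (tab, row)."""

    def __init__(self, errors: Optional[list] = None) -> None:
        self._errors: list = list(errors or [])

    def add(self, error: DatasetError) -> None:
        self._errors.append(error)

    def extend(self, report: "ValidationReport") -> None:
        self._errors.extend(report._errors)

    @property
    def errors(self) -> list:
        return sorted(
            self._errors, key=lambda e: (e.tab_name, e.row_number, e.column_name, e.code)
        )

    def only(self, severity: str) -> list:
        return [e for e in self.errors if e.severity == severity]

    @property
    def has_errors(self) -> bool:
        return any(e.severity == SEVERITY_ERROR for e in self._errors)

    def __len__(self) -> int:
        return len(self._errors)

    def __iter__(self):
        return iter(self.errors)

    def __bool__(self) -> bool:
        return bool(self._errors)

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "code": e.code,
                    "tab": e.tab_name,
                    "row": e.row_number,
                    "column": e.column_name,
                    "message": e.message,
                    "severity": e.severity,
                }
                for e in self.errors
            ],
            indent=2,
        )

    def to_text(self) -> str:
        lines = []
        for e in self.errors:
            lines.append(
                f"[{e.severity.upper()}] {e.tab_name}!row {e.row_number} "
                f"({e.column_name}): {e.code}: {e.message}"
            )
        return "\n".join(lines)


# Stable machine-readable error codes (human messages accompany each use).
ERR_MISSING_TAB = "MISSING_TAB"
ERR_MISSING_METADATA = "MISSING_METADATA"
ERR_BAD_CELL = "BAD_CELL"
ERR_BAD_CARDINALITY = "BAD_CARDINALITY"
ERR_MIN_GT_MAX = "MIN_GT_MAX"
ERR_UNKNOWN_PARENT = "UNKNOWN_PARENT"
ERR_DUPLICATE_CONCEPT = "DUPLICATE_CONCEPT"
ERR_STANDARD_NOT_DECLARED = "STANDARD_NOT_DECLARED"
ERR_UNKNOWN_VALUE_TYPE = "UNKNOWN_VALUE_TYPE"
ERR_INHERITED_NOT_IN_PARENT = "INHERITED_NOT_IN_PARENT"
ERR_MISSING_INHERITED_ROW = "MISSING_INHERITED_ROW"
ERR_UNKNOWN_CONCEPT_REFERENCE = "UNKNOWN_CONCEPT_REFERENCE"
ERR_PREFIX_NOT_USED = "PREFIX_NOT_USED"
ERR_CODING_SYSTEM_NOT_LINKABLE = "CODING_SYSTEM_NOT_LINKABLE"
ERR_EMPTY_NAME = "EMPTY_NAME"
WARN_UNKNOWN_COLUMN = "UNKNOWN_COLUMN"
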