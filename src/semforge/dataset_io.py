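"""Read a dataset workbook (XLSX), materialize the typed model, validate it.

The workbook follows the standard six-tab layout of which three are
consumed: ``Metadata`` (key/value rows), ``Coding System and Version``
(one terminology per row) and ``Concepts`` (one concept or composedOf
attribute per row, 23 columns).  Parsing is total: every cell either maps
into the model or produces a row-anchored :class:`~semforge.model.DatasetError`;
nothing is silently dropped.  Tab and column matching is case-insensitive
on normalized whitespace.
"""

from __future__ import annotations

import re
from typing import Dict, List, Optional, Sequence, Tuple

from openpyxl import load_workbook

from .model import (
    ERR_BAD_CARDINALITY,
    ERR_BAD_CELL,
    ERR_DUPLICATE_CONCEPT,
    ERR_EMPTY_NAME,
    ERR_INHERITED_NOT_IN_PARENT,
    ERR_MIN_GT_MAX,
    ERR_MISSING_INHERITED_ROW,
    ERR_MISSING_METADATA,
    ERR_MISSING_TAB,
    ERR_PREFIX_NOT_USED,
    ERR_STANDARD_NOT_DECLARED,
    ERR_UNKNOWN_CONCEPT_REFERENCE,
    ERR_UNKNOWN_PARENT,
    ERR_UNKNOWN_VALUE_TYPE,
    SEVERITY_WARNING,
    UNBOUNDED,
    AttributeRow,
    Cardinality,
    CodeValidity,
    CodingSystemRecord,
    ConceptRow,
    DatasetError,
    DatasetModel,
    MetadataRecord,
    ValidationReport,
    ValueSet,
    VALUE_SET_CODES,
    VALUE_SET_DESCENDANT,
    VALUE_SET_LABELS,
)
from .naming import CONCEPT_LINK, DEFAULT_DATATYPE_MAP  # noqa: F401  (re-export)

TAB_METADATA = "Metadata"
TAB_CODING = "Coding System and Version"
TAB_CONCEPTS = "Concepts"
CONSUMED_TABS = (TAB_METADATA, TAB_CODING, TAB_CONCEPTS)

#: the full Concepts-tab header set (23 columns)
CONCEPTS_COLUMNS: Tuple[str, ...] = (
    "release",
    "IRI",
    "active status (yes/no)",
    "concept reference",
    "concept or concept compositions or inherited",
    "general concept name",
    "general description",
    "contextualized concept name",
    "contextualized description",
    "contextualized parent",
    "contextualized type",
    "parent",
    "type",
    "excluded type descendants",
    "standard",
    "value set or subset",
    "meaning binding",
    "additional information",
    "cardinality for composedOf",
    "cardinality for concept to Administrative Case",
    "cardinality for concept to Subject Pseudo Identifier",
    "cardinality for concept to Source System",
    "sensitive (yes/no)",
)

#: Metadata tab element names (first column), values in the second column
METADATA_FIELDS: Tuple[str, ...] = (
    "Prefix",
    "Title",
    "Description",
    "Version",
    "Prior version",
    "Copyright",
    "License",
    "Canonical IRI",
    "Versioned IRI",
)

CODING_COLUMNS: Tuple[str, ...] = (
    "Name",
    "Namespace",
    "Version",
    "RDF available (yes/no)",
    "Root node",
    "Code validity",
)

_CARD_RE = re.compile(r"^\s*(\d+)\s*:\s*(\d+|n)\s*$")
_ABS_IRI_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.-]*://\S+$")


class WorkbookError(Exception):
    """Fatal structural problem (e.g. a consumed tab is missing)."""


class CardinalityError(ValueError):
    def __init__(self, code: str, message: str) -> None:
        super().__init__(message)
        self.code = code


def _norm(text: str) -> str:
    return " ".join(str(text).split()).lower()


def _cell_str(value) -> str:
    if value is None:
        return ""
    return str(value).strip()


def _is_yes(value: str) -> bool:
    return _norm(value) in ("yes", "true", "y", "1")


# ---------------------------------------------------------------------------
# Cell grammars
# ---------------------------------------------------------------------------

def parse_cardinality(text: str) -> Cardinality:
    """Parse a cardinality cell ``"min:max"`` where max may be ``n``.

    An empty cell means "no constraint": ``(0, UNBOUNDED)``.

    Raises :class:`CardinalityError` (codes ``BAD_CARDINALITY`` /
    ``MIN_GT_MAX``) on malformed strings or inverted bounds.
    """
    text = _cell_str(text)
    if not text:
        return (0, UNBOUNDED)
    m = _CARD_RE.match(text)
    if not m:
        raise CardinalityError(
            ERR_BAD_CARDINALITY, f"cardinality {text!r} does not match 'INT:(INT|n)'"
        )
    lo = int(m.group(1))
    hi: object = UNBOUNDED if m.group(2) == "n" else int(m.group(2))
    if not isinstance(hi, type(UNBOUNDED)) and lo > hi:
        raise CardinalityError(
            ERR_MIN_GT_MAX, f"cardinality {text!r} has minimum greater than maximum"
        )
    return (lo, hi)  # type: ignore[return-value]


def parse_value_set(text: str, value_type: str) -> Optional[ValueSet]:
    """Parse a ``value set or subset`` cell.

    Grammar: ``descendant of CODE`` selects a terminology subtree;
    otherwise the cell enumerates values separated by ``;`` (or ``,``).
    When the attribute's value type is ``code`` the entries are terminology
    codes, otherwise qualitative labels.
    """
    text = _cell_str(text)
    if not text:
        return None
    m = re.match(r"^descendant\s+of\s+(\S.*)$", text, flags=re.IGNORECASE)
    if m:
        return ValueSet(VALUE_SET_DESCENDANT, (m.group(1).strip(),))
    sep = ";" if ";" in text else ","
    values = tuple(v.strip() for v in text.split(sep) if v.strip())
    kind = VALUE_SET_CODES if _norm(value_type) == "code" else VALUE_SET_LABELS
    return ValueSet(kind, values)


def parse_meaning_binding(text: str) -> Optional[Tuple[str, str]]:
    """Parse ``"<coding system name>: <code>"`` into its two parts."""
    text = _cell_str(text)
    if not text:
        return None
    if ":" not in text:
        raise ValueError(f"meaning binding {text!r} is not of the form 'standard: code'")
    name, code = text.rsplit(":", 1)
    return (name.strip(), code.strip())


def parse_code_validity(text: str) -> Tuple[CodeValidity, ...]:
    """Parse the compact per-code validity cell.

    Entries separated by ``;``, each ``CODE|from=...|to=...|changed=yes|derivable=yes``.
    """
    text = _cell_str(text)
    if not text:
        return ()
    out: List[CodeValidity] = []
    for entry in text.split(";"):
        entry = entry.strip()
        if not entry:
            continue
        parts = entry.split("|")
        kwargs = {"code": parts[0].strip()}
        for p in parts[1:]:
            if "=" not in p:
                raise ValueError(f"malformed code-validity fragment {p!r}")
            key, val = (s.strip() for s in p.split("=", 1))
            if key == "from":
                kwargs["valid_from"] = val
            elif key == "to":
                kwargs["valid_to"] = val
            elif key == "changed":
                kwargs["meaning_changed"] = _is_yes(val)
            elif key == "derivable":
                kwargs["meaning_derivable"] = _is_yes(val)
            else:
                raise ValueError(f"unknown code-validity key {key!r}")
        out.append(CodeValidity(**kwargs))
    return tuple(out)


def _split_list(text: str) -> Tuple[str, ...]:
    text = _cell_str(text)
    if not text:
        return ()
    sep = ";" if ";" in text else ","
    return tuple(v.strip() for v in text.split(sep) if v.strip())


# ---------------------------------------------------------------------------
# Workbook reading
# ---------------------------------------------------------------------------

def _find_sheet(wb, wanted: str):
    for name in wb.sheetnames:
        if _norm(name) == _norm(wanted):
            return wb[name]
    return None


def _header_index(
    header_row: Sequence, expected: Sequence[str], tab: str, report: ValidationReport
) -> Dict[str, int]:
    """Map normalized expected column names to 0-based indices."""
    actual = {_norm(_cell_str(c)): i for i, c in enumerate(header_row) if _cell_str(c)}
    index: Dict[str, int] = {}
    for col in expected:
        if _norm(col) in actual:
            index[col] = actual[_norm(col)]
    known = {_norm(c) for c in expected}
    for name, i in actual.items():
        if name not in known:
            report.add(
                DatasetError(
                    code="UNKNOWN_COLUMN",
                    tab_name=tab,
                    row_number=1,
                    column_name=name,
                    message=f"unrecognized column {name!r} is ignored",
                    severity=SEVERITY_WARNING,
                )
            )
    return index


def _read_metadata(sheet, report: ValidationReport) -> MetadataRecord:
    values: Dict[str, str] = {}
    rownum: Dict[str, int] = {}
    for i, row in enumerate(sheet.iter_rows(values_only=True), start=1):
        if not row:
            continue
        key = _cell_str(row[0] if len(row) > 0 else "")
        val = _cell_str(row[1] if len(row) > 1 else "")
        if key:
            values[_norm(key)] = val
            rownum[_norm(key)] = i
    get = lambda name: values.get(_norm(name), "")
    return MetadataRecord(
        prefix=get("Prefix"),
        title=get("Title"),
        description=get("Description"),
        version=get("Version"),
        prior_version=get("Prior version") or None,
        copyright=get("Copyright"),
        license=get("License"),
        canonical_iri=get("Canonical IRI"),
        versioned_iri=get("Versioned IRI"),
    )


def _read_coding_systems(sheet, report: ValidationReport) -> List[CodingSystemRecord]:
    rows = list(sheet.iter_rows(values_only=True))
    if not rows:
        return []
    index = _header_index(rows[0], CODING_COLUMNS, TAB_CODING, report)
    out: List[CodingSystemRecord] = []
    for rno, row in enumerate(rows[1:], start=2):
        get = lambda col: _cell_str(row[index[col]]) if col in index and index[col] < len(row) else ""
        name = get("Name")
        if not name:
            continue
        try:
            validity = parse_code_validity(get("Code validity"))
        except ValueError as exc:
            report.add(
                DatasetError(
                    code=ERR_BAD_CELL,
                    tab_name=TAB_CODING,
                    row_number=rno,
                    column_name="Code validity",
                    message=str(exc),
                )
            )
            validity = ()
        out.append(
            CodingSystemRecord(
                name=name,
                namespace=get("Namespace"),
                version=get("Version"),
                rdf_available=_is_yes(get("RDF available (yes/no)")),
                root_node=get("Root node") or None,
                code_validity=validity,
            )
        )
    return out


def _read_concepts(sheet, report: ValidationReport) -> List[ConceptRow]:
    rows = list(sheet.iter_rows(values_only=True))
    if not rows:
        return []
    index = _header_index(rows[0], CONCEPTS_COLUMNS, TAB_CONCEPTS, report)

    concepts: List[ConceptRow] = []
    by_name: Dict[str, ConceptRow] = {}
    orphans: List[AttributeRow] = []

    def cell(row, col: str) -> str:
        i = index.get(col)
        if i is None or i >= len(row):
            return ""
        return _cell_str(row[i])

    def card(row, rno: int, col: str) -> Optional[Cardinality]:
        text = cell(row, col)
        if not text:
            return None
        try:
            return parse_cardinality(text)
        except CardinalityError as exc:
            report.add(
                DatasetError(
                    code=exc.code,
                    tab_name=TAB_CONCEPTS,
                    row_number=rno,
                    column_name=col,
                    message=str(exc),
                )
            )
            return None

    for rno, row in enumerate(rows[1:], start=2):
        if all(_cell_str(c) == "" for c in row):
            continue
        kind = _norm(cell(row, "concept or concept compositions or inherited"))
        name = cell(row, "general concept name")
        active = _is_yes(cell(row, "active status (yes/no)") or "yes")
        if kind == "concept":
            if not name:
                report.add(
                    DatasetError(
                        code=ERR_EMPTY_NAME,
                        tab_name=TAB_CONCEPTS,
                        row_number=rno,
                        column_name="general concept name",
                        message="concept row has no name",
                    )
                )
                continue
            binding = None
            try:
                binding = parse_meaning_binding(cell(row, "meaning binding"))
            except ValueError as exc:
                report.add(
                    DatasetError(
                        code=ERR_BAD_CELL,
                        tab_name=TAB_CONCEPTS,
                        row_number=rno,
                        column_name="meaning binding",
                        message=str(exc),
                    )
                )
            concept = ConceptRow(
                name=name,
                general_description=cell(row, "general description"),
                row_number=rno,
                parent=cell(row, "parent") or None,
                semantic_type=cell(row, "type"),
                meaning_binding=binding,
                excluded_type_descendants=_split_list(
                    cell(row, "excluded type descendants")
                ),
                card_admin_case=card(
                    row, rno, "cardinality for concept to Administrative Case"
                ),
                card_subject_pseudo_id=card(
                    row, rno, "cardinality for concept to Subject Pseudo Identifier"
                ),
                card_source_system=card(
                    row, rno, "cardinality for concept to Source System"
                ),
                active=active,
            )
            concepts.append(concept)
            by_name[name] = concept
        elif kind in ("composedof", "inherited"):
            ref = cell(row, "concept reference")
            value_type = cell(row, "type")
            cardinality = card(row, rno, "cardinality for composedOf") or (0, UNBOUNDED)
            try:
                vset = parse_value_set(cell(row, "value set or subset"), value_type)
            except ValueError as exc:
                report.add(
                    DatasetError(
                        code=ERR_BAD_CELL,
                        tab_name=TAB_CONCEPTS,
                        row_number=rno,
                        column_name="value set or subset",
                        message=str(exc),
                    )
                )
                vset = None
            attr = AttributeRow(
                concept_reference=ref,
                row_kind="composedOf" if kind == "composedof" else "inherited",
                name=name,
                general_description=cell(row, "general description"),
                value_type=value_type,
                row_number=rno,
                excluded_type_descendants=_split_list(
                    cell(row, "excluded type descendants")
                ),
                standard=cell(row, "standard") or None,
                value_set=vset,
                cardinality=cardinality,
                sensitive=_is_yes(cell(row, "sensitive (yes/no)")),
                active=active,
            )
            if ref and ref in by_name:
                by_name[ref].attributes.append(attr)
            else:
                orphans.append(attr)
        else:
            report.add(
                DatasetError(
                    code=ERR_BAD_CELL,
                    tab_name=TAB_CONCEPTS,
                    row_number=rno,
                    column_name="concept or concept compositions or inherited",
                    message=f"row kind {kind!r} is not one of concept/composedOf/inherited",
                )
            )

    # attribute rows may precede their concept row; attach them now
    for attr in list(orphans):
        if attr.concept_reference in by_name:
            by_name[attr.concept_reference].attributes.append(attr)
            orphans.remove(attr)
    for attr in orphans:
        report.add(
            DatasetError(
                code=ERR_UNKNOWN_CONCEPT_REFERENCE,
                tab_name=TAB_CONCEPTS,
                row_number=attr.row_number,
                column_name="concept reference",
                message=(
                    f"composedOf row references unknown concept "
                    f"{attr.concept_reference!r}"
                ),
            )
        )
    for c in by_name.values():
        c.attributes.sort(key=lambda a: a.row_number)
    return concepts


def read_workbook(path) -> DatasetModel:
    """Read the three consumed tabs of a dataset workbook into a model.

    Missing consumed tabs raise :class:`WorkbookError`; unreadable cells are
    recorded in ``model.read_report`` anchored to their row.  Inactive rows
    are retained but flagged, so later errors can still anchor to them.
    """
    wb = load_workbook(path, read_only=True, data_only=True)
    try:
        report = ValidationReport()
        sheets = {}
        for tab in CONSUMED_TABS:
            sheet = _find_sheet(wb, tab)
            if sheet is None:
                raise WorkbookError(f"{ERR_MISSING_TAB}: workbook has no {tab!r} tab")
            sheets[tab] = sheet
        metadata = _read_metadata(sheets[TAB_METADATA], report)
        coding = _read_coding_systems(sheets[TAB_CODING], report)
        concepts = _read_concepts(sheets[TAB_CONCEPTS], report)
        return DatasetModel(
            metadata=metadata,
            coding_systems=coding,
            concepts=concepts,
            read_report=report,
        )
    finally:
        wb.close()


# ---------------------------------------------------------------------------
# Inheritance resolution
# ---------------------------------------------------------------------------

def _ancestors(model: DatasetModel, concept: ConceptRow) -> List[ConceptRow]:
    """Parent chain from nearest to farthest; cycles are truncated."""
    chain: List[ConceptRow] = []
    seen = {concept.name}
    cur = concept
    while cur.parent:
        parent = model.concept(cur.parent)
        if parent is None or parent.name in seen:
            break
        chain.append(parent)
        seen.add(parent.name)
        cur = parent
    return chain


def inherited_attribute_set(model: DatasetModel, concept: ConceptRow) -> Dict[str, AttributeRow]:
    """The attributes a concept must repeat as 'inherited' rows: the union of
    its ancestors' composedOf rows, nearest ancestor winning on name clashes,
    minus names the concept itself overrides with a composedOf row."""
    own_overrides = {
        a.name for a in concept.active_attributes() if a.row_kind == "composedOf"
    }
    expected: Dict[str, AttributeRow] = {}
    for ancestor in _ancestors(model, concept):
        for attr in ancestor.active_attributes():
            if attr.row_kind != "composedOf":
                continue
            if attr.name in own_overrides or attr.name in expected:
                continue
            expected[attr.name] = attr
    return expected


def _inheritance_errors(model: DatasetModel) -> ValidationReport:
    report = ValidationReport()
    for concept in model.active_concepts():
        expected = inherited_attribute_set(model, concept)
        seen_inherited = set()
        for attr in concept.active_attributes():
            if attr.row_kind != "inherited":
                continue
            seen_inherited.add(attr.name)
            if attr.name not in expected:
                report.add(
                    DatasetError(
                        code=ERR_INHERITED_NOT_IN_PARENT,
                        tab_name=TAB_CONCEPTS,
                        row_number=attr.row_number,
                        column_name="general concept name",
                        message=(
                            f"concept {concept.name!r} marks {attr.name!r} as "
                            "inherited but no ancestor defines it"
                        ),
                    )
                )
        for name in expected:
            if name not in seen_inherited:
                report.add(
                    DatasetError(
                        code=ERR_MISSING_INHERITED_ROW,
                        tab_name=TAB_CONCEPTS,
                        row_number=concept.row_number,
                        column_name="general concept name",
                        message=(
                            f"concept {concept.name!r} is missing an inherited row "
                            f"for parent attribute {name!r} "
                            f"(defined by {expected[name].concept_reference!r})"
                        ),
                    )
                )
    return report


def resolve_inheritance(model: DatasetModel, report: Optional[ValidationReport] = None) -> DatasetModel:
    """Annotate inherited rows with their defining ancestor; verify coverage.

    Returns a new model in which every 'inherited' AttributeRow carries
    ``inherited_from`` (the ancestor concept that defines the attribute).
    Mismatches (inherited rows with no matching parent attribute, or parent
    attributes with no inherited row) are appended to *report* when given.
    Idempotent: resolving an already-resolved model changes nothing.
    """
    resolved = model.copy()
    for concept in resolved.active_concepts():
        expected = inherited_attribute_set(resolved, concept)
        for attr in concept.attributes:
            if attr.row_kind == "inherited" and attr.name in expected:
                attr.inherited_from = expected[attr.name].concept_reference
    if report is not None:
        report.extend(_inheritance_errors(resolved))
    return resolved


def effective_attributes(model: DatasetModel, concept: ConceptRow) -> List[AttributeRow]:
    """The full attribute set in force for a concept: its own composedOf rows
    plus ancestor attributes it does not override (override wins)."""
    own = [a for a in concept.active_attributes() if a.row_kind == "composedOf"]
    inherited = inherited_attribute_set(model, concept)
    return own + [inherited[n] for n in sorted(inherited)]


# ---------------------------------------------------------------------------
# Structural validation catalog
# ---------------------------------------------------------------------------

def validate_dataset(
    model: DatasetModel,
    project_prefix: Optional[str] = None,
    external_parents: Sequence[str] = (),
) -> ValidationReport:
    """Run the structural rule catalog; an empty report means forge-ready.

    *external_parents* names concepts defined outside this workbook (e.g. the
    base schema a project extension builds on) that parents may refer to.
    """
    report = ValidationReport()
    meta = model.metadata
    required = {
        "Prefix": meta.prefix,
        "Title": meta.title,
        "Description": meta.description,
        "Version": meta.version,
        "Copyright": meta.copyright,
        "License": meta.license,
        "Canonical IRI": meta.canonical_iri,
        "Versioned IRI": meta.versioned_iri,
    }
    for i, (field_name, value) in enumerate(required.items(), start=1):
        if not _cell_str(value):
            report.add(
                DatasetError(
                    code=ERR_MISSING_METADATA,
                    tab_name=TAB_METADATA,
                    row_number=i,
                    column_name=field_name,
                    message=f"required metadata element {field_name!r} is empty",
                )
            )
    if meta.prefix and any(ch.isspace() for ch in meta.prefix):
        report.add(
            DatasetError(
                code=ERR_MISSING_METADATA,
                tab_name=TAB_METADATA,
                row_number=1,
                column_name="Prefix",
                message=f"prefix {meta.prefix!r} must not contain whitespace",
            )
        )
    for col, iri in (("Canonical IRI", meta.canonical_iri), ("Versioned IRI", meta.versioned_iri)):
        if _cell_str(iri) and not _ABS_IRI_RE.match(iri):
            report.add(
                DatasetError(
                    code=ERR_MISSING_METADATA,
                    tab_name=TAB_METADATA,
                    row_number=1,
                    column_name=col,
                    message=f"{col} {iri!r} is not an absolute IRI",
                )
            )

    coding_names = {cs.name for cs in model.coding_systems}
    known_concepts = {c.name for c in model.active_concepts()}
    known_parents = known_concepts | set(external_parents)
    datatype_names = {k.lower() for k in DEFAULT_DATATYPE_MAP}

    seen_names: Dict[str, int] = {}
    for concept in model.active_concepts():
        if concept.name in seen_names:
            report.add(
                DatasetError(
                    code=ERR_DUPLICATE_CONCEPT,
                    tab_name=TAB_CONCEPTS,
                    row_number=concept.row_number,
                    column_name="general concept name",
                    message=(
                        f"concept {concept.name!r} already defined at row "
                        f"{seen_names[concept.name]}"
                    ),
                )
            )
        else:
            seen_names[concept.name] = concept.row_number

        if concept.parent and concept.parent not in known_parents:
            report.add(
                DatasetError(
                    code=ERR_UNKNOWN_PARENT,
                    tab_name=TAB_CONCEPTS,
                    row_number=concept.row_number,
                    column_name="parent",
                    message=f"parent {concept.parent!r} is not a known concept",
                )
            )
        if concept.meaning_binding and concept.meaning_binding[0] not in coding_names:
            report.add(
                DatasetError(
                    code=ERR_STANDARD_NOT_DECLARED,
                    tab_name=TAB_CONCEPTS,
                    row_number=concept.row_number,
                    column_name="meaning binding",
                    message=(
                        f"meaning binding uses coding system "
                        f"{concept.meaning_binding[0]!r} which is not declared "
                        "in the Coding System and Version tab"
                    ),
                )
            )
        if project_prefix and not _norm(concept.name).startswith(_norm(project_prefix)):
            report.add(
                DatasetError(
                    code=ERR_PREFIX_NOT_USED,
                    tab_name=TAB_CONCEPTS,
                    row_number=concept.row_number,
                    column_name="general concept name",
                    message=(
                        f"project concept {concept.name!r} does not start with "
                        f"the declared project prefix {project_prefix!r}"
                    ),
                )
            )

        for attr in concept.active_attributes():
            vt = _cell_str(attr.value_type)
            if (
                vt
                and vt.lower() not in datatype_names
                and vt.lower() not in ("code", "qualitative")
                and vt not in known_concepts
            ):
                report.add(
                    DatasetError(
                        code=ERR_UNKNOWN_VALUE_TYPE,
                        tab_name=TAB_CONCEPTS,
                        row_number=attr.row_number,
                        column_name="type",
                        message=(
                            f"value type {vt!r} is neither a primitive, 'code', "
                            "'qualitative', nor a known concept"
                        ),
                    )
                )
            if attr.standard and attr.standard not in coding_names:
                report.add(
                    DatasetError(
                        code=ERR_STANDARD_NOT_DECLARED,
                        tab_name=TAB_CONCEPTS,
                        row_number=attr.row_number,
                        column_name="standard",
                        message=(
                            f"standard {attr.standard!r} is not declared in the "
                            "Coding System and Version tab"
                        ),
                    )
                )

    report.extend(_inheritance_errors(model))
    return report


def load_dataset(
    path, project_prefix: Optional[str] = None, external_parents: Sequence[str] = ()
) -> Tuple[DatasetModel, ValidationReport]:
    """Read + resolve inheritance + validate, returning the combined report."""
    model = read_workbook(path)
    report = ValidationReport(list(model.read_report))
    model = resolve_inheritance(model)
    report.extend(validate_dataset(model, project_prefix, external_parents))
    return model, report
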