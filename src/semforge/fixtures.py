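"""Self-contained test and demo inputs: workbooks, toy terminologies, RDF data.

Nothing here ships real terminology content — coding systems are referenced
only by configurable root-node IRIs (the worked example uses the public
SNOMED CT root identifier 138875005 and a toy ICD-10-GM namespace), so no
licensed vocabulary is ever required.  All outputs are byte-stable for a
fixed seed and timestamp override.
"""

from __future__ import annotations

import datetime
import random
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from openpyxl import Workbook
from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import RDF, RDFS, XSD

from .dataset_io import (
    CODING_COLUMNS,
    CONCEPTS_COLUMNS,
    METADATA_FIELDS,
    inherited_attribute_set,
)
from .model import (
    UNBOUNDED,
    AttributeRow,
    CodeValidity,
    CodingSystemRecord,
    ConceptRow,
    DatasetModel,
    MetadataRecord,
    ValueSet,
    VALUE_SET_CODES,
    VALUE_SET_LABELS,
    format_cardinality,
)
from .schema_builder import SchemaGraph
from .shacl_builder import collect_class_property_map, prepare

SNOMED_ROOT = "http://snomed.info/id/138875005"

#: defect kinds generate_instance_data can seed (exactly one violation each)
DEFECT_KINDS = (
    "missing_mandatory",
    "over_max",
    "wrong_class",
    "unlisted_member",
    "start_gt_end",
    "bad_iri",
)

_FIXED_TIMESTAMP = datetime.datetime(2025, 1, 1, 0, 0, 0)


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs for the deterministic fixture generators."""

    seed: int = 0
    n_concepts: int = 8
    max_depth: int = 3
    branching: int = 2
    n_instances: int = 1
    defect: Optional[str] = None
    timestamp: datetime.datetime = _FIXED_TIMESTAMP
    data_namespace: str = "https://example.org/data/"
    terminology_root: str = "https://example.org/toyterm/ROOT"


class FixtureError(Exception):
    pass


# ---------------------------------------------------------------------------
# Workbook writing
# ---------------------------------------------------------------------------

def _attr_to_row(attr: AttributeRow) -> Dict[str, str]:
    vs = ""
    if attr.value_set is not None:
        if attr.value_set.kind == "descendant_of":
            vs = f"descendant of {attr.value_set.values[0]}"
        else:
            vs = "; ".join(attr.value_set.values)
    return {
        "active status (yes/no)": "yes" if attr.active else "no",
        "concept reference": attr.concept_reference,
        "concept or concept compositions or inherited": attr.row_kind,
        "general concept name": attr.name,
        "general description": attr.general_description,
        "type": attr.value_type,
        "excluded type descendants": "; ".join(attr.excluded_type_descendants),
        "standard": attr.standard or "",
        "value set or subset": vs,
        "cardinality for composedOf": format_cardinality(attr.cardinality),
        "sensitive (yes/no)": "yes" if attr.sensitive else "no",
    }


def _concept_to_row(concept: ConceptRow) -> Dict[str, str]:
    mb = ""
    if concept.meaning_binding:
        mb = f"{concept.meaning_binding[0]}: {concept.meaning_binding[1]}"
    row = {
        "active status (yes/no)": "yes" if concept.active else "no",
        "concept or concept compositions or inherited": "concept",
        "general concept name": concept.name,
        "general description": concept.general_description,
        "parent": concept.parent or "",
        "type": concept.semantic_type,
        "excluded type descendants": "; ".join(concept.excluded_type_descendants),
        "meaning binding": mb,
    }
    for col, card in (
        ("cardinality for concept to Administrative Case", concept.card_admin_case),
        (
            "cardinality for concept to Subject Pseudo Identifier",
            concept.card_subject_pseudo_id,
        ),
        ("cardinality for concept to Source System", concept.card_source_system),
    ):
        row[col] = format_cardinality(card) if card is not None else ""
    return row


def _code_validity_cell(entries: Sequence[CodeValidity]) -> str:
    parts = []
    for cv in entries:
        frags = [cv.code]
        if cv.valid_from:
            frags.append(f"from={cv.valid_from}")
        if cv.valid_to:
            frags.append(f"to={cv.valid_to}")
        frags.append(f"changed={'yes' if cv.meaning_changed else 'no'}")
        frags.append(f"derivable={'yes' if cv.meaning_derivable else 'no'}")
        parts.append("|".join(frags))
    return "; ".join(parts)


def write_model_workbook(
    model: DatasetModel, path, timestamp: datetime.datetime = _FIXED_TIMESTAMP
) -> None:
    """Write a model out as a six-tab workbook (fixtures are the only place
    workbooks are ever written)."""
    wb = Workbook()
    guideline = wb.active
    guideline.title = "Guideline"
    guideline["A1"] = "Placeholder guideline describing the dataset structure."
    wb.create_sheet("License")["A1"] = "Placeholder license text."
    wb.create_sheet("Release Notes")["A1"] = "Placeholder release notes."

    meta_sheet = wb.create_sheet("Metadata")
    meta = model.metadata
    values = {
        "Prefix": meta.prefix,
        "Title": meta.title,
        "Description": meta.description,
        "Version": meta.version,
        "Prior version": meta.prior_version or "",
        "Copyright": meta.copyright,
        "License": meta.license,
        "Canonical IRI": meta.canonical_iri,
        "Versioned IRI": meta.versioned_iri,
    }
    for i, name in enumerate(METADATA_FIELDS, start=1):
        meta_sheet.cell(row=i, column=1, value=name)
        meta_sheet.cell(row=i, column=2, value=values[name])

    coding_sheet = wb.create_sheet("Coding System and Version")
    for j, col in enumerate(CODING_COLUMNS, start=1):
        coding_sheet.cell(row=1, column=j, value=col)
    for i, cs in enumerate(model.coding_systems, start=2):
        row = {
            "Name": cs.name,
            "Namespace": cs.namespace,
            "Version": cs.version,
            "RDF available (yes/no)": "yes" if cs.rdf_available else "no",
            "Root node": cs.root_node or "",
            "Code validity": _code_validity_cell(cs.code_validity),
        }
        for j, col in enumerate(CODING_COLUMNS, start=1):
            coding_sheet.cell(row=i, column=j, value=row[col])

    concepts_sheet = wb.create_sheet("Concepts")
    for j, col in enumerate(CONCEPTS_COLUMNS, start=1):
        concepts_sheet.cell(row=1, column=j, value=col)
    rownum = 2
    for concept in model.concepts:
        for cells in [_concept_to_row(concept)] + [
            _attr_to_row(a) for a in concept.attributes
        ]:
            for j, col in enumerate(CONCEPTS_COLUMNS, start=1):
                if col in cells and cells[col] != "":
                    concepts_sheet.cell(row=rownum, column=j, value=cells[col])
            rownum += 1

    wb.properties.created = timestamp
    wb.properties.modified = timestamp
    wb.save(path)


def generate_template_workbook(path, timestamp: datetime.datetime = _FIXED_TIMESTAMP) -> None:
    """The empty starting-point workbook: all six tabs, full headers, no data."""
    empty_meta = MetadataRecord(
        prefix="", title="", description="", version="",
        copyright="", license="", canonical_iri="", versioned_iri="",
    )
    write_model_workbook(DatasetModel(metadata=empty_meta), path, timestamp)


# ---------------------------------------------------------------------------
# The worked example: Billed Diagnosis
# ---------------------------------------------------------------------------

def billed_diagnosis_model() -> DatasetModel:
    """Diagnosis / BilledDiagnosis / Age with the worked-example attributes.

    BilledDiagnosis inherits everything from Diagnosis, overrides the code
    attribute to constrain it to ICD-10-GM, and adds a rank code restricted
    to an enumerated set of SNOMED-style codes (child codes excluded).
    """
    meta = MetadataRecord(
        prefix="sphn",
        title="Demo health-data schema",
        description="Worked example schema around the Billed Diagnosis concept.",
        version="2025.1",
        prior_version="2024.2",
        copyright="(c) Example consortium",
        license="CC BY 4.0",
        canonical_iri="https://example.org/rdf/schema/sphn",
        versioned_iri="https://example.org/rdf/schema/sphn/2025.1",
    )
    icd = CodingSystemRecord(
        name="ICD-10-GM",
        namespace="https://example.org/terminology/icd-10-gm/",
        version="2024",
        rdf_available=True,
        root_node="https://example.org/terminology/icd-10-gm/ICD-10-GM",
    )
    snomed = CodingSystemRecord(
        name="SNOMED CT",
        namespace="http://snomed.info/id/",
        version="2024-07-01",
        rdf_available=True,
        root_node=SNOMED_ROOT,
    )
    rn = iter(range(2, 100))
    diagnosis = ConceptRow(
        name="Diagnosis",
        general_description="Determination of a disease from signs and symptoms.",
        row_number=next(rn),
        attributes=[],
    )
    diagnosis.attributes = [
        AttributeRow(
            concept_reference="Diagnosis",
            row_kind="composedOf",
            name="code",
            general_description="Code describing the diagnosis.",
            value_type="code",
            standard="SNOMED CT",
            cardinality=(1, 1),
            row_number=next(rn),
        ),
        AttributeRow(
            concept_reference="Diagnosis",
            row_kind="composedOf",
            name="record datetime",
            general_description="Time at which the diagnosis was recorded.",
            value_type="datetime",
            cardinality=(1, 1),
            row_number=next(rn),
        ),
        AttributeRow(
            concept_reference="Diagnosis",
            row_kind="composedOf",
            name="subject age",
            general_description="Age of the subject at the time of diagnosis.",
            value_type="Age",
            cardinality=(0, 1),
            row_number=next(rn),
        ),
    ]
    billed = ConceptRow(
        name="Billed Diagnosis",
        general_description="Diagnosis at discharge used by the hospital billing system.",
        row_number=next(rn),
        parent="Diagnosis",
        attributes=[],
    )
    billed.attributes = [
        AttributeRow(
            concept_reference="Billed Diagnosis",
            row_kind="composedOf",  # override: semantics narrowed to ICD-10-GM
            name="code",
            general_description="ICD-10-GM code billed for this diagnosis.",
            value_type="code",
            standard="ICD-10-GM",
            cardinality=(1, 1),
            row_number=next(rn),
        ),
        AttributeRow(
            concept_reference="Billed Diagnosis",
            row_kind="inherited",
            name="record datetime",
            general_description="Time at which the diagnosis was recorded.",
            value_type="datetime",
            cardinality=(1, 1),
            row_number=next(rn),
        ),
        AttributeRow(
            concept_reference="Billed Diagnosis",
            row_kind="inherited",
            name="subject age",
            general_description="Age of the subject at the time of diagnosis.",
            value_type="Age",
            cardinality=(0, 1),
            row_number=next(rn),
        ),
        AttributeRow(
            concept_reference="Billed Diagnosis",
            row_kind="composedOf",
            name="rank code",
            general_description="Rank of the billed diagnosis (primary/secondary).",
            value_type="code",
            standard="SNOMED CT",
            value_set=ValueSet(VALUE_SET_CODES, ("8319008", "85097005")),
            cardinality=(0, 1),
            row_number=next(rn),
        ),
    ]
    age = ConceptRow(
        name="Age",
        general_description="Age of an individual, as a quantity at a point in time.",
        row_number=next(rn),
        attributes=[],
    )
    age.attributes = [
        AttributeRow(
            concept_reference="Age",
            row_kind="composedOf",
            name="quantity",
            general_description="Numerical value of the age.",
            value_type="double",
            cardinality=(1, 1),
            row_number=next(rn),
        ),
        AttributeRow(
            concept_reference="Age",
            row_kind="composedOf",
            name="determination datetime",
            general_description="When the age was determined.",
            value_type="datetime",
            cardinality=(0, 1),
            row_number=next(rn),
        ),
    ]
    return DatasetModel(
        metadata=meta,
        coding_systems=[icd, snomed],
        concepts=[diagnosis, billed, age],
    )


def generate_billed_diagnosis_workbook(
    path, timestamp: datetime.datetime = _FIXED_TIMESTAMP
) -> None:
    write_model_workbook(billed_diagnosis_model(), path, timestamp)


def demo_model() -> DatasetModel:
    """The worked example plus an Encounter concept exercising qualitative
    value sets, start/end datetime ordering, concept-level context links and
    code-validity metadata."""
    model = billed_diagnosis_model()
    icd = model.coding_systems[0]
    model.coding_systems[0] = replace(
        icd,
        code_validity=(
            CodeValidity(
                code="A41.9", valid_from="2020", valid_to="2024",
                meaning_changed=True, meaning_derivable=True,
            ),
            CodeValidity(
                code="C10", valid_from="2020",
                meaning_changed=True, meaning_derivable=True,
            ),
            CodeValidity(
                code="B20", valid_from="2020",
                meaning_changed=True, meaning_derivable=False,
            ),
        ),
    )
    rn = iter(range(100, 130))
    encounter = ConceptRow(
        name="Encounter",
        general_description="A stay or visit during which care is provided.",
        row_number=next(rn),
        card_admin_case=(1, 1),
        attributes=[],
    )
    encounter.attributes = [
        AttributeRow(
            concept_reference="Encounter",
            row_kind="composedOf",
            name="start datetime",
            general_description="When the encounter began.",
            value_type="datetime",
            cardinality=(1, 1),
            row_number=next(rn),
        ),
        AttributeRow(
            concept_reference="Encounter",
            row_kind="composedOf",
            name="end datetime",
            general_description="When the encounter ended.",
            value_type="datetime",
            cardinality=(1, 1),
            row_number=next(rn),
        ),
        AttributeRow(
            concept_reference="Encounter",
            row_kind="composedOf",
            name="care setting",
            general_description="The setting in which care was delivered.",
            value_type="qualitative",
            value_set=ValueSet(VALUE_SET_LABELS, ("Inpatient", "Outpatient", "Emergency")),
            cardinality=(1, 1),
            sensitive=True,
            row_number=next(rn),
        ),
    ]
    model.concepts.append(encounter)
    return model


# ---------------------------------------------------------------------------
# Toy terminology graphs
# ---------------------------------------------------------------------------

def generate_toy_terminology(spec: FixtureSpec) -> Tuple[Graph, List[CodeValidity]]:
    """A deterministic complete subclass tree under ``spec.terminology_root``.

    Depth d with branching b yields (b^(d+1)-1)/(b-1) codes including the
    root.  Each non-root code carries validity metadata; a seeded subset is
    flagged as meaning-changed (derivable or not).
    """
    rng = random.Random(spec.seed)
    graph = Graph()
    root = URIRef(spec.terminology_root)
    base = spec.terminology_root.rsplit("/", 1)[0] + "/"
    graph.add((root, RDF.type, RDFS.Class))
    graph.add((root, RDFS.label, Literal("ROOT")))
    validity: List[CodeValidity] = []

    frontier = [(root, "ROOT")]
    for depth in range(spec.max_depth):
        nxt = []
        for parent, pcode in frontier:
            for b in range(spec.branching):
                code = f"{pcode}.{b}"
                node = URIRef(base + code)
                graph.add((node, RDF.type, RDFS.Class))
                graph.add((node, RDFS.subClassOf, parent))
                graph.add((node, RDFS.label, Literal(code)))
                changed = rng.random() < 0.2
                validity.append(
                    CodeValidity(
                        code=code,
                        valid_from="2020",
                        valid_to="2024" if changed and rng.random() < 0.5 else None,
                        meaning_changed=changed,
                        meaning_derivable=bool(changed and rng.random() < 0.7),
                    )
                )
                nxt.append((node, code))
        frontier = nxt
    return graph, validity


def terminology_descendants(graph: Graph, node: URIRef) -> set:
    """All transitive subclasses of *node* (used against a BFS oracle in tests)."""
    out = set()
    frontier = [node]
    while frontier:
        cur = frontier.pop()
        for child in graph.subjects(RDFS.subClassOf, cur):
            if child not in out:
                out.add(child)
                frontier.append(child)
    return out


# ---------------------------------------------------------------------------
# Random valid models (property tests)
# ---------------------------------------------------------------------------

def random_model(spec: FixtureSpec) -> DatasetModel:
    """A randomly shaped but structurally valid dataset model: a concept
    forest with datatype / code / qualitative / concept-link attributes and
    complete inherited rows."""
    rng = random.Random(spec.seed)
    meta = MetadataRecord(
        prefix="toy",
        title="Random toy schema",
        description="Randomly generated structurally valid schema.",
        version="1.0",
        copyright="(c) nobody",
        license="CC0",
        canonical_iri="https://example.org/rdf/schema/toy",
        versioned_iri="https://example.org/rdf/schema/toy/1.0",
    )
    term = CodingSystemRecord(
        name="TOYTERM",
        namespace="https://example.org/toyterm/",
        version="1",
        rdf_available=True,
        root_node=spec.terminology_root,
    )
    model = DatasetModel(metadata=meta, coding_systems=[term])
    rownum = 2
    datatypes = ("string", "integer", "datetime", "double")
    cards = ((0, UNBOUNDED), (0, 1), (1, 1), (1, UNBOUNDED), (2, 5))
    for i in range(spec.n_concepts):
        name = f"Sample Concept {i + 1}"
        parent = None
        if i > 0 and rng.random() < 0.6:
            parent = model.concepts[rng.randrange(i)].name
        concept = ConceptRow(
            name=name,
            general_description=f"Randomly generated concept number {i + 1}.",
            row_number=rownum,
            parent=parent,
            attributes=[],
        )
        rownum += 1
        for a in range(rng.randint(1, 3)):
            aname = f"field {i + 1} {a + 1}"
            kind = rng.choice(("datatype", "datatype", "code", "qualitative", "concept"))
            attr = AttributeRow(
                concept_reference=name,
                row_kind="composedOf",
                name=aname,
                general_description=f"Attribute {aname}.",
                value_type="string",
                cardinality=rng.choice(cards),
                sensitive=rng.random() < 0.2,
                row_number=rownum,
            )
            if kind == "datatype":
                attr.value_type = rng.choice(datatypes)
            elif kind == "code":
                attr.value_type = "code"
                attr.standard = "TOYTERM"
                if rng.random() < 0.3:
                    attr.value_set = ValueSet(
                        VALUE_SET_CODES, tuple(f"ROOT.{j}" for j in range(2))
                    )
            elif kind == "qualitative":
                attr.value_type = "qualitative"
                attr.value_set = ValueSet(
                    VALUE_SET_LABELS,
                    tuple(f"Level {chr(65 + j)} {i + 1} {a + 1}" for j in range(3)),
                )
            else:
                attr.value_type = model.concepts[rng.randrange(i)].name if i else "string"
            concept.attributes.append(attr)
            rownum += 1
        model.concepts.append(concept)

    # add the inherited rows every child must repeat
    for concept in model.concepts:
        for aname, ancestor_attr in sorted(inherited_attribute_set(model, concept).items()):
            concept.attributes.append(
                replace(
                    ancestor_attr,
                    concept_reference=concept.name,
                    row_kind="inherited",
                    row_number=rownum,
                )
            )
            rownum += 1
    return model


#: validate_dataset error codes seedable into a random model
MODEL_DEFECTS = (
    "UNKNOWN_PARENT",
    "DUPLICATE_CONCEPT",
    "STANDARD_NOT_DECLARED",
    "UNKNOWN_VALUE_TYPE",
    "MISSING_INHERITED_ROW",
    "INHERITED_NOT_IN_PARENT",
    "MISSING_METADATA",
)


def seed_model_defect(model: DatasetModel, code: str) -> DatasetModel:
    """Return a copy of *model* with exactly one defect of the given error code."""
    out = model.copy()
    if code == "UNKNOWN_PARENT":
        for c in out.concepts:
            if c.parent is None and not any(
                a.row_kind == "inherited" for a in c.attributes
            ):
                c.parent = "No Such Concept"
                return out
    elif code == "DUPLICATE_CONCEPT":
        dup = ConceptRow(
            name=out.concepts[0].name,
            general_description="Deliberate duplicate.",
            row_number=999,
        )
        out.concepts.append(dup)
        return out
    elif code == "STANDARD_NOT_DECLARED":
        for c in out.concepts:
            for a in c.attributes:
                if a.standard and a.row_kind == "composedOf":
                    # inherited copies match by name only, so one bad cell
                    # yields exactly one error
                    a.standard = "GHOST-TERM"
                    return out
    elif code == "UNKNOWN_VALUE_TYPE":
        for c in out.concepts:
            for a in c.attributes:
                if a.row_kind == "composedOf" and a.value_type in (
                    "string", "integer", "datetime", "double",
                ):
                    a.value_type = "mystery meat"
                    return out
    elif code == "MISSING_INHERITED_ROW":
        for c in out.concepts:
            inherited = [a for a in c.attributes if a.row_kind == "inherited"]
            if inherited:
                c.attributes.remove(inherited[0])
                return out
    elif code == "INHERITED_NOT_IN_PARENT":
        for c in out.concepts:
            if c.parent is None:
                c.attributes.append(
                    AttributeRow(
                        concept_reference=c.name,
                        row_kind="inherited",
                        name="phantom attribute",
                        general_description="Not defined by any ancestor.",
                        value_type="string",
                        row_number=998,
                    )
                )
                return out
    elif code == "MISSING_METADATA":
        out.metadata = replace(out.metadata, title="")
        return out
    raise FixtureError(f"defect {code!r} is not applicable to this model")


# ---------------------------------------------------------------------------
# Instance data
# ---------------------------------------------------------------------------

def _local(iri: URIRef) -> str:
    text = str(iri).rstrip("/#")
    return text.rsplit("#", 1)[-1].rsplit("/", 1)[-1]


def generate_instance_data(
    schema: SchemaGraph, mode: str = "conforming", spec: Optional[FixtureSpec] = None
) -> Graph:
    """Instance data typed against the schema's classes.

    ``conforming`` mode satisfies every effective restriction (including the
    IRI naming convention ``<ClassLocal>-<k>``); each defect mode then seeds
    exactly one violation of the named kind.
    """
    spec = spec or FixtureSpec()
    if mode != "conforming" and mode not in DEFECT_KINDS:
        raise FixtureError(f"unknown mode {mode!r}")
    prepared = prepare(schema)
    cpmap = collect_class_property_map(prepared)
    ns = spec.data_namespace

    shaped = [
        cls
        for cls in sorted(cpmap.entries, key=str)
        if cls not in cpmap.value_set_classes
        and (cls, URIRef("http://www.w3.org/2002/07/owl#oneOf"), None)
        not in prepared.graph
    ]
    data = Graph()
    data.bind("ex", Namespace(ns))
    instances: Dict[URIRef, List[URIRef]] = {}
    for cls in shaped:
        instances[cls] = [
            URIRef(f"{ns}{_local(cls)}-{k + 1}") for k in range(spec.n_instances)
        ]
        for inst in instances[cls]:
            data.add((inst, RDF.type, cls))

    code_counter = [0]

    def make_value(cls, inst_idx, prop, entry, j):
        loc = _local(prop)
        if entry.datatype is not None:
            if entry.datatype == XSD.dateTime:
                hour = 5 + j if "Start" in loc else (20 + j if "End" in loc else 10 + j)
                return Literal(f"2024-03-01T{hour:02d}:00:00", datatype=XSD.dateTime)
            if entry.datatype == XSD.date:
                return Literal("2024-03-01", datatype=XSD.date)
            if entry.datatype == XSD.integer:
                return Literal(41 + j, datatype=XSD.integer)
            if entry.datatype == XSD.double:
                return Literal(62.5 + j, datatype=XSD.double)
            if entry.datatype == XSD.boolean:
                return Literal(True)
            return Literal(f"value-{j + 1}")
        if entry.in_values:
            return entry.in_values[j % len(entry.in_values)]
        if entry.class_targets:
            target = entry.class_targets[0]
            if target in instances:
                return instances[target][inst_idx % len(instances[target])]
            code_counter[0] += 1
            node = URIRef(f"{ns}code-{code_counter[0]}")
            data.add((node, RDF.type, target))
            return node
        return URIRef(f"{ns}context-{_local(cls)}-{j + 1}")

    for cls in shaped:
        entries = cpmap.effective(cls)
        for inst_idx, inst in enumerate(instances[cls]):
            for prop in sorted(entries, key=str):
                entry = entries[prop]
                cap = entry.max_count if entry.max_count is not None else None
                count = entry.min_count or 0
                if count == 0 and (cap is None or cap >= 1):
                    count = 1  # exercise optional paths too
                for j in range(count):
                    data.add(
                        (inst, prop, make_value(cls, inst_idx, prop, entry, j))
                    )

    if mode == "conforming":
        return data
    _seed_data_defect(data, prepared, cpmap, instances, mode, spec, make_value)
    return data


def _seed_data_defect(data, prepared, cpmap, instances, mode, spec, make_value):
    ns = spec.data_namespace
    roots = prepared.roots

    def first_entry(predicate):
        for cls in sorted(instances, key=str):
            for prop, entry in sorted(cpmap.effective(cls).items(), key=lambda kv: str(kv[0])):
                if predicate(entry):
                    return cls, prop, entry
        return None

    if mode == "missing_mandatory":
        found = first_entry(lambda e: (e.min_count or 0) >= 1)
        if not found:
            raise FixtureError("no mandatory property in schema")
        cls, prop, _ = found
        inst = instances[cls][0]
        for obj in list(data.objects(inst, prop)):
            data.remove((inst, prop, obj))
    elif mode == "over_max":
        # pick a property whose surplus values can themselves conform, so the
        # only violation seeded is the cardinality one
        found = first_entry(
            lambda e: e.max_count is not None
            and not e.in_values
            and not (e.class_targets and e.class_targets[0] in instances)
        )
        if not found:
            raise FixtureError("no bounded property in schema")
        cls, prop, entry = found
        inst = instances[cls][0]
        have = len(list(data.objects(inst, prop)))
        for j in range(have, entry.max_count + 1):
            data.add((inst, prop, make_value(cls, 0, prop, entry, j)))
    elif mode == "wrong_class":
        found = first_entry(lambda e: bool(e.class_targets) and not e.in_values)
        if not found:
            raise FixtureError("no class-targeted property in schema")
        cls, prop, _ = found
        inst = instances[cls][0]
        for obj in list(data.objects(inst, prop)):
            data.remove((inst, prop, obj))
        imposter = URIRef(f"{ns}{_local(roots[0])}-99")
        data.add((imposter, RDF.type, roots[0]))
        data.add((inst, prop, imposter))
    elif mode == "unlisted_member":
        if not cpmap.value_set_classes:
            raise FixtureError("schema has no value-set classes")
        vs_cls = sorted(cpmap.value_set_classes, key=str)[0]
        stray = URIRef(f"{ns}{_local(vs_cls)}-unlisted")
        data.add((stray, RDF.type, vs_cls))
    elif mode == "start_gt_end":
        found = None
        for cls in sorted(instances, key=str):
            eff = cpmap.effective(cls)
            starts = [p for p in eff if _local(p) == "hasStartDateTime"]
            ends = [p for p in eff if _local(p) == "hasEndDateTime"]
            if starts and ends:
                found = (cls, starts[0])
                break
        if not found:
            raise FixtureError("no class bears both start and end datetimes")
        cls, start_prop = found
        inst = instances[cls][0]
        for obj in list(data.objects(inst, start_prop)):
            data.remove((inst, start_prop, obj))
        data.add(
            (inst, start_prop, Literal("2030-01-01T00:00:00", datatype=XSD.dateTime))
        )
    elif mode == "bad_iri":
        cls = sorted(instances, key=str)[0]
        inst = instances[cls][0]
        rogue = URIRef(f"{ns}completely-unconventional-name")
        for s, p, o in list(data):
            if s == inst:
                data.remove((s, p, o))
                data.add((rogue, p, o))
            elif o == inst:
                data.remove((s, p, o))
                data.add((s, p, rogue))
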