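"""Compile a dataset model into an OWL/RDFS/SKOS schema graph.

Mapping conventions:

* a concept row becomes an ``owl:Class`` with ``rdfs:label`` (original name)
  and ``skos:definition`` (general description), ``rdfs:subClassOf`` its
  parent (or the auto-generated schema root class);
* a composedOf row becomes an ``owl:ObjectProperty`` (concept or code
  valued) or ``owl:DatatypeProperty`` (primitive valued), with per-class
  ``owl:Restriction`` nodes carrying ``owl:minCardinality`` /
  ``owl:maxCardinality`` / ``owl:someValuesFrom``;
* a meaning binding becomes ``owl:equivalentClass`` to the external code IRI;
* excluded type descendants become ``skos:scopeNote`` annotations (with the
  excluded IRIs spelled out in angle brackets so downstream shape derivation
  can read them back);
* sensitivity becomes a boolean ``subjectToDeIdentification`` annotation on
  the restriction node of the (class, property) pair.
"""

from __future__ import annotations

import re
from typing import Dict, Iterable, List, Optional, Set, Tuple

from rdflib import BNode, Graph, Literal, URIRef
from rdflib.collection import Collection
from rdflib.namespace import DCTERMS, OWL, RDF, RDFS, SKOS, XSD

from .dataset_io import effective_attributes  # noqa: F401  (re-export for callers)
from .model import (
    UNBOUNDED,
    AttributeRow,
    CodingSystemRecord,
    ConceptRow,
    DatasetModel,
    MetadataRecord,
    VALUE_SET_CODES,
    VALUE_SET_DESCENDANT,
    VALUE_SET_LABELS,
)
from .naming import (
    NamingContext,
    mint_class_iri,
    mint_individual_iri,
    mint_property_iri,
    pascal_case,
)

#: fixed grammar of machine-readable exclusion notes (IRIs in angle brackets)
_EXCLUSION_NOTE_PREFIX = "The following type descendants are excluded as values:"
_EXCLUSION_IRI_RE = re.compile(r"<([^<>\s]+)>")

#: the three concept-level context links every concept may be constrained on
CONTEXT_LINKS = (
    ("Administrative Case", "card_admin_case"),
    ("Subject Pseudo Identifier", "card_subject_pseudo_id"),
    ("Source System", "card_source_system"),
)


class SchemaBuildError(Exception):
    pass


class SchemaGraph:
    """An rdflib graph plus the prefix map and naming context that built it."""

    def __init__(self, graph: Graph, ctx: NamingContext, prefix_map: Dict[str, str]):
        self.graph = graph
        self.ctx = ctx
        self.prefix_map = dict(prefix_map)

    @property
    def namespace(self) -> str:
        return self.ctx.namespace

    @property
    def prefix(self) -> str:
        return self.ctx.prefix

    def __len__(self) -> int:
        return len(self.graph)

    def classes(self) -> List[URIRef]:
        return sorted(
            s for s in self.graph.subjects(RDF.type, OWL.Class) if isinstance(s, URIRef)
        )


def naming_context_for(meta: MetadataRecord, **kwargs) -> NamingContext:
    """Derive the naming context from workbook metadata (namespace = canonical IRI + '#')."""
    ns = meta.canonical_iri
    if not ns.endswith(("/", "#")):
        ns = ns + "#"
    return NamingContext(namespace=ns, prefix=meta.prefix, **kwargs)


def _prefix_token(name: str) -> str:
    token = re.sub(r"[^0-9A-Za-z]+", "-", name.strip().lower()).strip("-")
    return token or "ns"


def subject_to_deidentification_iri(ctx: NamingContext) -> URIRef:
    return URIRef(ctx.namespace + "subjectToDeIdentification")


def exclusion_note(iris: Iterable[str]) -> Literal:
    listed = ", ".join(f"<{iri}>" for iri in iris)
    return Literal(f"{_EXCLUSION_NOTE_PREFIX} {listed}")


def parse_exclusion_note(note: str) -> Tuple[str, ...]:
    """Read the excluded IRIs back out of a scope-note literal."""
    if not str(note).startswith(_EXCLUSION_NOTE_PREFIX):
        return ()
    return tuple(_EXCLUSION_IRI_RE.findall(str(note)))


# ---------------------------------------------------------------------------
# Header and classes
# ---------------------------------------------------------------------------

def build_ontology_header(meta: MetadataRecord, ctx: NamingContext) -> List[tuple]:
    """The single ``owl:Ontology`` node carrying the Metadata-tab elements."""
    onto = URIRef(meta.canonical_iri)
    triples = [
        (onto, RDF.type, OWL.Ontology),
        (onto, OWL.versionIRI, URIRef(meta.versioned_iri)),
        (onto, DCTERMS.title, Literal(meta.title)),
        (onto, DCTERMS.description, Literal(meta.description)),
        (onto, OWL.versionInfo, Literal(meta.version)),
        (onto, DCTERMS.rights, Literal(meta.copyright)),
        (onto, DCTERMS.license, Literal(meta.license)),
    ]
    if meta.prior_version:
        prior: object = (
            URIRef(meta.prior_version)
            if meta.prior_version.startswith(("http://", "https://"))
            else Literal(meta.prior_version)
        )
        triples.append((onto, OWL.priorVersion, prior))
    return triples


def build_root_class(ctx: NamingContext) -> List[tuple]:
    root = ctx.root_class_iri()
    return [
        (root, RDF.type, OWL.Class),
        (root, RDFS.label, Literal(ctx.root_class_name)),
        (
            root,
            SKOS.definition,
            Literal("Automatically generated root class of this schema."),
        ),
    ]


def build_concept_class(
    concept: ConceptRow,
    ctx: NamingContext,
    coding: Optional[Dict[str, CodingSystemRecord]] = None,
) -> List[tuple]:
    """Class declaration + label/definition + subclass edge + meaning binding."""
    cls = mint_class_iri(concept.name, ctx)
    parent = (
        mint_class_iri(concept.parent, ctx) if concept.parent else ctx.root_class_iri()
    )
    triples = [
        (cls, RDF.type, OWL.Class),
        (cls, RDFS.label, Literal(concept.name)),
        (cls, SKOS.definition, Literal(concept.general_description or concept.name)),
        (cls, RDFS.subClassOf, parent),
    ]
    if concept.meaning_binding:
        cs_name, code = concept.meaning_binding
        cs = (coding or {}).get(cs_name)
        if cs is None:
            raise SchemaBuildError(
                f"meaning binding of {concept.name!r} names unknown coding system "
                f"{cs_name!r}"
            )
        triples.append((cls, OWL.equivalentClass, URIRef(cs.code_iri(code))))
    if concept.excluded_type_descendants:
        iris = [mint_class_iri(n, ctx) for n in concept.excluded_type_descendants]
        triples.append((cls, SKOS.scopeNote, exclusion_note(iris)))
    return triples


# ---------------------------------------------------------------------------
# Attribute axioms
# ---------------------------------------------------------------------------

def _restriction(cls: URIRef, prop: URIRef, kind: str) -> Tuple[BNode, List[tuple]]:
    # deterministic blank-node label: serialization is byte-stable across runs
    local = lambda iri: str(iri).rstrip("/#").rsplit("#", 1)[-1].rsplit("/", 1)[-1]
    node = BNode(f"restr_{local(cls)}_{local(prop)}_{kind}")
    return node, [
        (cls, RDFS.subClassOf, node),
        (node, RDF.type, OWL.Restriction),
        (node, OWL.onProperty, prop),
    ]


def _enumeration_class(
    graph_triples: List[tuple], cls_iri: URIRef, member_iris: List[URIRef], label: str
) -> None:
    graph_triples.append((cls_iri, RDF.type, OWL.Class))
    graph_triples.append((cls_iri, RDFS.label, Literal(label)))
    graph_triples.append(
        (cls_iri, SKOS.definition, Literal(f"Enumeration of permitted codes for {label}."))
    )
    # owl:oneOf list; the RDF list cells are materialized when added to a graph
    graph_triples.append((cls_iri, OWL.oneOf, tuple(member_iris)))


def build_attribute_axioms(
    attr: AttributeRow,
    owner: ConceptRow,
    ctx: NamingContext,
    coding: Dict[str, CodingSystemRecord],
    declared: Optional[Set[URIRef]] = None,
) -> List[tuple]:
    """Property declaration (once globally) plus per-owner restriction nodes.

    Returns plain triples except that an ``owl:oneOf`` object may be a tuple
    of IRIs, expanded into an RDF collection by :func:`add_triples`.
    """
    prop = mint_property_iri(attr.name, ctx)
    owner_cls = mint_class_iri(owner.name, ctx)
    vt = attr.value_type.strip()
    vt_lower = vt.lower()
    triples: List[tuple] = []

    if vt_lower in ctx.datatype_map and not (
        attr.value_set is not None and attr.value_set.kind == VALUE_SET_LABELS
    ):
        prop_kind, target = "datatype", ctx.datatype_map[vt_lower]
    elif vt_lower in ("code", "qualitative"):
        prop_kind, target = "object", None  # resolved below via standard / value set
    else:
        prop_kind, target = "object", mint_class_iri(vt, ctx)

    if declared is None or prop not in declared:
        triples += [
            (
                prop,
                RDF.type,
                OWL.DatatypeProperty if prop_kind == "datatype" else OWL.ObjectProperty,
            ),
            (prop, RDFS.label, Literal(attr.name)),
            (prop, SKOS.definition, Literal(attr.general_description or attr.name)),
        ]
        if declared is not None:
            declared.add(prop)

    lo, hi = attr.cardinality
    restriction_nodes: List[BNode] = []
    if lo > 0:
        node, t = _restriction(owner_cls, prop, "min")
        t.append((node, OWL.minCardinality, Literal(lo, datatype=XSD.nonNegativeInteger)))
        triples += t
        restriction_nodes.append(node)
    if not isinstance(hi, type(UNBOUNDED)):
        node, t = _restriction(owner_cls, prop, "max")
        t.append((node, OWL.maxCardinality, Literal(hi, datatype=XSD.nonNegativeInteger)))
        triples += t
        restriction_nodes.append(node)

    # value restriction (owl:someValuesFrom)
    some_target: Optional[URIRef] = None
    cs = coding.get(attr.standard) if attr.standard else None
    if attr.value_set is not None:
        vs = attr.value_set
        if vs.kind == VALUE_SET_DESCENDANT:
            if cs is None:
                raise SchemaBuildError(
                    f"'descendant of' value set on {owner.name}.{attr.name} "
                    "requires a declared standard"
                )
            some_target = URIRef(cs.code_iri(vs.values[0]))
        elif vs.kind == VALUE_SET_CODES:
            if cs is None:
                raise SchemaBuildError(
                    f"enumerated codes on {owner.name}.{attr.name} require a "
                    "declared standard"
                )
            enum_cls = URIRef(
                ctx.namespace + pascal_case(owner.name) + pascal_case(attr.name) + "CodeSet"
            )
            _enumeration_class(
                triples,
                enum_cls,
                [URIRef(cs.code_iri(c)) for c in vs.values],
                f"{owner.name} {attr.name} codes",
            )
            some_target = enum_cls
        else:  # qualitative labels -> generated value-set class with individuals
            vs_cls = URIRef(
                ctx.namespace + pascal_case(owner.name) + pascal_case(attr.name) + "ValueSet"
            )
            triples += [
                (vs_cls, RDF.type, OWL.Class),
                (vs_cls, RDFS.label, Literal(f"{owner.name} {attr.name} value set")),
                (
                    vs_cls,
                    SKOS.definition,
                    Literal(f"Permitted values for {owner.name} {attr.name}."),
                ),
            ]
            for label in vs.values:
                ind = mint_individual_iri(label, ctx.namespace)
                triples += [
                    (ind, RDF.type, OWL.NamedIndividual),
                    (ind, RDF.type, vs_cls),
                    (ind, RDFS.label, Literal(label)),
                ]
            some_target = vs_cls
    elif cs is not None:
        if not cs.root_node:
            raise SchemaBuildError(
                f"CODING_SYSTEM_NOT_LINKABLE: coding system {cs.name!r} used by "
                f"{owner.name}.{attr.name} has no root node"
                + ("" if cs.rdf_available else " and is not available in RDF")
            )
        some_target = URIRef(cs.root_node)
    elif prop_kind == "datatype":
        some_target = target
    elif target is not None:
        some_target = target

    if some_target is not None:
        node, t = _restriction(owner_cls, prop, "some")
        t.append((node, OWL.someValuesFrom, some_target))
        triples += t
        restriction_nodes.append(node)

    if attr.excluded_type_descendants:
        if cs is not None:
            iris = [URIRef(cs.code_iri(c)) for c in attr.excluded_type_descendants]
        else:
            iris = [mint_class_iri(n, ctx) for n in attr.excluded_type_descendants]
        anchor = restriction_nodes[-1] if restriction_nodes else owner_cls
        triples.append((anchor, SKOS.scopeNote, exclusion_note(iris)))

    if attr.sensitive:
        anchor = restriction_nodes[0] if restriction_nodes else prop
        triples.append(
            (anchor, subject_to_deidentification_iri(ctx), Literal(True))
        )
    return triples


def _context_link_axioms(
    concept: ConceptRow, ctx: NamingContext, known: Set[str], declared: Set[URIRef]
) -> List[tuple]:
    """Concept-level cardinalities to Administrative Case / Subject Pseudo
    Identifier / Source System, routed through hasX object properties."""
    triples: List[tuple] = []
    cls = mint_class_iri(concept.name, ctx)
    for link_name, field_name in CONTEXT_LINKS:
        card = getattr(concept, field_name)
        if card is None:
            continue
        prop = mint_property_iri(link_name, ctx)
        if prop not in declared:
            triples += [
                (prop, RDF.type, OWL.ObjectProperty),
                (prop, RDFS.label, Literal(link_name.lower())),
                (
                    prop,
                    SKOS.definition,
                    Literal(f"Links a concept instance to its {link_name}."),
                ),
            ]
            declared.add(prop)
        lo, hi = card
        if lo > 0:
            node, t = _restriction(cls, prop, "min")
            t.append(
                (node, OWL.minCardinality, Literal(lo, datatype=XSD.nonNegativeInteger))
            )
            triples += t
        if not isinstance(hi, type(UNBOUNDED)):
            node, t = _restriction(cls, prop, "max")
            t.append(
                (node, OWL.maxCardinality, Literal(hi, datatype=XSD.nonNegativeInteger))
            )
            triples += t
        if link_name in known:
            node, t = _restriction(cls, prop, "some")
            t.append((node, OWL.someValuesFrom, mint_class_iri(link_name, ctx)))
            triples += t
    return triples


# ---------------------------------------------------------------------------
# Whole-schema assembly
# ---------------------------------------------------------------------------

def add_triples(graph: Graph, triples: Iterable[tuple]) -> None:
    """Add triples, expanding tuple-valued objects into RDF collections."""
    for s, p, o in triples:
        if isinstance(o, tuple):
            head = BNode()
            Collection(graph, head, list(o))
            graph.add((s, p, head))
        else:
            graph.add((s, p, o))


def build_schema(model: DatasetModel, ctx: Optional[NamingContext] = None) -> SchemaGraph:
    """Compile the full schema graph: header, root class, concept classes,
    attribute axioms, value-set classes and concept-level context links.

    The model is expected to be validation-clean (``validate_dataset`` empty);
    structural defects that slip through raise :class:`SchemaBuildError`.
    Compilation is deterministic: the same model yields an isomorphic graph.
    """
    if ctx is None:
        ctx = naming_context_for(model.metadata)
    graph = Graph()
    prefix_map = {
        ctx.prefix: ctx.namespace,
        "rdf": str(RDF),
        "rdfs": str(RDFS),
        "owl": str(OWL),
        "skos": str(SKOS),
        "xsd": str(XSD),
        "dcterms": str(DCTERMS),
    }
    coding = {cs.name: cs for cs in model.coding_systems}
    for cs in model.coding_systems:
        if cs.rdf_available and cs.namespace:
            prefix_map.setdefault(_prefix_token(cs.name), cs.namespace)
    for prefix, ns in prefix_map.items():
        graph.bind(prefix, ns, override=True, replace=True)

    add_triples(graph, build_ontology_header(model.metadata, ctx))
    add_triples(graph, build_root_class(ctx))

    declared: Set[URIRef] = set()
    known = {c.name for c in model.active_concepts()}
    for concept in model.active_concepts():
        add_triples(graph, build_concept_class(concept, ctx, coding))
        add_triples(graph, _context_link_axioms(concept, ctx, known, declared))
        for attr in concept.active_attributes():
            if attr.row_kind != "composedOf":
                # plain inherited rows rely on the parent's restriction via
                # subclassing; overrides are composedOf rows and land here
                continue
            add_triples(
                graph, build_attribute_axioms(attr, concept, ctx, coding, declared)
            )

    # a global rdfs:domain where a property has exactly one owning class
    owners: Dict[URIRef, Set[URIRef]] = {}
    for restriction in graph.subjects(RDF.type, OWL.Restriction):
        prop = graph.value(restriction, OWL.onProperty)
        for cls in graph.subjects(RDFS.subClassOf, restriction):
            owners.setdefault(prop, set()).add(cls)
    for prop, classes in owners.items():
        if len(classes) == 1:
            graph.add((prop, RDFS.domain, next(iter(classes))))

    return SchemaGraph(graph, ctx, prefix_map)


def serialize_turtle(schema: SchemaGraph, path=None) -> str:
    """Serialize to Turtle; byte-stable across runs on identical input."""
    text = schema.graph.serialize(format="turtle")
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text
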