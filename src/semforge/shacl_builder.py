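"""Derive SHACL validation shapes from a compiled schema graph.

The derivation follows six steps: extract root classes and prefixes, merge
the base and project schema graphs, produce the shape-file metadata
(creation date, conformance, license, RDFS entailment), load every class's
property restrictions and expand them through the subclass hierarchy, emit
one ``sh:NodeShape`` per non-value-set class below a root, and emit one
reverse instance-listing shape per value-set class.

The shapes operate under a closed-world reading of the schema: validation
is meant to run with RDFS entailment, so a restriction may reference a
terminology root class only — descendants need no expansion.  ``sh:closed``
is false when validating against the base schema alone and true when a
project extension is merged in.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from rdflib import BNode, Graph, Literal, URIRef
from rdflib.collection import Collection
from rdflib.namespace import DCTERMS, OWL, RDF, RDFS, SH, SKOS, XSD

from .model import CodingSystemRecord
from .schema_builder import SchemaGraph, parse_exclusion_note

ENTAILMENT_RDFS = URIRef("http://www.w3.org/ns/entailment/RDFS")
SHACL_SPEC = URIRef("https://www.w3.org/TR/shacl/")

#: SHACL severity IRIs; the schema-compliance default is sh:Violation
SEV_VIOLATION = SH.Violation
SEV_WARNING = SH.Warning
SEV_INFO = SH.Info


class ShapeDerivationError(Exception):
    pass


def _local(iri: URIRef) -> str:
    text = str(iri).rstrip("/#")
    return text.rsplit("#", 1)[-1].rsplit("/", 1)[-1]


# ---------------------------------------------------------------------------
# Step 1-3: prepare
# ---------------------------------------------------------------------------

@dataclass
class PreparedSchema:
    graph: Graph
    roots: List[URIRef]
    prefixes: Dict[str, str]
    metadata: Dict[str, object]
    closed_mode: bool
    namespaces: Tuple[str, ...]  # schema namespaces (base first, then project)


def prepare(
    schema: SchemaGraph,
    project: Optional[SchemaGraph] = None,
    closed: Optional[bool] = None,
    today: Optional[datetime.date] = None,
) -> PreparedSchema:
    """Merge graphs, find root classes, assemble shape-file metadata.

    ``closed`` defaults to False for base-only validation and True when a
    project schema is merged.  A project graph that re-parents a base-namespace
    class inconsistently is rejected.
    """
    merged = Graph()
    for t in schema.graph:
        merged.add(t)
    namespaces: Tuple[str, ...] = (schema.namespace,)
    if project is not None:
        for cls in project.graph.subjects(RDF.type, OWL.Class):
            if isinstance(cls, URIRef) and str(cls).startswith(schema.namespace):
                base_parents = {
                    o
                    for o in schema.graph.objects(cls, RDFS.subClassOf)
                    if isinstance(o, URIRef)
                }
                proj_parents = {
                    o
                    for o in project.graph.objects(cls, RDFS.subClassOf)
                    if isinstance(o, URIRef)
                }
                if base_parents and proj_parents and not proj_parents <= base_parents:
                    raise ShapeDerivationError(
                        f"project schema re-parents base class {cls} "
                        f"({sorted(proj_parents)} vs {sorted(base_parents)})"
                    )
        for t in project.graph:
            merged.add(t)
        namespaces = (schema.namespace, project.namespace)

    classes = {
        s
        for s in merged.subjects(RDF.type, OWL.Class)
        if isinstance(s, URIRef) and str(s).startswith(namespaces)
    }
    roots = sorted(
        c
        for c in classes
        if not any(
            isinstance(p, URIRef) and p in classes
            for p in merged.objects(c, RDFS.subClassOf)
        )
    )
    prefixes = dict(schema.prefix_map)
    if project is not None:
        for pfx, ns in project.prefix_map.items():
            prefixes.setdefault(pfx, ns)

    license_lit = None
    for onto in merged.subjects(RDF.type, OWL.Ontology):
        license_lit = merged.value(onto, DCTERMS.license) or license_lit
    metadata = {
        "created": today or datetime.date.today(),
        "conforms_to": SHACL_SPEC,
        "license": license_lit,
        "entailment": ENTAILMENT_RDFS,
    }
    return PreparedSchema(
        graph=merged,
        roots=roots,
        prefixes=prefixes,
        metadata=metadata,
        closed_mode=bool(project is not None if closed is None else closed),
        namespaces=namespaces,
    )


# ---------------------------------------------------------------------------
# Step 4: class/property map with subclass expansion
# ---------------------------------------------------------------------------

@dataclass
class PropertyEntry:
    """Effective constraints for one (class, property) combination."""

    prop: URIRef
    path: Tuple[URIRef, ...] = ()  # length > 1 encodes a sequence path
    min_count: Optional[int] = None
    max_count: Optional[int] = None
    class_targets: List[URIRef] = field(default_factory=list)
    datatype: Optional[URIRef] = None
    in_values: Optional[List[URIRef]] = None
    excluded: Tuple[URIRef, ...] = ()
    sensitive: bool = False
    source_class: Optional[URIRef] = None

    def merged_with(self, other: "PropertyEntry", cls: URIRef) -> "PropertyEntry":
        """Combine two direct declarations on the same class; contradictory
        cardinalities raise, naming both sources."""
        for attr_name in ("min_count", "max_count"):
            a, b = getattr(self, attr_name), getattr(other, attr_name)
            if a is not None and b is not None and a != b:
                raise ShapeDerivationError(
                    f"contradictory {attr_name} for {cls} / {self.prop}: "
                    f"{a} (from {self.source_class}) vs {b} (from {other.source_class})"
                )
        out = PropertyEntry(
            prop=self.prop,
            path=self.path or other.path,
            min_count=self.min_count if self.min_count is not None else other.min_count,
            max_count=self.max_count if self.max_count is not None else other.max_count,
            class_targets=sorted(set(self.class_targets) | set(other.class_targets)),
            datatype=self.datatype or other.datatype,
            in_values=self.in_values or other.in_values,
            excluded=tuple(sorted(set(self.excluded) | set(other.excluded))),
            sensitive=self.sensitive or other.sensitive,
            source_class=self.source_class,
        )
        return out


@dataclass
class ClassPropertyMap:
    entries: Dict[URIRef, Dict[URIRef, PropertyEntry]]
    value_set_classes: Dict[URIRef, List[URIRef]]  # class -> sorted instances
    parents: Dict[URIRef, Set[URIRef]]

    def ancestors(self, cls: URIRef) -> List[URIRef]:
        """All (transitive) superclasses, nearest first, breadth-first."""
        out: List[URIRef] = []
        frontier = [cls]
        seen = {cls}
        while frontier:
            nxt: List[URIRef] = []
            for c in frontier:
                for p in sorted(self.parents.get(c, ())):
                    if p not in seen:
                        seen.add(p)
                        out.append(p)
                        nxt.append(p)
            frontier = nxt
        return out

    def effective(self, cls: URIRef) -> Dict[URIRef, PropertyEntry]:
        """Own declarations plus inherited ones; own (or nearer) shadow farther."""
        result: Dict[URIRef, PropertyEntry] = dict(self.entries.get(cls, {}))
        for ancestor in self.ancestors(cls):
            for prop, entry in self.entries.get(ancestor, {}).items():
                if prop not in result:
                    result[prop] = entry
        return result


def _instances_of(graph: Graph, cls: URIRef) -> List[URIRef]:
    return sorted(
        s
        for s in graph.subjects(RDF.type, cls)
        if isinstance(s, URIRef) and (s, RDF.type, OWL.Class) not in graph
    )


def collect_class_property_map(prepared: PreparedSchema) -> ClassPropertyMap:
    """Load restrictions for every class and expand through subclass edges.

    A class's own restriction on a property shadows any ancestor restriction
    on the same property (override wins).  Classes possessing instances are
    marked as value-set classes; a ``someValuesFrom`` target carrying an
    ``owl:oneOf`` enumeration or holding instances is folded into an
    ``in_values`` listing.
    """
    graph = prepared.graph
    in_ns = lambda iri: isinstance(iri, URIRef) and str(iri).startswith(
        prepared.namespaces
    )

    classes = [
        s
        for s in graph.subjects(RDF.type, OWL.Class)
        if isinstance(s, URIRef) and in_ns(s)
    ]
    parents: Dict[URIRef, Set[URIRef]] = {}
    for cls in classes:
        parents[cls] = {
            o for o in graph.objects(cls, RDFS.subClassOf) if isinstance(o, URIRef)
        }

    value_sets: Dict[URIRef, List[URIRef]] = {}
    for cls in classes:
        inst = _instances_of(graph, cls)
        if inst:
            value_sets[cls] = inst

    entries: Dict[URIRef, Dict[URIRef, PropertyEntry]] = {c: {} for c in classes}
    for cls in sorted(classes):
        for restriction in sorted(graph.objects(cls, RDFS.subClassOf)):
            if not isinstance(restriction, BNode):
                continue
            if (restriction, RDF.type, OWL.Restriction) not in graph:
                continue
            prop = graph.value(restriction, OWL.onProperty)
            if prop is None:
                continue
            entry = PropertyEntry(prop=prop, path=(prop,), source_class=cls)
            min_lit = graph.value(restriction, OWL.minCardinality)
            max_lit = graph.value(restriction, OWL.maxCardinality)
            if min_lit is not None:
                entry.min_count = int(min_lit)
            if max_lit is not None:
                entry.max_count = int(max_lit)
            target = graph.value(restriction, OWL.someValuesFrom)
            if target is not None:
                one_of = graph.value(target, OWL.oneOf)
                if one_of is not None:
                    entry.in_values = list(Collection(graph, one_of))
                elif target in value_sets:
                    entry.in_values = list(value_sets[target])
                elif isinstance(target, URIRef) and str(target).startswith(str(XSD)):
                    entry.datatype = target
                else:
                    entry.class_targets = [target]
            for note in graph.objects(restriction, SKOS.scopeNote):
                excluded = parse_exclusion_note(str(note))
                if excluded:
                    entry.excluded = tuple(
                        sorted(set(entry.excluded) | {URIRef(e) for e in excluded})
                    )
            sens = [
                o
                for p, o in graph.predicate_objects(restriction)
                if str(p).endswith("subjectToDeIdentification")
            ]
            if sens and any(bool(o.toPython()) for o in sens if isinstance(o, Literal)):
                entry.sensitive = True
            if prop in entries[cls]:
                entries[cls][prop] = entries[cls][prop].merged_with(entry, cls)
            else:
                entries[cls][prop] = entry

    return ClassPropertyMap(entries=entries, value_set_classes=value_sets, parents=parents)


# ---------------------------------------------------------------------------
# Steps 5-6: shape emission
# ---------------------------------------------------------------------------

def _shape_iri(cls: URIRef) -> URIRef:
    return URIRef(str(cls) + "Shape")


def _add_list(graph: Graph, members: Sequence) -> BNode:
    head = BNode()
    Collection(graph, head, list(members))
    return head


def _sparql_constraint(
    graph: Graph,
    shape: URIRef,
    select: str,
    message: str,
    severity: URIRef,
    prefixes: Dict[str, str],
) -> BNode:
    node = BNode()
    graph.add((shape, SH.sparql, node))
    graph.add((node, RDF.type, SH.SPARQLConstraint))
    graph.add((node, SH.message, Literal(message)))
    graph.add((node, SH.severity, severity))
    graph.add((node, SH.select, Literal(select)))
    return node


def build_node_shape(
    graph: Graph,
    cls: URIRef,
    entry_map: Dict[URIRef, PropertyEntry],
    closed_mode: bool,
    prefixes: Dict[str, str],
    sparql_target: bool = False,
) -> URIRef:
    """Emit the NodeShape for one class into *graph* and return its IRI."""
    shape = _shape_iri(cls)
    graph.add((shape, RDF.type, SH.NodeShape))
    graph.add((shape, SH.targetClass, cls))
    if sparql_target:
        # parent and child carry different rules; target exactly the class's
        # own (direct) instances via an explicit SPARQL target
        tnode = BNode()
        graph.add((shape, SH.target, tnode))
        graph.add((tnode, RDF.type, SH.SPARQLTarget))
        graph.add(
            (
                tnode,
                SH.select,
                Literal(f"SELECT ?this WHERE {{ ?this a <{cls}> . }}"),
            )
        )
    graph.add((shape, SH.closed, Literal(closed_mode)))
    graph.add((shape, SH.ignoredProperties, _add_list(graph, [RDF.type])))

    for prop in sorted(entry_map):
        entry = entry_map[prop]
        if not any(
            (
                entry.class_targets,
                entry.datatype,
                entry.in_values,
                entry.min_count,
                entry.max_count is not None,
            )
        ):
            raise ShapeDerivationError(
                f"property {prop} on {cls} has neither a class/datatype target "
                "nor any cardinality bound"
            )
        pshape = BNode()
        graph.add((shape, SH.property, pshape))
        if len(entry.path) > 1:
            graph.add((pshape, SH.path, _add_list(graph, list(entry.path))))
        else:
            graph.add((pshape, SH.path, prop))
        if entry.min_count is not None and entry.min_count > 0:
            graph.add((pshape, SH.minCount, Literal(entry.min_count)))
        if entry.max_count is not None:
            graph.add((pshape, SH.maxCount, Literal(entry.max_count)))
        if entry.in_values is not None:
            graph.add((pshape, SH["in"], _add_list(graph, sorted(entry.in_values))))
        elif len(entry.class_targets) == 1:
            graph.add((pshape, SH["class"], entry.class_targets[0]))
        elif len(entry.class_targets) > 1:
            alts = []
            for target in sorted(entry.class_targets):
                alt = BNode()
                graph.add((alt, SH["class"], target))
                alts.append(alt)
            graph.add((pshape, SH["or"], _add_list(graph, alts)))
        if entry.datatype is not None:
            graph.add((pshape, SH.datatype, entry.datatype))

        if entry.excluded:
            union = " UNION ".join(
                f"{{ ?value a/rdfs:subClassOf* <{ex}> . }}" for ex in entry.excluded
            )
            select = (
                "PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>\n"
                f"SELECT $this ?value WHERE {{ $this <{prop}> ?value . {union} }}"
            )
            _sparql_constraint(
                graph,
                shape,
                select,
                f"Value of {_local(prop)} falls under an excluded type descendant.",
                SEV_VIOLATION,
                prefixes,
            )
    return shape


def build_value_set_shape(
    graph: Graph, cls: URIRef, instances: Sequence[URIRef]
) -> URIRef:
    """Reverse instance listing: members of a value-set class must be one of
    the schema-declared individuals."""
    shape = _shape_iri(cls)
    graph.add((shape, RDF.type, SH.NodeShape))
    graph.add((shape, SH.targetClass, cls))
    graph.add((shape, SH["in"], _add_list(graph, sorted(instances))))
    return shape


def build_special_rules(
    graph: Graph,
    prepared: PreparedSchema,
    cpmap: ClassPropertyMap,
    shaped_classes: Sequence[URIRef],
    coding_systems: Sequence[CodingSystemRecord] = (),
    iri_convention: str = "{local}-",
) -> None:
    """Attach the cross-cutting rules.

    (a) start/end datetime ordering at Error severity on every class bearing
        both properties; (b) an instance-IRI naming-convention check at
        Warning severity on every shaped class; (c) code-validity rules from
        terminology version metadata: Info severity when the meaning change
        is derivable (still-valid and no-longer-valid codes alike), Warning
        when it is not.
    """
    for cls in shaped_classes:
        shape = _shape_iri(cls)
        eff = cpmap.effective(cls)
        start = [p for p in eff if _local(p) == "hasStartDateTime"]
        end = [p for p in eff if _local(p) == "hasEndDateTime"]
        if start and end:
            select = (
                "SELECT $this WHERE { "
                f"$this <{start[0]}> ?start ; <{end[0]}> ?end . "
                "FILTER(?start > ?end) }"
            )
            _sparql_constraint(
                graph,
                shape,
                select,
                "hasStartDateTime must occur before or equal hasEndDateTime.",
                SEV_VIOLATION,
                prepared.prefixes,
            )
        pattern = iri_convention.format(local=_local(cls))
        select = (
            "SELECT $this WHERE { "
            'BIND(REPLACE(STR($this), "^.*[/#]", "") AS ?localname) '
            f'FILTER(!STRSTARTS(?localname, "{pattern}")) }}'
        )
        _sparql_constraint(
            graph,
            shape,
            select,
            f"Instance IRI does not follow the naming convention "
            f"'{pattern}<identifier>'.",
            SEV_WARNING,
            prepared.prefixes,
        )

    for cs in sorted(coding_systems, key=lambda c: c.name):
        for cv in cs.code_validity:
            if not cv.meaning_changed:
                continue
            code_iri = URIRef(cs.code_iri(cv.code))
            shape = URIRef(str(code_iri) + "Shape")
            graph.add((shape, RDF.type, SH.NodeShape))
            graph.add((shape, SH.targetClass, code_iri))
            if cv.meaning_derivable:
                severity = SEV_INFO
                status = (
                    "still valid in the current release"
                    if cv.valid_to is None
                    else f"no longer valid since {cv.valid_to}"
                )
                message = (
                    f"Code {cv.code} of {cs.name} changed meaning; the exact "
                    f"meaning is derivable from version metadata ({status})."
                )
            else:
                severity = SEV_WARNING
                message = (
                    f"Code {cv.code} of {cs.name} changed meaning and the exact "
                    "meaning cannot be derived for this version."
                )
            select = "SELECT $this WHERE { $this a ?type . }"
            _sparql_constraint(graph, shape, select, message, severity, prepared.prefixes)


# ---------------------------------------------------------------------------
# Whole shape-set assembly
# ---------------------------------------------------------------------------

class ShapeSet:
    """The derived shapes graph plus its creation metadata."""

    def __init__(self, graph: Graph, closed_mode: bool, metadata: Dict[str, object]):
        self.graph = graph
        self.closed_mode = closed_mode
        self.metadata = metadata

    def serialize(self, path=None) -> str:
        text = self.graph.serialize(format="turtle")
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    def node_shapes(self) -> List[URIRef]:
        return sorted(
            s
            for s in self.graph.subjects(RDF.type, SH.NodeShape)
            if isinstance(s, URIRef)
        )


def build_shapes(
    schema: SchemaGraph,
    project: Optional[SchemaGraph] = None,
    coding_systems: Sequence[CodingSystemRecord] = (),
    closed: Optional[bool] = None,
    today: Optional[datetime.date] = None,
    iri_convention: str = "{local}-",
) -> ShapeSet:
    """Run the full six-step derivation and return the shape set."""
    prepared = prepare(schema, project, closed=closed, today=today)
    cpmap = collect_class_property_map(prepared)

    graph = Graph()
    for pfx, ns in sorted(prepared.prefixes.items()):
        graph.bind(pfx, ns, override=True, replace=True)
    graph.bind("sh", SH, override=True, replace=True)

    shapes_iri = URIRef(schema.namespace.rstrip("/#") + "/shapes")
    graph.add((shapes_iri, RDF.type, OWL.Ontology))
    graph.add(
        (
            shapes_iri,
            DCTERMS.created,
            Literal(prepared.metadata["created"].isoformat(), datatype=XSD.date),
        )
    )
    graph.add((shapes_iri, DCTERMS.conformsTo, prepared.metadata["conforms_to"]))
    if prepared.metadata["license"] is not None:
        graph.add((shapes_iri, DCTERMS.license, prepared.metadata["license"]))
    graph.add((shapes_iri, SH.entailment, prepared.metadata["entailment"]))

    # classes below the roots, without instances, get node shapes
    shaped: List[URIRef] = []
    for cls in sorted(cpmap.entries):
        if cls in cpmap.value_set_classes:
            continue
        if (cls, OWL.oneOf, None) in prepared.graph:
            continue
        eff = cpmap.effective(cls)
        own = cpmap.entries.get(cls, {})
        differs = any(
            prop in own
            and any(
                prop in cpmap.entries.get(anc, {})
                and cpmap.entries[anc][prop] != own[prop]
                for anc in cpmap.ancestors(cls)
            )
            for prop in own
        )
        build_node_shape(
            graph,
            cls,
            eff,
            prepared.closed_mode,
            prepared.prefixes,
            sparql_target=differs,
        )
        shaped.append(cls)

    for cls in sorted(cpmap.value_set_classes):
        if cpmap.entries.get(cls):
            raise ShapeDerivationError(
                f"value-set class {cls} has outgoing property restrictions"
            )
        build_value_set_shape(graph, cls, cpmap.value_set_classes[cls])

    build_special_rules(
        graph,
        prepared,
        cpmap,
        shaped,
        coding_systems=coding_systems,
        iri_convention=iri_convention,
    )
    return ShapeSet(graph, prepared.closed_mode, prepared.metadata)
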