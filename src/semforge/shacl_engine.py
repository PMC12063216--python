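"""Execute SHACL shapes against RDF instance data.

This is a focused validator for exactly the constraint vocabulary the shape
generator emits: ``sh:minCount`` / ``sh:maxCount``, ``sh:class`` (and
``sh:or`` over class alternatives), ``sh:datatype``, ``sh:in`` (node- and
property-level), ``sh:closed`` with ``sh:ignoredProperties``, sequence
paths, ``sh:SPARQLTarget`` and ``sh:SPARQLConstraint`` with per-constraint
severities.  Validation runs under RDFS entailment: the schema graph is
unioned with the data and subclass edges are honored when checking class
membership, so a shape may reference a terminology root class and accept
instances of any descendant.  ``sh:targetClass`` matches direct instances
(the shape of each class carries its own effective rule set; subclass
instances are matched by their own shape).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from rdflib import BNode, Graph, Literal, URIRef, Variable
from rdflib.collection import Collection
from rdflib.namespace import RDF, RDFS, SH, XSD
from rdflib.plugins.sparql import prepareQuery

SEV_VIOLATION = SH.Violation
SEV_WARNING = SH.Warning
SEV_INFO = SH.Info


@dataclass(frozen=True)
class ValidationResult:
    focus: object
    component: URIRef
    severity: URIRef
    message: str
    source_shape: object
    path: Optional[object] = None
    value: Optional[object] = None


@dataclass
class ValidationReport:
    results: List[ValidationResult] = field(default_factory=list)

    @property
    def conforms(self) -> bool:
        return not self.results

    def by_severity(self, severity: URIRef) -> List[ValidationResult]:
        return [r for r in self.results if r.severity == severity]

    def by_component(self, component: URIRef) -> List[ValidationResult]:
        return [r for r in self.results if r.component == component]

    def __len__(self) -> int:
        return len(self.results)

    def text(self) -> str:
        lines = [f"Conforms: {self.conforms}"]
        for r in self.results:
            lines.append(
                f"  [{str(r.severity).rsplit('#', 1)[-1]}] focus={r.focus} "
                f"path={r.path} value={r.value}: {r.message}"
            )
        return "\n".join(lines)


def _list_members(graph: Graph, head) -> List:
    if head is None:
        return []
    return list(Collection(graph, head))


class _ShapeRunner:
    def __init__(self, data: Graph, shapes: Graph, ont: Optional[Graph] = None):
        self.data = data
        self.shapes = shapes
        self.union = Graph()
        for t in data:
            self.union.add(t)
        if ont is not None:
            for t in ont:
                self.union.add(t)
        self._super_cache: Dict[URIRef, Set[URIRef]] = {}
        self.report = ValidationReport()

    # -- RDFS entailment helpers -------------------------------------------

    def _superclasses(self, cls: URIRef) -> Set[URIRef]:
        if cls in self._super_cache:
            return self._super_cache[cls]
        out: Set[URIRef] = {cls}
        frontier = [cls]
        while frontier:
            nxt = []
            for c in frontier:
                for p in self.union.objects(c, RDFS.subClassOf):
                    if isinstance(p, URIRef) and p not in out:
                        out.add(p)
                        nxt.append(p)
            frontier = nxt
        self._super_cache[cls] = out
        return out

    def _value_is_instance_of(self, value, target: URIRef) -> bool:
        if isinstance(value, Literal):
            return False
        for t in self.union.objects(value, RDF.type):
            if isinstance(t, URIRef) and target in self._superclasses(t):
                return True
        return False

    # -- target selection ---------------------------------------------------

    def _targets(self, shape) -> List:
        for tnode in self.shapes.objects(shape, SH.target):
            if (tnode, RDF.type, SH.SPARQLTarget) in self.shapes:
                select = self.shapes.value(tnode, SH.select)
                rows = self.union.query(str(select))
                return sorted({row[0] for row in rows}, key=str)
        focus: Set = set()
        for cls in self.shapes.objects(shape, SH.targetClass):
            # direct instances only: each class's shape carries its own
            # effective rules (subclasses have their own shapes)
            for inst in self.data.subjects(RDF.type, cls):
                focus.add(inst)
        return sorted(focus, key=str)

    # -- value retrieval ----------------------------------------------------

    def _path_values(self, focus, path) -> List:
        if isinstance(path, (URIRef,)):
            return list(self.data.objects(focus, path))
        # sequence path: RDF list of predicates
        steps = _list_members(self.shapes, path)
        nodes = [focus]
        for step in steps:
            nodes = [o for n in nodes for o in self.data.objects(n, step)]
        return nodes

    # -- constraint checks --------------------------------------------------

    def _emit(self, **kwargs) -> None:
        self.report.results.append(ValidationResult(**kwargs))

    def _check_property_shape(self, shape, pshape, focus, default_sev) -> None:
        path = self.shapes.value(pshape, SH.path)
        severity = self.shapes.value(pshape, SH.severity) or default_sev
        values = self._path_values(focus, path)
        path_repr = (
            tuple(_list_members(self.shapes, path))
            if isinstance(path, BNode)
            else path
        )

        min_count = self.shapes.value(pshape, SH.minCount)
        if min_count is not None and len(values) < int(min_count):
            self._emit(
                focus=focus,
                component=SH.MinCountConstraintComponent,
                severity=severity,
                message=f"fewer than {int(min_count)} values on path",
                source_shape=shape,
                path=path_repr,
            )
        max_count = self.shapes.value(pshape, SH.maxCount)
        if max_count is not None and len(values) > int(max_count):
            self._emit(
                focus=focus,
                component=SH.MaxCountConstraintComponent,
                severity=severity,
                message=f"more than {int(max_count)} values on path",
                source_shape=shape,
                path=path_repr,
            )

        cls_target = self.shapes.value(pshape, SH["class"])
        if cls_target is not None:
            for v in values:
                if not self._value_is_instance_of(v, cls_target):
                    self._emit(
                        focus=focus,
                        component=SH.ClassConstraintComponent,
                        severity=severity,
                        message=f"value is not an instance of {cls_target}",
                        source_shape=shape,
                        path=path_repr,
                        value=v,
                    )
        or_head = self.shapes.value(pshape, SH["or"])
        if or_head is not None:
            alt_classes = [
                self.shapes.value(alt, SH["class"])
                for alt in _list_members(self.shapes, or_head)
            ]
            for v in values:
                if not any(
                    c is not None and self._value_is_instance_of(v, c)
                    for c in alt_classes
                ):
                    self._emit(
                        focus=focus,
                        component=SH.OrConstraintComponent,
                        severity=severity,
                        message="value matches none of the permitted classes",
                        source_shape=shape,
                        path=path_repr,
                        value=v,
                    )

        datatype = self.shapes.value(pshape, SH.datatype)
        if datatype is not None:
            for v in values:
                vdt = (
                    (v.datatype or XSD.string)
                    if isinstance(v, Literal)
                    else None
                )
                if vdt != datatype:
                    self._emit(
                        focus=focus,
                        component=SH.DatatypeConstraintComponent,
                        severity=severity,
                        message=f"value is not a literal of datatype {datatype}",
                        source_shape=shape,
                        path=path_repr,
                        value=v,
                    )

        in_head = self.shapes.value(pshape, SH["in"])
        if in_head is not None:
            permitted = set(_list_members(self.shapes, in_head))
            for v in values:
                if v not in permitted:
                    self._emit(
                        focus=focus,
                        component=SH.InConstraintComponent,
                        severity=severity,
                        message="value is not in the permitted list",
                        source_shape=shape,
                        path=path_repr,
                        value=v,
                    )

    def _check_closed(self, shape, focus, default_sev) -> None:
        closed = self.shapes.value(shape, SH.closed)
        if closed is None or not bool(closed.toPython()):
            return
        allowed: Set[URIRef] = set(
            _list_members(self.shapes, self.shapes.value(shape, SH.ignoredProperties))
        )
        for pshape in self.shapes.objects(shape, SH.property):
            path = self.shapes.value(pshape, SH.path)
            if isinstance(path, URIRef):
                allowed.add(path)
            else:
                steps = _list_members(self.shapes, path)
                if steps:
                    allowed.add(steps[0])
        for pred in set(self.data.predicates(focus, None)):
            if pred not in allowed:
                self._emit(
                    focus=focus,
                    component=SH.ClosedConstraintComponent,
                    severity=default_sev,
                    message=f"predicate {pred} is not declared on a closed shape",
                    source_shape=shape,
                    path=pred,
                )

    def _check_node_in(self, shape, focus, default_sev) -> None:
        in_head = self.shapes.value(shape, SH["in"])
        if in_head is None:
            return
        permitted = set(_list_members(self.shapes, in_head))
        if focus not in permitted:
            self._emit(
                focus=focus,
                component=SH.InConstraintComponent,
                severity=default_sev,
                message="node is not a listed member of this value set",
                source_shape=shape,
                value=focus,
            )

    def _check_sparql(self, shape, focus, default_sev) -> None:
        for cnode in self.shapes.objects(shape, SH.sparql):
            select = self.shapes.value(cnode, SH.select)
            severity = self.shapes.value(cnode, SH.severity) or default_sev
            message = self.shapes.value(cnode, SH.message) or Literal(
                "SPARQL constraint violated"
            )
            query = prepareQuery(str(select))
            rows = self.union.query(query, initBindings={"this": focus})
            has_value = rows.vars is not None and Variable("value") in rows.vars
            for row in rows:
                value = row[Variable("value")] if has_value else None
                self._emit(
                    focus=focus,
                    component=SH.SPARQLConstraintComponent,
                    severity=severity,
                    message=str(message),
                    source_shape=shape,
                    value=value,
                )

    # -- driver -------------------------------------------------------------

    def run(self) -> ValidationReport:
        shapes = sorted(
            set(self.shapes.subjects(RDF.type, SH.NodeShape)), key=str
        )
        for shape in shapes:
            default_sev = self.shapes.value(shape, SH.severity) or SEV_VIOLATION
            for focus in self._targets(shape):
                self._check_node_in(shape, focus, default_sev)
                self._check_closed(shape, focus, default_sev)
                self._check_sparql(shape, focus, default_sev)
                for pshape in sorted(self.shapes.objects(shape, SH.property), key=str):
                    self._check_property_shape(shape, pshape, focus, default_sev)
        return self.report


def validate(
    data_graph: Graph,
    shapes_graph: Graph,
    ont_graph: Optional[Graph] = None,
) -> ValidationReport:
    """Validate *data_graph* against *shapes_graph*.

    *ont_graph* (typically the compiled schema) supplies the subclass
    hierarchy used for RDFS-entailed class checks and for SPARQL constraints
    that walk ``rdfs:subClassOf*``.
    """
    return _ShapeRunner(data_graph, shapes_graph, ont_graph).run()
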