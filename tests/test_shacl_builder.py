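"""Shape derivation: preparation, subclass expansion, node/value-set shapes."""

import datetime

import pytest
from rdflib import BNode, Graph, Literal, URIRef
from rdflib.collection import Collection
from rdflib.compare import isomorphic
from rdflib.namespace import OWL, RDF, RDFS, SH, XSD

from semforge import build_schema, build_shapes
from semforge.dataset_io import resolve_inheritance
from semforge.fixtures import FixtureSpec, demo_model, random_model
from semforge.naming import NamingContext
from semforge.schema_builder import SchemaGraph
from semforge.shacl_builder import (
    ENTAILMENT_RDFS,
    ShapeDerivationError,
    collect_class_property_map,
    prepare,
)

FIXED = datetime.date(2025, 1, 1)
NS = "https://example.org/rdf/schema/sphn#"


def _project_schema():
    """A self-contained extension schema in its own namespace."""
    ctx = NamingContext(namespace="https://example.org/rdf/schema/proj#", prefix="proj")
    g = Graph()
    cls = URIRef(ctx.namespace + "StudyVisit")
    g.add((cls, RDF.type, OWL.Class))
    g.add((cls, RDFS.label, Literal("Study Visit")))
    g.add((cls, RDFS.subClassOf, URIRef(ctx.namespace + "ProjConcept")))
    root = URIRef(ctx.namespace + "ProjConcept")
    g.add((root, RDF.type, OWL.Class))
    return SchemaGraph(g, ctx, {"proj": ctx.namespace})


class TestPrepare:
    def test_base_only_is_open(self, demo_schema):
        prepared = prepare(demo_schema, today=FIXED)
        assert prepared.closed_mode is False

    def test_with_project_is_closed(self, demo_schema):
        prepared = prepare(demo_schema, _project_schema(), today=FIXED)
        assert prepared.closed_mode is True

    def test_metadata_declares_rdfs_entailment(self, demo_schema):
        prepared = prepare(demo_schema, today=FIXED)
        assert prepared.metadata["entailment"] == ENTAILMENT_RDFS
        assert prepared.metadata["created"] == FIXED

    def test_roots_found(self, demo_schema):
        prepared = prepare(demo_schema, today=FIXED)
        assert URIRef(NS + "SphnConcept") in prepared.roots

    def test_inconsistent_reparenting_rejected(self, demo_schema):
        bad = _project_schema()
        bad.graph.add((URIRef(NS + "Age"), RDF.type, OWL.Class))
        bad.graph.add(
            (URIRef(NS + "Age"), RDFS.subClassOf, URIRef(bad.namespace + "ProjConcept"))
        )
        with pytest.raises(ShapeDerivationError, match="re-parents"):
            prepare(demo_schema, bad, today=FIXED)

    def test_monotone_extension(self, demo_schema):
        """Merging a project that only adds concepts leaves every
        base-namespace triple unchanged."""
        merged = prepare(demo_schema, _project_schema(), today=FIXED).graph

        def base_triples(graph):
            keep = set()
            for s, p, o in graph:
                if isinstance(s, URIRef) and str(s).startswith(NS):
                    keep.add((s, p, o))
            return keep

        assert base_triples(merged) == base_triples(demo_schema.graph)


def _expansion_oracle(graph, namespaces):
    """Naive ancestor-walk: for each class collect its own restriction
    (class, property) pairs, then inherit any pair not shadowed by a nearer
    declaration, walking subclass edges one level at a time."""
    classes = [
        c
        for c in graph.subjects(RDF.type, OWL.Class)
        if isinstance(c, URIRef) and str(c).startswith(tuple(namespaces))
    ]
    direct = {c: {} for c in classes}
    for c in classes:
        for r in graph.objects(c, RDFS.subClassOf):
            if isinstance(r, BNode) and (r, RDF.type, OWL.Restriction) in graph:
                prop = graph.value(r, OWL.onProperty)
                direct[c][prop] = c  # value = declaring class
    result = {}
    for c in classes:
        eff = dict(direct[c])
        level = [c]
        seen = {c}
        while level:
            parents = []
            for x in level:
                for p in graph.objects(x, RDFS.subClassOf):
                    if isinstance(p, URIRef) and p in direct and p not in seen:
                        parents.append(p)
                        seen.add(p)
            for p in parents:
                for prop, src in direct[p].items():
                    eff.setdefault(prop, src)
            level = parents
        result[c] = eff
    return result


class TestClassPropertyMap:
    def test_inherited_restriction_appears_on_child(self, demo_schema):
        cpmap = collect_class_property_map(prepare(demo_schema, today=FIXED))
        eff = cpmap.effective(URIRef(NS + "BilledDiagnosis"))
        assert URIRef(NS + "hasRecordDateTime") in eff
        # and the override shadows the parent's SNOMED target
        code_entry = eff[URIRef(NS + "hasCode")]
        assert code_entry.class_targets == [
            URIRef("https://example.org/terminology/icd-10-gm/ICD-10-GM")
        ]

    def test_class_without_properties_has_empty_entry(self, demo_schema):
        cpmap = collect_class_property_map(prepare(demo_schema, today=FIXED))
        assert cpmap.effective(URIRef(NS + "SphnConcept")) == {}

    @pytest.mark.parametrize("seed", [2, 9, 21])
    def test_expansion_equals_bruteforce_oracle(self, seed):
        model = resolve_inheritance(random_model(FixtureSpec(seed=seed, n_concepts=20)))
        schema = build_schema(model)
        prepared = prepare(schema, today=FIXED)
        cpmap = collect_class_property_map(prepared)
        oracle = _expansion_oracle(prepared.graph, prepared.namespaces)
        for cls, expected in oracle.items():
            eff = cpmap.effective(cls)
            assert set(eff) == set(expected), cls
            for prop, src in expected.items():
                assert eff[prop].source_class == src, (cls, prop)

    def test_contradictory_cardinalities_rejected(self, demo_schema):
        prepared = prepare(demo_schema, today=FIXED)
        cls = URIRef(NS + "Age")
        prop = URIRef(NS + "hasQuantity")
        extra = BNode()
        prepared.graph.add((cls, RDFS.subClassOf, extra))
        prepared.graph.add((extra, RDF.type, OWL.Restriction))
        prepared.graph.add((extra, OWL.onProperty, prop))
        prepared.graph.add(
            (extra, OWL.minCardinality, Literal(3, datatype=XSD.nonNegativeInteger))
        )
        with pytest.raises(ShapeDerivationError, match="contradictory"):
            collect_class_property_map(prepared)


class TestNodeShapes:
    def test_shape_structure(self, demo_shapes):
        g = demo_shapes.graph
        shape = URIRef(NS + "BilledDiagnosisShape")
        assert (shape, RDF.type, SH.NodeShape) in g
        assert g.value(shape, SH.targetClass) == URIRef(NS + "BilledDiagnosis")
        assert g.value(shape, SH.closed) == Literal(False)
        ignored = list(Collection(g, g.value(shape, SH.ignoredProperties)))
        assert RDF.type in ignored

    def test_every_node_shape_has_one_target_class(self, demo_shapes):
        g = demo_shapes.graph
        for shape in g.subjects(RDF.type, SH.NodeShape):
            assert len(list(g.objects(shape, SH.targetClass))) == 1

    def test_snomed_root_no_descendant_expansion(self, demo_shapes):
        """The SNOMED-valued property points at the root code only; RDFS
        entailment covers all descendants, so none are listed."""
        g = demo_shapes.graph
        targets = [o for o in g.objects(None, SH["class"]) if "snomed" in str(o)]
        assert targets == [URIRef("http://snomed.info/id/138875005")]

    def test_datatype_constraint(self, demo_shapes):
        g = demo_shapes.graph
        shape = URIRef(NS + "EncounterShape")
        datatypes = set()
        for ps in g.objects(shape, SH.property):
            dt = g.value(ps, SH.datatype)
            if dt is not None:
                datatypes.add(dt)
        assert XSD.dateTime in datatypes

    def test_min_max_counts_from_cardinalities(self, demo_shapes):
        g = demo_shapes.graph
        shape = URIRef(NS + "DiagnosisShape")
        by_path = {
            g.value(ps, SH.path): ps for ps in g.objects(shape, SH.property)
        }
        code = by_path[URIRef(NS + "hasCode")]
        assert g.value(code, SH.minCount) == Literal(1)
        assert g.value(code, SH.maxCount) == Literal(1)

    def test_value_set_membership_via_in(self, demo_shapes):
        g = demo_shapes.graph
        shape = URIRef(NS + "EncounterShape")
        in_lists = []
        for ps in g.objects(shape, SH.property):
            head = g.value(ps, SH["in"])
            if head is not None:
                in_lists.append(set(Collection(g, head)))
        assert {URIRef(NS + "Inpatient"), URIRef(NS + "Outpatient"),
                URIRef(NS + "Emergency")} in in_lists

    def test_reverse_value_set_shape(self, demo_shapes):
        g = demo_shapes.graph
        shape = URIRef(NS + "EncounterCareSettingValueSetShape")
        assert g.value(shape, SH.targetClass) == URIRef(NS + "EncounterCareSettingValueSet")
        members = set(Collection(g, g.value(shape, SH["in"])))
        assert len(members) == 3

    def test_excluded_descendants_become_sparql_constraint(self):
        model = demo_model()
        diag = model.concept("Diagnosis")
        attr = next(a for a in diag.attributes if a.name == "subject age")
        attr.excluded_type_descendants = ("Encounter",)
        schema = build_schema(resolve_inheritance(model))
        shapes = build_shapes(schema, today=FIXED)
        g = shapes.graph
        selects = [
            str(g.value(c, SH.select))
            for c in g.objects(URIRef(NS + "DiagnosisShape"), SH.sparql)
        ]
        assert any("Encounter" in s and "subClassOf" in s for s in selects)

    def test_derivation_deterministic_up_to_bnodes(self, demo_schema, demo_dataset):
        s1 = build_shapes(demo_schema, coding_systems=demo_dataset.coding_systems, today=FIXED)
        s2 = build_shapes(demo_schema, coding_systems=demo_dataset.coding_systems, today=FIXED)
        assert isomorphic(s1.graph, s2.graph)


class TestSpecialRules:
    def test_start_end_rule_at_error_severity(self, demo_shapes):
        g = demo_shapes.graph
        found = []
        for c in g.objects(URIRef(NS + "EncounterShape"), SH.sparql):
            msg = str(g.value(c, SH.message) or "")
            if "StartDateTime" in msg:
                found.append(g.value(c, SH.severity))
        assert found == [SH.Violation]

    def test_naming_convention_at_warning_severity(self, demo_shapes):
        g = demo_shapes.graph
        sev = []
        for c in g.objects(URIRef(NS + "AgeShape"), SH.sparql):
            if "naming convention" in str(g.value(c, SH.message) or ""):
                sev.append(g.value(c, SH.severity))
        assert sev == [SH.Warning]

    def test_code_validity_severities(self, demo_shapes):
        """Derivable meaning changes are Info (valid and no-longer-valid
        alike); underivable ones are Warning."""
        g = demo_shapes.graph
        icd = "https://example.org/terminology/icd-10-gm/"
        sev_by_code = {}
        for shape in g.subjects(RDF.type, SH.NodeShape):
            target = g.value(shape, SH.targetClass)
            if target and str(target).startswith(icd) and "Shape" in str(shape):
                for c in g.objects(shape, SH.sparql):
                    sev_by_code[str(target)[len(icd):]] = g.value(c, SH.severity)
        assert sev_by_code["A41.9"] == SH.Info
        assert sev_by_code["C10"] == SH.Info
        assert sev_by_code["B20"] == SH.Warning

    def test_shape_file_metadata(self, demo_shapes):
        g = demo_shapes.graph
        onto = URIRef("https://example.org/rdf/schema/sphn/shapes")
        assert (onto, SH.entailment, ENTAILMENT_RDFS) in g
        created = g.value(onto, URIRef("http://purl.org/dc/terms/created"))
        assert str(created) == "2025-01-01"
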