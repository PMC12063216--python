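"""Workbook model -> OWL/RDFS/SKOS compilation."""

import pytest
from rdflib import Graph, Literal, URIRef
from rdflib.compare import isomorphic
from rdflib.namespace import OWL, RDF, RDFS, SKOS, XSD

from semforge import build_schema, serialize_turtle
from semforge.dataset_io import resolve_inheritance
from semforge.fixtures import (
    FixtureSpec,
    billed_diagnosis_model,
    demo_model,
    random_model,
)
from semforge.model import UNBOUNDED
from semforge.schema_builder import parse_exclusion_note

NS = "https://example.org/rdf/schema/sphn#"


def _restriction_cell_count(model) -> int:
    """Brute-force count of non-empty constraint cells over active rows."""
    count = 0
    known = {c.name for c in model.active_concepts()}
    coding = {cs.name for cs in model.coding_systems}
    datatypes = {"string", "integer", "datetime", "date", "double", "decimal", "boolean"}
    for concept in model.active_concepts():
        for card in (
            concept.card_admin_case,
            concept.card_subject_pseudo_id,
            concept.card_source_system,
        ):
            if card is not None:
                lo, hi = card
                count += (lo > 0) + (not isinstance(hi, type(UNBOUNDED)))
        for attr in concept.active_attributes():
            if attr.row_kind != "composedOf":
                continue
            lo, hi = attr.cardinality
            count += (lo > 0) + (not isinstance(hi, type(UNBOUNDED)))
            has_target = (
                attr.value_set is not None
                or (attr.standard in coding)
                or attr.value_type.lower() in datatypes
                or attr.value_type in known
            )
            count += bool(has_target)
    return count


class TestClasses:
    def test_subclass_edge(self, billed_schema):
        g = billed_schema.graph
        assert (URIRef(NS + "BilledDiagnosis"), RDFS.subClassOf, URIRef(NS + "Diagnosis")) in g

    def test_parentless_concepts_subclass_the_root(self, billed_schema):
        g = billed_schema.graph
        root = URIRef(NS + "SphnConcept")
        assert (URIRef(NS + "Diagnosis"), RDFS.subClassOf, root) in g
        assert (URIRef(NS + "Age"), RDFS.subClassOf, root) in g

    def test_every_class_has_one_label_and_definition(self, demo_schema):
        g = demo_schema.graph
        for cls in g.subjects(RDF.type, OWL.Class):
            assert len(list(g.objects(cls, RDFS.label))) == 1
            assert len(list(g.objects(cls, SKOS.definition))) == 1

    def test_every_restriction_has_one_on_property(self, demo_schema):
        g = demo_schema.graph
        for node in g.subjects(RDF.type, OWL.Restriction):
            assert len(list(g.objects(node, OWL.onProperty))) == 1

    def test_inactive_concept_emits_no_triples(self):
        model = demo_model()
        model.concept("Encounter").active = False
        g = build_schema(resolve_inheritance(model)).graph
        assert (URIRef(NS + "Encounter"), None, None) not in g

    def test_meaning_binding_is_equivalent_class(self):
        model = billed_diagnosis_model()
        model.concept("Diagnosis").meaning_binding = ("SNOMED CT", "439401001")
        g = build_schema(resolve_inheritance(model)).graph
        assert (
            URIRef(NS + "Diagnosis"),
            OWL.equivalentClass,
            URIRef("http://snomed.info/id/439401001"),
        ) in g

    def test_excluded_descendants_become_scope_note(self):
        model = billed_diagnosis_model()
        diag = model.concept("Diagnosis")
        diag.excluded_type_descendants = ("Billed Diagnosis",)
        g = build_schema(resolve_inheritance(model)).graph
        notes = list(g.objects(URIRef(NS + "Diagnosis"), SKOS.scopeNote))
        assert len(notes) == 1
        assert parse_exclusion_note(str(notes[0])) == (NS + "BilledDiagnosis",)


class TestAttributes:
    def test_code_attribute_axioms(self, billed_schema):
        """code 1:1 with a standard: object property plus min, max and
        someValuesFrom-the-root restrictions on the owner."""
        g = billed_schema.graph
        prop = URIRef(NS + "hasCode")
        assert (prop, RDF.type, OWL.ObjectProperty) in g
        owner = URIRef(NS + "BilledDiagnosis")
        seen = {"min": False, "max": False, "some": False}
        for node in g.objects(owner, RDFS.subClassOf):
            if (node, OWL.onProperty, prop) not in g:
                continue
            if g.value(node, OWL.minCardinality) is not None:
                seen["min"] = True
            if g.value(node, OWL.maxCardinality) is not None:
                seen["max"] = True
            if g.value(node, OWL.someValuesFrom) == URIRef(
                "https://example.org/terminology/icd-10-gm/ICD-10-GM"
            ):
                seen["some"] = True
        assert all(seen.values())

    def test_datetime_attribute_is_datatype_property(self, billed_schema):
        g = billed_schema.graph
        prop = URIRef(NS + "hasRecordDateTime")
        assert (prop, RDF.type, OWL.DatatypeProperty) in g
        some = [
            g.value(n, OWL.someValuesFrom)
            for n in g.subjects(OWL.onProperty, prop)
        ]
        assert XSD.dateTime in some

    def test_enumerated_codes_become_one_of(self, billed_schema):
        g = billed_schema.graph
        enum_cls = URIRef(NS + "BilledDiagnosisRankCodeCodeSet")
        head = g.value(enum_cls, OWL.oneOf)
        from rdflib.collection import Collection

        members = set(Collection(g, head))
        assert members == {
            URIRef("http://snomed.info/id/8319008"),
            URIRef("http://snomed.info/id/85097005"),
        }

    def test_qualitative_value_set_individuals(self, demo_schema):
        g = demo_schema.graph
        vs = URIRef(NS + "EncounterCareSettingValueSet")
        members = set(g.subjects(RDF.type, vs))
        assert members == {
            URIRef(NS + "Inpatient"),
            URIRef(NS + "Outpatient"),
            URIRef(NS + "Emergency"),
        }

    def test_sensitive_flag_on_restriction_node(self, demo_schema):
        g = demo_schema.graph
        flag = URIRef(NS + "subjectToDeIdentification")
        nodes = [s for s, o in g.subject_objects(flag) if o == Literal(True)]
        assert len(nodes) == 1
        assert g.value(nodes[0], OWL.onProperty) == URIRef(NS + "hasCareSetting")

    def test_single_owner_gets_global_domain(self, billed_schema):
        g = billed_schema.graph
        assert (URIRef(NS + "hasQuantity"), RDFS.domain, URIRef(NS + "Age")) in g
        # hasCode is owned by two classes: no global domain
        assert (URIRef(NS + "hasCode"), RDFS.domain, None) not in g


class TestWholeSchema:
    def test_ontology_header(self, billed_schema):
        g = billed_schema.graph
        onto = URIRef("https://example.org/rdf/schema/sphn")
        assert (onto, RDF.type, OWL.Ontology) in g
        assert g.value(onto, OWL.versionInfo) == Literal("2025.1")
        assert g.value(onto, OWL.priorVersion) == Literal("2024.2")
        assert g.value(onto, OWL.versionIRI) == URIRef(
            "https://example.org/rdf/schema/sphn/2025.1"
        )

    def test_header_without_prior_version(self):
        from dataclasses import replace

        model = billed_diagnosis_model()
        model.metadata = replace(model.metadata, prior_version=None)
        g = build_schema(resolve_inheritance(model)).graph
        onto = URIRef("https://example.org/rdf/schema/sphn")
        assert g.value(onto, OWL.priorVersion) is None

    @pytest.mark.parametrize("seed", [0, 5, 17])
    def test_restriction_count_matches_cell_count(self, seed):
        model = resolve_inheritance(random_model(FixtureSpec(seed=seed)))
        g = build_schema(model).graph
        emitted = len(set(g.subjects(RDF.type, OWL.Restriction)))
        assert emitted == _restriction_cell_count(model)

    def test_restriction_count_on_demo(self, demo_dataset, demo_schema):
        emitted = len(set(demo_schema.graph.subjects(RDF.type, OWL.Restriction)))
        assert emitted == _restriction_cell_count(demo_dataset)

    def test_deterministic_compilation(self, demo_dataset):
        g1 = build_schema(demo_dataset).graph
        g2 = build_schema(demo_dataset).graph
        assert isomorphic(g1, g2)

    def test_turtle_roundtrip_isomorphic(self, demo_schema):
        text = serialize_turtle(demo_schema)
        reparsed = Graph().parse(data=text, format="turtle")
        assert isomorphic(reparsed, demo_schema.graph)

    def test_turtle_byte_stable(self, demo_dataset):
        t1 = serialize_turtle(build_schema(demo_dataset))
        t2 = serialize_turtle(build_schema(demo_dataset))
        assert t1 == t2

    def test_prefix_declarations(self, billed_schema):
        text = serialize_turtle(billed_schema)
        assert "@prefix sphn:" in text
        assert "@prefix owl:" in text

    def test_empty_model_is_header_and_root_only(self):
        model = billed_diagnosis_model()
        model.concepts = []
        g = build_schema(model).graph
        classes = list(g.subjects(RDF.type, OWL.Class))
        assert classes == [URIRef(NS + "SphnConcept")]
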