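"""Query synthesis: schema indexing, DFS path expansion, the four kinds."""

import itertools

from hypothesis import given, settings, strategies as st
from rdflib import BNode, Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS, XSD
from rdflib.plugins.sparql import prepareQuery

from semforge import build_query_bundle, expand_paths, index_schema
from semforge.fixtures import generate_instance_data
from semforge.naming import NamingContext
from semforge.query_builder import (
    QUERY_KINDS,
    build_aggregate_queries,
    build_flattening_query,
)
from semforge.schema_builder import SchemaGraph

NS = "https://example.org/rdf/schema/sphn#"
TOY = "https://example.org/rdf/schema/cyclic#"


def _synthetic_schema(n: int, edges, leaf_classes=()):
    """A schema graph with classes C0..Cn-1 linked per *edges*; classes in
    *leaf_classes* additionally get a datatype property."""
    ctx = NamingContext(namespace=TOY, prefix="cyc")
    g = Graph()
    for i in range(n):
        cls = URIRef(f"{TOY}C{i}")
        g.add((cls, RDF.type, OWL.Class))
        g.add((cls, RDFS.label, Literal(f"C{i}")))
    for i, j in edges:
        cls = URIRef(f"{TOY}C{i}")
        prop = URIRef(f"{TOY}hasLink{i}to{j}")
        g.add((prop, RDF.type, OWL.ObjectProperty))
        node = BNode(f"r{i}_{j}")
        g.add((cls, RDFS.subClassOf, node))
        g.add((node, RDF.type, OWL.Restriction))
        g.add((node, OWL.onProperty, prop))
        g.add((node, OWL.someValuesFrom, URIRef(f"{TOY}C{j}")))
    for i in leaf_classes:
        cls = URIRef(f"{TOY}C{i}")
        prop = URIRef(f"{TOY}hasValue{i}")
        g.add((prop, RDF.type, OWL.DatatypeProperty))
        node = BNode(f"v{i}")
        g.add((cls, RDFS.subClassOf, node))
        g.add((node, RDF.type, OWL.Restriction))
        g.add((node, OWL.onProperty, prop))
        g.add((node, OWL.someValuesFrom, XSD.integer))
    return SchemaGraph(g, ctx, {"cyc": TOY})


class TestIndex:
    def test_worked_example_index(self, billed_schema):
        index = index_schema(billed_schema)
        billed = URIRef(NS + "BilledDiagnosis")
        assert billed in index.concepts
        assert URIRef(NS + "hasCode") in index.object_properties
        assert URIRef(NS + "hasRecordDateTime") in index.datatype_properties

    def test_value_set_classes_are_terminal(self, demo_schema):
        index = index_schema(demo_schema)
        assert URIRef(NS + "EncounterCareSettingValueSet") in index.value_set_classes
        assert URIRef(NS + "EncounterCareSettingValueSet") not in index.concepts

    def test_property_counts_match_triple_scan(self, demo_schema):
        index = index_schema(demo_schema)
        g = demo_schema.graph
        declared_obj = {
            p for p in g.subjects(RDF.type, OWL.ObjectProperty)
        }
        declared_dt = {
            p for p in g.subjects(RDF.type, OWL.DatatypeProperty)
        }
        assert set(index.object_properties) == declared_obj
        assert set(index.datatype_properties) == declared_dt

    def test_empty_schema_empty_index(self):
        schema = _synthetic_schema(0, [])
        index = index_schema(schema)
        assert index.concepts == {}


class TestPathExpansion:
    def test_nested_expansion_through_age(self, billed_schema):
        index = index_schema(billed_schema)
        pathset = expand_paths(index, URIRef(NS + "BilledDiagnosis"))
        rendered = {
            tuple(str(s.prop).rsplit("#", 1)[-1] for s in p.steps)
            for p in pathset.paths
        }
        assert ("hasSubjectAge", "hasQuantity") in rendered
        assert ("hasSubjectAge", "hasDeterminationDateTime") in rendered
        assert ("hasCode",) in rendered

    def test_self_referencing_class_traversed_once(self):
        schema = _synthetic_schema(1, [(0, 0)])
        index = index_schema(schema)
        pathset = expand_paths(index, URIRef(TOY + "C0"))
        assert len(pathset.paths) == 1
        assert len(pathset.paths[0].steps) == 1

    def test_two_cycle_finite(self):
        schema = _synthetic_schema(2, [(0, 1), (1, 0)], leaf_classes=(1,))
        index = index_schema(schema)
        pathset = expand_paths(index, URIRef(TOY + "C0"))
        # loop C0->C1->C0 traversed once, then stops
        assert all(len(p.steps) <= 3 for p in pathset.paths)
        assert pathset.paths

    def test_datatype_only_concept_has_length_one_paths(self, billed_schema):
        index = index_schema(billed_schema)
        pathset = expand_paths(index, URIRef(NS + "Age"))
        assert pathset.paths
        assert all(len(p.steps) == 1 for p in pathset.paths)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(data=st.data(), n=st.integers(min_value=2, max_value=50))
    def test_terminates_on_random_cyclic_schemas(self, data, n):
        edges = data.draw(
            st.lists(
                st.tuples(
                    st.integers(min_value=0, max_value=n - 1),
                    st.integers(min_value=0, max_value=n - 1),
                ),
                max_size=2 * n,
                unique=True,
            )
        )
        schema = _synthetic_schema(n, edges)
        index = index_schema(schema)
        pathset = expand_paths(index, URIRef(TOY + "C0"))
        assert all(len(p.steps) <= 10 for p in pathset.paths)
        again = expand_paths(index, URIRef(TOY + "C0"))
        assert pathset.paths == again.paths  # deterministic ordering


def _walk(data, node, props):
    nodes = [node]
    for p in props:
        nodes = [o for n in nodes for o in data.objects(n, p)]
    return nodes


def _oracle_rows(data, pathset):
    """Direct triple walk per instance; OPTIONAL semantics are an unbound
    (None) column, mandatory paths filter the instance out."""
    rows = set()
    for inst in set(data.subjects(RDF.type, pathset.source)):
        per_path = []
        ok = True
        for path in pathset.paths:
            vals = _walk(data, inst, [s.prop for s in path.steps])
            if not vals:
                if path.optional:
                    vals = [None]
                else:
                    ok = False
                    break
            per_path.append(vals)
        if not ok:
            continue
        for combo in itertools.product(*per_path):
            rows.add((inst,) + combo)
    return rows


class TestFlatteningQueries:
    def test_all_emitted_queries_parse(self, demo_schema):
        bundle = build_query_bundle(demo_schema)
        assert bundle.files()
        for _, text in bundle.files():
            prepareQuery(text)

    def test_result_columns(self, billed_schema):
        index = index_schema(billed_schema)
        pathset = expand_paths(index, URIRef(NS + "BilledDiagnosis"))
        text = build_flattening_query(pathset)
        assert "?code" in text
        assert "?recordDateTime" in text
        assert "?subjectAge_quantity" in text

    def test_rows_equal_triple_walk_oracle(self, demo_schema):
        data = generate_instance_data(demo_schema, "conforming")
        index = index_schema(demo_schema)
        for concept in index.concepts:
            pathset = expand_paths(index, concept)
            text = build_flattening_query(pathset)
            got = {tuple(row) for row in data.query(text)}
            assert got == _oracle_rows(data, pathset), concept

    def test_empty_pathset_returns_instances_only(self):
        schema = _synthetic_schema(1, [])
        index = index_schema(schema)
        pathset = expand_paths(index, URIRef(TOY + "C0"))
        text = build_flattening_query(pathset)
        assert "?instance" in text
        prepareQuery(text)


class TestAggregateQueries:
    def test_four_kinds_attempted_per_concept(self, demo_schema):
        bundle = build_query_bundle(demo_schema)
        for concept, queries in bundle.queries.items():
            assert set(queries) <= set(QUERY_KINDS)
            assert "flattening" in queries
            assert "count_of_instances" in queries

    def test_no_code_property_no_code_count(self, billed_schema):
        index = index_schema(billed_schema)
        out = build_aggregate_queries(index, URIRef(NS + "Age"))
        assert out["count_of_codes"] is None

    def test_code_counts_grouped(self, billed_schema, demo_schema):
        index = index_schema(billed_schema)
        out = build_aggregate_queries(index, URIRef(NS + "BilledDiagnosis"))
        data = Graph()
        billed = URIRef(NS + "BilledDiagnosis")
        code = URIRef("https://example.org/terminology/icd-10-gm/J45.9")
        for k in range(3):
            inst = URIRef(f"https://example.org/data/BilledDiagnosis-{k}")
            data.add((inst, RDF.type, billed))
            data.add((inst, URIRef(NS + "hasCode"), code))
        rows = list(data.query(out["count_of_codes"]))
        assert len(rows) == 1
        assert int(rows[0][1]) == 3

    def test_min_max_values(self, billed_schema):
        """MIN/MAX over {3, 7, 5} is (3, 7)."""
        index = index_schema(billed_schema)
        out = build_aggregate_queries(index, URIRef(NS + "Age"))
        data = Graph()
        for k, v in enumerate((3.0, 7.0, 5.0)):
            inst = URIRef(f"https://example.org/data/Age-{k}")
            data.add((inst, RDF.type, URIRef(NS + "Age")))
            data.add((inst, URIRef(NS + "hasQuantity"), Literal(v, datatype=XSD.double)))
        row = next(iter(data.query(out["min_max"])))
        values = {str(var): row[var] for var in row.labels}
        assert float(values["min_quantity"]) == 3.0
        assert float(values["max_quantity"]) == 7.0

    def test_count_of_instances_on_empty_data(self, billed_schema):
        index = index_schema(billed_schema)
        out = build_aggregate_queries(index, URIRef(NS + "Age"))
        row = next(iter(Graph().query(out["count_of_instances"])))
        assert int(row[0]) == 0
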