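# semforge

Clinical data networks routinely define their semantics — the concepts a
hospital must deliver (a diagnosis, an encounter, an age), the attributes of
each concept, permitted value sets and bindings to external terminologies
such as SNOMED CT or ICD-10-GM — in a structured spreadsheet, because a
spreadsheet is the format clinicians, data managers and engineers all read.
Exchanging and validating the actual patient data, however, happens in RDF.
Someone has to translate the human-readable workbook into the
machine-readable artifacts, and doing it by hand is slow and error-prone.

`semforge` automates that translation. From one workbook it forges:

1. an **OWL/RDFS/SKOS schema** (Turtle) — each concept row becomes an
   `owl:Class` with `rdfs:label`/`skos:definition` and `rdfs:subClassOf`
   edges; each composedOf row becomes an `owl:ObjectProperty` or
   `owl:DatatypeProperty` with per-class `owl:Restriction` nodes carrying
   `owl:minCardinality`, `owl:maxCardinality` and `owl:someValuesFrom`;
   meaning bindings become `owl:equivalentClass` to external code IRIs;
2. **SHACL validation shapes** (Turtle) — derived from the schema under a
   closed-world reading: one `sh:NodeShape` per class with
   `sh:minCount`/`sh:maxCount`, `sh:class`/`sh:or`, `sh:datatype`, `sh:in`,
   `sh:closed` + `sh:ignoredProperties`, plus SPARQL constraints for
   start/end datetime ordering (Violation), instance-IRI naming conventions
   (Warning) and terminology code-validity metadata (Info/Warning).
   Validation is meant to run under RDFS entailment, so a restriction may
   name a terminology root (e.g. `http://snomed.info/id/138875005`) and
   cover every descendant without expansion;
3. **statistical SPARQL queries** — four kinds per concept via depth-first
   path expansion (each loop traversed once): a flattening query returning
   one column per leaf value, counts of codes, counts of instances, and
   MIN/MAX aggregates over numeric/datetime leaves;
4. a **single-file HTML documentation** with alphabetical class/property
   listings, a client-side search panel, per-class restriction and value-set
   tables, and optional concept diagrams embedded by relative path.

The package also ships a validator (`semforge.shacl_engine`) for exactly the
constraint vocabulary the shape generator emits, and a fixtures module that
generates every input needed to exercise the pipeline — template and
worked-example workbooks, toy terminology trees, conforming and deliberately
defective instance data — so no licensed terminology content or download is
ever required.

## Worked example

The bundled worked example builds a workbook with three concepts:
`Diagnosis` (code bound to SNOMED CT, a mandatory record datetime, an
optional subject age), `Billed Diagnosis` (inheriting everything, overriding
the code to ICD-10-GM, adding a rank code restricted to two enumerated
SNOMED-style codes) and `Age` (a quantity plus determination datetime).

```python
import datetime, os, tempfile
from semforge.fixtures import generate_billed_diagnosis_workbook, generate_instance_data
from semforge.dataset_io import load_dataset
from semforge import build_schema, build_shapes, build_query_bundle, validate

d = tempfile.mkdtemp()
path = os.path.join(d, "billed_diagnosis.xlsx")
generate_billed_diagnosis_workbook(path)

model, report = load_dataset(path)
print("validation errors:", len(report))

schema = build_schema(model)
print("classes:", [str(c).rsplit("#", 1)[-1] for c in schema.classes()])

shapes = build_shapes(schema, coding_systems=model.coding_systems,
                      today=datetime.date(2025, 1, 1))
print("node shapes:", len(shapes.node_shapes()))

bundle = build_query_bundle(schema)
print("query files:", len(bundle.files()))

data = generate_instance_data(schema, "conforming")
result = validate(data, shapes.graph, ont_graph=schema.graph)
print("conforms:", result.conforms)
```

prints

```
validation errors: 0
classes: ['Age', 'BilledDiagnosis', 'BilledDiagnosisRankCodeCodeSet', 'Diagnosis', 'SphnConcept']
node shapes: 4
query files: 13
conforms: True
```

The five classes are the three concepts, the generated enumeration class
for the rank-code value set, and the auto-generated schema root every
parentless concept subclasses.  Four node shapes cover the non-value-set
classes; 13 query files are the four kinds for each concept that supports
them (`Age` has no code property, so it gets no count-of-codes query).  The
generated instance data satisfies every restriction, so validation reports
zero results.

The same pipeline runs from the shell:

```bash
semforge all billed_diagnosis.xlsx -o out/
# out/schema.ttl  out/shapes.ttl  out/queries/*.rq  out/documentation.html
```

Exit codes: 0 on success, 1 when the workbook fails validation (a
row-anchored error report is printed), 2 on I/O problems.

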