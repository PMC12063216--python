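# Methods

## The workbook contract

A dataset workbook has six tabs; three are consumed. **Metadata** is a
key/value tab holding the schema-level elements (prefix, title, description,
version, prior version, copyright, license, canonical and versioned IRIs —
all required except the prior version). **Coding System and Version** lists
one external terminology per row: a name (the key `standard` cells refer
to), a namespace IRI, a version string, an RDF-availability flag, an
optional root-node IRI, and optional per-code validity metadata. **Concepts**
is a single 23-column tab in which every row is either a `concept`, a
`composedOf` attribute, or an `inherited` attribute repetition. Four columns
(`release`, `IRI`, contextualized name/description and the two
contextualized parent/type variants, `additional information`) are stored
verbatim for documentation and never emitted as triples.

Parsing is total: every cell either maps into the typed model or produces a
row-anchored error with a stable machine-readable code (`BAD_CARDINALITY`,
`UNKNOWN_PARENT`, `STANDARD_NOT_DECLARED`, …). Inactive rows (`active
status = no`) are parsed and flagged rather than skipped so errors can still
anchor to them; they are excluded from all downstream generation.

Cardinality cells follow the closed grammar `INT ":" (INT | "n")`; an empty
cell means `0:n`. The parser is the exact inverse of the formatter (property
tested), and `min > max` is rejected.

Inheritance follows the rule that a child concept always carries all parent
attributes: every effective ancestor attribute must reappear as an
`inherited` row, unless the child overrides it with its own `composedOf` row
(override wins; this is how a child narrows an attribute, e.g. re-binding a
code from one terminology to another). `resolve_inheritance` annotates each
inherited row with its defining ancestor and is idempotent.

## Schema compilation

IRIs are minted mechanically: concept names in PascalCase
(`billed diagnosis` → `BilledDiagnosis`), attribute names as
`has` + UpperCamelCase (`record datetime` → `hasRecordDateTime`). The word
`datetime` is treated as a compound with an internal hump (`DateTime`),
matching the field convention. Sanitization strips punctuation, collapses
whitespace and ASCII-folds with a logged warning; names reducing to nothing
are errors. The namespace is the canonical IRI plus `#` unless it already
ends in a separator.

A single root class `<ns>{PascalCase(prefix)}Concept` is auto-generated and
every parentless concept subclasses it, so "classes below the root" is
always well defined for shape derivation.

Restrictions are attached as `rdfs:subClassOf` anonymous `owl:Restriction`
nodes on the owning class — one node per constraint (min, max, value) — not
as global `rdfs:domain`/`rdfs:range`, because shape derivation reads the
explicit (class, property) combination. A global `rdfs:domain` is
additionally emitted when a property has exactly one owning class.
Restriction blank nodes carry deterministic labels derived from
(class, property, constraint-kind), which makes Turtle serialization
byte-stable across runs.

Value targets map as follows:

| cell situation | emitted target |
|---|---|
| primitive value type | `owl:someValuesFrom` the XSD datatype (`string`→`xsd:string`, `datetime`→`xsd:dateTime`, `date`, `integer`, `double`/`decimal`, `boolean`; configurable) |
| `standard` only | `owl:someValuesFrom` the coding-system root class |
| `descendant of CODE` | `owl:someValuesFrom` the code's class; descendants follow by entailment |
| enumerated codes | a generated class `<Owner><Attr>CodeSet` with `owl:oneOf` over the code IRIs (child codes deliberately excluded) |
| enumerated labels | a generated class `<Owner><Attr>ValueSet` with one `owl:NamedIndividual` per label |
| a concept name | `owl:someValuesFrom` that concept's class |

Meaning bindings emit `owl:equivalentClass` directly to the external code
IRI. Excluded type descendants become `skos:scopeNote` annotations whose
text spells the excluded IRIs in angle brackets — a fixed grammar the shape
deriver parses back, keeping the schema the single carrier of all hints.
Sensitivity (`sensitive = yes`) becomes a boolean
`subjectToDeIdentification` annotation on the restriction node of the
(class, property) pair, so inheritance-specific sensitivity survives.
Concept-level cardinalities to Administrative Case / Subject Pseudo
Identifier / Source System are routed through `hasAdministrativeCase`,
`hasSubjectPseudoIdentifier` and `hasSourceSystem` object properties.

The ontology header annotates the canonical IRI with `owl:versionIRI`,
`owl:versionInfo`, `owl:priorVersion`, `dcterms:title/description/rights/
license` — the Dublin-Core choice is a documented constant of this package.

## Shape derivation

Derivation proceeds in six steps: extract root classes and prefixes; merge
the base and (optional) project graphs, rejecting a project that re-parents
a base-namespace class inconsistently; produce the shape-file metadata
(creation date, SHACL conformance, license, an RDFS entailment
declaration); load every class's restrictions and expand them through the
subclass hierarchy (a class's own declaration shadows an ancestor's;
contradictory cardinalities on one (class, property) raise an error naming
both sources); emit one `sh:NodeShape` per non-value-set class; and emit a
reverse instance-listing shape (`sh:in` over the declared individuals) per
value-set class, which must have no outgoing restrictions.

`sh:closed` is `false` when validating against the base schema alone and
`true` when a project extension is merged (overridable); `sh:ignoredProperties`
always includes `rdf:type`. Where a class overrides an ancestor's rule on
the same property, its shape additionally carries an explicit SPARQL target
selecting its direct instances, so parent and child each validate exactly
their own effective rule set. Severities use the standard SHACL IRIs:
`sh:Violation` for schema-compliance errors, `sh:Warning` for the
naming-convention check and underivable meaning changes, `sh:Info` for
derivable meaning changes (covering both still-valid and retired codes).

The instance-IRI naming convention — unspecified upstream, configurable
here — defaults to requiring the local part to begin with the target
class's local name followed by `-`.

Property chains (sequence paths) are supported in the class-property map
and emitted as `sh:path` lists, capped at depth 2; the bundled schema
builder does not currently produce nested restriction paths, so chains do
not arise end-to-end.

## The validation engine

No general-purpose SHACL processor is part of this package's dependency
set; instead `semforge.shacl_engine` implements exactly the constraint
vocabulary the generator emits (min/max count, class/or, datatype, in,
closed, SPARQL targets and constraints with per-constraint severities,
sequence paths). Class-membership checks honor `rdfs:subClassOf` closure
over the supplied ontology graph — the RDFS-entailment regime under which
the shapes are defined — while `sh:targetClass` matches direct instances,
mirroring the per-class effective-rule-set design. SPARQL constraints are
executed through rdflib's SPARQL engine with `$this` pre-bound. The engine
is deliberately not a conformance-complete SHACL implementation; shapes
emitted by this package are its contract.

## Query synthesis

The schema is indexed into concept/object-property/datatype-property
dictionaries with their restrictions. From each concept, paths are expanded
depth-first, branches ordered alphabetically by property IRI for
reproducible output; expansion stops at datatype properties, value-set or
enumerated targets, external classes, and at any (class, property) pair
already on the current path — each loop is traversed exactly once, so
expansion terminates on any finite graph (property tested on random cyclic
schemas up to 50 classes). Safety caps: maximum depth 10 and at most
10 000 paths per concept, both logged when hit.

Four query kinds are attempted per concept: flattening (one SELECT column
per leaf, non-mandatory paths wrapped in OPTIONAL blocks with disjoint
variables so blocks stay independent), count of codes (grouped counts over
the `hasCode` property only; omitted when the concept has none), count of
instances, and min–max (one MIN/MAX pair per numeric or datetime leaf, no
grouping by code context). Every emitted query parses under rdflib's SPARQL
1.1 grammar; files are named `<ConceptLocalName>__<kind>.rq`, one query per
file.

## Fixtures: what the generated data does and does not emulate

The fixtures module generates the template workbook (six tabs, 23-column
Concepts header, no data rows), the Billed Diagnosis worked example
(metadata prefix `sphn`, version 2025.1, prior 2024.2; ICD-10-GM and SNOMED
CT coding-system rows with root-node IRIs, the SNOMED root being the public
identifier 138875005), random structurally valid models with seedable
single defects, toy terminology trees with per-code validity metadata, and
instance data. Conforming instance data satisfies every effective
restriction, names instances `<ClassLocal>-<k>`, and orders start/end
datetimes correctly; each of six defect modes (missing mandatory value,
value over maxCount, wrong target class, unlisted value-set member,
start > end, unconventional IRI) seeds exactly one violation so tests can
check a one-to-one defect-to-result correspondence.

What this does **not** emulate: real terminology content (only root IRIs
are referenced — licensing forbids shipping SNOMED CT or ICD-10-GM), real
release-scale datasets (the actual network's workbook has dozens of coding
systems and hundreds of concepts), multi-valued clinical records, free-text
noise, or source-system heterogeneity. Passing tests therefore demonstrate
the correctness of the transformation and validation logic on
structure-faithful inputs, not data-quality performance on real hospital
exports. Problem sizes in the test suite (models up to 20 concepts,
cyclic graphs up to 50 classes, one or two instances per class) were chosen
as the smallest sizes at which the invariants are non-trivial.

## Numerical and tie-break choices

* Workbook outputs are byte-stable: fixed timestamp override, deterministic
  row order; schema Turtle is byte-stable via deterministic blank-node
  labels; shape graphs are deterministic up to blank-node naming.
* All iteration over classes, properties and shapes is sorted by IRI.
* Empty cardinality cells default to `0:n`; empty cells elsewhere mean
  "absent", never an error by themselves.
* Degenerate inputs: an empty workbook yields an empty model and an empty
  report; an empty model compiles to header + root class only; a concept
  with no properties gets a shape with only target, closedness and ignored
  properties.

## Known limitations

* The worked example encodes each attribute's cardinality from its own
  cell; upstream descriptions differ on whether the code or the record
  datetime is "the" mandatory attribute, and this package simply compiles
  what the cells say.
* Project extensions are compiled against their own namespace; a project
  row referencing a base concept as parent is supported at validation level
  (`external_parents`) but cross-namespace parent IRIs are not re-minted
  into the base namespace.
* The HTML documentation reproduces the listed features (alphabetical
  ordering, search, restriction and value-set tables, image embedding), not
  the visual fidelity of any particular documentation generator.
* The validation engine covers the emitted constraint subset only (see
  above); it is not a drop-in SHACL processor for arbitrary shapes.
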