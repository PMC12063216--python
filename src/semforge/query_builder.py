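"""Synthesize statistical SPARQL queries from a compiled schema.

For every concept class the builder attempts four query kinds:

* **flattening** — walk every expanded path from the concept down to a
  datatype leaf or a value, returning one column per leaf for each instance;
* **count of codes** — grouped counts over the code property (``hasCode``);
* **count of instances** — the number of typed instances;
* **min–max** — MIN/MAX aggregates over every numeric or datetime leaf.

Paths are expanded depth-first, branches ordered alphabetically by property
IRI; a technical loop (a class referencing itself, or a reoccurring
(class, property) pair) is traversed only once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

from rdflib import URIRef
from rdflib.namespace import XSD

from .shacl_builder import ClassPropertyMap, PropertyEntry, collect_class_property_map, prepare
from .schema_builder import SchemaGraph

logger = logging.getLogger(__name__)

QUERY_KINDS = ("flattening", "count_of_codes", "count_of_instances", "min_max")

_NUMERIC_OR_TEMPORAL = {
    XSD.integer,
    XSD.double,
    XSD.decimal,
    XSD.float,
    XSD.date,
    XSD.dateTime,
}

DEFAULT_MAX_DEPTH = 10
DEFAULT_MAX_PATHS = 10_000


def _local(iri: URIRef) -> str:
    text = str(iri).rstrip("/#")
    return text.rsplit("#", 1)[-1].rsplit("/", 1)[-1]


def _step_word(prop: URIRef) -> str:
    name = _local(prop)
    if name.startswith("has") and len(name) > 3:
        name = name[3:]
    return name[:1].lower() + name[1:]


# ---------------------------------------------------------------------------
# Schema index
# ---------------------------------------------------------------------------

@dataclass
class SchemaIndex:
    """Dictionaries of concepts, object/datatype properties and restrictions."""

    concepts: Dict[URIRef, Dict[str, object]]
    object_properties: Dict[URIRef, Dict[str, object]]
    datatype_properties: Dict[URIRef, Dict[str, object]]
    cpmap: ClassPropertyMap
    value_set_classes: Set[URIRef]

    def effective(self, cls: URIRef) -> Dict[URIRef, PropertyEntry]:
        return self.cpmap.effective(cls)


def index_schema(schema: SchemaGraph) -> SchemaIndex:
    """Build the concept/property dictionaries including their restrictions.

    Value-set classes (classes possessing instances) and enumeration classes
    are marked terminal: path expansion stops at them.
    """
    from rdflib.namespace import OWL, RDF, RDFS

    prepared = prepare(schema)
    cpmap = collect_class_property_map(prepared)
    graph = prepared.graph

    value_sets = set(cpmap.value_set_classes)
    for cls in graph.subjects(OWL.oneOf, None):
        if isinstance(cls, URIRef):
            value_sets.add(cls)

    concepts: Dict[URIRef, Dict[str, object]] = {}
    for cls in cpmap.entries:
        if cls in value_sets:
            continue
        concepts[cls] = {"label": str(graph.value(cls, RDFS.label) or _local(cls))}

    obj_props: Dict[URIRef, Dict[str, object]] = {}
    dt_props: Dict[URIRef, Dict[str, object]] = {}
    for prop in graph.subjects(RDF.type, OWL.ObjectProperty):
        if isinstance(prop, URIRef):
            obj_props[prop] = {"label": str(graph.value(prop, RDFS.label) or "")}
    for prop in graph.subjects(RDF.type, OWL.DatatypeProperty):
        if isinstance(prop, URIRef):
            dt_props[prop] = {"label": str(graph.value(prop, RDFS.label) or "")}
    for cls, entries in cpmap.entries.items():
        for prop, entry in entries.items():
            bucket = dt_props if entry.datatype is not None else obj_props
            bucket.setdefault(prop, {"label": ""})
            bucket[prop].setdefault("domains", set())
            bucket[prop]["domains"].add(cls)

    return SchemaIndex(
        concepts=concepts,
        object_properties=obj_props,
        datatype_properties=dt_props,
        cpmap=cpmap,
        value_set_classes=value_sets,
    )


# ---------------------------------------------------------------------------
# Depth-first path expansion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathStep:
    prop: URIRef
    optional: bool  # min cardinality 0 at this step
    leaf_datatype: Optional[URIRef] = None  # set on the final step when literal


@dataclass(frozen=True)
class Path:
    steps: Tuple[PathStep, ...]

    @property
    def optional(self) -> bool:
        return any(s.optional for s in self.steps)

    @property
    def leaf_datatype(self) -> Optional[URIRef]:
        return self.steps[-1].leaf_datatype if self.steps else None

    def variable(self) -> str:
        return "_".join(_step_word(s.prop) for s in self.steps)


@dataclass
class PathSet:
    source: URIRef
    paths: List[Path] = field(default_factory=list)


def expand_paths(
    index: SchemaIndex,
    concept: URIRef,
    max_depth: int = DEFAULT_MAX_DEPTH,
    max_paths: int = DEFAULT_MAX_PATHS,
) -> PathSet:
    """All maximal paths from *concept*, depth-first, each loop traversed once.

    Expansion follows effective (inherited + own) property entries.  It stops
    at datatype properties, value-set or enumerated targets, external classes
    (terminology roots), and at any (class, property) pair already on the
    current path — the loop guard that makes expansion terminate on cyclic
    schemas.
    """
    paths: List[Path] = []

    def walk(cls: URIRef, prefix: Tuple[PathStep, ...], guard: Set[Tuple[URIRef, URIRef]]):
        if len(paths) >= max_paths:
            logger.warning(
                "path expansion from %s truncated at %d paths", concept, max_paths
            )
            return
        if len(prefix) >= max_depth:
            logger.warning(
                "path expansion from %s truncated at depth %d", concept, max_depth
            )
            paths.append(Path(prefix))
            return
        emitted = False
        entries = index.effective(cls)
        for prop in sorted(entries, key=str):
            entry = entries[prop]
            optional = not entry.min_count
            if (cls, prop) in guard:
                continue  # reoccurring (class, property): traversed once already
            emitted = True
            if entry.datatype is not None:
                paths.append(
                    Path(prefix + (PathStep(prop, optional, entry.datatype),))
                )
                continue
            step = PathStep(prop, optional)
            target = entry.class_targets[0] if entry.class_targets else None
            if (
                entry.in_values is not None
                or target is None
                or target not in index.concepts
            ):
                # value-set members, enumerated codes, external roots, or
                # untyped links are values: the path ends here
                paths.append(Path(prefix + (step,)))
                continue
            walk(target, prefix + (step,), guard | {(cls, prop)})
        if not emitted and prefix:
            # every outgoing edge was a loop already traversed (or the class
            # is a sink): the path is maximal here
            paths.append(Path(prefix))

    walk(concept, (), set())
    return PathSet(source=concept, paths=paths)


# ---------------------------------------------------------------------------
# Query text generation
# ---------------------------------------------------------------------------

def _path_block(path: Path, indent: str = "    ") -> str:
    # intermediate variables carry the full leaf-variable prefix so that
    # separate (possibly OPTIONAL) path blocks never share variables
    lines = []
    subject = "?instance"
    for i, step in enumerate(path.steps):
        var = (
            f"?{path.variable()}"
            if i == len(path.steps) - 1
            else f"?{path.variable()}__n{i}"
        )
        lines.append(f"{indent}{subject} <{step.prop}> {var} .")
        subject = var
    return "\n".join(lines)


def build_flattening_query(pathset: PathSet) -> str:
    """One SELECT returning every leaf value for each instance of the source
    class; every non-mandatory path is wrapped as an OPTIONAL pattern."""
    variables = ["?instance"] + [f"?{p.variable()}" for p in pathset.paths]
    blocks = [f"    ?instance a <{pathset.source}> ."]
    for path in pathset.paths:
        block = _path_block(path, indent="        " if path.optional else "    ")
        if path.optional:
            blocks.append("    OPTIONAL {\n" + block + "\n    }")
        else:
            blocks.append(block)
    body = "\n".join(blocks)
    return f"SELECT {' '.join(variables)}\nWHERE {{\n{body}\n}}\n"


def build_aggregate_queries(
    index: SchemaIndex, concept: URIRef, max_depth: int = DEFAULT_MAX_DEPTH
) -> Dict[str, Optional[str]]:
    """The three aggregate kinds; a kind inapplicable to the concept is None.

    ``count_of_codes`` only parses the code property; ``min_max`` aggregates
    every numeric or datetime leaf of the expanded paths.
    """
    entries = index.effective(concept)
    out: Dict[str, Optional[str]] = {}

    code_props = [p for p in sorted(entries, key=str) if _local(p) == "hasCode"]
    if code_props:
        prop = code_props[0]
        out["count_of_codes"] = (
            "SELECT ?code (COUNT(?code) AS ?codeCount)\n"
            "WHERE {\n"
            f"    ?instance a <{concept}> ;\n"
            f"        <{prop}> ?code .\n"
            "}\n"
            "GROUP BY ?code\n"
            "ORDER BY DESC(?codeCount) ?code\n"
        )
    else:
        out["count_of_codes"] = None

    out["count_of_instances"] = (
        "SELECT (COUNT(DISTINCT ?instance) AS ?instanceCount)\n"
        f"WHERE {{\n    ?instance a <{concept}> .\n}}\n"
    )

    pathset = expand_paths(index, concept, max_depth=max_depth)
    numeric = [
        p for p in pathset.paths if p.leaf_datatype in _NUMERIC_OR_TEMPORAL
    ]
    if numeric:
        projections = []
        blocks = [f"    ?instance a <{concept}> ."]
        for path in numeric:
            var = path.variable()
            projections.append(f"(MIN(?{var}) AS ?min_{var}) (MAX(?{var}) AS ?max_{var})")
            blocks.append("    OPTIONAL {\n" + _path_block(path, "        ") + "\n    }")
        out["min_max"] = (
            f"SELECT {' '.join(projections)}\n"
            "WHERE {\n" + "\n".join(blocks) + "\n}\n"
        )
    else:
        out["min_max"] = None
    return out


@dataclass
class QueryBundle:
    """Named query texts grouped by concept and kind."""

    queries: Dict[URIRef, Dict[str, str]] = field(default_factory=dict)

    def files(self) -> List[Tuple[str, str]]:
        """(filename, text) pairs, one query per file."""
        out = []
        for concept in sorted(self.queries, key=str):
            for kind in QUERY_KINDS:
                text = self.queries[concept].get(kind)
                if text is not None:
                    out.append((f"{_local(concept)}__{kind}.rq", text))
        return out


def build_query_bundle(
    schema: SchemaGraph, max_depth: int = DEFAULT_MAX_DEPTH
) -> QueryBundle:
    """All four query kinds for every concept class in the schema."""
    index = index_schema(schema)
    bundle = QueryBundle()
    for concept in sorted(index.concepts, key=str):
        pathset = expand_paths(index, concept, max_depth=max_depth)
        queries: Dict[str, str] = {"flattening": build_flattening_query(pathset)}
        for kind, text in build_aggregate_queries(index, concept, max_depth).items():
            if text is not None:
                queries[kind] = text
        bundle.queries[concept] = queries
    return bundle


def write_queries(bundle: QueryBundle, outdir) -> List[str]:
    """Write one .rq file per query under *outdir*; returns the filenames."""
    import os

    os.makedirs(outdir, exist_ok=True)
    names = []
    for filename, text in bundle.files():
        with open(os.path.join(outdir, filename), "w", encoding="utf-8") as fh:
            fh.write(text)
        names.append(filename)
    return names
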