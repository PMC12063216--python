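"""Render single-file HTML documentation of a compiled schema.

Classes and properties are listed alphabetically, each class section shows
its definition, a restrictions table and (where applicable) a value-set
table, and a client-side search panel filters sections by label substring.
Pre-prepared concept images are embedded at the class's own section via the
relative paths given in the image map.
"""

from __future__ import annotations

import html
import logging
from typing import Dict, List, Optional

from rdflib import Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS, SKOS

from .schema_builder import SchemaGraph
from .shacl_builder import collect_class_property_map, prepare

logger = logging.getLogger(__name__)

# written without '<' so the document stays well-formed XML as served
_SEARCH_SCRIPT = """
function filterSections() {
  var q = document.getElementById('search').value.toLowerCase();
  var sections = document.getElementsByClassName('entity');
  for (var i = 0; sections.length > i; i++) {
    var label = sections[i].getAttribute('data-label');
    sections[i].style.display = label.indexOf(q) >= 0 ? '' : 'none';
  }
}
"""

_STYLE = """
body { font-family: sans-serif; margin: 2em; }
table { border-collapse: collapse; margin: 0.5em 0; }
td, th { border: 1px solid #999; padding: 0.3em 0.6em; text-align: left; }
.entity { margin-bottom: 1.5em; }
#search { width: 20em; padding: 0.3em; }
"""


def _local(iri: URIRef) -> str:
    text = str(iri).rstrip("/#")
    return text.rsplit("#", 1)[-1].rsplit("/", 1)[-1]


def _esc(value) -> str:
    return html.escape(str(value))


def render_html(
    schema: SchemaGraph, image_map: Optional[Dict[str, str]] = None
) -> str:
    """Render the schema to one self-contained HTML document.

    *image_map* maps class local names (or full IRIs) to relative image
    paths; entries matching no class produce a warning and are skipped.
    """
    prepared = prepare(schema)
    cpmap = collect_class_property_map(prepared)
    graph = prepared.graph
    image_map = dict(image_map or {})

    classes = sorted(cpmap.entries, key=lambda c: _local(c).lower())
    properties = sorted(
        set(
            list(graph.subjects(RDF.type, OWL.ObjectProperty))
            + list(graph.subjects(RDF.type, OWL.DatatypeProperty))
        ),
        key=lambda p: _local(p).lower(),
    )

    resolved_images: Dict[URIRef, str] = {}
    by_local = {_local(c): c for c in classes}
    for key, rel_path in image_map.items():
        cls = by_local.get(key) or (URIRef(key) if URIRef(key) in set(classes) else None)
        if cls is None:
            logger.warning("image map entry %r matches no schema class; skipped", key)
            continue
        resolved_images[cls] = rel_path

    title = "Schema documentation"
    for onto in graph.subjects(RDF.type, OWL.Ontology):
        t = graph.value(onto, URIRef("http://purl.org/dc/terms/title"))
        if t:
            title = str(t)
            break

    parts: List[str] = [
        "<!DOCTYPE html>",
        '<html lang="en">',
        "<head>",
        '<meta charset="utf-8"/>',
        f"<title>{_esc(title)}</title>",
        f"<style>{_STYLE}</style>",
        "</head>",
        "<body>",
        f"<h1>{_esc(title)}</h1>",
        '<div id="searchpanel">',
        '<input id="search" type="text" placeholder="Search classes and properties"'
        ' onkeyup="filterSections()"/>',
        "</div>",
        "<h2>Classes</h2>",
        "<ul>",
    ]
    for cls in classes:
        parts.append(
            f'<li><a href="#{_esc(_local(cls))}">{_esc(_local(cls))}</a></li>'
        )
    parts.append("</ul>")
    parts.append("<h2>Properties</h2>")
    parts.append("<ul>")
    for prop in properties:
        parts.append(
            f'<li><a href="#{_esc(_local(prop))}">{_esc(_local(prop))}</a></li>'
        )
    parts.append("</ul>")

    parts.append("<h2>Class details</h2>")
    for cls in classes:
        label = str(graph.value(cls, RDFS.label) or _local(cls))
        definition = str(graph.value(cls, SKOS.definition) or "")
        parts.append(
            f'<div class="entity" id="{_esc(_local(cls))}" data-label="{_esc(label.lower())}">'
        )
        parts.append(f"<h3>{_esc(label)}</h3>")
        parts.append(f"<p><code>{_esc(cls)}</code></p>")
        if definition:
            parts.append(f"<p>{_esc(definition)}</p>")
        if cls in resolved_images:
            parts.append(
                f'<img src="{_esc(resolved_images[cls])}" alt="{_esc(label)} diagram"/>'
            )
        parents = sorted(
            (p for p in graph.objects(cls, RDFS.subClassOf) if isinstance(p, URIRef)),
            key=str,
        )
        if parents:
            links = ", ".join(
                f'<a href="#{_esc(_local(p))}">{_esc(_local(p))}</a>' for p in parents
            )
            parts.append(f"<p>Subclass of: {links}</p>")

        entries = cpmap.effective(cls)
        if entries:
            parts.append("<table><tr><th>Property</th><th>Cardinality</th>"
                         "<th>Target</th></tr>")
            for prop in sorted(entries, key=str):
                e = entries[prop]
                lo = e.min_count if e.min_count is not None else 0
                hi = e.max_count if e.max_count is not None else "n"
                if e.datatype is not None:
                    target = _local(e.datatype)
                elif e.in_values is not None:
                    target = f"value set ({len(e.in_values)} members)"
                elif e.class_targets:
                    target = ", ".join(_local(t) for t in e.class_targets)
                else:
                    target = ""
                parts.append(
                    f"<tr><td>{_esc(_local(prop))}</td><td>{lo}:{hi}</td>"
                    f"<td>{_esc(target)}</td></tr>"
                )
            parts.append("</table>")
        if cls in cpmap.value_set_classes:
            parts.append("<table><tr><th>Permitted value</th></tr>")
            for member in cpmap.value_set_classes[cls]:
                member_label = graph.value(member, RDFS.label) or _local(member)
                parts.append(f"<tr><td>{_esc(member_label)}</td></tr>")
            parts.append("</table>")
        parts.append("</div>")

    parts.append("<h2>Property details</h2>")
    for prop in properties:
        label = str(graph.value(prop, RDFS.label) or _local(prop))
        definition = str(graph.value(prop, SKOS.definition) or "")
        kind = (
            "Datatype property"
            if (prop, RDF.type, OWL.DatatypeProperty) in graph
            else "Object property"
        )
        parts.append(
            f'<div class="entity" id="{_esc(_local(prop))}" '
            f'data-label="{_esc(label.lower())}">'
        )
        parts.append(f"<h3>{_esc(_local(prop))}</h3>")
        parts.append(f"<p><code>{_esc(prop)}</code> — {kind}</p>")
        if definition:
            parts.append(f"<p>{_esc(definition)}</p>")
        parts.append("</div>")

    parts.append(f"<script>{_SEARCH_SCRIPT}</script>")
    parts.append("</body>")
    parts.append("</html>")
    return "\n".join(parts)
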