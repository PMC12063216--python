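"""IRI minting conventions: PascalCase classes, has-prefixed camelCase properties.

Concept names like ``"billed diagnosis"`` become class local names
``BilledDiagnosis``; attribute names like ``"record datetime"`` become
property local names ``hasRecordDateTime``.  Minting is deterministic and
purely mechanical: split on whitespace/punctuation runs, capitalize each
word's first letter, join.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from typing import Dict, Optional

from rdflib import URIRef
from rdflib.namespace import XSD

logger = logging.getLogger(__name__)

#: marker used in the datatype map for value types that link to another concept
CONCEPT_LINK = "CONCEPT-LINK"

#: default mapping from workbook value-type names to XSD datatypes
DEFAULT_DATATYPE_MAP: Dict[str, URIRef] = {
    "string": XSD.string,
    "datetime": XSD.dateTime,
    "date": XSD.date,
    "integer": XSD.integer,
    "double": XSD.double,
    "decimal": XSD.double,
    "boolean": XSD.boolean,
}

_WORD_SPLIT = re.compile(r"[^0-9A-Za-z]+")

#: compound words with an internal camel hump in the naming convention
#: (e.g. "record datetime" mints hasRecordDateTime, not hasRecordDatetime)
_COMPOUND_WORDS = {"datetime": "DateTime"}


def _ascii_fold(text: str) -> str:
    folded = (
        unicodedata.normalize("NFKD", text).encode("ascii", "ignore").decode("ascii")
    )
    if folded != text:
        logger.warning("non-ASCII characters folded while minting IRI from %r", text)
    return folded


def pascal_case(name: str) -> str:
    """``"oxygen  saturation"`` -> ``"OxygenSaturation"``.

    Splits on any run of whitespace or punctuation, uppercases the first
    letter of each word and preserves the rest (so ``"ICD-10 code"`` ->
    ``"ICD10Code"``).  Non-ASCII characters are ASCII-folded with a warning,
    never transliterated further.
    """
    words = [w for w in _WORD_SPLIT.split(_ascii_fold(name)) if w]
    return "".join(
        _COMPOUND_WORDS.get(w.lower(), w[:1].upper() + w[1:]) for w in words
    )


def camel_case(name: str) -> str:
    pascal = pascal_case(name)
    return pascal[:1].lower() + pascal[1:] if pascal else pascal


@dataclass
class NamingContext:
    """Namespace + prefix + datatype map governing all minted IRIs."""

    namespace: str
    prefix: str
    datatype_map: Dict[str, URIRef] = field(
        default_factory=lambda: dict(DEFAULT_DATATYPE_MAP)
    )

    def __post_init__(self) -> None:
        if not self.namespace.endswith(("/", "#")):
            raise ValueError(
                f"namespace must end in '/' or '#', got {self.namespace!r}"
            )

    @property
    def root_class_name(self) -> str:
        # every parentless concept subclasses a single auto-generated root
        return pascal_case(self.prefix) + "Concept"

    def root_class_iri(self) -> URIRef:
        return URIRef(self.namespace + self.root_class_name)


def mint_class_iri(name: str, ctx: NamingContext) -> URIRef:
    """Mint the owl:Class IRI for a concept name."""
    local = pascal_case(name)
    if not local:
        raise ValueError(f"concept name {name!r} reduces to nothing after normalization")
    return URIRef(ctx.namespace + local)


def mint_property_iri(name: str, ctx: NamingContext) -> URIRef:
    """Mint the property IRI for an attribute name: ``has`` + UpperCamelCase."""
    local = pascal_case(name)
    if not local:
        raise ValueError(
            f"attribute name {name!r} reduces to nothing after normalization"
        )
    return URIRef(ctx.namespace + "has" + local)


def mint_individual_iri(label: str, namespace: str) -> URIRef:
    """Mint a named-individual IRI for a qualitative value-set label."""
    local = pascal_case(label)
    if not local:
        raise ValueError(f"label {label!r} reduces to nothing after normalization")
    return URIRef(namespace + local)


def classify_value_type(
    value_type: str, ctx: NamingContext, known_concepts
) -> Optional[str]:
    """Return ``"datatype"``, ``"code"`` or ``"concept"``; None when unknown."""
    vt = value_type.strip()
    if vt.lower() in ctx.datatype_map:
        return "datatype"
    if vt.lower() == "code":
        return "code"
    if vt in known_concepts:
        return "concept"
    return None
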