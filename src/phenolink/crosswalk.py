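"""Bidirectional code translation through the unified concept layer.

A source code maps to its concept(s); a concept projects back into any
vocabulary with atoms on it — including vocabularies never used to annotate
the data, and including *retired* codes (reactivation: a retired code
becomes retrievable because its concept also carries an active one).
Translation is the composition of the two lookups through the CUI pivot.
Reactivation is reported, never applied: every mapping carries its status
and callers decide whether retired codes are usable.
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import NotFoundError
from .terminology import TerminologyGraph, lookup_code


@dataclass(frozen=True, order=True)
class CodeMapping:
    source: str
    code: str
    cui: str
    status: str  # "active" | "retired"
    label: str = ""


def code_to_cuis(graph: TerminologyGraph, source: str, code: str) -> set[str]:
    """All CUIs carrying an atom with (source, code); empty set if unmapped.

    Retired atoms participate whenever they are present in the graph (i.e.
    the graph was loaded with ``include_suppressed=True``).
    """
    return lookup_code(graph, source, code)


def cuis_to_codes(graph: TerminologyGraph, cui: str, target_source: str) -> set[CodeMapping]:
    """Project a concept into ``target_source``.

    Both active and retired versions of a code are returned when present,
    with distinct statuses. Unknown CUIs raise :class:`NotFoundError`.
    """
    if cui not in graph.concepts:
        raise NotFoundError(f"unknown concept {cui}")
    mappings = set()
    for atom in graph.concepts[cui].atoms:
        if atom.source != target_source:
            continue
        mappings.add(
            CodeMapping(
                source=atom.source,
                code=atom.code,
                cui=cui,
                status="retired" if atom.obsolete else "active",
                label=atom.label,
            )
        )
    return mappings


def translate(
    graph: TerminologyGraph, source: str, code: str, target_source: str
) -> set[CodeMapping]:
    """Translate a source code into another vocabulary via the CUI pivot.

    Equals the union over ``code_to_cuis`` of ``cuis_to_codes``; a code
    mapping to several concepts translates through all of them, each result
    carrying its provenance CUI. Returns the empty set for an empty chain.
    """
    mappings: set[CodeMapping] = set()
    for cui in code_to_cuis(graph, source, code):
        mappings |= cuis_to_codes(graph, cui, target_source)
    return mappings
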