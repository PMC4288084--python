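"""Metathesaurus-style terminology store.

Parses pipe-delimited RRF-subset files (concept/atom, relation, semantic
type, attribute tables) into an in-memory concept graph keyed by concept
unique identifiers (CUIs), and derives the source-restricted hierarchical
view that all downstream stages (expansion, propagation, browsing) traverse.

Two dialects are accepted per file, auto-detected by column count: the full
MRCONSO/MRREL/MRSTY/MRSAT column layouts of a real Metathesaurus release,
and minimal fixture-friendly subsets (e.g. ``CUI|LAT|AUI|SAB|TTY|CODE|STR|
SUPPRESS`` for atoms). Only English-language atoms are indexed.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import (
    ConfigurationError,
    NotFoundError,
    TerminologyLoadError,
    TerminologyParseError,
)

#: Default set of vocabularies whose hierarchical assertions are trusted for
#: browsing and query expansion. Hierarchies asserted only by other sources
#: are ignored because they can create nonsensical traversal paths.
DEFAULT_ALLOWED_SOURCES = frozenset(
    {"MTH", "SNOMEDCT", "LNC", "RXNORM", "NDFRT", "HCPCS", "ICD9CM", "ICD10CM"}
)

#: Non-hierarchical relations promoted to parent/child edges to augment the
#: relatively flat LOINC and RxNorm hierarchies (e.g. a LOINC test that
#: *measures* a drug becomes a child of the drug concept).
DEFAULT_AUGMENTATION_RELATIONS = frozenset(
    {("LNC", "class_of"), ("LNC", "measured_by"), ("RXNORM", "has_ingredient")}
)

#: Preference order used when electing a concept's preferred label.
_SOURCE_PRIORITY = ("MTH", "SNOMEDCT", "LNC", "RXNORM", "NDFRT", "ICD10CM", "ICD9CM", "HCPCS")

_SUPPRESS_FLAGS = {"O", "E", "Y"}


@dataclass(frozen=True)
class Atom:
    """One (vocabulary, code, string) occurrence of a concept."""

    atom_id: str
    cui: str
    source: str
    code: str
    label: str
    suppressed: bool = False
    obsolete: bool = False


@dataclass
class Concept:
    cui: str
    atoms: list[Atom] = field(default_factory=list)
    semantic_types: set[str] = field(default_factory=set)
    preferred_label: str = ""


@dataclass(frozen=True)
class Relation:
    """A typed edge stored in the normalized child -> parent direction."""

    child_cui: str
    parent_cui: str
    rel: str  # "hierarchical" (PAR/CHD rows) or "other"
    rela: str
    source: str


@dataclass(frozen=True)
class Attribute:
    cui: str
    name: str
    value: str
    source: str


@dataclass
class TerminologyGraph:
    """The loaded Metathesaurus subset."""

    concepts: dict[str, Concept] = field(default_factory=dict)
    relations: list[Relation] = field(default_factory=list)
    attributes: list[Attribute] = field(default_factory=list)
    code_index: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    attribute_index: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def __contains__(self, cui: str) -> bool:
        return cui in self.concepts

    def atoms(self) -> Iterable[Atom]:
        for concept in self.concepts.values():
            yield from concept.atoms

    def canonical_serialization(self) -> str:
        """Deterministic text rendering used by equality/determinism checks."""
        buf = io.StringIO()
        for cui in sorted(self.concepts):
            c = self.concepts[cui]
            atoms = sorted(
                (a.source, a.code, a.label, a.atom_id, a.suppressed, a.obsolete)
                for a in c.atoms
            )
            buf.write(f"{cui}\t{c.preferred_label}\t{sorted(c.semantic_types)}\t{atoms}\n")
        for rel in sorted(self.relations, key=lambda r: (r.child_cui, r.parent_cui, r.rel, r.rela, r.source)):
            buf.write(f"{rel.child_cui}\t{rel.parent_cui}\t{rel.rel}\t{rel.rela}\t{rel.source}\n")
        for att in sorted(self.attributes, key=lambda a: (a.cui, a.name, a.value, a.source)):
            buf.write(f"{att.cui}\t{att.name}\t{att.value}\t{att.source}\n")
        return buf.getvalue()


@dataclass
class HierarchyView:
    """Source-restricted, augmented parent/child graph over a graph's CUIs."""

    parent_edges: dict[str, set[str]]
    child_edges: dict[str, set[str]]
    provenance: dict[tuple[str, str], set[tuple[str, str]]]
    allowed_sources: frozenset[str]
    augmentation_relations: frozenset[tuple[str, str]]
    concepts: frozenset[str]

    def edges(self) -> Iterable[tuple[str, str]]:
        for child, parents in self.parent_edges.items():
            for parent in parents:
                yield child, parent


# ---------------------------------------------------------------------------
# File parsing
# ---------------------------------------------------------------------------

def _rows(path: Path, widths: dict[int, str]):
    """Yield (line_number, fields) for a pipe-delimited file.

    ``widths`` maps accepted column counts to a dialect tag. RRF rows may
    carry a trailing pipe; the resulting empty last field is dropped.
    """
    with open(path, encoding="utf-8") as handle:
        for line_number, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("|")
            if fields[-1] == "" and (len(fields) - 1) in widths:
                fields = fields[:-1]
            if len(fields) not in widths:
                raise TerminologyParseError(
                    path,
                    line_number,
                    f"expected {sorted(widths)} pipe-delimited columns, got {len(fields)}",
                )
            yield line_number, widths[len(fields)], fields


def _parse_concept_file(path: Path) -> tuple[list[Atom], set[str]]:
    """Parse an MRCONSO-compatible file; returns atoms and all CUIs seen."""
    atoms: list[Atom] = []
    seen_cuis: set[str] = set()
    seen_atom_ids: set[str] = set()
    auto_id = 0
    for line_number, dialect, f in _rows(path, {18: "full", 8: "minimal"}):
        if dialect == "full":
            cui, lat, aui, sab, code, label, suppress = (
                f[0], f[1], f[7], f[11], f[13], f[14], f[16],
            )
        else:  # CUI|LAT|AUI|SAB|TTY|CODE|STR|SUPPRESS
            cui, lat, aui, sab, code, label, suppress = (
                f[0], f[1], f[2], f[3], f[5], f[6], f[7],
            )
        seen_cuis.add(cui)
        if lat and lat != "ENG":
            continue
        if not label:
            raise TerminologyParseError(path, line_number, "empty atom label (STR)")
        if not aui:
            auto_id += 1
            aui = f"A{auto_id:07d}"
        if aui in seen_atom_ids:
            raise TerminologyParseError(path, line_number, f"duplicate atom id {aui}")
        seen_atom_ids.add(aui)
        atoms.append(
            Atom(
                atom_id=aui,
                cui=cui,
                source=sab,
                code=code,
                label=label,
                suppressed=suppress in _SUPPRESS_FLAGS,
                obsolete=suppress == "O",
            )
        )
    return atoms, seen_cuis


def _parse_relation_file(path: Path) -> list[tuple[str, str, str, str, str]]:
    """Parse MRREL-compatible rows into raw (cui1, rel, rela, cui2, sab)."""
    rows = []
    for _line_number, dialect, f in _rows(path, {16: "full", 5: "minimal"}):
        if dialect == "full":
            cui1, rel, cui2, rela, sab = f[0], f[3], f[4], f[7], f[10]
        else:  # CUI1|REL|RELA|CUI2|SAB
            cui1, rel, rela, cui2, sab = f
        rows.append((cui1, rel, rela, cui2, sab))
    return rows


def _parse_semantic_file(path: Path) -> list[tuple[str, str]]:
    rows = []
    for _line_number, dialect, f in _rows(path, {6: "full", 3: "minimal"}):
        sty = f[3] if dialect == "full" else f[2]
        rows.append((f[0], sty))
    return rows


def _parse_attribute_file(path: Path) -> list[Attribute]:
    rows = []
    for _line_number, dialect, f in _rows(path, {13: "full", 4: "minimal"}):
        if dialect == "full":
            cui, atn, sab, atv = f[0], f[8], f[9], f[10]
        else:  # CUI|ATN|ATV|SAB
            cui, atn, atv, sab = f
        rows.append(Attribute(cui=cui, name=atn, value=atv, source=sab))
    return rows


def _preferred_label(atoms: list[Atom]) -> str:
    def priority(atom: Atom) -> tuple:
        try:
            rank = _SOURCE_PRIORITY.index(atom.source)
        except ValueError:
            rank = len(_SOURCE_PRIORITY)
        return (atom.suppressed, rank, atom.source, atom.atom_id)

    return min(atoms, key=priority).label


def load_terminology(
    concept_file,
    relation_file,
    semantic_file,
    attribute_file=None,
    include_suppressed: bool = False,
) -> TerminologyGraph:
    """Load RRF-subset files into a :class:`TerminologyGraph`.

    Suppressed/obsolete atoms are excluded unless ``include_suppressed`` is
    set, in which case they are retained with their ``obsolete`` flag — this
    is what makes retired-code reactivation visible to the crosswalk.

    Relations, semantic types, or attributes referencing a CUI never seen in
    the concept file raise :class:`TerminologyLoadError`; references to CUIs
    whose atoms were all suppressed away are silently dropped.
    """
    atoms, seen_cuis = _parse_concept_file(Path(concept_file))
    if not include_suppressed:
        atoms = [a for a in atoms if not a.suppressed]

    graph = TerminologyGraph()
    for atom in atoms:
        concept = graph.concepts.setdefault(atom.cui, Concept(cui=atom.cui))
        concept.atoms.append(atom)
        graph.code_index.setdefault((atom.source, atom.code), set()).add(atom.cui)
    for concept in graph.concepts.values():
        concept.preferred_label = _preferred_label(concept.atoms)

    unknown: list[str] = []

    def resolve(cui: str, context: str) -> bool:
        if cui in graph.concepts:
            return True
        if cui not in seen_cuis:
            unknown.append(f"{context}: unknown CUI {cui}")
        return False

    raw_relations = _parse_relation_file(Path(relation_file))
    for cui1, rel, rela, cui2, sab in raw_relations:
        ok1 = resolve(cui1, relation_file)
        ok2 = resolve(cui2, relation_file)
        if not (ok1 and ok2):
            continue
        # REL names the second concept's relation to the first: PAR means
        # cui2 is the parent of cui1, CHD the inverse. Other categories keep
        # the file direction (cui1 -> cui2) and are only usable as
        # augmentation edges.
        if rel == "CHD":
            child, parent = cui2, cui1
        else:
            child, parent = cui1, cui2
        category = "hierarchical" if rel in {"PAR", "CHD"} else "other"
        graph.relations.append(
            Relation(child_cui=child, parent_cui=parent, rel=category, rela=rela, source=sab)
        )

    for cui, sty in _parse_semantic_file(Path(semantic_file)):
        if resolve(cui, semantic_file):
            graph.concepts[cui].semantic_types.add(sty)

    if attribute_file is not None:
        for att in _parse_attribute_file(Path(attribute_file)):
            if resolve(att.cui, attribute_file):
                graph.attributes.append(att)
                graph.attribute_index.setdefault((att.name, att.value), set()).add(att.cui)

    if unknown:
        raise TerminologyLoadError(
            "rows reference CUIs absent from the concept file:\n  " + "\n  ".join(unknown)
        )
    return graph


# ---------------------------------------------------------------------------
# Hierarchy view
# ---------------------------------------------------------------------------

def build_hierarchy(
    graph: TerminologyGraph,
    allowed_sources: Iterable[str] = DEFAULT_ALLOWED_SOURCES,
    augmentation_relations: Iterable[tuple[str, str]] = DEFAULT_AUGMENTATION_RELATIONS,
) -> HierarchyView:
    """Derive the restricted parent/child view from a loaded graph.

    An edge is admitted iff (a) it is a hierarchical (PAR/CHD) relation
    asserted by an allowed source, or (b) its (source, rela) pair is
    configured as an augmentation relation. Cycles are preserved as-is and
    handled downstream by condensation.
    """
    allowed = frozenset(allowed_sources)
    augmentation = frozenset(tuple(pair) for pair in augmentation_relations)
    if not allowed:
        raise ConfigurationError("allowed_sources must not be empty")

    parent_edges: dict[str, set[str]] = {}
    child_edges: dict[str, set[str]] = {}
    provenance: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for rel in graph.relations:
        hierarchical = rel.rel == "hierarchical" and rel.source in allowed
        augmented = (rel.source, rel.rela) in augmentation
        if not (hierarchical or augmented):
            continue
        parent_edges.setdefault(rel.child_cui, set()).add(rel.parent_cui)
        child_edges.setdefault(rel.parent_cui, set()).add(rel.child_cui)
        provenance.setdefault((rel.child_cui, rel.parent_cui), set()).add(
            (rel.source, rel.rela)
        )
    return HierarchyView(
        parent_edges=parent_edges,
        child_edges=child_edges,
        provenance=provenance,
        allowed_sources=allowed,
        augmentation_relations=augmentation,
        concepts=frozenset(graph.concepts),
    )


def hierarchy_neighbors(view: HierarchyView, cui: str, direction: str) -> list[str]:
    """Adjacent CUIs of ``cui`` in the view, sorted for determinism."""
    if cui not in view.concepts:
        raise NotFoundError(f"unknown concept {cui}")
    if direction == "parents":
        return sorted(view.parent_edges.get(cui, ()))
    if direction == "children":
        return sorted(view.child_edges.get(cui, ()))
    raise ConfigurationError(f"direction must be 'parents' or 'children', got {direction!r}")


# ---------------------------------------------------------------------------
# Lookups
# ---------------------------------------------------------------------------

def lookup_code(graph: TerminologyGraph, source: str, code: str) -> set[str]:
    """CUIs carrying an atom with the given (source, code); empty if none."""
    return set(graph.code_index.get((source, code), set()))


def lookup_ndc(graph: TerminologyGraph, ndc_value: str) -> set[str]:
    """Resolve a National Drug Code via the attribute table.

    NDCs do not exist as term codes in the concept table, so a dedicated
    attribute lookup (name ``NDC``) is required.
    """
    return set(graph.attribute_index.get(("NDC", ndc_value), set()))


def read_source_config(path) -> tuple[frozenset[str], frozenset[tuple[str, str]]]:
    """Read allowed sources and augmentation relations from a key=value file.

    Recognized keys: ``allowed_sources`` (comma-separated) and
    ``augmentation_relations`` (comma-separated ``SOURCE:RELA`` pairs).
    Missing keys fall back to the package defaults.
    """
    values: Mapping[str, str] = {}
    text = Path(path).read_text(encoding="utf-8")
    values = {
        key.strip(): value.strip()
        for key, _, value in (
            line.partition("=") for line in text.splitlines()
            if line.strip() and not line.strip().startswith("#")
        )
    }
    allowed = DEFAULT_ALLOWED_SOURCES
    augmentation = DEFAULT_AUGMENTATION_RELATIONS
    if "allowed_sources" in values:
        allowed = frozenset(s.strip() for s in values["allowed_sources"].split(",") if s.strip())
    if "augmentation_relations" in values:
        pairs = []
        for chunk in values["augmentation_relations"].split(","):
            chunk = chunk.strip()
            if not chunk:
                continue
            source, _, rela = chunk.partition(":")
            pairs.append((source.strip(), rela.strip()))
        augmentation = frozenset(pairs)
    return allowed, augmentation
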