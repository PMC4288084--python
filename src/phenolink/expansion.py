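"""Query expansion, cycle condensation, and patient-set propagation.

Expansion walks a concept's ancestors in the restricted hierarchy and keeps
those sharing at least one semantic type with the *origin* concept — the
comparison is always against the origin, never the previous node on the
path, and traversal continues *through* excluded ancestors (filter, not
prune): a high-level ancestor remains reachable even when an intermediate
node has a different semantic type.

Because overlapping source hierarchies produce cycles, the view is first
condensed by strongly connected components into a DAG. Propagation then
pushes *sets* of unique patient identifiers (never counts) from descendants
to ancestors, so multiple inheritance and duplicate annotations cannot
inflate the per-concept cohort counts. Negated information is the relative
complement of each concept's propagated set with respect to the universe of
patients carrying at least one propagated annotation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .elt import PatientProfile
from .terminology import HierarchyView, TerminologyGraph

REASON_SEMANTIC_TYPE = "semantic-type mismatch"
REASON_SOURCE_RESTRICTED = "source-restricted edge"


@dataclass(frozen=True)
class ExpansionResult:
    origin_cui: str
    expanded_cuis: frozenset[str]
    excluded_cuis: Mapping[str, str]  # cui -> exclusion reason


@dataclass
class CondensedDag:
    """Quotient of the hierarchy view by its strongly connected components.

    Each supernode is identified by the lexicographically smallest CUI of
    its component, which keeps identifiers stable across runs.
    """

    members: dict[str, frozenset[str]]  # supernode id -> component CUIs
    cui_to_super: dict[str, str]
    parents: dict[str, set[str]]  # supernode -> parent supernodes
    children: dict[str, set[str]]

    def supernodes(self) -> list[str]:
        return sorted(self.members)


@dataclass
class ConceptPatientMap:
    """Per-concept distinct-patient sets after propagation."""

    patients: dict[str, frozenset[str]] = field(default_factory=dict)
    complements: dict[str, frozenset[str]] = field(default_factory=dict)
    orphan_annotations: dict[str, frozenset[str]] = field(default_factory=dict)

    def count(self, cui: str) -> int:
        return len(self.patients.get(cui, ()))

    def complement_count(self, cui: str) -> int:
        return len(self.complements.get(cui, ()))


# ---------------------------------------------------------------------------
# Expansion
# ---------------------------------------------------------------------------

def _ancestors(view: HierarchyView, cui: str) -> set[str]:
    """All strict ancestors of ``cui`` in the view (cycle-safe)."""
    seen: set[str] = set()
    stack = sorted(view.parent_edges.get(cui, ()))
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        stack.extend(view.parent_edges.get(node, set()) - seen)
    seen.discard(cui)
    return seen


def expand_concept(view: HierarchyView, graph: TerminologyGraph, cui: str) -> ExpansionResult:
    """Semantic-type-constrained ancestor expansion of one concept.

    An ancestor is *expanded* iff its semantic-type set intersects the
    origin's; otherwise it is recorded in ``excluded_cuis``. A concept
    without semantic types cannot be compared and yields an empty expansion
    with a warning.
    """
    origin_types = graph.concepts[cui].semantic_types if cui in graph.concepts else set()
    if not origin_types:
        warnings.warn(f"concept {cui} has no semantic types; expansion skipped", stacklevel=2)
        return ExpansionResult(origin_cui=cui, expanded_cuis=frozenset(), excluded_cuis={})

    expanded: set[str] = set()
    excluded: dict[str, str] = {}
    for ancestor in _ancestors(view, cui):
        ancestor_types = (
            graph.concepts[ancestor].semantic_types if ancestor in graph.concepts else set()
        )
        if ancestor_types & origin_types:
            expanded.add(ancestor)
        else:
            excluded[ancestor] = REASON_SEMANTIC_TYPE
    return ExpansionResult(
        origin_cui=cui, expanded_cuis=frozenset(expanded), excluded_cuis=excluded
    )


def expand_patient(
    profile: PatientProfile, view: HierarchyView, graph: TerminologyGraph
) -> PatientProfile:
    """Add every expanded ancestor of the profile's direct annotations.

    A patient annotated with two specific cardiovascular conditions gains
    e.g. their shared "cardiovascular diseases" ancestor, so broad queries
    match specific records. Idempotent: expansion derives only from direct
    annotations.
    """
    for cui in sorted(profile.cuis("direct")):
        if cui not in graph.concepts or not graph.concepts[cui].semantic_types:
            continue
        result = expand_concept(view, graph, cui)
        for ancestor in result.expanded_cuis:
            profile.annotations.add((ancestor, "expanded"))
    return profile


# ---------------------------------------------------------------------------
# Condensation
# ---------------------------------------------------------------------------

def condense_cycles(view: HierarchyView) -> CondensedDag:
    """Collapse strongly connected components into supernodes.

    The quotient graph is guaranteed acyclic; on an already-acyclic view
    every supernode is a singleton and edges are unchanged.
    """
    digraph = nx.DiGraph()
    digraph.add_nodes_from(view.concepts)
    digraph.add_edges_from(view.edges())  # child -> parent

    members: dict[str, frozenset[str]] = {}
    cui_to_super: dict[str, str] = {}
    for component in nx.strongly_connected_components(digraph):
        super_id = min(component)
        members[super_id] = frozenset(component)
        for cui in component:
            cui_to_super[cui] = super_id

    parents: dict[str, set[str]] = {s: set() for s in members}
    children: dict[str, set[str]] = {s: set() for s in members}
    for child, parent in view.edges():
        cs, ps = cui_to_super[child], cui_to_super[parent]
        if cs != ps:
            parents[cs].add(ps)
            children[ps].add(cs)
    return CondensedDag(members=members, cui_to_super=cui_to_super, parents=parents, children=children)


# ---------------------------------------------------------------------------
# Propagation
# ---------------------------------------------------------------------------

def propagate_patients(
    dag: CondensedDag, profiles: Sequence[PatientProfile]
) -> ConceptPatientMap:
    """Propagate unique patient sets from descendants to ancestors.

    ``patients(c)`` is the union of patient identifiers annotated (any
    provenance — direct, expanded, or complement) at ``c`` or any descendant
    supernode; every CUI inherits its supernode's set. Annotations to CUIs
    absent from the DAG are collected into ``orphan_annotations`` and still
    counted at that CUI.
    """
    direct: dict[str, set[str]] = {s: set() for s in dag.members}
    orphans: dict[str, set[str]] = {}
    for profile in profiles:
        for cui, _provenance in profile.annotations:
            super_id = dag.cui_to_super.get(cui)
            if super_id is None:
                orphans.setdefault(cui, set()).add(profile.patient_id)
            else:
                direct[super_id].add(profile.patient_id)

    # Accumulate bottom-up: children before parents.
    quotient = nx.DiGraph()
    quotient.add_nodes_from(dag.members)
    for child, parent_set in dag.parents.items():
        for parent in parent_set:
            quotient.add_edge(child, parent)
    accumulated: dict[str, set[str]] = {}
    for super_id in nx.topological_sort(quotient):
        patients = set(direct[super_id])
        for child in dag.children.get(super_id, ()):
            patients |= accumulated[child]
        accumulated[super_id] = patients

    cpm = ConceptPatientMap()
    for super_id, component in dag.members.items():
        frozen = frozenset(accumulated[super_id])
        for cui in component:
            cpm.patients[cui] = frozen
    for cui, patients in orphans.items():
        cpm.patients[cui] = frozenset(patients)
        cpm.orphan_annotations[cui] = frozenset(patients)
    return cpm


def complement_sets(
    cpm: ConceptPatientMap, profiles: Sequence[PatientProfile] | None = None
) -> ConceptPatientMap:
    """Fill ``complements`` with U \\ patients(c) for every concept.

    The universe U is the set of patients carrying at least one propagated
    annotation (not all patients in the input file).
    """
    universe: set[str] = set()
    for patients in cpm.patients.values():
        universe |= patients
    for cui, patients in cpm.patients.items():
        cpm.complements[cui] = frozenset(universe - patients)
    return cpm
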