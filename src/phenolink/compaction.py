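"""Hub ranking, Steiner-tree compaction, and the three-pane browser view.

A terminology of millions of concepts has no obvious starting points, so
entry points are chosen by ranking concepts on how often they occur across
source vocabularies (source count) and how many children they have
(branching factor) — the working hypothesis being that a concept asserted
by many sources is more relevant for navigation.

The data-driven perspective compacts the condensed hierarchy to only the
concepts actually used in a dataset (the terminals) plus their best
connected ancestors, by approximating a minimum Steiner tree with the
classic shortest-path (nearest-terminal) 2-approximation on the undirected
view with unit edge weights. Terminals with no path into the hierarchy are
orphans, attached directly under a synthetic root so output is always a
single tree.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .errors import ConfigurationError, NotFoundError
from .expansion import CondensedDag, ConceptPatientMap
from .terminology import HierarchyView, TerminologyGraph

#: Reserved identifier of the synthetic root anchoring orphans and forests.
SYNTHETIC_ROOT = "ROOT"


@dataclass(frozen=True)
class HubScore:
    cui: str
    branching_factor: int
    source_count: int

    def sort_key(self) -> tuple:
        return (-self.source_count, -self.branching_factor, self.cui)


@dataclass
class CompactTree:
    """Steiner-approximated tree over the concepts used in a dataset."""

    nodes: set[str] = field(default_factory=set)  # incl. SYNTHETIC_ROOT
    edges: set[tuple[str, str]] = field(default_factory=set)  # (child, parent)
    roots: set[str] = field(default_factory=set)  # component roots under ROOT
    orphans: set[str] = field(default_factory=set)
    members: dict[str, frozenset[str]] = field(default_factory=dict)  # supernode contents

    def parents_of(self, node: str) -> list[str]:
        return sorted(p for c, p in self.edges if c == node)

    def children_of(self, node: str) -> list[str]:
        return sorted(c for c, p in self.edges if p == node)


@dataclass(frozen=True)
class ViewTriple:
    """The three horizontally aligned panes around one active concept."""

    active: str
    parents: tuple[str, ...]
    siblings: tuple[str, ...]
    children: tuple[str, ...]
    counts: dict[str, int]
    has_children: dict[str, bool]


# ---------------------------------------------------------------------------
# Hub ranking and entry points
# ---------------------------------------------------------------------------

def rank_hubs(graph: TerminologyGraph, view: HierarchyView) -> list[HubScore]:
    """Rank all concepts by (source count, branching factor), descending.

    Ties break by CUI so the ordering is deterministic.
    """
    scores = []
    for cui, concept in graph.concepts.items():
        scores.append(
            HubScore(
                cui=cui,
                branching_factor=len(view.child_edges.get(cui, ())),
                source_count=len({a.source for a in concept.atoms}),
            )
        )
    return sorted(scores, key=HubScore.sort_key)


def select_entry_points(
    graph: TerminologyGraph,
    view: HierarchyView,
    per_source_n: int,
    sources: Sequence[str],
) -> set[str]:
    """Choose browser entry points from the top-ranked hubs of each source.

    Takes the ``per_source_n`` best-ranked concepts per listed source
    (overlapping selections collapse in the union), induces the hierarchy
    subgraph on the union, and returns the nodes with no parent inside it.
    """
    if per_source_n <= 0:
        raise ConfigurationError("per_source_n must be positive")
    ranking = rank_hubs(graph, view)
    selected: set[str] = set()
    for source in sources:
        with_source = [
            h.cui
            for h in ranking
            if any(a.source == source for a in graph.concepts[h.cui].atoms)
        ]
        selected.update(with_source[:per_source_n])
    return {
        cui
        for cui in selected
        if not (view.parent_edges.get(cui, set()) & selected)
    }


# ---------------------------------------------------------------------------
# Steiner compaction
# ---------------------------------------------------------------------------

def _steiner_component(undirected: nx.Graph, terminals: list[str]) -> tuple[set[str], set[frozenset]]:
    """Shortest-path Steiner heuristic within one connected component.

    Grow a tree from the lexicographically smallest terminal, repeatedly
    attaching the nearest unconnected terminal along a shortest path (unit
    weights). Ties break toward smaller CUIs, keeping output deterministic.
    """
    tree_nodes: set[str] = {terminals[0]}
    tree_edges: set[frozenset] = set()
    remaining = set(terminals[1:])
    while remaining:
        # Multi-source BFS from the current tree.
        dist: dict[str, int] = {n: 0 for n in tree_nodes}
        back: dict[str, str] = {}
        frontier = sorted(tree_nodes)
        found: str | None = None
        while frontier and found is None:
            nxt: list[str] = []
            for node in frontier:
                for neighbor in sorted(undirected.neighbors(node)):
                    if neighbor in dist:
                        continue
                    dist[neighbor] = dist[node] + 1
                    back[neighbor] = node
                    if neighbor in remaining and found is None:
                        found = neighbor
                    nxt.append(neighbor)
            frontier = nxt
        assert found is not None, "terminal unreachable within its own component"
        node = found
        while node not in tree_nodes:
            prev = back[node]
            tree_edges.add(frozenset((node, prev)))
            tree_nodes.add(node)
            node = prev
        remaining.discard(found)
    return tree_nodes, tree_edges


def _orient_component(
    dag: CondensedDag, tree_nodes: set[str], tree_edges: set[frozenset]
) -> tuple[str, set[tuple[str, str]]]:
    """Root and orient one undirected component tree.

    The root is the tree node with no hierarchy parent inside the tree
    (lexicographically smallest when several qualify); edges are then
    directed child -> parent away from the root.
    """
    candidates = sorted(
        n for n in tree_nodes if not (dag.parents.get(n, set()) & tree_nodes)
    )
    root = candidates[0] if candidates else min(tree_nodes)
    adjacency: dict[str, set[str]] = {n: set() for n in tree_nodes}
    for edge in tree_edges:
        a, b = sorted(edge)
        adjacency[a].add(b)
        adjacency[b].add(a)
    oriented: set[tuple[str, str]] = set()
    seen = {root}
    frontier = [root]
    while frontier:
        parent = frontier.pop()
        for child in sorted(adjacency[parent] - seen):
            oriented.add((child, parent))
            seen.add(child)
            frontier.append(child)
    return root, oriented


def compact_tree(dag: CondensedDag, terminals: Sequence[str]) -> CompactTree:
    """Compact the condensed hierarchy to a tree over ``terminals``.

    Terminals are mapped to their supernodes; each connected group of
    terminals is joined by the Steiner heuristic and rooted at its topmost
    node. Terminals absent from the DAG, or isolated in it, are orphans
    placed directly under the synthetic root. An empty terminal set yields
    an empty tree.
    """
    tree = CompactTree()
    if not terminals:
        return tree
    tree.nodes.add(SYNTHETIC_ROOT)

    super_terminals: set[str] = set()
    for cui in terminals:
        super_id = dag.cui_to_super.get(cui)
        if super_id is None:
            tree.orphans.add(cui)
        else:
            super_terminals.add(super_id)

    undirected = nx.Graph()
    undirected.add_nodes_from(dag.members)
    for child, parent_set in dag.parents.items():
        for parent in parent_set:
            undirected.add_edge(child, parent)

    by_component: dict[int, list[str]] = {}
    component_of: dict[str, int] = {}
    for idx, component in enumerate(nx.connected_components(undirected)):
        for node in component:
            component_of[node] = idx
    for terminal in sorted(super_terminals):
        if undirected.degree(terminal) == 0:
            tree.orphans.add(terminal)
            continue
        by_component.setdefault(component_of[terminal], []).append(terminal)

    for _idx, component_terminals in sorted(by_component.items()):
        nodes, edges = _steiner_component(undirected, sorted(component_terminals))
        root, oriented = _orient_component(dag, nodes, edges)
        tree.nodes |= nodes
        tree.edges |= oriented
        tree.roots.add(root)
        tree.edges.add((root, SYNTHETIC_ROOT))

    for orphan in tree.orphans:
        tree.nodes.add(orphan)
        tree.edges.add((orphan, SYNTHETIC_ROOT))

    for node in tree.nodes:
        if node == SYNTHETIC_ROOT:
            continue
        tree.members[node] = dag.members.get(node, frozenset({node}))
    return tree


# ---------------------------------------------------------------------------
# Browser view
# ---------------------------------------------------------------------------

def browser_view(
    view: HierarchyView,
    cui: str,
    counts: ConceptPatientMap | None = None,
    perspective: str = "full",
    compact: CompactTree | None = None,
) -> ViewTriple:
    """Build the parents / active+siblings / children panes around ``cui``.

    With ``perspective="full"`` the panes come from the restricted
    hierarchy; with ``"compact"`` they come from a :class:`CompactTree`
    (pass it as ``compact``). Every displayed node carries its propagated
    patient count and a flag marking concepts with children (the "+"
    convention of the browser).
    """
    if perspective == "compact":
        if compact is None:
            raise ConfigurationError("compact perspective requires a CompactTree")
        if cui not in compact.nodes:
            raise NotFoundError(
                f"{cui} is not part of the compact perspective; try the full perspective"
            )
        parents = [p for p in compact.parents_of(cui) if p != SYNTHETIC_ROOT]
        children = compact.children_of(cui)
        sibling_set = {c for p in parents for c in compact.children_of(p)}
        all_children = lambda node: compact.children_of(node)  # noqa: E731
    elif perspective == "full":
        if cui not in view.concepts:
            raise NotFoundError(f"unknown concept {cui}")
        parents = sorted(view.parent_edges.get(cui, ()))
        children = sorted(view.child_edges.get(cui, ()))
        sibling_set = {c for p in parents for c in view.child_edges.get(p, ())}
        all_children = lambda node: view.child_edges.get(node, ())  # noqa: E731
    else:
        raise ConfigurationError(f"unknown perspective {perspective!r}")

    sibling_set.add(cui)
    siblings = sorted(sibling_set)
    shown = set(parents) | set(siblings) | set(children)
    count_map = {
        node: (counts.count(node) if counts is not None else 0) for node in sorted(shown)
    }
    has_children = {node: bool(all_children(node)) for node in sorted(shown)}
    return ViewTriple(
        active=cui,
        parents=tuple(parents),
        siblings=tuple(siblings),
        children=tuple(children),
        counts=count_map,
        has_children=has_children,
    )
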