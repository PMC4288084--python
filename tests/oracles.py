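"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (exhaustive reachability scans,
subset enumeration) and shares no code with the package's algorithms.
"""
from __future__ import annotations

import itertools

from phenolink import load_terminology


def load_fixture(files, directory, include_suppressed=False):
    """Materialize in-memory fixture files and load them."""
    paths = files.write(directory)
    return load_terminology(
        paths["concepts"],
        paths["relations"],
        paths["semantic_types"],
        paths.get("attributes"),
        include_suppressed=include_suppressed,
    )


def reachable_ancestors(parent_edges: dict, start: str) -> set:
    """All nodes reachable from ``start`` by repeatedly following parents."""
    seen = set()
    frontier = [start]
    while frontier:
        node = frontier.pop()
        for parent in parent_edges.get(node, set()):
            if parent not in seen:
                seen.add(parent)
                frontier.append(parent)
    seen.discard(start)
    return seen


def brute_expansion(view, graph, origin: str) -> set:
    """Typed-ancestor closure: ancestors sharing a semantic type with origin."""
    origin_types = graph.concepts[origin].semantic_types
    out = set()
    for ancestor in reachable_ancestors(view.parent_edges, origin):
        if graph.concepts[ancestor].semantic_types & origin_types:
            out.add(ancestor)
    return out


def brute_scc(nodes, edges) -> set:
    """Strongly connected components by pairwise reachability."""
    forward = {}
    for a, b in edges:
        forward.setdefault(a, set()).add(b)

    def reach(start):
        seen = {start}
        frontier = [start]
        while frontier:
            n = frontier.pop()
            for m in forward.get(n, ()):  # noqa: B007
                if m not in seen:
                    seen.add(m)
                    frontier.append(m)
        return seen

    reachability = {n: reach(n) for n in nodes}
    components = set()
    for n in nodes:
        component = frozenset(
            m for m in nodes if m in reachability[n] and n in reachability[m]
        )
        components.add(component)
    return components


def brute_propagation(parent_edges: dict, nodes, annotations: dict) -> dict:
    """patients(c) = all patients annotated at any node that reaches c.

    ``annotations`` maps cui -> set of patient ids. Works directly on the
    cyclic child->parent graph via exhaustive reachability, without any
    condensation.
    """
    result = {}
    for c in nodes:
        patients = set(annotations.get(c, set()))
        for a in nodes:
            if a == c:
                continue
            if c in reachable_ancestors(parent_edges, a):
                patients |= annotations.get(a, set())
        result[c] = patients
    return result


def brute_steiner_optimum(nodes, undirected_edges, terminals) -> int | None:
    """Minimum number of edges of a connected subgraph spanning terminals.

    Exhaustive: tries every superset of the terminal set, smallest first.
    Returns None when the terminals cannot be connected at all.
    """
    adjacency = {}
    for a, b in undirected_edges:
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    terminals = set(terminals)
    others = sorted(set(nodes) - terminals)

    def connected(subset):
        subset = set(subset)
        start = next(iter(subset))
        seen = {start}
        frontier = [start]
        while frontier:
            n = frontier.pop()
            for m in adjacency.get(n, ()):  # noqa: B007
                if m in subset and m not in seen:
                    seen.add(m)
                    frontier.append(m)
        return seen == subset

    if not terminals:
        return 0
    for extra in range(len(others) + 1):
        for combo in itertools.combinations(others, extra):
            subset = terminals | set(combo)
            if connected(subset):
                # A tree over the subset has |subset| - 1 edges; a connected
                # induced subgraph always contains a spanning tree.
                return len(subset) - 1
    return None
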