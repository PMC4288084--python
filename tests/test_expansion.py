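"""Typed query expansion, cycle condensation, and patient-set propagation."""
import random

import pytest

from phenolink import (
    FixtureSpec,
    PatientProfile,
    build_hierarchy,
    complement_sets,
    condense_cycles,
    expand_concept,
    expand_patient,
    generate_mini_terminology,
    propagate_patients,
)

from oracles import brute_expansion, brute_propagation, brute_scc, load_fixture


def _random_case(tmp_path, seed, cycles=0, n=30):
    spec = FixtureSpec(
        n_concepts=n,
        n_sources=2,
        multi_parent_fraction=0.3,
        cycle_count=cycles,
        seed=seed,
    )
    graph = load_fixture(generate_mini_terminology(spec), tmp_path / f"case{seed}")
    view = build_hierarchy(graph, allowed_sources={"SAB1", "SAB2"})
    return graph, view


# ---------------------------------------------------------------------------
# Expansion
# ---------------------------------------------------------------------------

def test_thrombosis_expansion_filters_by_semantic_type(view, graph):
    """Ancestors keep only concepts typed like the origin; the differently
    typed intermediate is excluded but still traversed through."""
    result = expand_concept(view, graph, "C0149871")
    assert "C0040046" in result.expanded_cuis  # Thrombophlebitis, same type
    assert "C0012634" in result.expanded_cuis  # Disease, same type
    assert "C0042487" not in result.expanded_cuis  # Venous Thrombosis
    assert result.excluded_cuis["C0042487"] == "semantic-type mismatch"
    # filter-not-prune: this ancestor is reachable only through the
    # excluded node, yet it is expanded
    assert "C0042373" in result.expanded_cuis


def test_expansion_of_parentless_concept_is_empty(view, graph):
    result = expand_concept(view, graph, "C0012634")
    assert result.expanded_cuis == frozenset()


def test_concept_without_semantic_types_warns(tmp_path):
    (tmp_path / "c.rrf").write_text(
        "C1|ENG|A1|SAB1|PT|1|child|N\nC2|ENG|A2|SAB1|PT|2|parent|N\n"
    )
    (tmp_path / "r.rrf").write_text("C1|PAR|isa|C2|SAB1\n")
    (tmp_path / "empty").write_text("")
    from phenolink import load_terminology

    g = load_terminology(tmp_path / "c.rrf", tmp_path / "r.rrf", tmp_path / "empty")
    v = build_hierarchy(g, allowed_sources={"SAB1"})
    with pytest.warns(UserWarning):
        result = expand_concept(v, g, "C1")
    assert result.expanded_cuis == frozenset()


@pytest.mark.parametrize("seed", range(20))
def test_expansion_matches_typed_ancestor_oracle(tmp_path, seed):
    """Random graphs: expansion equals the brute-force DFS-closure filter."""
    graph, view = _random_case(tmp_path, seed)
    for cui in sorted(graph.concepts):
        result = expand_concept(view, graph, cui)
        assert set(result.expanded_cuis) == brute_expansion(view, graph, cui)


def test_patient_expansion_adds_shared_cardiovascular_ancestor(view, graph):
    profile = PatientProfile(
        patient_id="p1",
        annotations={("C0149871", "direct"), ("C0155626", "direct")},
    )
    expand_patient(profile, view, graph)
    assert ("C0007222", "expanded") in profile.annotations  # cardiovascular diseases
    once = set(profile.annotations)
    expand_patient(profile, view, graph)
    assert profile.annotations == once  # fixpoint


def test_expanding_empty_profile_is_a_no_op(view, graph):
    profile = PatientProfile(patient_id="p0")
    expand_patient(profile, view, graph)
    assert profile.annotations == set()


# ---------------------------------------------------------------------------
# Condensation
# ---------------------------------------------------------------------------

def test_acyclic_view_condenses_to_singletons(view, dag):
    assert all(len(members) == 1 for members in dag.members.values())
    assert set(dag.cui_to_super.values()) == set(dag.members)
    edges = {(c, p) for c, parents in dag.parents.items() for p in parents}
    assert edges == set(view.edges())


def test_two_cycle_collapses_to_one_supernode(tmp_path):
    (tmp_path / "c.rrf").write_text(
        "C1|ENG|A1|SAB1|PT|1|a|N\nC2|ENG|A2|SAB1|PT|2|b|N\n"
    )
    (tmp_path / "r.rrf").write_text("C1|PAR|isa|C2|SAB1\nC2|PAR|isa|C1|SAB1\n")
    (tmp_path / "empty").write_text("")
    from phenolink import load_terminology

    g = load_terminology(tmp_path / "c.rrf", tmp_path / "r.rrf", tmp_path / "empty")
    dag = condense_cycles(build_hierarchy(g, allowed_sources={"SAB1"}))
    assert dag.members == {"C1": frozenset({"C1", "C2"})}
    assert dag.parents["C1"] == set()


@pytest.mark.parametrize("seed", range(15))
def test_condensation_matches_pairwise_reachability_oracle(tmp_path, seed):
    graph, view = _random_case(tmp_path, seed, cycles=seed % 5, n=40)
    dag = condense_cycles(view)
    assert set(dag.members.values()) == brute_scc(view.concepts, list(view.edges()))
    # quotient is acyclic: topological order must exist
    import networkx as nx

    quotient = nx.DiGraph()
    quotient.add_nodes_from(dag.members)
    quotient.add_edges_from(
        (c, p) for c, parents in dag.parents.items() for p in parents
    )
    assert nx.is_directed_acyclic_graph(quotient)


# ---------------------------------------------------------------------------
# Propagation
# ---------------------------------------------------------------------------

def _propagate(view, assignments):
    dag = condense_cycles(view)
    profiles = [
        PatientProfile(patient_id=pid, annotations={(c, "direct") for c in cuis})
        for pid, cuis in assignments.items()
    ]
    return complement_sets(propagate_patients(dag, profiles), profiles)


def test_chain_propagates_to_ancestor(tmp_path):
    (tmp_path / "c.rrf").write_text(
        "CB|ENG|A1|SAB1|PT|1|b|N\nCA|ENG|A2|SAB1|PT|2|a|N\n"
    )
    (tmp_path / "r.rrf").write_text("CB|PAR|isa|CA|SAB1\n")
    (tmp_path / "empty").write_text("")
    from phenolink import load_terminology

    g = load_terminology(tmp_path / "c.rrf", tmp_path / "r.rrf", tmp_path / "empty")
    cpm = _propagate(build_hierarchy(g, allowed_sources={"SAB1"}), {"p1": {"CB"}})
    assert cpm.count("CA") == cpm.count("CB") == 1


def test_multi_parent_paths_do_not_inflate_counts(view):
    """One bronchitis patient counts once at the shared ancestor even though
    two parent paths lead there."""
    cpm = _propagate(view, {"p1": {"C0006277"}})
    assert cpm.count("C0021311") == 1  # infection
    assert cpm.count("C0006261") == 1  # bronchial disease
    assert cpm.count("C0012634") == 1  # shared ancestor: 1, not 2


def test_duplicate_annotations_change_nothing(view):
    once = _propagate(view, {"p1": {"C0006277"}})
    profile = PatientProfile(
        patient_id="p1", annotations={("C0006277", "direct"), ("C0006277", "expanded")}
    )
    dag = condense_cycles(view)
    twice = complement_sets(propagate_patients(dag, [profile]), [profile])
    assert once.patients == twice.patients


def test_annotation_to_concept_outside_dag_is_reported_as_orphan(view):
    cpm = _propagate(view, {"p1": {"CX999999"}})  # not in the terminology
    assert cpm.orphan_annotations == {"CX999999": frozenset({"p1"})}
    assert cpm.count("CX999999") == 1  # still counted at that concept


def test_complements_partition_the_universe(view):
    cpm = _propagate(view, {"p1": {"C0006277"}, "p2": {"C0149871"}, "p3": {"C0149871"}})
    universe = {"p1", "p2", "p3"}
    for cui in cpm.patients:
        patients = cpm.patients[cui]
        complement = cpm.complements[cui]
        assert patients | complement == universe
        assert patients & complement == set()


def test_concept_annotated_by_everyone_has_empty_complement(view):
    cpm = _propagate(view, {"p1": {"C0149871"}, "p2": {"C0149871"}})
    assert cpm.complements["C0149871"] == frozenset()
    assert cpm.complements["C0006277"] == {"p1", "p2"}  # annotated by none


@pytest.mark.parametrize("seed", range(25))
def test_propagation_matches_descendant_closure_oracle(tmp_path, seed):
    """Random cyclic graphs and annotations: counts and complements equal
    the brute-force reachability computation; monotone along every edge."""
    rng = random.Random(seed)
    graph, view = _random_case(tmp_path, seed, cycles=rng.randrange(4), n=rng.randrange(10, 50))
    cuis = sorted(graph.concepts)
    patients = [f"p{i}" for i in range(rng.randrange(1, 20))]
    assignments = {
        pid: {rng.choice(cuis) for _ in range(rng.randrange(1, 5))} for pid in patients
    }
    cpm = _propagate(view, assignments)

    annotations = {}
    for pid, chosen in assignments.items():
        for cui in chosen:
            annotations.setdefault(cui, set()).add(pid)
    expected = brute_propagation(view.parent_edges, cuis, annotations)
    universe = set().union(*expected.values()) if expected else set()
    for cui in cuis:
        assert set(cpm.patients[cui]) == expected[cui], cui
        assert set(cpm.complements[cui]) == universe - expected[cui], cui
    for child, parent in view.edges():
        assert cpm.patients[parent] >= cpm.patients[child]
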