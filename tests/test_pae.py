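"""Parsimony engine: Fitch scoring, tree search, consensus, Newick."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endemicity import (
    AreaTree,
    IncidenceMatrix,
    exhaustive_search,
    fitch_length,
    heuristic_search,
    majority_rule_consensus,
    simulate_area_cladogram,
    stepwise_addition,
    tbr_search,
    write_newick,
)
from endemicity.incidence import OUTGROUP_LABEL
from endemicity.trees import enumerate_topologies

from _oracles import (
    brute_force_matrix_length,
    dendropy_majority_clades,
    newick_clades,
)
from conftest import random_matrix


def quartet_tree(labels=("A", "B", "C", "D")):
    """((A,B),(C,D)) with the outgroup attached to the central edge."""
    adj = {0: [5], 1: [5], 2: [6], 3: [6], 4: [7],
           5: [0, 1, 7], 6: [2, 3, 7], 7: [4, 5, 6]}
    return AreaTree(tuple(labels) + (OUTGROUP_LABEL,), adj)


# ---------------------------------------------------------------------------
# Fitch length
# ---------------------------------------------------------------------------

def test_fitch_constant_and_synapomorphic_characters():
    tree = quartet_tree()
    absent = IncidenceMatrix(("s",), tuple("ABCD"), np.array([[0, 0, 0, 0]]))
    cherry = IncidenceMatrix(("s",), tuple("ABCD"), np.array([[1, 1, 0, 0]]))
    scattered = IncidenceMatrix(("s",), tuple("ABCD"), np.array([[1, 0, 1, 0]]))
    assert fitch_length(tree, absent) == 0
    assert fitch_length(tree, cherry) == 1
    assert fitch_length(tree, scattered) == 2  # two independent gains


def test_fitch_label_mismatch_lists_symmetric_difference():
    tree = quartet_tree()
    m = IncidenceMatrix(("s",), ("A", "B", "C", "E"), np.array([[1, 0, 1, 0]]))
    with pytest.raises(ValueError, match="D.*E|E.*D"):
        fitch_length(tree, m)


@given(seed=st.integers(0, 10**6), n_areas=st.integers(3, 7))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_fitch_matches_bruteforce_enumeration(seed, n_areas):
    """Fitch equals the minimum over all internal state assignments."""
    rng = np.random.default_rng(seed)
    m = random_matrix(rng, 8, n_areas)
    tree = simulate_area_cladogram(n_areas, seed=seed,
                                   labels=m.area_ids)
    assert fitch_length(tree, m) == brute_force_matrix_length(tree, m)


@given(seed=st.integers(0, 10**6))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_fitch_invariant_under_row_and_leaf_permutation(seed):
    rng = np.random.default_rng(seed)
    m = random_matrix(rng, 10, 6)
    tree = simulate_area_cladogram(6, seed=seed, labels=m.area_ids)
    base = fitch_length(tree, m)
    # permute species rows
    perm = rng.permutation(m.n_species)
    m2 = IncidenceMatrix(tuple(np.array(m.species_ids)[perm]), m.area_ids,
                         m.presence[perm])
    assert fitch_length(tree, m2) == base
    # permute area columns (tree labels unchanged; lookup is by label)
    aperm = rng.permutation(m.n_areas)
    m3 = IncidenceMatrix(m.species_ids, tuple(np.array(m.area_ids)[aperm]),
                         m.presence[:, aperm])
    assert fitch_length(tree, m3) == base


# ---------------------------------------------------------------------------
# stepwise addition
# ---------------------------------------------------------------------------

def test_stepwise_three_areas_and_determinism(rng):
    m = random_matrix(rng, 6, 3)
    t1 = stepwise_addition(m, seed=7)
    t2 = stepwise_addition(m, seed=7)
    assert t1.clades() == t2.clades()
    assert t1.n_leaves == 4


def test_stepwise_rejects_too_few_areas():
    m = IncidenceMatrix(("s1",), ("A", "B"), np.array([[1, 0]]))
    with pytest.raises(ValueError, match="3 areas"):
        stepwise_addition(m, seed=0)


def test_stepwise_nested_species_reach_analytic_minimum():
    """Perfectly nested ranges: one gain per informative species."""
    # areas A..F; species ranges are nested prefixes of size >= 2
    n_areas = 6
    areas = tuple("ABCDEF")
    rows = [[1] * k + [0] * (n_areas - k) for k in range(2, n_areas + 1)]
    m = IncidenceMatrix(tuple(f"s{k}" for k in range(len(rows))), areas,
                        np.array(rows))
    tree = stepwise_addition(m, order=list(areas), seed=0)
    assert fitch_length(tree, m) == len(rows)


# ---------------------------------------------------------------------------
# exhaustive enumeration and TBR
# ---------------------------------------------------------------------------

def test_enumeration_counts_double_factorial():
    assert enumerate_topologies(4, lambda adj: None) == 3
    assert enumerate_topologies(6, lambda adj: None) == 105


def test_exhaustive_refuses_large_ingroup(rng):
    m = random_matrix(rng, 5, 10)
    with pytest.raises(ValueError, match="9 areas"):
        exhaustive_search(m)


def test_exhaustive_minimum_bounded_by_occupied_species(rng):
    m = random_matrix(rng, 12, 5)
    res = exhaustive_search(m)
    occupied = int((m.presence.sum(axis=1) >= 1).sum())
    assert res.best_score >= occupied
    assert res.n_examined == 105  # 5 areas + outgroup = 6 leaves: (2*6-5)!!


def test_tbr_never_worse_than_start_and_keep_one(rng):
    m = random_matrix(rng, 15, 6)
    start = stepwise_addition(m, seed=3)
    res = tbr_search(start, m, keep=1)
    assert len(res.trees) == 1
    assert res.best_score <= fitch_length(start, m)


def test_tbr_from_optimal_tree_matches_exhaustive(rng):
    m = random_matrix(rng, 12, 5)
    ex = exhaustive_search(m)
    res = tbr_search(ex.trees[0], m, keep=50)
    assert res.best_score == ex.best_score


# ---------------------------------------------------------------------------
# heuristic search
# ---------------------------------------------------------------------------

def test_heuristic_deterministic_rerun(rng):
    m = random_matrix(rng, 20, 6)
    a = heuristic_search(m, replicates=2, keep=10, seed=5)
    b = heuristic_search(m, replicates=2, keep=10, seed=5)
    assert a.best_score == b.best_score
    assert [t.newick() for t in a.trees] == [t.newick() for t in b.trees]
    assert a.replicate_scores == b.replicate_scores


def test_heuristic_pooled_best_not_worse_than_any_replicate(rng):
    m = random_matrix(rng, 20, 6)
    res = heuristic_search(m, replicates=5, keep=10, seed=9)
    assert res.best_score == min(res.replicate_scores)
    assert all(s >= res.best_score for s in res.scores)


def test_adding_clade_species_raises_score_by_one_topology_neutral():
    """A new synapomorphy of an existing optimal clade adds exactly 1 step;
    a single-area endemic adds 1 to every tree."""
    rng = np.random.default_rng(4)
    tree = simulate_area_cladogram(6, seed=2)
    areas = tree.area_labels
    clades = sorted(tree.clades(), key=lambda c: sorted(c))
    rows = []
    for c in clades:  # one species per true clade: tree is the unique optimum
        rows.append([1 if a in c else 0 for a in areas])
    m = IncidenceMatrix(tuple(f"s{i}" for i in range(len(rows))), areas,
                        np.array(rows))
    ex = exhaustive_search(m)
    assert ex.best_score == len(rows)
    base_opt = {t.clades() for t in ex.trees}
    # duplicate one clade-species
    m2 = IncidenceMatrix(m.species_ids + ("extra",), areas,
                         np.vstack([m.presence, m.presence[0]]))
    ex2 = exhaustive_search(m2)
    assert ex2.best_score == ex.best_score + 1
    assert {t.clades() for t in ex2.trees} == base_opt
    # single-area endemic is topology-neutral too
    endemic = np.zeros(len(areas), dtype=int)
    endemic[0] = 1
    m3 = IncidenceMatrix(m.species_ids + ("endemic",), areas,
                         np.vstack([m.presence, endemic]))
    ex3 = exhaustive_search(m3)
    assert ex3.best_score == ex.best_score + 1
    assert {t.clades() for t in ex3.trees} == base_opt


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def test_consensus_of_identical_trees_is_that_tree_at_full_support():
    t = simulate_area_cladogram(6, seed=1)
    cons = majority_rule_consensus([t, t, t])
    assert set(cons.clades()) == set(t.clades())
    assert all(s == 100.0 for s in cons.clades().values())


def test_consensus_of_conflicting_quartets_is_star():
    t1 = quartet_tree()  # AB|CD
    adj = {0: [5], 2: [5], 1: [6], 3: [6], 4: [7],
           5: [0, 2, 7], 6: [1, 3, 7], 7: [4, 5, 6]}
    t2 = AreaTree(("A", "B", "C", "D", OUTGROUP_LABEL), adj)  # AC|BD
    cons = majority_rule_consensus([t1, t2])
    assert cons.clades() == {}
    assert cons.newick().count("(") == 1  # single polytomy


def test_consensus_two_thirds_support_rounded():
    t1 = quartet_tree()
    t2 = quartet_tree()
    adj = {0: [5], 2: [5], 1: [6], 3: [6], 4: [7],
           5: [0, 2, 7], 6: [1, 3, 7], 7: [4, 5, 6]}
    t3 = AreaTree(("A", "B", "C", "D", OUTGROUP_LABEL), adj)
    cons = majority_rule_consensus([t1, t2, t3])
    assert cons.clades() == {frozenset("AB"): 66.7, frozenset("CD"): 66.7}


def test_consensus_rejects_mismatched_leaf_sets():
    t1 = quartet_tree()
    t2 = quartet_tree(labels=("A", "B", "C", "E"))
    with pytest.raises(ValueError, match="mismatched"):
        majority_rule_consensus([t1, t2])


@given(seed=st.integers(0, 10**6))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_consensus_clades_pairwise_compatible_and_match_dendropy(seed):
    rng = np.random.default_rng(seed)
    trees = [simulate_area_cladogram(7, seed=[seed, k]) for k in range(5)]
    cons = majority_rule_consensus(trees)
    clades = list(cons.clades())
    for i, a in enumerate(clades):
        for b in clades[i + 1:]:
            x = a & b
            assert x in (frozenset(), a, b)
    oracle = dendropy_majority_clades([t.newick() for t in trees],
                                      OUTGROUP_LABEL)
    assert frozenset(clades) == oracle


# ---------------------------------------------------------------------------
# Newick output
# ---------------------------------------------------------------------------

def test_newick_single_line_and_roundtrip():
    t = simulate_area_cladogram(5, seed=8)
    nwk = write_newick(t)
    assert nwk.endswith(";") and "\n" not in nwk
    assert newick_clades(nwk, OUTGROUP_LABEL) == t.clades()


def test_newick_quotes_spaced_labels():
    t = simulate_area_cladogram(3, seed=0,
                                labels=("Amazonas Lowlands", "Chaco", "Llanos"))
    assert "'Amazonas Lowlands'" in write_newick(t)


@given(seed=st.integers(0, 10**6), n_areas=st.integers(4, 9))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_newick_roundtrip_preserves_topology(seed, n_areas):
    t = simulate_area_cladogram(n_areas, seed=seed)
    assert newick_clades(t.newick(), OUTGROUP_LABEL) == t.clades()
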