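import numpy as np
import pytest

import cladistron as cl
from cladistron.parsimony import MatrixScorer
from cladistron.search import (
    SearchConfig,
    branch_and_bound,
    collapse_zero_branches,
    enumerate_full_topologies,
    exhaustive_search,
    exists_strictly_better,
    heuristic_search,
    k_sweep,
)

from conftest import adjacency_of, random_mixed_matrix


def test_topology_counts():
    sim4 = random_mixed_matrix(1, n_taxa=4)
    assert enumerate_full_topologies(sim4.matrix, lambda a, s: None) == 3
    sim6 = random_mixed_matrix(2, n_taxa=6)
    assert enumerate_full_topologies(sim6.matrix, lambda a, s: None) == 105


def test_exhaustive_taxon_limit():
    sim = random_mixed_matrix(3, n_taxa=8)
    big = cl.simulate_matrix(cl.simulate_tree(11, seed=1),
                             cl.SimConfig(n_taxa=11, n_binary=5, n_ordered=3,
                                          n_unordered=1, seed=1))
    with pytest.raises(ValueError, match="exhaustive"):
        exhaustive_search(big.matrix, SearchConfig(mode="exhaustive"))
    # 8 taxa is fine
    exhaustive_search(sim.matrix, SearchConfig(mode="exhaustive"))


@pytest.mark.parametrize("criterion,k", [("equal", None), ("implied", 3.0)])
def test_branch_and_bound_equals_exhaustive(criterion, k):
    """B&B returns exactly the exhaustive MPC set (a reduced version of the
    full 200-matrix acceptance check)."""
    for seed in range(12):
        sim = random_mixed_matrix(400 + seed)
        cfg = dict(criterion=criterion, k=k or 3.0, collapse_rule="none")
        ex = exhaustive_search(sim.matrix, SearchConfig(mode="exhaustive", **cfg))
        bb = branch_and_bound(sim.matrix, SearchConfig(**cfg))
        assert bb.canonical == ex.canonical
        assert bb.best_score.length == ex.best_score.length


def test_heuristic_finds_optimum_on_small_instances():
    hits = 0
    for seed in range(15):
        sim = random_mixed_matrix(500 + seed, n_taxa=8)
        bb = branch_and_bound(sim.matrix, SearchConfig())
        h = heuristic_search(
            sim.matrix, SearchConfig(mode="heuristic", n_replicates=5, seed=seed)
        )
        hits += h.best_score.length == bb.best_score.length
    assert hits >= 14


def test_homoplasy_free_unique_mpc_is_generating_tree():
    tree = cl.simulate_tree(8, seed=31)
    pm = cl.perfect_matrix(tree, 2)
    res = branch_and_bound(pm, SearchConfig())
    assert res.n_mpcs == 1
    assert res.trees[0].bipartitions() == tree.bipartitions()
    assert res.best_score.ci == 1.0


def test_three_taxon_degenerate_input():
    sim = random_mixed_matrix(6, n_taxa=3)
    res = heuristic_search(sim.matrix, SearchConfig(mode="heuristic"))
    assert res.n_mpcs == 1  # the unique unrooted topology


def test_condensation_idempotent(small_sim):
    scorer = MatrixScorer(small_sim.matrix)
    res = branch_and_bound(small_sim.matrix, SearchConfig(collapse_rule="none"))
    for t in res.trees[:5]:
        adj = adjacency_of(t, small_sim.matrix)
        once = collapse_zero_branches(adj, scorer)
        twice = collapse_zero_branches(once, scorer)
        labels = small_sim.matrix.taxa
        assert cl.trees.canonical_adjacency(once, labels) == \
            cl.trees.canonical_adjacency(twice, labels)


def test_collapse_rule_none_gives_at_least_as_many_mpcs(small_sim):
    res_none = branch_and_bound(small_sim.matrix, SearchConfig(collapse_rule="none"))
    res_collapse = branch_and_bound(
        small_sim.matrix, SearchConfig(collapse_rule="min_length_zero")
    )
    assert res_none.n_mpcs >= res_collapse.n_mpcs


def test_seeded_heuristic_is_reproducible(small_sim):
    cfg = SearchConfig(mode="heuristic", n_replicates=4, seed=17)
    a = heuristic_search(small_sim.matrix, cfg)
    b = heuristic_search(small_sim.matrix, cfg)
    assert a.canonical == b.canonical
    assert a.best_score.length == b.best_score.length


def test_k_sweep_limit_matches_equal_weights(small_sim):
    eq = branch_and_bound(small_sim.matrix, SearchConfig(criterion="equal"))
    sweep = k_sweep(small_sim.matrix, [1.0, 3.0, 1e6],
                    SearchConfig(criterion="implied", mode="branch_and_bound"))
    # at huge K the implied optima are equal-weights optima (exact rational
    # tie-breaking can still thin equal-length ties, hence subset)
    assert sweep.results[1e6].canonical <= eq.canonical
    assert sweep.results[1e6].best_score.length == eq.best_score.length
    # intervals partition the grid
    ks = [k for a, b, _ in sweep.intervals for k in (a, b)]
    assert ks[0] == 1.0 and ks[-1] == 1e6


def test_k_sweep_rejects_empty_grid(small_sim):
    with pytest.raises(ValueError, match="empty"):
        k_sweep(small_sim.matrix, [])


def test_constant_matrix_flagged_degenerate():
    m = cl.matrix_io.build_matrix(
        ["a", "b", "c", "d"],
        [[frozenset([0])] for _ in range(4)],
        ordered=set(),
    )
    res = exhaustive_search(m, SearchConfig(mode="exhaustive"))
    assert res.log["degenerate"]
    assert res.n_binary_optima == 3  # every topology is optimal


def test_exists_strictly_better_decision(small_sim):
    m = small_sim.matrix
    scorer = MatrixScorer(m)
    best = branch_and_bound(m, SearchConfig()).best_score
    # the optimum itself cannot be beaten
    assert not exists_strictly_better(m, np.array(best.steps))
    # a deliberately worse profile can be
    worse = np.array(best.steps) + 2
    assert exists_strictly_better(m, worse)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SearchConfig(criterion="bayes")
    with pytest.raises(ValueError):
        SearchConfig(criterion="implied", k=0)
    with pytest.raises(ValueError):
        SearchConfig(swap="fuse")
    with pytest.raises(ValueError):
        SearchConfig(collapse_rule="strict")
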