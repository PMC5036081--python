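from itertools import product

import numpy as np
import pytest

import cladistron as cl
from cladistron.parsimony import (
    MatrixScorer,
    linear_cost,
    max_steps,
    min_steps,
    score_from_steps,
    unit_cost,
)

from conftest import adjacency_of, random_mixed_matrix


def brute_force_cost(tree, column, cost):
    """Minimum total change cost over every assignment of states to every
    node (tips range over their allowed sets) — the independent oracle."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if n.children]
    tips = [n for n in nodes if n.is_leaf]
    S = len(cost)
    tip_opts = [
        sorted(column.get(n.label)) if column.get(n.label) else list(range(S))
        for n in tips
    ]
    best = float("inf")
    for tip_assign in product(*tip_opts):
        state = {id(n): s for n, s in zip(tips, tip_assign)}
        for internal_assign in product(range(S), repeat=len(internals)):
            for n, s in zip(internals, internal_assign):
                state[id(n)] = s
            c = sum(
                cost[state[id(n.parent)]][state[id(n)]]
                for n in nodes
                if n.parent is not None
            )
            if c < best:
                best = c
    return best


def random_column(rng, labels, n_states, poly=True):
    col = {}
    for lab in labels:
        r = rng.random()
        if r < 0.12:
            col[lab] = frozenset()
        elif poly and r < 0.25:
            col[lab] = frozenset(
                rng.choice(n_states, size=2, replace=False).tolist()
            )
        else:
            col[lab] = frozenset([int(rng.integers(n_states))])
    return col


# ---------------------------------------------------------------------------
# single-column passes vs the brute-force oracle


def test_fitch_trivial_cases():
    t = cl.Tree.from_newick("((A,B),(C,D));")
    assert cl.fitch_steps(t, {"A": 0, "B": 0, "C": 0, "D": 0}) == 0
    assert cl.fitch_steps(t, {"A": 0, "B": 0, "C": 1, "D": 1}) == 1


@pytest.mark.parametrize("seed", range(12))
def test_fitch_matches_exhaustive_labelings(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 7))
    t = cl.simulate_tree(n, seed=seed)
    labels = t.leaf_labels()
    for _ in range(4):
        S = int(rng.integers(2, 4))
        col = random_column(rng, labels, S)
        expected = brute_force_cost(t, col, unit_cost(S).tolist())
        assert cl.fitch_steps(t, col) == expected


def test_sankoff_trivial_cases():
    two = cl.Tree.from_newick("(A,B);")
    assert cl.sankoff_steps(two, {"A": 0, "B": 3}, linear_cost(4)) == 3
    star = cl.Tree.from_newick("(A,B,C);")
    assert cl.sankoff_steps(star, {"A": 0, "B": 1, "C": 2}, linear_cost(3)) == 2


@pytest.mark.parametrize("seed", range(10))
def test_sankoff_matches_exhaustive_labelings(seed):
    rng = np.random.default_rng(100 + seed)
    n = int(rng.integers(4, 7))
    t = cl.simulate_tree(n, seed=seed)
    labels = t.leaf_labels()
    for _ in range(3):
        S = int(rng.integers(2, 5))
        # random metric-free cost matrix with zero diagonal
        cost = rng.integers(1, 5, size=(S, S))
        np.fill_diagonal(cost, 0)
        col = random_column(rng, labels, S)
        expected = brute_force_cost(t, col, cost.tolist())
        assert cl.sankoff_steps(t, col, cost) == expected


def test_sankoff_rejects_bad_cost_matrix():
    t = cl.Tree.from_newick("(A,B);")
    with pytest.raises(ValueError, match="square"):
        cl.sankoff_steps(t, {"A": 0, "B": 1}, np.zeros((2, 3)))


def test_sankoff_equals_fitch_under_unit_costs():
    rng = np.random.default_rng(7)
    for seed in range(40):
        n = int(rng.integers(4, 8))
        t = cl.simulate_tree(n, seed=seed)
        S = int(rng.integers(2, 5))
        col = random_column(rng, t.leaf_labels(), S)
        assert cl.sankoff_steps(t, col, unit_cost(S)) == cl.fitch_steps(t, col)


def test_rerooting_invariance():
    sim = random_mixed_matrix(3, n_taxa=7)
    scorer = MatrixScorer(sim.matrix)
    adj = adjacency_of(sim.tree, sim.matrix)
    ref = scorer.steps(adj, 0)
    for leaf in range(1, 7):
        assert np.array_equal(scorer.steps(adj, leaf), ref)


# ---------------------------------------------------------------------------
# step bounds


def test_min_steps_examples():
    unordered = [frozenset([0]), frozenset([1]), frozenset([2])]
    assert min_steps(unordered, "unordered") == 2
    ordered = [frozenset([0]), frozenset([1]), frozenset([3])]
    assert min_steps(ordered, "ordered") == 3


def test_max_steps_examples():
    col = [frozenset([s]) for s in (0, 0, 0, 1, 1)]
    assert max_steps(col, "unordered") == 2  # 5 - 3 copies of the mode
    ordered = [frozenset([s]) for s in (0, 1, 3)]
    assert max_steps(ordered, "ordered") == 3  # median state 1: 1 + 0 + 2


def test_all_missing_column_is_flagged_uninformative():
    col = [frozenset(), frozenset(), frozenset()]
    assert min_steps(col, "unordered") == 0
    assert max_steps(col, "unordered") == 0


def test_ordered_max_steps_is_min_absolute_deviation():
    rng = np.random.default_rng(11)
    for _ in range(30):
        vals = rng.integers(0, 5, size=int(rng.integers(3, 9)))
        col = [frozenset([int(v)]) for v in vals]
        expected = min(sum(abs(int(v) - a) for v in vals) for a in range(5))
        assert max_steps(col, "ordered") == expected


@pytest.mark.parametrize("seed", range(8))
def test_bound_sandwich_on_random_trees(seed):
    sim = random_mixed_matrix(200 + seed)
    scorer = MatrixScorer(sim.matrix)
    other = cl.simulate_tree(sim.matrix.n_taxa, seed=999 - seed,
                             labels=list(sim.matrix.taxa))
    for tree in (sim.tree, other):
        steps = scorer.steps(adjacency_of(tree, sim.matrix))
        assert np.all(scorer.m_vec <= steps)
        assert np.all(steps <= scorer.g_vec)


# ---------------------------------------------------------------------------
# tree-level score


def test_homoplasy_free_scores(small_sim):
    tree = cl.simulate_tree(8, seed=21)
    pm = cl.perfect_matrix(tree, 2)
    score = cl.score_tree(tree, pm, k=3.0)
    assert score.ci == 1.0
    assert score.fit == -pm.n_chars
    assert score.length == sum(
        min_steps(pm.column(j), c.char_type) for j, c in enumerate(pm.characters)
    )


def test_single_character_fit_contribution():
    # es = 3 at K = 3 contributes -K/(K+es) = -0.5
    s = score_from_steps([4], [1], [5], [1], k=3.0)
    assert s.fit == pytest.approx(-0.5)


def test_ci_is_one_iff_no_homoplasy(small_sim):
    m = small_sim.matrix
    scorer = MatrixScorer(m)
    true_steps = scorer.steps(adjacency_of(small_sim.tree, m))
    score = score_from_steps(true_steps, scorer.m_vec, scorer.g_vec, scorer.weights)
    assert (score.ci == 1.0) == (score.length == int(scorer.m_vec.sum()))


def test_fit_monotone_in_homoplasy():
    m_vec, g_vec, w = [1, 1, 1], [4, 4, 4], [1, 1, 1]
    base = score_from_steps([1, 1, 1], m_vec, g_vec, w, k=3.0)
    worse = score_from_steps([1, 2, 1], m_vec, g_vec, w, k=3.0)
    worst = score_from_steps([2, 2, 2], m_vec, g_vec, w, k=3.0)
    assert base.fit < worse.fit < worst.fit  # more homoplasy, less negative


def test_fit_ranking_approaches_length_ranking_as_k_grows():
    # profiles with equal length rank differently at small K but tie at
    # K -> infinity; profiles with different lengths eventually rank by length
    a = np.array([3, 0, 0])  # length 3, concentrated homoplasy
    b = np.array([1, 1, 0])  # length 2
    m = np.zeros(3, dtype=int)
    g = np.full(3, 5)
    w = np.ones(3, dtype=int)
    for k in (1e3, 1e6):
        fa = score_from_steps(a, m, g, w, k=k).fit
        fb = score_from_steps(b, m, g, w, k=k).fit
        assert fb < fa  # shorter tree wins for large K
    assert score_from_steps(a, m, g, w, k=0.1).fit < score_from_steps(
        b, m, g, w, k=0.1
    ).fit  # strong concavity prefers concentrating homoplasy


def test_k_must_be_positive(small_sim):
    with pytest.raises(ValueError, match="positive"):
        cl.score_tree(small_sim.tree, small_sim.matrix, k=-1.0)


def test_score_tree_rejects_mismatched_leaves(small_sim):
    other = cl.simulate_tree(8, seed=55)  # different labels
    other_labels = cl.simulate_tree(8, seed=55, labels=[f"x{i}" for i in range(8)])
    with pytest.raises(ValueError, match="differ"):
        cl.score_tree(other_labels, small_sim.matrix)


def test_packed_pass_agrees_with_generic_dp():
    for seed in range(15):
        sim = random_mixed_matrix(300 + seed)
        scorer = MatrixScorer(sim.matrix)
        adj = adjacency_of(sim.tree, sim.matrix)
        assert np.array_equal(scorer.steps(adj), scorer._steps_generic(adj, 0))


def test_edge_min_lengths_zero_iff_collapsible():
    # a character supporting a split makes its edge length 1; an edge with no
    # support has minimum length 0
    t = cl.Tree.from_newick("((A,B),(C,D));")
    m = cl.matrix_io.build_matrix(
        ["A", "B", "C", "D"],
        [[frozenset([0])], [frozenset([0])], [frozenset([1])], [frozenset([1])]],
        ordered=set(),
    )
    scorer = MatrixScorer(m)
    adj = adjacency_of(t, m)
    emin = scorer.edge_min_lengths(adj)
    internal = [e for e in emin if all(len(adj[x]) == 3 for x in e)]
    assert len(internal) == 1 and emin[internal[0]] == 1
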