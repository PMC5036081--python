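"""Search for most parsimonious cladograms (MPCs).

Three modes share one notion of optimality:

* ``exhaustive`` — stepwise enumeration of all (2n-5)!! unrooted binary
  topologies (guarded to small taxon counts); the oracle for the others.
* ``branch_and_bound`` — stepwise enumeration with an admissible lower bound:
  the partial tree's score plus, per character, steps forced by the taxa not
  yet placed (states no placed taxon can show, or ordered-range extension).
  Because per-character steps never decrease when a taxon is added, pruning
  is exact and all optima are recovered.
* ``heuristic`` — random-addition greedy starts followed by hill-climbing
  (NNI/SPR/TBR) and a closure sweep that keeps swapping from every optimum
  found until no new equally-optimal topology appears.

Optimality criterion: equal weights (minimise total length) or implied
weights at concavity K (minimise the total distortion ``sum es/(K+es)``,
equivalently maximise the concave fit).  Implied-weight ties are decided in
exact rational arithmetic so MPC sets are reproducible.

Duplicate-topology condensation: under the ``min_length_zero`` collapse rule
internal branches whose minimum optimised length is zero are contracted
(iterated to a fixed point), and the resulting possibly-multifurcating
topologies are deduplicated by a canonical form; ``none`` keeps all distinct
binary optima.  Published MPC counts depend on this convention, which is why
both rules ship.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Iterator

import numpy as np

from .matrix_io import CharacterMatrix, CharType
from .parsimony import MatrixScorer, TreeScore, score_from_steps
from .trees import Tree, adjacency_to_tree, canonical_adjacency

_EXHAUSTIVE_LIMIT = 10


@dataclass
class SearchConfig:
    criterion: str = "equal"  # "equal" | "implied"
    k: float = 3.0
    mode: str = "branch_and_bound"  # "exhaustive" | "branch_and_bound" | "heuristic"
    n_replicates: int = 10
    swap: str = "SPR"  # "NNI" | "SPR" | "TBR"
    seed: int = 0
    collapse_rule: str = "min_length_zero"  # or "none"
    max_trees: int = 5000
    closure_budget: int = 2000  # optima to expand while sweeping for ties

    def __post_init__(self):
        if self.criterion not in ("equal", "implied"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.criterion == "implied" and self.k <= 0:
            raise ValueError("concavity constant K must be positive")
        if self.swap not in ("NNI", "SPR", "TBR"):
            raise ValueError(f"unknown swap {self.swap!r}")
        if self.collapse_rule not in ("none", "min_length_zero"):
            raise ValueError(f"unknown collapse rule {self.collapse_rule!r}")


@dataclass
class SearchResult:
    trees: list[Tree]
    canonical: frozenset
    best_score: TreeScore
    criterion: str
    k: float | None
    n_binary_optima: int
    log: dict = dc_field(default_factory=dict)

    @property
    def n_mpcs(self) -> int:
        return len(self.trees)


# ---------------------------------------------------------------------------
# adjacency plumbing


def _copy_adj(adj):
    return {u: list(vs) for u, vs in adj.items()}


def _edges(adj):
    return [(u, v) for u in adj for v in adj[u] if u < v]


def _insert(adj, u, v, x, w):
    adj[u].remove(v)
    adj[v].remove(u)
    adj[u].append(w)
    adj[v].append(w)
    adj[w] = [u, v, x]
    adj[x] = [w]


def _remove(adj, u, v, x, w):
    del adj[x]
    del adj[w]
    adj[u].remove(w)
    adj[v].remove(w)
    adj[u].append(v)
    adj[v].append(u)


def _initial_star(order, n):
    a, b, c = order[:3]
    hub = n
    return {a: [hub], b: [hub], c: [hub], hub: [a, b, c]}


# ---------------------------------------------------------------------------
# criteria


class _Criterion:
    """Comparable score keys; implied-weight ties resolved exactly."""

    def __init__(self, scorer: MatrixScorer, criterion: str, k: float | None):
        self.scorer = scorer
        self.criterion = criterion
        self.k = k

    def key(self, steps):
        if self.criterion == "equal":
            return int(self.scorer.weights @ steps)
        return self.scorer.distortion_exact(steps, self.k)

    def float_key(self, steps) -> float:
        if self.criterion == "equal":
            return float(self.scorer.weights @ steps)
        return self.scorer.distortion(steps, self.k)

    def lower_bound(self, steps_partial, extra) -> float:
        if self.criterion == "equal":
            return float(self.scorer.weights @ (steps_partial + extra))
        es = np.maximum(steps_partial + extra - self.scorer.m_vec, 0)
        return float(np.sum(self.scorer.weights * es / (self.k + es)))

    def tree_score(self, steps) -> TreeScore:
        return score_from_steps(
            steps,
            self.scorer.m_vec,
            self.scorer.g_vec,
            self.scorer.weights,
            self.k if self.criterion == "implied" else None,
        )


# ---------------------------------------------------------------------------
# addition order and completion bounds


def _addition_order(matrix: CharacterMatrix, scorer: MatrixScorer) -> list[int]:
    """Most-data, most-informative taxa first (shrinks the search tree)."""
    scores = []
    info = scorer.informative
    for i in range(matrix.n_taxa):
        coded = sum(
            1 for j, cell in enumerate(matrix.cells[i]) if cell and info[j]
        )
        scores.append((-coded, i))
    return [i for _, i in sorted(scores)]


def _completion_bounds(matrix: CharacterMatrix, order: list[int]) -> np.ndarray:
    """``extra[d, j]``: steps character j must still gain once taxa
    ``order[:d]`` are placed (admissible: counts states only unplaced taxa
    force, or the ordered-range extension beyond the placed hull)."""
    n, nc = matrix.n_taxa, matrix.n_chars
    extra = np.zeros((n + 1, nc), dtype=np.int64)
    for j, cdef in enumerate(matrix.characters):
        col = matrix.column(j)
        ordered = cdef.char_type is CharType.ORDERED
        for d in range(3, n):
            placed = [col[i] for i in order[:d] if col[i]]
            suffix = [col[i] for i in order[d:] if len(col[i]) == 1]
            if not suffix:
                continue
            if ordered:
                if not placed:
                    smax = max(max(c) for c in suffix)
                    smin = min(min(c) for c in suffix)
                    extra[d, j] = smax - smin
                    continue
                pmax = max(max(c) for c in placed)
                pmin = min(min(c) for c in placed)
                smax = max(max(c) for c in suffix)
                smin = min(min(c) for c in suffix)
                extra[d, j] = max(0, smax - pmax) + max(0, pmin - smin)
            else:
                seen = set().union(*placed) if placed else set()
                forced = {next(iter(c)) for c in suffix}
                extra[d, j] = len(forced - seen) - (0 if placed else 1)
                if extra[d, j] < 0:
                    extra[d, j] = 0
    return extra


# ---------------------------------------------------------------------------
# enumeration


def enumerate_full_topologies(
    matrix: CharacterMatrix, visit: Callable[[dict, np.ndarray], None]
) -> int:
    """Call ``visit(adj, per_character_steps)`` for every unrooted binary
    topology on the matrix's taxa; returns the number visited."""
    n = matrix.n_taxa
    if n > _EXHAUSTIVE_LIMIT:
        raise ValueError(
            f"exhaustive enumeration limited to {_EXHAUSTIVE_LIMIT} taxa (got {n})"
        )
    scorer = MatrixScorer(matrix)
    order = list(range(n))
    count = 0
    if n < 3:
        raise ValueError("need at least 3 taxa")
    adj = _initial_star(order, n)
    root = order[0]

    def rec(depth):
        nonlocal count
        if depth == n:
            count += 1
            visit(adj, scorer.steps(adj, root))
            return
        x = order[depth]
        w = n + depth - 2
        for u, v in _edges(adj):
            _insert(adj, u, v, x, w)
            rec(depth + 1)
            _remove(adj, u, v, x, w)

    rec(3)
    return count


# ---------------------------------------------------------------------------
# condensation


def collapse_zero_branches(adj, scorer: MatrixScorer):
    """Contract internal branches whose minimum optimised length is zero.

    Each batch of zero-length edges is contracted simultaneously (the result
    is independent of edge order) and the minimum lengths are recomputed on
    the contracted tree until none remain, so the operation is idempotent."""
    adj = _copy_adj(adj)
    while True:
        emin = scorer.edge_min_lengths(adj)
        zero = [
            (u, v)
            for (u, v), val in emin.items()
            if val == 0 and len(adj[u]) > 1 and len(adj[v]) > 1
        ]
        if not zero:
            return adj
        parent = {u: u for u in adj}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for u, v in zero:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[max(ru, rv)] = min(ru, rv)
        merged: dict[int, list[int]] = {}
        for u in adj:
            ru = find(u)
            nbrs = merged.setdefault(ru, [])
            for v in adj[u]:
                rv = find(v)
                if rv != ru:
                    nbrs.append(rv)
        adj = {u: sorted(vs) for u, vs in sorted(merged.items())}


def _condense_set(adjs, scorer, rule, labels):
    out = {}
    for adj in adjs:
        c = collapse_zero_branches(adj, scorer) if rule == "min_length_zero" else adj
        out.setdefault(canonical_adjacency(c, labels), c)
    return out


def _make_result(optima, crit: _Criterion, config, matrix, log) -> SearchResult:
    labels = matrix.taxa
    scorer = crit.scorer
    condensed = _condense_set(optima, scorer, config.collapse_rule, labels)
    trees = [adjacency_to_tree(a, labels) for a in condensed.values()]
    steps0 = scorer.steps(optima[0])
    return SearchResult(
        trees=trees,
        canonical=frozenset(condensed),
        best_score=crit.tree_score(steps0),
        criterion=config.criterion,
        k=config.k if config.criterion == "implied" else None,
        n_binary_optima=len(optima),
        log=log,
    )


# ---------------------------------------------------------------------------
# exhaustive


def exhaustive_search(
    matrix: CharacterMatrix, config: SearchConfig, weights=None
) -> SearchResult:
    crit = _Criterion(
        MatrixScorer(matrix, weights),
        config.criterion,
        config.k if config.criterion == "implied" else None,
    )
    best = [None]
    optima: list[dict] = []

    def visit(adj, steps):
        key = crit.key(steps)
        if best[0] is None or key < best[0]:
            best[0] = key
            optima.clear()
            optima.append(_copy_adj(adj))
        elif key == best[0] and len(optima) < config.max_trees:
            optima.append(_copy_adj(adj))

    n_vis = enumerate_full_topologies(matrix, visit)
    log = {"mode": "exhaustive", "n_topologies": n_vis,
           "degenerate": not bool(crit.scorer.informative.any())}
    return _make_result(optima, crit, config, matrix, log)


# ---------------------------------------------------------------------------
# branch and bound


def branch_and_bound(
    matrix: CharacterMatrix, config: SearchConfig, weights=None
) -> SearchResult:
    n = matrix.n_taxa
    scorer = MatrixScorer(matrix, weights)
    crit = _Criterion(scorer, config.criterion, config.k if config.criterion == "implied" else None)
    order = _addition_order(matrix, scorer)
    extra = _completion_bounds(matrix, order)
    root = order[0]

    # seed the upper bound with a quick greedy search
    seed_cfg = SearchConfig(
        criterion=config.criterion, k=config.k, mode="heuristic",
        n_replicates=2, swap="NNI", seed=config.seed, collapse_rule="none",
    )
    warm = heuristic_search(matrix, seed_cfg, weights=weights, _closure=False)
    best_key = crit.key(np.array(warm.best_score.steps))
    best_float = crit.float_key(np.array(warm.best_score.steps))
    optima: list[dict] = []
    pruned = [0]

    adj = _initial_star(order, n)

    def rec(depth):
        nonlocal best_key, best_float
        steps = scorer.steps(adj, root)
        if depth == n:
            if crit.float_key(steps) > best_float + 1e-9:
                return
            key = crit.key(steps)
            if key < best_key:
                best_key = key
                best_float = crit.float_key(steps)
                optima.clear()
                optima.append(_copy_adj(adj))
            elif key == best_key and len(optima) < config.max_trees:
                optima.append(_copy_adj(adj))
            return
        lb = crit.lower_bound(steps, extra[depth])
        if lb > best_float + 1e-9:
            pruned[0] += 1
            return
        x = order[depth]
        w = n + depth - 2
        for u, v in _edges(adj):
            _insert(adj, u, v, x, w)
            rec(depth + 1)
            _remove(adj, u, v, x, w)

    rec(3)
    if not optima:  # the warm-start tree was already optimal and none tied
        optima = [_tree_to_adj(warm.trees[0], matrix)] if warm.trees else []
        # warm trees may be collapsed; rebuild from its stored binary optimum
    log = {"mode": "branch_and_bound", "pruned_nodes": pruned[0],
           "degenerate": not bool(scorer.informative.any())}
    return _make_result(optima, crit, config, matrix, log)


def _tree_to_adj(tree: Tree, matrix: CharacterMatrix):
    from .trees import tree_to_adjacency

    index = {t: i for i, t in enumerate(matrix.taxa)}
    return tree_to_adjacency(tree, index)


# ---------------------------------------------------------------------------
# heuristic search


def _nni_neighbors(adj) -> Iterator[dict]:
    for u in list(adj):
        for v in adj[u]:
            if u < v and len(adj[u]) == 3 and len(adj[v]) == 3:
                a, b = [x for x in adj[u] if x != v]
                c, d = [x for x in adj[v] if x != u]
                for y in (c, d):
                    nb = _copy_adj(adj)
                    nb[u][nb[u].index(a)] = y
                    nb[v][nb[v].index(y)] = a
                    nb[a][nb[a].index(u)] = v
                    nb[y][nb[y].index(v)] = u
                    yield nb


def _spr_neighbors(adj) -> Iterator[dict]:
    for p in list(adj):
        if len(adj[p]) != 3:
            continue
        for s in adj[p]:
            # prune the subtree rooted (away from p) at s
            pruned = _component(adj, s, p)
            base = _copy_adj(adj)
            a, b = [x for x in base[p] if x != s]
            base[p] = [s]  # keep p attached to s; detach from rest
            base[a][base[a].index(p)] = b
            base[b][base[b].index(p)] = a
            for x, y in _edges(base):
                if x in pruned or y in pruned or {x, y} == {a, b}:
                    continue
                nb = _copy_adj(base)
                nb[x].remove(y)
                nb[y].remove(x)
                nb[x].append(p)
                nb[y].append(p)
                nb[p] = [s, x, y]
                yield nb


def _tbr_neighbors(adj) -> Iterator[dict]:
    yield from _spr_neighbors(adj)
    for p in list(adj):
        for s in adj[p]:
            if p > s or len(adj[p]) != 3 or len(adj[s]) != 3:
                continue
            side_s = _component(adj, s, p)
            base = _copy_adj(adj)
            # fully detach the edge p-s, suppressing both endpoints
            a, b = [x for x in base[p] if x != s]
            c, d = [x for x in base[s] if x != p]
            base[a][base[a].index(p)] = b
            base[b][base[b].index(p)] = a
            base[c][base[c].index(s)] = d
            base[d][base[d].index(s)] = c
            del base[p], base[s]
            for x1, y1 in _edges(base):
                if x1 not in side_s:
                    continue
                if {x1, y1} == {c, d}:
                    continue  # SPR already covers the original rooting
                for x2, y2 in _edges(base):
                    if x2 in side_s or y2 in side_s:
                        continue
                    nb = _copy_adj(base)
                    for (x, y, w) in ((x1, y1, s), (x2, y2, p)):
                        nb[x].remove(y)
                        nb[y].remove(x)
                        nb[x].append(w)
                        nb[y].append(w)
                        nb[w] = [x, y]
                    nb[s].append(p)
                    nb[p].append(s)
                    yield nb


def _component(adj, start, blocked):
    seen = {blocked, start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    seen.discard(blocked)
    return seen


_NEIGHBORS = {"NNI": _nni_neighbors, "SPR": _spr_neighbors, "TBR": _tbr_neighbors}


def heuristic_search(
    matrix: CharacterMatrix, config: SearchConfig, weights=None, _closure: bool = True
) -> SearchResult:
    n = matrix.n_taxa
    scorer = MatrixScorer(matrix, weights)
    crit = _Criterion(scorer, config.criterion, config.k if config.criterion == "implied" else None)
    labels = matrix.taxa
    rng = np.random.default_rng(config.seed)
    neighbors = _NEIGHBORS[config.swap]

    best_key = None
    best_float = float("inf")
    pool: dict[str, dict] = {}

    if n == 3:
        adj = _initial_star(list(range(3)), 3)
        optima = [adj]
        log = {"mode": "heuristic", "n_starts": 0, "degenerate": False}
        return _make_result(optima, crit, config, matrix, log)

    def consider(adj, key, fkey):
        nonlocal best_key, best_float
        if best_key is None or key < best_key:
            best_key = key
            best_float = fkey
            pool.clear()
            pool[canonical_adjacency(adj, labels)] = _copy_adj(adj)
            return True
        if key == best_key and len(pool) < config.max_trees:
            pool.setdefault(canonical_adjacency(adj, labels), _copy_adj(adj))
        return False

    for _ in range(max(1, config.n_replicates)):
        order = [int(i) for i in rng.permutation(n)]
        adj = _initial_star(order, n)
        for depth in range(3, n):
            x = order[depth]
            w = n + depth - 2
            cands = []
            for u, v in _edges(adj):
                _insert(adj, u, v, x, w)
                cands.append((crit.float_key(scorer.steps(adj, order[0])), (u, v)))
                _remove(adj, u, v, x, w)
            lo = min(c[0] for c in cands)
            ties = [uv for val, uv in cands if val <= lo + 1e-12]
            u, v = ties[int(rng.integers(len(ties)))]
            _insert(adj, u, v, x, w)
        # hill climb (first improvement, cheap float comparisons)
        improved = True
        while improved:
            improved = False
            cur = crit.float_key(scorer.steps(adj))
            for nb in neighbors(adj):
                if crit.float_key(scorer.steps(nb)) < cur - 1e-9:
                    adj = nb
                    improved = True
                    break
        final_steps = scorer.steps(adj)
        consider(adj, crit.key(final_steps), crit.float_key(final_steps))

    closure_complete = True
    if _closure:
        # swap from every optimum, absorbing equal-score neighbours, until
        # the MPC set stops growing (or the expansion budget is spent)
        frontier = list(pool.values())
        expanded = 0
        while frontier:
            if expanded >= config.closure_budget:
                closure_complete = False
                break
            expanded += 1
            adj = frontier.pop()
            for nb in neighbors(adj):
                steps = scorer.steps(nb)
                fkey = crit.float_key(steps)
                if fkey > best_float + 1e-9:
                    continue
                key = crit.key(steps)
                if key > best_key:
                    continue
                if key < best_key:
                    best_key = key
                    best_float = fkey
                    pool.clear()
                    can = canonical_adjacency(nb, labels)
                    pool[can] = _copy_adj(nb)
                    frontier = [pool[can]]
                    break
                can = canonical_adjacency(nb, labels)
                if can not in pool and len(pool) < config.max_trees:
                    pool[can] = _copy_adj(nb)
                    frontier.append(pool[can])

    optima = list(pool.values())
    log = {"mode": "heuristic", "n_starts": config.n_replicates,
           "closure_complete": closure_complete,
           "degenerate": not bool(scorer.informative.any())}
    return _make_result(optima, crit, config, matrix, log)


def exists_strictly_better(
    matrix: CharacterMatrix,
    reference_steps: np.ndarray,
    criterion: str = "equal",
    k: float = 3.0,
    weights=None,
) -> bool:
    """Decide whether any unrooted binary topology beats the score implied by
    ``reference_steps`` — a cheap way to test whether a known tree is among
    the optima without enumerating ties.  Pruning discards everything at or
    above the reference score, so the search space collapses quickly."""
    n = matrix.n_taxa
    scorer = MatrixScorer(matrix, weights)
    crit = _Criterion(scorer, criterion, k if criterion == "implied" else None)
    ub = crit.key(np.asarray(reference_steps))
    ub_float = crit.float_key(np.asarray(reference_steps))
    order = _addition_order(matrix, scorer)
    extra = _completion_bounds(matrix, order)
    root = order[0]
    adj = _initial_star(order, n)
    found = [False]

    def rec(depth):
        if found[0]:
            return
        steps = scorer.steps(adj, root)
        if depth == n:
            if crit.float_key(steps) < ub_float - 1e-9 or (
                crit.float_key(steps) < ub_float + 1e-9 and crit.key(steps) < ub
            ):
                found[0] = True
            return
        lb = crit.lower_bound(steps, extra[depth])
        if crit.criterion == "equal":
            if lb > ub_float - 0.5:  # integer scores: equal-or-worse cannot improve
                return
        elif lb > ub_float - 1e-9:
            return
        x = order[depth]
        w = n + depth - 2
        for u, v in _edges(adj):
            _insert(adj, u, v, x, w)
            rec(depth + 1)
            _remove(adj, u, v, x, w)
            if found[0]:
                return

    rec(3)
    return found[0]


# ---------------------------------------------------------------------------
# dispatcher and K sweep


def search(matrix: CharacterMatrix, config: SearchConfig, weights=None) -> SearchResult:
    if config.mode == "exhaustive":
        return exhaustive_search(matrix, config, weights)
    if config.mode == "branch_and_bound":
        return branch_and_bound(matrix, config, weights)
    if config.mode == "heuristic":
        return heuristic_search(matrix, config, weights)
    raise ValueError(f"unknown search mode {config.mode!r}")


DEFAULT_K_GRID = tuple(range(1, 21)) + (32, 64, 128, 256, 512, 1024, 1405)


@dataclass
class KSweepResult:
    results: dict
    intervals: list  # (k_lo, k_hi, canonical MPC set)


def k_sweep(matrix: CharacterMatrix, k_grid=DEFAULT_K_GRID, config: SearchConfig | None = None) -> KSweepResult:
    """Implied-weights search at each K; reports the runs of the grid over
    which the MPC set is constant."""
    if config is None:
        config = SearchConfig(criterion="implied")
    if not k_grid:
        raise ValueError("empty K grid")
    results = {}
    for k in k_grid:
        cfg = SearchConfig(
            criterion="implied", k=float(k), mode=config.mode,
            n_replicates=config.n_replicates, swap=config.swap,
            seed=config.seed, collapse_rule=config.collapse_rule,
            max_trees=config.max_trees,
        )
        results[k] = search(matrix, cfg)
    intervals = []
    ks = sorted(results)
    start = ks[0]
    cur = results[start].canonical
    for k_prev, k_next in zip(ks, ks[1:]):
        nxt = results[k_next].canonical
        if nxt != cur:
            intervals.append((start, k_prev, cur))
            start, cur = k_next, nxt
    intervals.append((start, ks[-1], cur))
    return KSweepResult(results=results, intervals=intervals)
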