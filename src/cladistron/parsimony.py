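"""Parsimony scoring: Fitch and Sankoff passes, step bounds, ensemble indices
and the implied-weighting (concave) fit.

Characters are scored on unrooted topologies; every pass is rooted at an
arbitrary tip purely for traversal, which leaves the step count unchanged.

Three per-character statistics anchor the homoplasy measures: ``s`` (steps on
the tree at hand), ``m`` (the minimum conceivable over all trees) and ``g``
(the maximum, attained on the star tree).  Extra steps ``es = s - m`` feed the
implied-weighting fit ``f = K / (K + es)`` with concavity constant ``K``;
tree-level fit is reported as ``-sum(f)`` (the sign convention of the programs
this field uses), so a homoplasy-free matrix scores ``-n_chars`` and better
trees under implied weighting have more negative fit.  Ensemble consistency
index ``CI = sum(m) / sum(s)`` is taken over all characters; ensemble
retention index ``RI = (sum(g) - sum(s)) / (sum(g) - sum(m))`` is taken over
parsimony-informative characters only (``g > m``), the others contributing
0/0.  Both conventions (with and without uninformative characters) are
computed, since published ensemble values do not always state theirs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .matrix_io import CharacterMatrix, CharType
from .trees import Tree, tree_to_adjacency

_FIELD = 8  # bits per character lane in the packed Fitch pass
_BIG = 10**6


# ---------------------------------------------------------------------------
# per-character step bounds


def _normalize_column(column) -> list[frozenset[int]]:
    out = []
    for cell in column:
        if cell is None:
            out.append(frozenset())
        elif isinstance(cell, (int, np.integer)):
            out.append(frozenset([int(cell)]))
        else:
            out.append(frozenset(int(s) for s in cell))
    return out


def min_steps(column, char_type: CharType | str, n_states: int | None = None) -> int:
    """Minimum conceivable steps ``m`` over all trees.

    Unordered: one fewer than the smallest number of states that can account
    for every (possibly polymorphic) observation.  Ordered: the length of the
    shortest state interval meeting every observation.
    """
    col = [c for c in _normalize_column(column) if c]
    if not col:
        return 0
    if CharType(char_type) is CharType.ORDERED:
        need_hi = max(min(c) for c in col)
        need_lo = min(max(c) for c in col)
        return max(0, need_hi - need_lo)
    forced = frozenset().union(*(c for c in col if len(c) == 1))
    uncovered = [c for c in col if not (c & forced)]
    if not uncovered:
        return max(0, len(forced) - 1)
    pool = sorted(frozenset().union(*uncovered))
    for k in range(1, len(pool) + 1):
        for extra in combinations(pool, k):
            es = set(extra)
            if all(c & es for c in uncovered):
                return len(forced) + k - 1
    raise AssertionError("unreachable: pool always covers")  # pragma: no cover


def max_steps(column, char_type: CharType | str, n_states: int | None = None) -> int:
    """Steps on the star (bush) tree — the ensemble RI's ``g``."""
    col = [c for c in _normalize_column(column) if c]
    if not col:
        return 0
    if CharType(char_type) is CharType.ORDERED:
        states = range(max(max(c) for c in col) + 1)
        return min(sum(min(abs(x - a) for x in c) for c in col) for a in states)
    states = sorted(frozenset().union(*col))
    return len(col) - max(sum(1 for c in col if s in c) for s in states)


# ---------------------------------------------------------------------------
# single-column passes on Tree objects (reference implementations)


def _column_from_mapping(tree: Tree, values: Mapping[str, object]) -> list[frozenset[int]]:
    return _normalize_column([values.get(label) for label in tree.leaf_labels()])


def _generic_steps(tree: Tree, column, cost: np.ndarray) -> int:
    """Sankoff dynamic programme on the tree as rooted; exact for any cost
    matrix with zero diagonal, including asymmetric ones (for which the
    rooting is meaningful — symmetric costs are rooting-invariant)."""
    labels = tree.leaf_labels()
    index = {t: i for i, t in enumerate(labels)}
    col = _normalize_column(column)
    S = cost.shape[0]
    full = frozenset(range(S))
    if len(labels) == 1:
        return 0
    D: dict[int, np.ndarray] = {}
    for n in tree.postorder():
        if n.is_leaf:
            allowed = col[index[n.label]] or full
            v = np.full(S, _BIG)
            v[sorted(allowed)] = 0
            D[id(n)] = v
        else:
            acc = np.zeros(S)
            for c in n.children:
                acc = acc + np.min(cost + D[id(c)][None, :], axis=1)
            D[id(n)] = acc
    return int(D[id(tree.root)].min())


def unit_cost(n_states: int) -> np.ndarray:
    c = np.ones((n_states, n_states), dtype=np.int64)
    np.fill_diagonal(c, 0)
    return c


def linear_cost(n_states: int) -> np.ndarray:
    idx = np.arange(n_states)
    return np.abs(idx[:, None] - idx[None, :]).astype(np.int64)


def fitch_steps(tree: Tree, column: Mapping[str, object] | Sequence) -> int:
    """Unordered parsimony steps of one character on ``tree``.

    ``column`` maps tip label to a state, state set, or None/empty (missing);
    a sequence aligned with ``tree.leaf_labels()`` is also accepted.
    """
    col = (
        _column_from_mapping(tree, column)
        if isinstance(column, Mapping)
        else _normalize_column(column)
    )
    if len(col) != len(tree.leaf_labels()):
        raise ValueError("column length does not match the tree's tip count")
    n_states = max((max(c) for c in col if c), default=0) + 1
    return _generic_steps(tree, col, unit_cost(max(2, n_states)))


def sankoff_steps(
    tree: Tree, column: Mapping[str, object] | Sequence, cost: np.ndarray
) -> int:
    """Minimal total cost of one character under an arbitrary step matrix."""
    cost = np.asarray(cost)
    if cost.ndim != 2 or cost.shape[0] != cost.shape[1]:
        raise ValueError("cost matrix must be square")
    col = (
        _column_from_mapping(tree, column)
        if isinstance(column, Mapping)
        else _normalize_column(column)
    )
    bad = [s for c in col for s in c if s >= cost.shape[0]]
    if bad:
        raise ValueError(f"states {sorted(set(bad))} outside the cost matrix alphabet")
    return _generic_steps(tree, col, cost)


# ---------------------------------------------------------------------------
# whole-matrix scorer (the engine behind tree search and resampling)


class MatrixScorer:
    """Vectorised per-character step counts for unrooted adjacency topologies.

    Binary and unordered characters run through a packed Fitch pass (one
    8-bit lane per character inside a single big integer, so one traversal
    scores them all); ordered characters use the additive interval method,
    falling back to a full Sankoff programme for the rare ordered character
    with a non-contiguous polymorphic observation.
    """

    def __init__(self, matrix: CharacterMatrix, weights=None):
        self.matrix = matrix
        self.n_taxa = matrix.n_taxa
        self.n_chars = matrix.n_chars
        if weights is None:
            weights = np.ones(self.n_chars, dtype=np.int64)
        self.weights = np.asarray(weights)

        self.m_vec = np.array(
            [
                min_steps(matrix.column(j), c.char_type, c.n_states)
                for j, c in enumerate(matrix.characters)
            ],
            dtype=np.int64,
        )
        self.g_vec = np.array(
            [
                max_steps(matrix.column(j), c.char_type, c.n_states)
                for j, c in enumerate(matrix.characters)
            ],
            dtype=np.int64,
        )
        self.informative = self.g_vec > self.m_vec

        # One packed-Fitch "lane" per unordered character, and one per
        # threshold factor of each ordered character (additive binary coding:
        # ordered parsimony length equals the sum of Fitch lengths of its
        # "state >= k" factors, provided tip state sets are contiguous).
        lane_states: list[list[list[int]]] = []  # per lane, per taxon, states
        lane_char: list[int] = []
        self._sankoff: list[tuple[int, np.ndarray, list[frozenset[int]]]] = []
        for j, c in enumerate(matrix.characters):
            col = matrix.column(j)
            if c.char_type is CharType.ORDERED:
                contiguous = all(
                    (not cell) or set(cell) == set(range(min(cell), max(cell) + 1))
                    for cell in col
                )
                if not contiguous:
                    self._sankoff.append((j, linear_cost(c.n_states), col))
                    continue
                for k in range(1, c.n_states):
                    states = [
                        sorted({int(s >= k) for s in cell}) if cell else [0, 1]
                        for cell in col
                    ]
                    lane_states.append(states)
                    lane_char.append(j)
            elif c.n_states > _FIELD - 1:
                self._sankoff.append((j, unit_cost(c.n_states), col))
            else:
                lane_states.append(
                    [
                        sorted(cell) if cell else list(range(c.n_states))
                        for cell in col
                    ]
                )
                lane_char.append(j)

        nf = len(lane_char)
        self._nf = nf
        self._lane_char = np.array(lane_char, dtype=np.int64)
        self._low = sum(((1 << (_FIELD - 1)) - 1) << (_FIELD * k) for k in range(nf))
        self._top = sum(1 << (_FIELD * k + _FIELD - 1) for k in range(nf))
        self._tip_codes: list[int] = []
        for i in range(self.n_taxa):
            code = 0
            for k in range(nf):
                for s in lane_states[k][i]:
                    code |= 1 << (_FIELD * k + s)
            self._tip_codes.append(code)
        self._cost_cache = {
            j: (
                linear_cost(c.n_states)
                if c.char_type is CharType.ORDERED
                else unit_cost(c.n_states)
            )
            for j, c in enumerate(matrix.characters)
        }
        # character groups sharing a cost matrix, for vectorised passes
        groups: dict[tuple, list[int]] = {}
        for j, c in enumerate(matrix.characters):
            kind = "lin" if c.char_type is CharType.ORDERED else "unit"
            groups.setdefault((kind, c.n_states), []).append(j)
        self._groups = []
        for (kind, S), idx in sorted(groups.items()):
            cost = linear_cost(S) if kind == "lin" else unit_cost(S)
            tipcost = np.full((self.n_taxa, len(idx), S), _BIG, dtype=np.int64)
            for col_pos, j in enumerate(idx):
                for t in range(self.n_taxa):
                    allowed = matrix.cells[t][j] or range(S)
                    tipcost[t, col_pos, sorted(allowed)] = 0
            self._groups.append((np.array(idx), cost, tipcost))

    # -- traversal helpers --------------------------------------------

    @staticmethod
    def _orient(adj: dict[int, list[int]], root_leaf: int):
        """Parent map and reversed-preorder (children-first) node order,
        rooted at tip ``root_leaf``."""
        parent = {root_leaf: -1}
        nbr = adj[root_leaf][0]
        parent[nbr] = root_leaf
        pre = []
        stack = [nbr]
        while stack:
            u = stack.pop()
            pre.append(u)
            for v in adj[u]:
                if v != parent[u]:
                    parent[v] = u
                    stack.append(v)
        return parent, pre

    @staticmethod
    def is_binary_adj(adj: dict[int, list[int]]) -> bool:
        return all(len(vs) in (1, 3) for vs in adj.values())

    # -- scoring ------------------------------------------------------

    def steps(self, adj: dict[int, list[int]], root_leaf: int | None = None) -> np.ndarray:
        """Per-character steps of the (partial or full) topology ``adj``."""
        if root_leaf is None:
            root_leaf = min(u for u in adj if len(adj[u]) == 1)
        if not self.is_binary_adj(adj):
            return self._steps_generic(adj, root_leaf)
        parent, pre = self._orient(adj, root_leaf)
        out = np.zeros(self.n_chars, dtype=np.int64)

        if self._nf:
            low, top, codes = self._low, self._top, self._tip_codes
            code: dict[int, int] = {}
            acc = 0
            for u in reversed(pre):
                if len(adj[u]) == 1:
                    code[u] = codes[u]
                    continue
                c = None
                for v in adj[u]:
                    if v == parent[u]:
                        continue
                    cv = code[v]
                    if c is None:
                        c = cv
                        continue
                    c, acc = _fitch_fold(c, cv, low, top, acc)
                code[u] = c
            nbr = adj[root_leaf][0]
            _, acc = _fitch_fold(code[nbr], codes[root_leaf], low, top, acc)
            counts = np.frombuffer(
                acc.to_bytes(self._nf, "little"), dtype=np.uint8
            ).astype(np.int64)
            np.add.at(out, self._lane_char, counts)

        for j, cost, col in self._sankoff:
            out[j] = self._sankoff_one(adj, root_leaf, parent, pre, cost, col)
        return out

    def _steps_generic(self, adj, root_leaf) -> np.ndarray:
        parent, pre = self._orient(adj, root_leaf)
        out = np.zeros(self.n_chars, dtype=np.int64)
        for j, c in enumerate(self.matrix.characters):
            out[j] = self._sankoff_one(
                adj, root_leaf, parent, pre, self._cost_cache[j], self.matrix.column(j)
            )
        return out

    def _sankoff_one(self, adj, root_leaf, parent, pre, cost, col) -> int:
        S = cost.shape[0]

        def tipvec(u):
            allowed = col[u] or range(S)
            v = np.full(S, _BIG, dtype=np.int64)
            v[sorted(allowed)] = 0
            return v

        D: dict[int, np.ndarray] = {}
        for u in reversed(pre):
            if len(adj[u]) == 1:
                D[u] = tipvec(u)
                continue
            acc = np.zeros(S, dtype=np.int64)
            for v in adj[u]:
                if v != parent[u]:
                    acc = acc + np.min(cost + D[v][None, :], axis=1)
            D[u] = acc
        nbr = adj[root_leaf][0]
        final = tipvec(root_leaf) + np.min(cost + D[nbr][None, :], axis=1)
        return int(final.min())

    # -- tree-level scores --------------------------------------------

    def length(self, adj, root_leaf: int | None = None) -> int:
        return int(self.weights @ self.steps(adj, root_leaf))

    def distortion(self, steps: np.ndarray, k: float) -> float:
        es = np.maximum(steps - self.m_vec, 0)
        return float(np.sum(self.weights * es / (k + es)))

    def distortion_exact(self, steps: np.ndarray, k) -> Fraction:
        kf = Fraction(str(k))
        total = Fraction(0)
        for w, s, m in zip(self.weights, steps, self.m_vec):
            es = max(0, int(s) - int(m))
            total += int(w) * Fraction(es, 1) / (kf + es)
        return total

    def tree_score(self, adj, k: float | None = None) -> "TreeScore":
        return score_from_steps(
            self.steps(adj), self.m_vec, self.g_vec, self.weights, k
        )

    # -- branch minimum lengths (collapse support) ---------------------

    def edge_min_lengths(self, adj, root_leaf: int | None = None) -> dict:
        """For every edge, the minimum possible optimised length (summed over
        characters, weighted): the basis of the 'collapse zero-length
        branches' rule.  Vectorised across characters sharing a cost matrix:
        a down pass gives subtree costs D, an up pass the outside costs H,
        and per edge the minimum change cost over all optimal joint endpoint
        states is accumulated."""
        if root_leaf is None:
            root_leaf = min(u for u in adj if len(adj[u]) == 1)
        parent, pre = self._orient(adj, root_leaf)
        nbr = adj[root_leaf][0]
        edges = {tuple(sorted((u, parent[u]))): 0 for u in pre}
        for idx, cost, tipcost in self._groups:
            w = self.weights[idx]
            if not w.any():
                continue
            D: dict[int, np.ndarray] = {}
            contrib: dict[int, np.ndarray] = {}  # child -> (nc, S) cost seen by parent
            for u in reversed(pre):
                if len(adj[u]) == 1:
                    D[u] = tipcost[u]
                else:
                    acc = 0
                    for v in adj[u]:
                        if v != parent[u]:
                            cv = (cost[None, :, :] + D[v][:, None, :]).min(axis=2)
                            contrib[v] = cv
                            acc = acc + cv
                    D[u] = acc
            # H[v](r): cost outside subtree(v) when v's parent has state r
            H: dict[int, np.ndarray] = {nbr: tipcost[root_leaf]}
            for u in pre:  # parents before children
                if len(adj[u]) == 1:
                    continue
                G_u = (cost[None, :, :] + H[u][:, :, None]).min(axis=1)
                children = [v for v in adj[u] if v != parent[u]]
                total = 0
                for v in children:
                    total = total + contrib[v]
                for v in children:
                    H[v] = G_u + total - contrib[v]
            for v in pre:
                T = H[v][:, :, None] + cost[None, :, :] + D[v][:, None, :]
                tmin = T.min(axis=(1, 2))
                masked = np.where(
                    T == tmin[:, None, None], cost[None, :, :], _BIG
                )
                emin = masked.min(axis=(1, 2))
                edges[tuple(sorted((v, parent[v])))] += int((w * emin).sum())
        return edges


def _fitch_fold(a: int, b: int, low: int, top: int, acc: int):
    inter = a & b
    nz = ((inter & low) + low) | inter
    empty = top & ~nz
    if empty:
        ones = empty >> (_FIELD - 1)
        fm = ones * ((1 << _FIELD) - 1)
        return ((a | b) & fm) | (inter & ~fm), acc + ones
    return inter, acc


# ---------------------------------------------------------------------------
# tree-level score record


@dataclass
class TreeScore:
    """Length, fit and ensemble indices of one tree against one matrix."""

    length: int
    ci: float
    ri: float
    k: float | None = None
    fit: float | None = None  # reported with the conventional negative sign
    ci_informative_only: float | None = None
    ri_all_chars: float | None = None
    steps: tuple = field(default_factory=tuple, repr=False)

    def as_dict(self) -> dict:
        d = {
            "length": self.length,
            "ci": self.ci,
            "ri": self.ri,
            "k": self.k,
            "fit": self.fit,
            "ci_informative_only": self.ci_informative_only,
            "ri_all_chars": self.ri_all_chars,
        }
        return d


def score_from_steps(steps, m_vec, g_vec, weights, k: float | None = None) -> TreeScore:
    steps = np.asarray(steps)
    w = np.asarray(weights)
    ws, wm, wg = w * steps, w * m_vec, w * g_vec
    length = int(ws.sum())
    ci = float(wm.sum() / ws.sum()) if ws.sum() > 0 else 1.0
    info = np.asarray(g_vec) > np.asarray(m_vec)
    denom = (wg - wm)[info].sum()
    ri = float((wg - ws)[info].sum() / denom) if denom > 0 else float("nan")
    denom_all = (wg - wm).sum()
    ri_all = float((wg - ws).sum() / denom_all) if denom_all > 0 else float("nan")
    ci_info = (
        float(wm[info].sum() / ws[info].sum()) if ws[info].sum() > 0 else 1.0
    )
    fit = None
    if k is not None:
        if k <= 0:
            raise ValueError("concavity constant K must be positive")
        es = np.maximum(steps - m_vec, 0)
        fit = float(-np.sum(w * k / (k + es)))
    return TreeScore(
        length=length,
        ci=ci,
        ri=ri,
        k=k,
        fit=fit,
        ci_informative_only=ci_info,
        ri_all_chars=ri_all,
        steps=tuple(int(s) for s in steps),
    )


def score_tree(
    tree: Tree, matrix: CharacterMatrix, k: float | None = None, weights=None
) -> TreeScore:
    """Score a tree (leaf set must equal the matrix's taxa) against a matrix."""
    if set(tree.leaf_labels()) != set(matrix.taxa):
        raise ValueError("tree tips and matrix taxa differ")
    scorer = MatrixScorer(matrix, weights)
    index = {t: i for i, t in enumerate(matrix.taxa)}
    adj = tree_to_adjacency(tree, index)
    return scorer.tree_score(adj, k)
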