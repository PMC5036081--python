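"""Strict consensus, resampling (GC) node support, and MPC selection.

GC ("group present/contradicted") support for a clade is the percentage of
resampling replicates whose optimal trees contain the clade, minus the
percentage of the most frequent clade incompatible with it; it ranges over
[-100, 100] and is 100 only for a group recovered in every replicate and
never contradicted.  Two resampling schemes are provided: plain character
bootstrap, and symmetric resampling in which each character's weight is
doubled or zeroed with equal probability p/2 (the scheme whose support
values are unaffected by differential character weights, which is why it is
preferred over the bootstrap when comparing implied-weighting trees).

When a search produces several equally optimal cladograms across a range of
concavity constants, :func:`select_mpc` ranks them by the summed GC of their
nodes against one shared resampling run, breaking ties by resolution and
then by reported fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .matrix_io import CharacterMatrix
from .search import SearchConfig, SearchResult, heuristic_search
from .trees import Node, Tree, splits_compatible

Bipartition = frozenset  # side of the split not containing the reference tip


# ---------------------------------------------------------------------------
# strict consensus


def strict_consensus(trees: list[Tree]) -> Tree:
    """The tree containing exactly the splits common to every input tree."""
    if not trees:
        raise ValueError("need at least one tree")
    labels = set(trees[0].leaf_labels())
    for t in trees[1:]:
        if set(t.leaf_labels()) != labels:
            raise ValueError("trees must share an identical leaf set")
    common = set.intersection(*(set(t.bipartitions()) for t in trees))
    ref = min(labels)
    return tree_from_splits(common, labels, ref)


def tree_from_splits(splits, labels: set[str], ref: str) -> Tree:
    """Build the (possibly multifurcating) tree realising a compatible set of
    splits, each given as its side excluding ``ref``."""
    rest = frozenset(labels) - {ref}
    clades = sorted({frozenset(s) for s in splits if 1 < len(s) < len(rest)}, key=len)

    def build(c: frozenset, inside: list[frozenset]) -> Node:
        node = Node()
        maximal = [d for d in inside if not any(d < e for e in inside)]
        covered = set().union(*maximal) if maximal else set()
        for leaf in sorted(c - covered):
            node.add(Node(leaf))
        for d in sorted(maximal, key=sorted):
            node.add(build(d, [e for e in inside if e < d]))
        return node

    root = Node()
    root.add(Node(ref))
    root.add(build(rest, clades))
    return Tree(root)


# ---------------------------------------------------------------------------
# support table


@dataclass
class SupportTable:
    """Split frequencies (%) from a resampling run, with GC accessors."""

    labels: frozenset
    freq: dict  # Bipartition -> percent of replicates containing it
    replicates: int
    scheme: str
    seed: int | None = None

    def best_contradicting(self, split: Bipartition) -> float:
        rivals = [
            f for s, f in self.freq.items()
            if s != split and not splits_compatible(s, split)
        ]
        return max(rivals, default=0.0)

    def gc(self, split: Bipartition) -> float:
        return self.freq.get(split, 0.0) - self.best_contradicting(split)

    def summed_gc(self, tree: Tree) -> float:
        return sum(self.gc(s) for s in tree.bipartitions())

    def rows(self):
        out = []
        for s in sorted(self.freq, key=lambda s: (-self.freq[s], sorted(s))):
            out.append(
                {
                    "group": "+".join(sorted(s)),
                    "frequency": self.freq[s],
                    "best_contradicting": self.best_contradicting(s),
                    "gc": self.gc(s),
                }
            )
        return out

    def to_tsv(self) -> str:
        lines = ["group\tfrequency\tbest_contradicting\tgc"]
        for r in self.rows():
            lines.append(
                f"{r['group']}\t{r['frequency']:.2f}"
                f"\t{r['best_contradicting']:.2f}\t{r['gc']:.2f}"
            )
        return "\n".join(lines) + "\n"


def _replicate_weights(rng, n_chars: int, scheme: str, p: float) -> np.ndarray:
    if scheme == "bootstrap":
        return rng.multinomial(n_chars, np.full(n_chars, 1.0 / n_chars)).astype(np.int64)
    if scheme == "symmetric":
        u = rng.random(n_chars)
        w = np.ones(n_chars, dtype=np.int64)
        w[u < p / 2] = 0
        w[(u >= p / 2) & (u < p)] = 2
        return w
    raise ValueError(f"unknown resampling scheme {scheme!r}")


def resample_support(
    matrix: CharacterMatrix,
    config: SearchConfig | None = None,
    scheme: str = "symmetric",
    p: float = 0.33,
    replicates: int = 10_000,
    seed: int = 0,
) -> SupportTable:
    """Accumulate split frequencies over seeded resampling replicates.

    Each replicate draws character weights, reruns the (heuristic) search,
    and contributes the splits of the strict consensus of its optima once.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if replicates < 100:
        warnings.warn(
            f"{replicates} replicates cannot resolve percentages finer than "
            f"{100 / replicates:.1f} points",
            stacklevel=2,
        )
    if config is None:
        config = SearchConfig(
            criterion="equal", mode="heuristic", n_replicates=2,
            swap="NNI", collapse_rule="none",
        )
    rng = np.random.default_rng(seed)
    counts: dict = {}
    for _ in range(replicates):
        w = _replicate_weights(rng, matrix.n_chars, scheme, p)
        rep_cfg = SearchConfig(
            criterion=config.criterion, k=config.k, mode="heuristic",
            n_replicates=config.n_replicates, swap=config.swap,
            seed=int(rng.integers(2**31 - 1)), collapse_rule="none",
            max_trees=min(config.max_trees, 64), closure_budget=32,
        )
        res = heuristic_search(matrix, rep_cfg, weights=w)
        splits = set.intersection(*(set(t.bipartitions()) for t in res.trees))
        for s in splits:
            counts[s] = counts.get(s, 0) + 1
    pct = {s: 100.0 * c / replicates for s, c in counts.items()}
    return SupportTable(
        labels=frozenset(matrix.taxa), freq=pct,
        replicates=replicates, scheme=scheme, seed=seed,
    )


# ---------------------------------------------------------------------------
# MPC selection


@dataclass
class MpcSelection:
    chosen_k: float
    chosen_tree: Tree
    table: list = field(default_factory=list)  # per-candidate report rows
    gc_by_k: dict = field(default_factory=dict)


def select_mpc(results_by_k: dict, support: SupportTable) -> MpcSelection:
    """Rank every MPC of every K by summed node GC against one shared
    resampling run; ties go to the better-resolved tree, then to the higher
    (less negative) reported fit, then to the smallest K."""
    if not results_by_k:
        raise ValueError("empty MPC map")
    rows = []
    for k in sorted(results_by_k):
        res: SearchResult = results_by_k[k]
        for idx, tree in enumerate(res.trees):
            rows.append(
                {
                    "k": k,
                    "tree_index": idx,
                    "summed_gc": support.summed_gc(tree),
                    "n_internal_splits": len(tree.bipartitions()),
                    "fit": res.best_score.fit,
                    "length": res.best_score.length,
                    "tree": tree,
                }
            )
    best = max(
        rows,
        key=lambda r: (
            r["summed_gc"],
            r["n_internal_splits"],
            r["fit"] if r["fit"] is not None else -float("inf"),
            -r["k"],
        ),
    )
    gc_by_k = {}
    for k in sorted(results_by_k):
        vals = [r["summed_gc"] for r in rows if r["k"] == k]
        gc_by_k[k] = max(vals)
    table = [{key: v for key, v in r.items() if key != "tree"} for r in rows]
    return MpcSelection(
        chosen_k=best["k"], chosen_tree=best["tree"], table=table, gc_by_k=gc_by_k
    )
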