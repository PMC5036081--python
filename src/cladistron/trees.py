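"""Phylogenetic tree structures.

A :class:`Tree` is a rooted tree over named tips.  Unrooted topologies (the
objects parsimony actually compares) are represented by rooting at an
arbitrary tip edge; all topology comparisons go through unrooted
bipartitions, so the placement of the root never matters for scoring.
Internal nodes may carry labels (support values), ages (Ma) and branch
lengths, which is all the reporting layer needs.
"""

from __future__ import annotations

from typing import Callable, Iterable, Iterator


class Node:
    __slots__ = ("children", "parent", "label", "length", "age", "annotations")

    def __init__(self, label: str | None = None):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.label = label
        self.length: float | None = None
        self.age: float | None = None
        self.annotations: dict = {}

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.label or '*'} children={len(self.children)}>"


class Tree:
    """Rooted tree; provides traversal, splits and newick (de)serialisation."""

    def __init__(self, root: Node):
        self.root = root

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        root, pos = _parse_clade(text.strip(), 0)
        return cls(root)

    def copy(self) -> "Tree":
        def rec(n: Node) -> Node:
            m = Node(n.label)
            m.length, m.age = n.length, n.age
            m.annotations = dict(n.annotations)
            for c in n.children:
                m.add(rec(c))
            return m

        return Tree(rec(self.root))

    # -- traversal ----------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return reversed(out)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self, include_root: bool = True) -> list[Node]:
        return [
            n
            for n in self.postorder()
            if n.children and (include_root or n is not self.root)
        ]

    def __len__(self) -> int:
        return len(self.leaves())

    def is_binary(self) -> bool:
        """True if every internal node (root may have 2) has exactly 2 children."""
        return all(len(n.children) == 2 for n in self.internal_nodes())

    # -- set views ----------------------------------------------------

    def clades(self, trivial: bool = False) -> set[frozenset[str]]:
        """Rooted clades (leaf sets below each internal node except the root)."""
        out: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        n_total = 0
        for n in self.postorder():
            if n.is_leaf:
                below[id(n)] = frozenset([n.label])
                n_total += 1
            else:
                s = frozenset().union(*(below[id(c)] for c in n.children))
                below[id(n)] = s
        for n in self.postorder():
            if n.children and n is not self.root:
                s = below[id(n)]
                if trivial or 1 < len(s):
                    out.add(s)
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial unrooted splits, each written as the side that does not
        contain the lexicographically smallest tip (a canonical choice)."""
        labels = set(self.leaf_labels())
        ref = min(labels)
        out = set()
        for s in self.clades():
            side = s if ref not in s else frozenset(labels - s)
            if 1 < len(side) < len(labels) - 1:
                out.add(side)
        return out

    # -- newick -------------------------------------------------------

    def to_newick(
        self,
        lengths: bool = False,
        internal_labels: bool = True,
        fmt: Callable[[float], str] = lambda x: f"{x:g}",
    ) -> str:
        def rec(n: Node) -> str:
            if n.is_leaf:
                s = _quote(n.label or "")
            else:
                s = "(" + ",".join(rec(c) for c in n.children) + ")"
                if internal_labels and n.label:
                    s += _quote(n.label)
            if lengths and n.length is not None:
                s += ":" + fmt(n.length)
            return s

        return rec(self.root) + ";"

    # -- canonical form -----------------------------------------------

    def canonical_unrooted(self) -> str:
        """Canonical string of the unrooted topology: reroot on the smallest
        tip's edge, sort children recursively.  Equal strings iff the unrooted
        (possibly multifurcating) topologies are equal."""
        adj = _adjacency(self.root)
        names = {id(n): n.label for n in self.postorder() if n.is_leaf}
        start = min((n for n in names), key=lambda i: names[i])

        def rec(node_id: int, parent_id: int) -> str:
            nbrs = [v for v in adj[node_id] if v != parent_id]
            if not nbrs:
                return names[node_id]
            return "(" + ",".join(sorted(rec(v, node_id) for v in nbrs)) + ")"

        (nbr,) = [v for v in adj[start]]  # a tip has exactly one neighbour
        return f"({names[start]},{rec(nbr, start)});"

    # -- rerooting ----------------------------------------------------

    def root_on_outgroup(self, outgroup: Iterable[str]) -> "Tree":
        """Return a copy rooted so that ``outgroup`` tips (or the rest of the
        tree, whichever forms a clade) attach at the base.  The root is placed
        on the edge separating outgroup from ingroup."""
        og = frozenset(outgroup)
        labels = frozenset(self.leaf_labels())
        if not og or not og < labels:
            raise ValueError("outgroup must be a proper non-empty subset of tips")
        adj = _adjacency(self.root)
        names = {id(n): n.label for n in self.postorder() if n.is_leaf}
        # find the edge whose removal separates og from the rest
        edge = _find_split_edge(adj, names, og)
        if edge is None:
            raise ValueError("outgroup is not a clade on the unrooted topology")
        a, b = edge  # a-side contains the outgroup
        root = Node()
        root.add(_build_down(adj, names, a, b))
        root.add(_build_down(adj, names, b, a))
        return Tree(root)


# ---------------------------------------------------------------------------
# helpers


def _quote(label: str) -> str:
    if any(ch in label for ch in "(),:;[] "):
        return "'" + label.replace("'", "''") + "'"
    return label


def _parse_clade(text: str, pos: int) -> tuple[Node, int]:
    node = Node()
    if pos < len(text) and text[pos] == "(":
        pos += 1
        while True:
            child, pos = _parse_clade(text, pos)
            node.add(child)
            if pos >= len(text):
                raise ValueError("unbalanced parentheses in newick string")
            if text[pos] == ",":
                pos += 1
                continue
            if text[pos] == ")":
                pos += 1
                break
            raise ValueError(f"unexpected character {text[pos]!r} at {pos}")
    label, pos = _parse_label(text, pos)
    if label:
        node.label = label
    if pos < len(text) and text[pos] == ":":
        pos += 1
        start = pos
        while pos < len(text) and text[pos] not in ",();":
            pos += 1
        node.length = float(text[start:pos])
    while pos < len(text) and text[pos] in "; \n\t":
        pos += 1
    return node, pos


def _parse_label(text: str, pos: int) -> tuple[str | None, int]:
    if pos < len(text) and text[pos] == "'":
        pos += 1
        out = []
        while pos < len(text):
            if text[pos] == "'":
                if pos + 1 < len(text) and text[pos + 1] == "'":
                    out.append("'")
                    pos += 2
                    continue
                pos += 1
                break
            out.append(text[pos])
            pos += 1
        return "".join(out), pos
    start = pos
    while pos < len(text) and text[pos] not in ",():;[] \n\t":
        pos += 1
    return (text[start:pos] or None), pos


def _adjacency(root: Node) -> dict[int, set[int]]:
    """Unrooted adjacency over node ids; a degree-2 root is suppressed."""
    adj: dict[int, set[int]] = {}
    stack = [root]
    nodes = []
    while stack:
        n = stack.pop()
        nodes.append(n)
        stack.extend(n.children)
    for n in nodes:
        adj.setdefault(id(n), set())
        for c in n.children:
            adj[id(n)].add(id(c))
            adj.setdefault(id(c), set()).add(id(n))
    if len(adj.get(id(root), ())) == 2:
        a, b = adj.pop(id(root))
        adj[a].discard(id(root))
        adj[b].discard(id(root))
        adj[a].add(b)
        adj[b].add(a)
    return adj


def _find_split_edge(adj, names, side: frozenset[str]):
    """Edge (a, b) such that removing it leaves exactly ``side`` tips on a's
    component, or None."""
    for a in list(adj):
        for b in adj[a]:
            tips = _tips_on_side(adj, names, a, b)
            if tips == side:
                return (a, b)
    return None


def _tips_on_side(adj, names, a, b) -> frozenset[str]:
    seen = {b, a}
    stack = [a]
    out = []
    while stack:
        u = stack.pop()
        if u in names:
            out.append(names[u])
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return frozenset(out)


def _build_down(adj, names, start, parent) -> Node:
    n = Node(names.get(start))
    for v in adj[start]:
        if v != parent:
            n.add(_build_down(adj, names, v, start))
    return n


def tree_to_adjacency(tree: Tree, index: dict[str, int]) -> dict[int, list[int]]:
    """Unrooted adjacency with tips numbered by ``index`` and internal nodes
    numbered from ``len(index)`` upward.  A degree-2 root is suppressed."""
    adj_ids = _adjacency(tree.root)
    names = {id(n): n.label for n in tree.postorder() if n.is_leaf}
    mapping: dict[int, int] = {}
    next_internal = len(index)
    for nid in adj_ids:
        if nid in names:
            mapping[nid] = index[names[nid]]
        else:
            mapping[nid] = next_internal
            next_internal += 1
    return {mapping[u]: [mapping[v] for v in vs] for u, vs in adj_ids.items()}


def adjacency_to_tree(
    adj: dict[int, list[int]], labels: list[str], root_leaf: int = 0
) -> Tree:
    """Root an unrooted adjacency on the edge above tip ``root_leaf``."""

    def build(u: int, parent: int) -> Node:
        n = Node(labels[u] if u < len(labels) and len(adj[u]) == 1 else None)
        if u < len(labels) and len(adj[u]) == 1:
            return n
        n.label = labels[u] if u < len(labels) else None
        for v in adj[u]:
            if v != parent:
                n.add(build(v, u))
        return n

    root = Node()
    root.add(Node(labels[root_leaf]))
    (nbr,) = [v for v in adj[root_leaf]]
    root.add(build(nbr, root_leaf))
    return Tree(root)


def canonical_adjacency(adj: dict[int, list[int]], labels: list[str]) -> str:
    """Canonical string of an unrooted adjacency (cf. Tree.canonical_unrooted)."""
    tips = [u for u in adj if len(adj[u]) == 1]
    start = min(tips, key=lambda u: labels[u])

    def rec(u: int, parent: int) -> str:
        nbrs = [v for v in adj[u] if v != parent]
        if not nbrs:
            return labels[u]
        return "(" + ",".join(sorted(rec(v, u) for v in nbrs)) + ")"

    (nbr,) = [v for v in adj[start]]
    return f"({labels[start]},{rec(nbr, start)});"


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    """Unrooted Robinson–Foulds distance (symmetric split difference)."""
    if set(t1.leaf_labels()) != set(t2.leaf_labels()):
        raise ValueError("trees must share an identical leaf set")
    b1, b2 = t1.bipartitions(), t2.bipartitions()
    return len(b1 ^ b2)


def splits_compatible(s1: frozenset, s2: frozenset) -> bool:
    """Compatibility of two splits given as reference-tip-excluded sides."""
    return s1 <= s2 or s2 <= s1 or not (s1 & s2)
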