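"""Mapping traits on trees and skull-measurement arithmetic.

Discrete traits (e.g. the four biogeographic areas) are optimised by
unordered parsimony; every node receives its set of most-parsimonious
reconstructions (MPR set) and the minimal number of state changes is
reported.  Continuous traits (e.g. a body-length proxy derived from
postorbital skull width) are optimised by squared-change parsimony: internal
values minimise the sum over edges of squared parent-child differences, the
unique solution of a small linear system, which keeps every ancestral value
inside the span of the tip values.

Measurement tables carry the flags this literature prints alongside values:
``*`` for a measurement estimated by doubling from one side and ``+`` for a
preserved (incomplete) distance.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .trees import Tree

_BIG = 10**6


# ---------------------------------------------------------------------------
# ratios


def ratio(numerator: float, denominator: float, digits: int = 2) -> float:
    """Half-up rounded ratio, matching how printed tables round (default 2
    decimals)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    q = Decimal(str(numerator)) / Decimal(str(denominator))
    quantum = Decimal(1).scaleb(-digits)
    return float(q.quantize(quantum, rounding=ROUND_HALF_UP))


def verify_ratios(claims: Iterable[tuple]) -> list[dict]:
    """Check printed ratios against their own printed inputs.

    Each claim is ``(name, numerator, denominator, printed)``; the report
    lists the recomputed value next to the printed one without reconciling
    them — typographic discrepancies in a source table should stay visible.
    """
    out = []
    for name, num, den, printed in claims:
        computed = ratio(num, den)
        out.append(
            {
                "name": name,
                "numerator": num,
                "denominator": den,
                "computed": computed,
                "printed": printed,
                "agrees": abs(computed - printed) < 1e-9,
            }
        )
    return out


# ---------------------------------------------------------------------------
# measurement tables


@dataclass(frozen=True)
class Measurement:
    value: float
    estimated: bool = False  # '*': doubled from one side
    preserved: bool = False  # '+': preserved (incomplete) distance


@dataclass
class MeasurementTable:
    """specimen -> measurement name -> Measurement (mm)."""

    data: dict = field(default_factory=dict)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeasurementTable":
        """CSV with a ``measurement`` column and one column per specimen;
        cells like ``468``, ``340*``, ``330+`` or empty/``-`` for absent."""
        table = cls()
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if "measurement" not in (reader.fieldnames or []):
                raise ValueError(f"{path}: expected a 'measurement' column")
            specimens = [c for c in reader.fieldnames if c != "measurement"]
            for row in reader:
                name = row["measurement"].strip()
                for sp in specimens:
                    raw = (row[sp] or "").strip()
                    if not raw or raw == "-":
                        continue
                    estimated = raw.endswith("*")
                    preserved = raw.endswith("+")
                    val = float(raw.rstrip("*+"))
                    if val <= 0:
                        raise ValueError(
                            f"{path}: non-positive measurement {name!r} for {sp}"
                        )
                    table.data.setdefault(sp, {})[name] = Measurement(
                        val, estimated, preserved
                    )
        return table

    def get(self, specimen: str, measurement: str) -> float:
        return self.data[specimen][measurement].value

    def specimens(self) -> list[str]:
        return sorted(self.data)


# ---------------------------------------------------------------------------
# trait tables


@dataclass
class TraitTable:
    """taxon -> value; values are strings for discrete traits and floats for
    continuous ones.  Missing taxa are simply absent."""

    values: dict = field(default_factory=dict)

    @classmethod
    def from_csv(cls, path: str | Path, value_column: str | None = None,
                 continuous: bool = False) -> "TraitTable":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            cols = reader.fieldnames or []
            if not cols or "taxon" not in cols:
                raise ValueError(f"{path}: expected a 'taxon' column")
            vc = value_column or [c for c in cols if c != "taxon"][0]
            vals = {}
            for row in reader:
                raw = (row[vc] or "").strip()
                if not raw or raw == "?":
                    continue
                vals[row["taxon"].strip()] = float(raw) if continuous else raw
        return cls(vals)


# ---------------------------------------------------------------------------
# discrete (Fitch/MPR) mapping


@dataclass
class DiscreteReconstruction:
    tree: Tree  # copy with node.annotations['state_set']
    n_changes: int
    alphabet: list


def map_discrete(tree: Tree, trait: TraitTable | Mapping) -> DiscreteReconstruction:
    """Unordered-parsimony ancestral state sets (MPR sets) on a rooted tree.

    Tips without a value are treated as bearing the full alphabet (with a
    warning); the change count equals the unordered parsimony steps of the
    same column.
    """
    values = trait.values if isinstance(trait, TraitTable) else dict(trait)
    t = tree.copy()
    tips = t.leaves()
    missing = [n.label for n in tips if n.label not in values]
    if missing:
        warnings.warn(
            f"tips without a trait value treated as unknown: {sorted(missing)}",
            stacklevel=2,
        )
    alphabet = sorted({str(v) for k, v in values.items()})
    if not alphabet:
        raise ValueError("no tip has a trait value")
    index = {a: i for i, a in enumerate(alphabet)}
    S = len(alphabet)
    cost = np.ones((S, S), dtype=np.int64)
    np.fill_diagonal(cost, 0)

    D: dict[int, np.ndarray] = {}
    for n in t.postorder():
        if n.is_leaf:
            v = np.full(S, _BIG, dtype=np.int64)
            if n.label in values:
                v[index[str(values[n.label])]] = 0
            else:
                v[:] = 0
            D[id(n)] = v
        else:
            D[id(n)] = sum(
                np.min(cost + D[id(c)][None, :], axis=1) for c in n.children
            )
    best = int(D[id(t.root)].min())

    # top-down: G[v](s) = cost of the rest of the tree if v has state s
    G: dict[int, np.ndarray] = {id(t.root): np.zeros(S, dtype=np.int64)}
    for n in t.preorder():
        if n.is_leaf:
            continue
        contrib = {id(c): np.min(cost + D[id(c)][None, :], axis=1) for c in n.children}
        total = sum(contrib.values())
        own = G[id(n)]
        for c in n.children:
            h = own + total - contrib[id(c)]  # parent-state cost excluding c
            G[id(c)] = np.min(cost + h[:, None], axis=0)
    for n in t.postorder():
        tot = D[id(n)] + G[id(n)]
        n.annotations["state_set"] = frozenset(
            alphabet[i] for i in np.flatnonzero(tot == tot.min())
        )
    return DiscreteReconstruction(tree=t, n_changes=best, alphabet=alphabet)


# ---------------------------------------------------------------------------
# continuous (squared-change) mapping


@dataclass
class ContinuousReconstruction:
    tree: Tree  # copy with node.annotations['value']
    sum_squared_change: float


def map_continuous(tree: Tree, trait: TraitTable | Mapping) -> ContinuousReconstruction:
    """Squared-change parsimony on a rooted tree (polytomies allowed).

    Internal values solve the linear system in which every internal node sits
    at the mean of its neighbours; tips without values are pruned (warned).
    """
    values = trait.values if isinstance(trait, TraitTable) else dict(trait)
    t = tree.copy()
    # prune unvalued tips
    pruned = []
    changed = True
    while changed:
        changed = False
        for n in list(t.postorder()):
            if n.is_leaf and n.parent is not None and n.label not in values:
                if n.label is not None:
                    pruned.append(n.label)
                n.parent.children.remove(n)
                changed = True
        for n in list(t.postorder()):
            if not n.is_leaf and len(n.children) == 1 and n.parent is not None:
                child = n.children[0]
                n.parent.children[n.parent.children.index(n)] = child
                child.parent = n.parent
                changed = True
        while len(t.root.children) == 1 and t.root.children[0].children:
            t.root = t.root.children[0]
            t.root.parent = None
            changed = True
    if pruned:
        warnings.warn(f"tips without values pruned: {sorted(set(pruned))}", stacklevel=2)
    tips = t.leaves()
    if len(tips) < 2:
        raise ValueError("need at least two valued tips")

    internal = [n for n in t.postorder() if not n.is_leaf]
    idx = {id(n): i for i, n in enumerate(internal)}
    m = len(internal)
    A = np.zeros((m, m))
    b = np.zeros(m)
    for n in internal:
        i = idx[id(n)]
        nbrs = list(n.children) + ([n.parent] if n.parent is not None else [])
        A[i, i] = len(nbrs)
        for nb in nbrs:
            if nb.is_leaf:
                b[i] += float(values[nb.label])
            else:
                A[i, idx[id(nb)]] -= 1.0
    x = np.linalg.solve(A, b)
    for n in t.postorder():
        n.annotations["value"] = (
            float(values[n.label]) if n.is_leaf else float(x[idx[id(n)]])
        )
    ssq = 0.0
    for n in t.postorder():
        if n.parent is not None:
            ssq += (n.annotations["value"] - n.parent.annotations["value"]) ** 2
    return ContinuousReconstruction(tree=t, sum_squared_change=ssq)


# ---------------------------------------------------------------------------
# body-size proxy


def body_size_proxy(
    measurements: MeasurementTable,
    regression: tuple[float, float] = (0.0, 1.0),
    measurement: str = "Postorbital width of skull",
) -> TraitTable:
    """Apply a user-supplied linear transform ``a + b * width`` to postorbital
    widths.  The default identity maps the width itself — regression
    coefficients for body length come from external sources and are never
    hard-coded here.  Specimens without the measurement are excluded with a
    warning.
    """
    a, b = regression
    out = {}
    skipped = []
    for sp in measurements.specimens():
        row = measurements.data[sp]
        if measurement in row:
            out[sp] = a + b * row[measurement].value
        else:
            skipped.append(sp)
    if skipped:
        warnings.warn(
            f"specimens without {measurement!r} excluded: {skipped}", stacklevel=2
        )
    return TraitTable(out)
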