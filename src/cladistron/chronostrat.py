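"""Stratigraphic calibration of a cladogram into a time-tree.

Inputs are tabular: node constraints (clade name, age bounds in Ma, clade
membership) and tip stratigraphic ranges (oldest, youngest occurrence in Ma,
extant flags).  Calibration is a single rootward pass:

* a tip's *point* age is the young end of its range (0 for extant taxa); the
  full (oldest, youngest) pair is kept as the plotted range bar;
* a node's age is the maximum of (a) its own constraint under the chosen
  policy (``range_top`` uses the old bound, ``range_mid`` the midpoint),
  (b) each child node's age plus a minimal internode ``eps``, (c) each child
  tip's point age plus ``eps``, and (d) the first-appearance datum (old
  bound) of any confidently-dated descendant tip — a clade must be at least
  as old as its oldest member, with no artificial padding above that datum.

Tips whose range comes from a coarse epoch-level default (a fossil known
only as "Neogene", say) are flagged low-confidence and do not push ancestor
ages; they would otherwise drag every containing clade to the epoch top.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .trees import Node, Tree

#: (oldest, youngest) bounds in Ma for coarse age terms, used as wide
#: low-confidence defaults for poorly dated material.
EPOCH_RANGES = {
    "neogene": (23.03, 2.58),
    "miocene": (23.03, 5.333),
    "early miocene": (23.03, 15.97),
    "middle miocene": (15.97, 11.63),
    "late miocene": (11.63, 5.333),
    "middle miocene-pliocene": (15.97, 2.58),
    "pliocene": (5.333, 2.58),
    "unknown": (23.03, 2.58),
}


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class TipRange:
    oldest: float
    youngest: float
    extant: bool = False
    low_confidence: bool = False

    def __post_init__(self):
        if self.oldest < self.youngest or self.youngest < 0:
            raise CalibrationError(
                f"invalid range ({self.oldest}, {self.youngest}): need oldest >= youngest >= 0"
            )

    @property
    def point_age(self) -> float:
        return 0.0 if self.extant else self.youngest


@dataclass(frozen=True)
class NodeConstraint:
    name: str
    max_age: float
    min_age: float
    members: frozenset
    kind: str = "mrca"  # "mrca" (crown of members) or "stem" (parent of that node)

    def __post_init__(self):
        if self.max_age < self.min_age or self.min_age < 0:
            raise CalibrationError(
                f"constraint {self.name!r}: need max_age >= min_age >= 0"
            )

    def age(self, policy: str) -> float:
        if policy == "range_top":
            return self.max_age
        if policy == "range_mid":
            return (self.max_age + self.min_age) / 2
        raise ValueError(f"unknown policy {policy!r}")


@dataclass
class CalibrationSet:
    node_constraints: dict = field(default_factory=dict)  # name -> NodeConstraint
    tip_ranges: dict = field(default_factory=dict)  # taxon -> TipRange

    @classmethod
    def from_tsv(cls, nodes_path: str | Path | None, tips_path: str | Path) -> "CalibrationSet":
        cal = cls()
        with open(tips_path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                cal.tip_ranges[row["taxon"].strip()] = TipRange(
                    oldest=float(row["oldest_ma"]),
                    youngest=float(row["youngest_ma"]),
                    extant=row.get("extant", "0").strip() in ("1", "true", "yes"),
                    low_confidence=row.get("confidence", "high").strip() == "low",
                )
        if nodes_path is not None:
            with open(nodes_path, newline="") as fh:
                for row in csv.DictReader(fh, delimiter="\t"):
                    name = row["clade"].strip()
                    cal.node_constraints[name] = NodeConstraint(
                        name=name,
                        max_age=float(row["max_ma"]),
                        min_age=float(row["min_ma"]),
                        members=frozenset(row["members"].split()),
                        kind=row.get("kind", "mrca").strip() or "mrca",
                    )
        return cal


@dataclass
class TimeTree:
    tree: Tree  # nodes carry .age; tips carry annotations['range']
    policy: str
    eps: float
    binding: list = field(default_factory=list)  # constraints that set their node's age


def _clade_sets(tree: Tree) -> dict:
    below = {}
    for n in tree.postorder():
        if n.is_leaf:
            below[id(n)] = frozenset([n.label])
        else:
            below[id(n)] = frozenset().union(*(below[id(c)] for c in n.children))
    return below


def calibrate(
    tree: Tree, cal: CalibrationSet, policy: str = "range_top", eps: float = 0.1
) -> TimeTree:
    """Assign ages (Ma) to every node of a rooted tree; see module docstring
    for the placement rule.  Raises on unresolvable constraints or undated
    tips."""
    t = tree.copy()
    tips = t.leaves()
    for n in tips:
        if n.label not in cal.tip_ranges:
            raise CalibrationError(f"tip {n.label!r} has no age range or extant flag")

    below = _clade_sets(t)
    node_for_constraint: dict[int, list[NodeConstraint]] = {}
    for con in cal.node_constraints.values():
        target = None
        for n in t.postorder():
            if not n.is_leaf and below[id(n)] == con.members:
                target = n
                break
        if target is None and con.kind == "stem" and len(con.members) == 1:
            (taxon,) = con.members
            target = next((n for n in tips if n.label == taxon), None)
        if target is None:
            raise CalibrationError(
                f"constraint clade {con.name!r} is not monophyletic in the tree"
            )
        if con.kind == "stem":
            target = target.parent
            if target is None:
                raise CalibrationError(
                    f"stem constraint {con.name!r} needs the clade to have a parent"
                )
        node_for_constraint.setdefault(id(target), []).append(con)

    binding = []
    for n in t.postorder():
        if n.is_leaf:
            rng = cal.tip_ranges[n.label]
            n.age = rng.point_age
            n.annotations["range"] = (rng.oldest, rng.youngest)
            n.annotations["low_confidence"] = rng.low_confidence
            n.annotations["fad"] = (
                0.0 if (rng.extant or rng.low_confidence)
                else (rng.oldest if policy == "range_top" else (rng.oldest + rng.youngest) / 2)
            )
            continue
        floor = 0.0
        for c in n.children:
            floor = max(floor, c.age + eps, c.annotations.get("fad", 0.0))
        age = floor
        source = None
        for con in node_for_constraint.get(id(n), []):
            if con.age(policy) >= age:
                age = con.age(policy)
                source = con.name
        n.age = age
        # carry the oldest well-dated first appearance of the subtree upward
        n.annotations["fad"] = max(c.annotations.get("fad", 0.0) for c in n.children)
        if source is not None:
            binding.append(source)
    for n in t.postorder():
        if n.parent is not None:
            n.length = n.parent.age - n.age
    return TimeTree(tree=t, policy=policy, eps=eps, binding=binding)


def node_age(tt: TimeTree, members) -> float:
    """Age of the most recent node whose clade equals ``members``."""
    target = frozenset(members)
    below = _clade_sets(tt.tree)
    for n in tt.tree.postorder():
        if not n.is_leaf and below[id(n)] == target:
            return n.age
    raise CalibrationError("no node with exactly that membership")


def validate_timetree(tt: TimeTree, cal: CalibrationSet | None = None) -> dict:
    """Report-only check: negative branches, constraint status, and tips
    whose entire range predates their parent node."""
    violations = []
    range_flags = []
    for n in tt.tree.postorder():
        if n.parent is None:
            continue
        if n.age - n.parent.age > 1e-9:
            violations.append(
                {
                    "node": n.label or "internal",
                    "age": n.age,
                    "parent_age": n.parent.age,
                }
            )
        if n.is_leaf:
            oldest, youngest = n.annotations.get("range", (n.age, n.age))
            if youngest - n.parent.age > 1e-9:
                range_flags.append(
                    {"tip": n.label, "range": (oldest, youngest), "parent_age": n.parent.age}
                )
    report = {
        "n_violations": len(violations),
        "violations": violations,
        "tips_entirely_older_than_parent": range_flags,
        "binding_constraints": sorted(set(tt.binding)),
    }
    if cal is not None:
        dominated = sorted(set(cal.node_constraints) - set(tt.binding))
        report["dominated_constraints"] = dominated
    return report
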