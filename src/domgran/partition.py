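"""Granular partitions and granularity trees.

A granular partition is a system of cells and subcells in which (i) the
subcell relation is a partial order, (ii) a unique maximal (root) cell
exists, (iii) chains of nested cells are finite, and (iv) two overlapping
cells always stand in the subcell relation — no partial overlap.  Every
finite granular partition can be drawn as a rooted tree (a granularity
tree); a *cut* through that tree at a fixed depth is one granularity level.

In a constitutive hierarchy every cut is type-homogeneous and sums
mereologically to the whole; in a cumulative-constitutive hierarchy —
the realistic organisation of organisms, with extracellular molecules and
free cells attached directly at coarse levels — cuts may fail to sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx

from .core import AssertionSet


# --------------------------------------------------------------------------
# Binary relations and order properties
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BinaryRelationInstance:
    """A finite binary relation given extensionally over a universe."""

    pairs: frozenset[tuple[str, str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        loose = {x for p in self.pairs for x in p} - self.universe
        if loose:
            raise ValueError(f"pair members outside universe: {sorted(loose)}")


@dataclass
class PropertyReport:
    """Outcome of order-property checks, with witnesses per failure."""

    properties: dict[str, bool]
    witnesses: dict[str, list[tuple]]
    warnings: list[str] = field(default_factory=list)

    def holds(self, name: str) -> bool:
        return self.properties[name]

    @property
    def all_hold(self) -> bool:
        return all(self.properties.values())


def _order_properties(rel: BinaryRelationInstance,
                      names: Sequence[str]) -> PropertyReport:
    """Decide order properties by exhaustive enumeration (small universes)."""
    pairs, universe = rel.pairs, rel.universe
    props: dict[str, bool] = {}
    wit: dict[str, list[tuple]] = {n: [] for n in names}
    succ: dict[str, set[str]] = {}
    for b, c in pairs:
        succ.setdefault(b, set()).add(c)

    if "reflexive" in names:
        missing = [(b,) for b in sorted(universe) if (b, b) not in pairs]
        props["reflexive"] = not missing
        wit["reflexive"] = missing
    if "irreflexive" in names:
        bad = [(b,) for b in sorted(universe) if (b, b) in pairs]
        props["irreflexive"] = not bad
        wit["irreflexive"] = bad
    if "antisymmetric" in names:
        bad2 = [(b, c) for (b, c) in sorted(pairs)
                if b != c and (c, b) in pairs]
        props["antisymmetric"] = not bad2
        wit["antisymmetric"] = bad2
    if "transitive" in names:
        bad3 = []
        for b in sorted(succ):
            for c in sorted(succ[b]):
                for d in sorted(succ.get(c, ())):
                    if (b, d) not in pairs:
                        bad3.append((b, c, d))
        props["transitive"] = not bad3
        wit["transitive"] = bad3

    warnings = []
    if not universe:
        warnings.append("empty universe: properties hold vacuously")
    return PropertyReport(props, wit, warnings)


def check_partial_order(rel: BinaryRelationInstance) -> PropertyReport:
    """Check transitivity, reflexivity and antisymmetry exhaustively."""
    return _order_properties(rel, ("transitive", "reflexive", "antisymmetric"))


def check_strict_partial_order(rel: BinaryRelationInstance) -> PropertyReport:
    """Check irreflexivity and transitivity (antisymmetry follows, but is
    verified as well)."""
    return _order_properties(rel, ("irreflexive", "transitive",
                                   "antisymmetric"))


def transitive_closure(pairs: set[tuple[str, str]]) -> set[tuple[str, str]]:
    g = nx.DiGraph(pairs)
    return {(a, b) for a in g for b in nx.descendants(g, a)}


# --------------------------------------------------------------------------
# Granular-partition validation
# --------------------------------------------------------------------------

@dataclass
class PartitionReport:
    """Per-condition pass/fail with witnesses for every failure."""

    conditions: dict[str, bool]
    witnesses: dict[str, list[tuple]]

    @property
    def valid(self) -> bool:
        return all(self.conditions.values())


def validate_granular_partition(
        cells: Mapping[str, frozenset[str] | set[str]],
        subcell_pairs: set[tuple[str, str]]) -> PartitionReport:
    """Check granular-partition conditions (i)-(iv) on explicit cells.

    ``cells`` maps cell ids to nonempty member sets; ``subcell_pairs`` is
    the (not necessarily closed) subcell relation, read "x subcell of y".
    """
    for cid, members in cells.items():
        if not members:
            raise ValueError(f"cell {cid!r} has empty member set")
    conditions: dict[str, bool] = {}
    witnesses: dict[str, list[tuple]] = {
        "partial_order": [], "unique_root": [],
        "finite_chains": [], "no_partial_overlap": []}

    closed = transitive_closure(subcell_pairs) | subcell_pairs
    # (i) the reflexive closure of the subcell relation is a partial order
    reflexive = closed | {(c, c) for c in cells}
    rep = check_partial_order(BinaryRelationInstance(
        frozenset(reflexive), frozenset(cells)))
    conditions["partial_order"] = rep.all_hold
    for name in ("transitive", "reflexive", "antisymmetric"):
        witnesses["partial_order"].extend(rep.witnesses[name])

    # (ii) a unique maximal (root) cell
    proper = {(a, b) for (a, b) in closed if a != b}
    non_maximal = {a for a, _ in proper}
    maximal = sorted(set(cells) - non_maximal)
    conditions["unique_root"] = len(maximal) == 1
    if len(maximal) != 1:
        witnesses["unique_root"] = [tuple(maximal)]

    # (iii) finite chains: for finite input this reduces to acyclicity
    g = nx.DiGraph(subcell_pairs)
    cycles = list(nx.simple_cycles(g))
    conditions["finite_chains"] = not cycles
    witnesses["finite_chains"] = [tuple(c) for c in cycles]

    # (iv) overlap implies subcellhood — no partial overlap
    ids = sorted(cells)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if (set(cells[a]) & set(cells[b])
                    and (a, b) not in closed and (b, a) not in closed):
                witnesses["no_partial_overlap"].append((a, b))
    conditions["no_partial_overlap"] = not witnesses["no_partial_overlap"]

    return PartitionReport(conditions, witnesses)


# --------------------------------------------------------------------------
# Granularity trees
# --------------------------------------------------------------------------

@dataclass
class GranularityTree:
    """Rooted tree of one granular partition of a single whole.

    ``extent`` maps each node to its matter as a set of ground units — the
    leaves of the asserted parthood forest; the framework never invents
    sub-leaf matter.
    """

    root: str
    parent: dict[str, str]
    depth: dict[str, int]
    extent: dict[str, frozenset[str]]

    def children(self, node: str) -> list[str]:
        return sorted(c for c, p in self.parent.items() if p == node)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.depth)

    @property
    def max_depth(self) -> int:
        return max(self.depth.values())

    def leaves(self) -> list[str]:
        parents = set(self.parent.values())
        return sorted(n for n in self.depth if n not in parents)

    def to_cells(self) -> tuple[dict[str, frozenset[str]],
                                set[tuple[str, str]]]:
        """The induced cells and subcell pairs (child subcell of parent)."""
        cells = dict(self.extent)
        pairs = set(self.parent.items())
        return cells, pairs


@dataclass(frozen=True)
class Cut:
    """A strict depth cut: the nodes at exactly one tree depth."""

    index: int
    members: frozenset[str]


class PartitionError(ValueError):
    """A parthood structure that is not a granular partition."""


def build_granularity_tree(assertions: AssertionSet, root: str,
                           relation: str = "directProperPartOf"
                           ) -> GranularityTree:
    """Build a granularity tree from parthood assertions under ``root``.

    Rejects cycles (with the offending cycle) and multi-parent nodes
    (partial overlap).  Extents are computed bottom-up: a leaf's extent is
    itself, an internal node's extent the union of its children's.
    """
    if root not in assertions.entities:
        raise PartitionError(f"unknown root entity: {root!r}")
    child_of: dict[str, str] = {}
    children: dict[str, list[str]] = {}
    for a in assertions.by_predicate(relation):
        if a.subject in child_of and child_of[a.subject] != a.object:
            raise PartitionError(
                f"node {a.subject!r} has two parents "
                f"({child_of[a.subject]!r}, {a.object!r}): partial overlap")
        child_of[a.subject] = a.object
        children.setdefault(a.object, []).append(a.subject)

    g = nx.DiGraph((c, p) for c, p in child_of.items())
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        raise PartitionError(f"cycle in parthood: {cycle}")

    # restrict to the subtree reachable from root
    depth: dict[str, int] = {root: 0}
    parent: dict[str, str] = {}
    order = [root]
    queue = [root]
    while queue:
        node = queue.pop(0)
        for c in sorted(children.get(node, ())):
            parent[c] = node
            depth[c] = depth[node] + 1
            order.append(c)
            queue.append(c)

    extent: dict[str, frozenset[str]] = {}
    for node in reversed(order):
        kids = [c for c in children.get(node, ()) if c in depth]
        if kids:
            extent[node] = frozenset().union(*(extent[c] for c in kids))
        else:
            extent[node] = frozenset({node})

    tree = GranularityTree(root, parent, depth, extent)
    report = validate_granular_partition(*tree.to_cells())
    if not report.valid:
        bad = {k: v for k, v in report.conditions.items() if not v}
        raise PartitionError(f"induced cells violate partition conditions: "
                             f"{sorted(bad)}")
    return tree


def extract_cuts(tree: GranularityTree) -> list[Cut]:
    """One strict cut per depth 1..max-depth (a depth-0 tree has none)."""
    cuts = []
    for k in range(1, tree.max_depth + 1):
        members = frozenset(n for n, d in tree.depth.items() if d == k)
        cuts.append(Cut(k, members))
    return cuts


def complete_cut(tree: GranularityTree, index: int) -> frozenset[str]:
    """Antichain variant of a cut: nodes at the given depth plus every leaf
    that bottoms out above it.  Its extents always partition the root's."""
    if not 1 <= index <= tree.max_depth:
        raise IndexError(f"cut index {index} out of range 1..{tree.max_depth}")
    leaves = set(tree.leaves())
    members = {n for n, d in tree.depth.items()
               if d == index or (n in leaves and 0 < d < index)}
    return frozenset(members)


def summation_check(tree: GranularityTree,
                    cut: Cut) -> tuple[bool, frozenset[str]]:
    """Does the mereological sum of a cut's members equal the whole?

    Returns (True, empty) when the union of member extents equals the root
    extent, else (False, uncovered ground units).
    """
    if not cut.members <= set(tree.depth):
        raise ValueError("cut does not belong to this tree")
    covered = frozenset().union(
        *(tree.extent[m] for m in cut.members)) if cut.members else frozenset()
    missing = tree.extent[tree.root] - covered
    return (not missing, missing)


def diagnose_organization(tree: GranularityTree,
                          type_of: Mapping[str, str]) -> str:
    """Classify the tree's organisation.

    ``constitutive`` iff every strict cut is type-homogeneous, every
    non-root node's parent sits in the immediately coarser cut, and every
    cut sums to the whole; ``cumulative-constitutive`` otherwise.
    """
    untyped = [n for n in tree.nodes if n not in type_of]
    if untyped:
        raise ValueError(f"untyped nodes: {untyped}")
    for cut in extract_cuts(tree):
        if len({type_of[m] for m in cut.members}) > 1:
            return "cumulative-constitutive"
        for m in cut.members:
            parent = tree.parent.get(m, tree.root)
            if tree.depth[parent] != cut.index - 1:
                return "cumulative-constitutive"
        if not summation_check(tree, cut)[0]:
            return "cumulative-constitutive"
    return "constitutive"
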