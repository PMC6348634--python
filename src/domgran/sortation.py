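"""Sortation-by-type: deriving type-level granularity from instance trees.

In a cumulative-constitutive organism, instances of one basic type (most
visibly 'molecule') occur at several cuts of the instance granularity tree,
so cuts cannot be identified with types directly.  Sortation-by-type lets
every type sediment to the finest cut occupied by any of its instances and
reads the type-level structure off the resulting ranking.  The type-level
structure is emitted as ordered levels plus an existential parthood edge
list — deliberately not as a tree, since type levels in a
cumulative-constitutive organisation neither sum to the whole nor nest
uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .partition import GranularityTree


@dataclass
class TypeLevelMap:
    """Per-type level assignment with full instance provenance."""

    levels: dict[str, int]
    provenance: dict[str, set[tuple[str, int]]]

    def span(self, type_name: str) -> set[int]:
        """The set of cut indices occupied by a type's instances."""
        return {idx for _, idx in self.provenance[type_name]}


def instance_levels(tree: GranularityTree) -> dict[str, int]:
    """Map every node to its strict-cut index (root maps to 0)."""
    return dict(tree.depth)


def sortation_by_type(tree: GranularityTree,
                      type_of: Mapping[str, str]) -> TypeLevelMap:
    """Assign each type the finest (deepest) cut index among its instances.

    Every non-root node must be typed; the root is excluded (it is the
    unpartitioned whole, not a member of any cut).
    """
    levels: dict[str, int] = {}
    provenance: dict[str, set[tuple[str, int]]] = {}
    for node, depth in tree.depth.items():
        if node == tree.root:
            continue
        if node not in type_of:
            raise ValueError(f"untyped node: {node!r}")
        t = type_of[node]
        provenance.setdefault(t, set()).add((node, depth))
        levels[t] = max(levels.get(t, 0), depth)
    return TypeLevelMap(levels, provenance)


def type_granularity_levels(
        type_map: TypeLevelMap,
        tree: GranularityTree | None = None,
        type_of: Mapping[str, str] | None = None,
) -> tuple[list[tuple[int, list[str]]], set[tuple[str, str]]]:
    """Group types by sorted level, coarse to fine, with parthood edges.

    Returns ``(levels, edges)`` where ``levels`` is a list of
    ``(level index, sorted types)`` ordered coarse→fine and ``edges``
    contains ``(A, B)`` iff some instance of type A is a direct proper part
    of some instance of type B (requires ``tree`` and ``type_of``).
    """
    if not type_map.levels:
        raise ValueError("empty type-level map")
    by_level: dict[int, list[str]] = {}
    for t, lv in type_map.levels.items():
        by_level.setdefault(lv, []).append(t)
    levels = [(lv, sorted(by_level[lv])) for lv in sorted(by_level)]
    edges: set[tuple[str, str]] = set()
    if tree is not None and type_of is not None:
        for child, parent in tree.parent.items():
            if parent == tree.root:
                continue
            edges.add((type_of[child], type_of[parent]))
    return levels, edges
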