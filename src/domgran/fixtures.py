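"""Deterministic test organisms.

``worked_example`` reproduces the idealised multi-cellular organism used as
the worked example: a constitutive variant (entities a-f) in which every
molecule sits in an organelle, every organelle in a cell, every cell in an
organ, and a cumulative-constitutive variant (entities g-y) in which
extracellular molecules hang directly off the organism and free molecules
off organs and cells.

``random_organism`` generates parameterised organisms with the same two
organisational patterns; the seed drives the random connectedness topology
among siblings, while the counts fix the parthood structure exactly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .core import Assertion, AssertionSet, EntityInstance
from .partition import GranularityTree, build_granularity_tree

ROOT_ID = "whole"

#: Letter-to-type mapping for the cumulative variant: one consistent
#: reading with cells q, m, n, o, p and molecules k, l at the second
#: partition; trivially editable.
CUMULATIVE_TYPES = {
    "i": "organ", "j": "organ",
    "g": "molecule", "h": "molecule",
    "q": "cell", "m": "cell", "n": "cell", "o": "cell", "p": "cell",
    "k": "molecule", "l": "molecule",
    "v": "organelle", "t": "organelle", "r": "organelle",
    "w": "molecule", "u": "molecule", "s": "molecule",
    "x": "molecule", "y": "molecule",
}

#: child -> parent edges of the cumulative-variant parthood tree.
CUMULATIVE_PARENT = {
    "i": ROOT_ID, "j": ROOT_ID, "g": ROOT_ID, "h": ROOT_ID,
    "m": "i", "n": "i", "k": "i",
    "q": "j", "o": "j", "p": "j", "l": "j",
    "v": "m", "w": "m",
    "t": "n", "u": "n",
    "r": "q", "s": "q",
    "x": "v", "y": "r",
}

CONSTITUTIVE_TYPES = {
    "f": "organ", "e": "cell", "c": "organelle", "d": "organelle",
    "a": "molecule", "b": "molecule",
}

CONSTITUTIVE_PARENT = {
    "f": ROOT_ID, "e": "f", "c": "e", "d": "e", "a": "c", "b": "d",
}

_COVER_BY_TYPE = {
    "molecule": "shared-electron-shell",
    "organelle": "plasma-membrane",
    "cell": "plasma-membrane",
    "organ": "epithelium",
    "organism": "epithelium",
}


def _assemble(types: dict[str, str],
              parent: dict[str, str]) -> AssertionSet:
    entities = [EntityInstance(ROOT_ID, label="whole organism",
                               asserted_types=frozenset({"organism"}))]
    for eid in sorted(types):
        entities.append(EntityInstance(
            eid, label=f"{types[eid]} {eid}",
            asserted_types=frozenset({types[eid]})))
    aset = AssertionSet(entities)
    for child in sorted(parent):
        aset.add_assertion(Assertion(child, "directProperPartOf",
                                     parent[child]))
        aset.add_assertion(Assertion(child, "properPartOf", parent[child]))
    # transitive properPartOf closure so containment queries need no inference
    for child in sorted(parent):
        anc = parent[child]
        while anc in parent:
            anc = parent[anc]
            aset.add_assertion(Assertion(child, "properPartOf", anc))
        if anc == ROOT_ID and parent[child] != ROOT_ID:
            aset.add_assertion(Assertion(child, "properPartOf", ROOT_ID))
    for eid, t in [(ROOT_ID, "organism")] + sorted(types.items()):
        aset.add_assertion(Assertion(eid, "hasPhysicalCovering",
                                     _COVER_BY_TYPE[t]))
    # function and shared-origin facts on cells and organs, so the
    # functional and historical/evolutionary frames are populated
    for eid, t in sorted(types.items()):
        if t in ("cell", "organ"):
            aset.add_assertion(Assertion(eid, "bearsFunction",
                                         f"function-of-{eid}"))
            aset.add_assertion(Assertion(eid, "sharesOrigin", "zygote"))
    aset.add_assertion(Assertion(ROOT_ID, "bearsFunction", "life"))
    aset.add_assertion(Assertion(ROOT_ID, "sharesOrigin", "zygote"))
    return aset


def worked_example(variant: str) -> tuple[AssertionSet, GranularityTree]:
    """The worked-example organism plus its expected granularity tree.

    ``variant`` is ``"constitutive"`` (entities a-f under the whole) or
    ``"cumulative"`` (entities g-y, with extracellular molecules g, h as
    direct parts of the organism and molecules at every partition depth).
    """
    if variant == "constitutive":
        types, parent = CONSTITUTIVE_TYPES, CONSTITUTIVE_PARENT
    elif variant == "cumulative":
        types, parent = CUMULATIVE_TYPES, CUMULATIVE_PARENT
    else:
        raise ValueError(f"unknown variant: {variant!r}")
    aset = _assemble(types, parent)

    depth: dict[str, int] = {ROOT_ID: 0}
    pending = dict(parent)
    while pending:
        for child, par in list(pending.items()):
            if par in depth:
                depth[child] = depth[par] + 1
                del pending[child]
    leaves = set(parent) - set(parent.values())
    extent: dict[str, frozenset[str]] = {}
    for node in sorted(depth, key=lambda n: -depth[n]):
        kids = [c for c, p in parent.items() if p == node]
        if node in leaves or not kids:
            extent[node] = frozenset({node})
        else:
            extent[node] = frozenset().union(*(extent[c] for c in kids))
    expected = GranularityTree(ROOT_ID, dict(parent), depth, extent)
    return aset, expected


def worked_example_types(variant: str) -> dict[str, str]:
    """Basic-type map for a fixture variant, including the root."""
    types = dict(CONSTITUTIVE_TYPES if variant == "constitutive"
                 else CUMULATIVE_TYPES)
    types[ROOT_ID] = "organism"
    return types


# --------------------------------------------------------------------------
# Random organisms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OrganismSpec:
    """Branching counts for a generated organism.

    Counts are exact; positive extracellular/free counts make the organism
    cumulative-constitutive, all-zero free counts make it constitutive.
    """

    n_organs: int = 2
    cells_per_organ: int = 2
    organelles_per_cell: int = 2
    molecules_per_organelle: int = 2
    extracellular_molecules_per_organ: int = 0
    free_molecules_per_cell: int = 0
    free_cells: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_organs", "cells_per_organ", "organelles_per_cell",
                     "molecules_per_organelle",
                     "extracellular_molecules_per_organ",
                     "free_molecules_per_cell", "free_cells"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def random_organism(spec: OrganismSpec) -> AssertionSet:
    """Generate an organism assertion set from a branching specification.

    Entity ids are counter-based (organ-1, cell-1-2, ...) for readable
    diffs.  The seed controls the random connectedTo spanning trees among
    sibling cells and organelles; the parthood topology is fixed by the
    counts, so identical specs serialise identically.
    """
    rng = random.Random(spec.seed)
    types: dict[str, str] = {}
    parent: dict[str, str] = {}

    for i in range(1, spec.n_organs + 1):
        organ = f"organ-{i}"
        types[organ] = "organ"
        parent[organ] = ROOT_ID
        for e in range(1, spec.extracellular_molecules_per_organ + 1):
            mid = f"ecmol-{i}-{e}"
            types[mid] = "molecule"
            parent[mid] = organ
        for j in range(1, spec.cells_per_organ + 1):
            cell = f"cell-{i}-{j}"
            types[cell] = "cell"
            parent[cell] = organ
            for fidx in range(1, spec.free_molecules_per_cell + 1):
                mid = f"freemol-{i}-{j}-{fidx}"
                types[mid] = "molecule"
                parent[mid] = cell
            for k in range(1, spec.organelles_per_cell + 1):
                org = f"organelle-{i}-{j}-{k}"
                types[org] = "organelle"
                parent[org] = cell
                for m in range(1, spec.molecules_per_organelle + 1):
                    mid = f"mol-{i}-{j}-{k}-{m}"
                    types[mid] = "molecule"
                    parent[mid] = org
    for c in range(1, spec.free_cells + 1):
        cell = f"freecell-{c}"
        types[cell] = "cell"
        parent[cell] = ROOT_ID

    aset = _assemble(types, parent)

    # random sibling adjacency: a seeded spanning tree over each organ's
    # cells and each cell's organelles
    def link_siblings(members: list[str]) -> None:
        if len(members) < 2:
            return
        shuffled = members[:]
        rng.shuffle(shuffled)
        for a, b in zip(shuffled, shuffled[1:]):
            aset.add_assertion(Assertion(a, "connectedTo", b))

    for i in range(1, spec.n_organs + 1):
        link_siblings([f"cell-{i}-{j}"
                       for j in range(1, spec.cells_per_organ + 1)])
        for j in range(1, spec.cells_per_organ + 1):
            link_siblings([f"organelle-{i}-{j}-{k}"
                           for k in range(1, spec.organelles_per_cell + 1)])
    return aset


def organism_tree(aset: AssertionSet) -> GranularityTree:
    """Granularity tree of a generated organism (rooted at the whole)."""
    return build_granularity_tree(aset, ROOT_ID)


def organism_types(aset: AssertionSet) -> dict[str, str]:
    return {eid: next(iter(e.asserted_types))
            for eid, e in aset.entities.items()}
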