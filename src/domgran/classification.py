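"""Frame-dependent classification and granular representation chains.

Bona fideness is frame-dependent: one concrete entity instantiates a
different material-entity category in every spatio-structural frame of
reference.  A eukaryotic cell is a building block at its own frame, a bona
fide cluster of molecules at the molecule frame, and — when it lies outside
every epithelially-delimited compartment — a non-countable portion of
eukaryotic-cell matter at coarser frames.  The per-frame readings of one
entity are tied together by granular representation relations
(hasCoarserGranRep, co_n-c_GranRep, co_c_GranRep, FuncGranRep,
Hist/EvGranRep), which form the entity's representation chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .core import (
    AssertionSet,
    BuildingBlockLevel,
    CategoryTaxonomy,
    FrameOfReference,
    FrameworkConfig,
    LEVEL_BY_ORDINAL,
    build_taxonomy,
    building_block_category,
    cluster_category,
    fiat_cluster_category,
    fiat_part_category,
    frame_inventory,
    group_of_fiat_category,
    group_of_objects_category,
    scattered_portions_category,
    self_connected_portion_category,
)

#: Granular representation relation names (their conventional spellings).
HAS_COARSER = "hasCoarserGranRep"
CO_NC = "co_n-c_GranRep"
CO_C = "co_c_GranRep"
FUNC_REP = "FuncGranRep"
HISTEV_REP = "Hist/EvGranRep"


@dataclass
class ClassificationResult:
    """One entity's category per frame plus countability flags."""

    entity_id: str
    per_frame: dict[FrameOfReference, str]
    intrinsic_level: Optional[BuildingBlockLevel]
    countable_in: dict[FrameOfReference, bool]


@dataclass
class RepresentationChain:
    """Frame-ordered granular representations of one entity.

    ``links`` holds (finer frame, coarser frame, relation, finer category,
    coarser category) for consecutive classified spatio-structural frames;
    ``side_links`` holds (relation, target category) entries for the
    functional and historical/evolutionary readings.
    """

    entity_id: str
    links: list[tuple[FrameOfReference, FrameOfReference, str, str, str]]
    side_links: list[tuple[str, str]]
    gaps: list[FrameOfReference] = field(default_factory=list)


class ClassificationContext:
    """Precomputed structural views over an assertion set.

    Parthood containment uses the transitive closure of properPartOf and
    directProperPartOf; self-connectedness is read from asserted
    connectedTo facts (no geometry is computed).
    """

    def __init__(self, assertions: AssertionSet,
                 config: FrameworkConfig | None = None,
                 taxonomy: CategoryTaxonomy | None = None) -> None:
        self.assertions = assertions
        self.config = config or FrameworkConfig()
        self.taxonomy = taxonomy or build_taxonomy(self.config)

        part_pairs = (assertions.pairs("directProperPartOf")
                      | assertions.pairs("properPartOf"))
        g = nx.DiGraph(part_pairs)
        g.add_nodes_from(assertions.entities)
        self._part_graph = g  # edge part -> whole
        self._components: dict[str, list[str]] = {
            e: sorted(a.subject
                      for a in assertions.by_predicate("directProperPartOf")
                      if a.object == e)
            for e in assertions.entities}
        conn = nx.Graph(assertions.pairs("connectedTo"))
        conn.add_nodes_from(assertions.entities)
        self._conn = conn
        self._functions = {a.subject
                           for a in assertions.by_predicate("bearsFunction")}
        self._origins = {a.subject
                         for a in assertions.by_predicate("sharesOrigin")}
        self._level_cache: dict[str, Optional[BuildingBlockLevel]] = {}

    # -- structural queries ---------------------------------------------

    def wholes_of(self, eid: str) -> set[str]:
        """All entities the given one is a (transitive) proper part of."""
        return nx.descendants(self._part_graph, eid)

    def parts_of(self, eid: str) -> set[str]:
        return nx.ancestors(self._part_graph, eid)

    def components(self, eid: str) -> list[str]:
        """Direct proper parts."""
        return self._components[eid]

    def self_connected(self, members: list[str]) -> bool:
        """Do the members adhere into one connectedTo component?"""
        if len(members) <= 1:
            return True
        sub = self._conn.subgraph(members)
        return nx.is_connected(sub)

    # -- intrinsic level ------------------------------------------------

    def intrinsic_level(self, eid: str) -> Optional[BuildingBlockLevel]:
        """The building-block level an entity occupies in its own right.

        Decided from the asserted physical covering: electron shell →
        atom; shared electron shell → molecule; plasma membrane without /
        with membrane-covered proper parts → single-membrane-enclosed /
        membrane-within-membrane entity; epithelium inside / not inside an
        epithelium-covered whole → compartment / organism.  Entities with
        no qualifying covering (aggregates, fiat regions) have none.
        """
        if eid in self._level_cache:
            return self._level_cache[eid]
        cover = self.assertions.covering_of(eid)
        level: Optional[BuildingBlockLevel] = None
        if cover == "electron-shell":
            level = LEVEL_BY_ORDINAL[1]
        elif cover == "shared-electron-shell":
            level = LEVEL_BY_ORDINAL[2]
        elif cover == "plasma-membrane":
            has_membrane_part = any(
                self.assertions.covering_of(p) == "plasma-membrane"
                for p in self.parts_of(eid))
            level = LEVEL_BY_ORDINAL[4 if has_membrane_part else 3]
        elif cover == "epithelium":
            inside = any(self.assertions.covering_of(w) == "epithelium"
                         for w in self.wholes_of(eid))
            level = LEVEL_BY_ORDINAL[5 if inside else 6]
        self._level_cache[eid] = level
        return level

    def _coarsest_constituent(self, eid: str) -> Optional[BuildingBlockLevel]:
        """Coarsest intrinsic level among an entity's transitive parts."""
        levels = [self.intrinsic_level(p) for p in self.parts_of(eid)]
        levels = [lv for lv in levels if lv is not None]
        return max(levels) if levels else None

    def _inside_block_of(self, eid: str, ordinal: int) -> bool:
        return any((lv := self.intrinsic_level(w)) is not None
                   and lv.ordinal == ordinal
                   for w in self.wholes_of(eid))

    # -- per-frame classification ---------------------------------------

    def classify_in_frame(self, eid: str,
                          frame: FrameOfReference) -> Optional[str]:
        """The category an entity instantiates at one frame of reference.

        Returns None when the frame offers no category for the entity
        (e.g. an entity with no structural facts at all).
        """
        if frame.kind == "functional":
            if eid in self._functions:
                return "functional_unit"
            if any(w in self._functions for w in self.wholes_of(eid)):
                return "fiat_functional_unit_part"
            return None
        if frame.kind == "historical-evolutionary":
            if eid in self._origins:
                return "historical_evolutionary_unit"
            if any(w in self._origins for w in self.wholes_of(eid)):
                return "fiat_historical_evolutionary_unit_part"
            return None

        assert frame.level is not None
        L = frame.level
        lvl = self.intrinsic_level(eid)

        if lvl is not None:
            if lvl.ordinal == L.ordinal:
                return building_block_category(L)
            if lvl.ordinal > L.ordinal:
                # a coarser building block is a bona fide composition of
                # clustered finer-level matter
                return cluster_category(L)
            # finer building block viewed at a coarser frame
            if self._inside_block_of(eid, L.ordinal):
                return fiat_part_category(L)
            return self_connected_portion_category(lvl)

        # no covering: aggregates and fiat regions
        coarsest = self._coarsest_constituent(eid)
        if coarsest is None:
            return None
        comps = self.components(eid)
        connected = self.self_connected(comps)

        if coarsest.ordinal > L.ordinal:
            return (cluster_category(L) if connected
                    else group_of_objects_category(L))
        if coarsest.ordinal == L.ordinal:
            all_objects = all(
                (clv := self.intrinsic_level(c)) is not None
                and clv.ordinal == L.ordinal
                for c in comps)
            if all_objects:
                return (cluster_category(L) if connected
                        else group_of_objects_category(L))
            return (fiat_cluster_category(L) if connected
                    else group_of_fiat_category(L))
        # all constituents finer than the frame
        if self._inside_block_of(eid, L.ordinal):
            return fiat_part_category(L)
        return (self_connected_portion_category(coarsest) if connected
                else scattered_portions_category(coarsest))

    def multiple_instantiation(
            self, eid: str,
            frames: list[FrameOfReference] | None = None
    ) -> ClassificationResult:
        """Classify one entity in every frame of the inventory."""
        frames = frames or frame_inventory(self.config)
        per_frame: dict[FrameOfReference, str] = {}
        countable: dict[FrameOfReference, bool] = {}
        for f in frames:
            cat = self.classify_in_frame(eid, f)
            if cat is None:
                continue
            per_frame[f] = cat
            countable[f] = not self.taxonomy.descends_from(
                cat, "portion_of_matter_entity")
        return ClassificationResult(eid, per_frame,
                                    self.intrinsic_level(eid), countable)

    def classify_all(self, frames: list[FrameOfReference] | None = None
                     ) -> dict[str, ClassificationResult]:
        return {eid: self.multiple_instantiation(eid, frames)
                for eid in sorted(self.assertions.entities)}


# --------------------------------------------------------------------------
# Module-level operation wrappers
# --------------------------------------------------------------------------

def intrinsic_level(eid: str,
                    assertions: AssertionSet) -> Optional[BuildingBlockLevel]:
    return ClassificationContext(assertions).intrinsic_level(eid)


def classify_in_frame(eid: str, frame: FrameOfReference,
                      assertions: AssertionSet) -> Optional[str]:
    return ClassificationContext(assertions).classify_in_frame(eid, frame)


def multiple_instantiation(eid: str, assertions: AssertionSet,
                           frames: list[FrameOfReference] | None = None
                           ) -> ClassificationResult:
    return ClassificationContext(assertions).multiple_instantiation(eid,
                                                                    frames)


def representation_chain(eid: str,
                         classification: ClassificationResult,
                         taxonomy: CategoryTaxonomy | None = None
                         ) -> RepresentationChain:
    """Link the entity's per-frame representations fine-to-coarse.

    hasCoarserGranRep preserves countability; co_n-c_GranRep marks a
    countable reading becoming a non-countable portion of matter at the
    next coarser frame; co_c_GranRep the reverse.  Functional and
    historical/evolutionary readings attach as side links.  A frame gap
    between populated frames truncates the chain and is reported.
    """
    ss = sorted((f for f in classification.per_frame
                 if f.kind == "spatio-structural"),
                key=lambda f: (f.level.ordinal, f.context_tag or ""))
    all_ss_ordinals = {f.level.ordinal for f in ss}
    links = []
    gaps: list[FrameOfReference] = []
    for fine, coarse in zip(ss, ss[1:]):
        if (coarse.level.ordinal - fine.level.ordinal > 1
                and any(o not in all_ss_ordinals
                        for o in range(fine.level.ordinal + 1,
                                       coarse.level.ordinal))):
            gaps.append(coarse)
            break
        c_fine = classification.countable_in[fine]
        c_coarse = classification.countable_in[coarse]
        if c_fine and not c_coarse:
            rel = CO_NC
        elif not c_fine and c_coarse:
            rel = CO_C
        else:
            rel = HAS_COARSER
        links.append((fine, coarse, rel,
                      classification.per_frame[fine],
                      classification.per_frame[coarse]))
    side = []
    for f, cat in classification.per_frame.items():
        if f.kind == "functional":
            side.append((FUNC_REP, cat))
        elif f.kind == "historical-evolutionary":
            side.append((HISTEV_REP, cat))
    return RepresentationChain(eid, links, sorted(side), gaps)
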