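"""Core domain vocabulary for the granularity framework.

The framework organises biological material entities along three frames of
reference — spatio-structural, functional, and historical/evolutionary — and,
within the spatio-structural frame, along six building-block levels (atom,
molecule, single-membrane-enclosed entity, membrane-within-membrane entity,
epithelially-delimited compartment, epithelially-delimited multi-cellular
organism).  A building block is a bona fide object held together by a
physical covering (electron shell, plasma membrane, or epithelium); bona fide
clusters, fiat parts and groups of such objects populate the remainder of
each level's category inventory.

This module defines the entity/assertion substrate, the causal-unity
registry, the frame inventory, and the generated ``material entity``
category taxonomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional


# --------------------------------------------------------------------------
# Relations and assertions
# --------------------------------------------------------------------------

#: Predicates accepted in assertion files.
PREDICATES = (
    "directProperPartOf",
    "properPartOf",
    "hasPhysicalCovering",
    "connectedTo",
    "bearsFunction",
    "sharesOrigin",
)

#: Legal objects of ``hasPhysicalCovering`` assertions.
COVERING_KINDS = (
    "electron-shell",
    "shared-electron-shell",
    "plasma-membrane",
    "epithelium",
    "none",
)


@dataclass(frozen=True)
class RelationDef:
    """A named binary relation with its declared formal properties."""

    name: str
    domain_category: str
    range_category: str
    declared_properties: frozenset[str] = frozenset()

    def is_strict_partial_order(self) -> bool:
        return {"transitive", "irreflexive"} <= self.declared_properties


#: Registered relation definitions, keyed by predicate name.
RELATION_DEFS: dict[str, RelationDef] = {
    "directProperPartOf": RelationDef(
        "directProperPartOf", "material entity", "material entity",
        frozenset({"irreflexive"})),
    "properPartOf": RelationDef(
        "properPartOf", "material entity", "material entity",
        frozenset({"transitive", "irreflexive"})),
    "hasPhysicalCovering": RelationDef(
        "hasPhysicalCovering", "material entity", "covering kind",
        frozenset()),
    "connectedTo": RelationDef(
        "connectedTo", "material entity", "material entity",
        frozenset({"reflexive"})),
    "bearsFunction": RelationDef(
        "bearsFunction", "material entity", "function", frozenset()),
    "sharesOrigin": RelationDef(
        "sharesOrigin", "material entity", "origin", frozenset()),
}


@dataclass(frozen=True)
class EntityInstance:
    """A particular (instance) with optional asserted category names."""

    id: str
    label: str = ""
    asserted_types: frozenset[str] = frozenset()


@dataclass(frozen=True)
class Assertion:
    """A binary fact: ``subject predicate object``.

    The object is an entity id for parthood/connectedness predicates, a
    covering kind for ``hasPhysicalCovering``, and an opaque function or
    origin identifier for ``bearsFunction`` / ``sharesOrigin``.
    """

    subject: str
    predicate: str
    object: str

    def __post_init__(self) -> None:
        if self.predicate not in PREDICATES:
            raise ValueError(f"unregistered predicate: {self.predicate!r}")
        if (self.predicate == "hasPhysicalCovering"
                and self.object not in COVERING_KINDS):
            raise ValueError(f"unknown covering kind: {self.object!r}")


class AssertionSet:
    """The factual substrate: entities, their types, and binary facts."""

    def __init__(self,
                 entities: Iterable[EntityInstance] = (),
                 assertions: Iterable[Assertion] = ()) -> None:
        self.entities: dict[str, EntityInstance] = {}
        self.assertions: list[Assertion] = []
        self._seen: set[Assertion] = set()
        for e in entities:
            self.add_entity(e)
        for a in assertions:
            self.add_assertion(a)

    def add_entity(self, entity: EntityInstance) -> None:
        if entity.id in self.entities:
            raise ValueError(f"duplicate entity id: {entity.id!r}")
        self.entities[entity.id] = entity

    def add_assertion(self, assertion: Assertion) -> bool:
        """Add a fact; returns False (and skips) for an exact duplicate."""
        if assertion in self._seen:
            return False
        for eid in (assertion.subject,):
            if eid not in self.entities:
                raise ValueError(f"unknown subject entity: {eid!r}")
        if assertion.predicate in ("directProperPartOf", "properPartOf",
                                   "connectedTo"):
            if assertion.object not in self.entities:
                raise ValueError(f"unknown object entity: {assertion.object!r}")
        self._seen.add(assertion)
        self.assertions.append(assertion)
        return True

    # -- convenience accessors ------------------------------------------

    def by_predicate(self, predicate: str) -> list[Assertion]:
        return [a for a in self.assertions if a.predicate == predicate]

    def pairs(self, predicate: str) -> set[tuple[str, str]]:
        return {(a.subject, a.object) for a in self.by_predicate(predicate)}

    def covering_of(self, entity_id: str) -> Optional[str]:
        """The asserted physical covering of an entity, or None.

        Raises ValueError on contradictory covering assertions.
        """
        kinds = {a.object for a in self.assertions
                 if a.predicate == "hasPhysicalCovering"
                 and a.subject == entity_id}
        kinds.discard("none")
        if len(kinds) > 1:
            raise ValueError(
                f"contradictory coverings for {entity_id!r}: {sorted(kinds)}")
        return next(iter(kinds), None)

    def types_of(self, entity_id: str) -> frozenset[str]:
        return self.entities[entity_id].asserted_types

    def sorted_entities(self) -> list[EntityInstance]:
        return [self.entities[k] for k in sorted(self.entities)]

    def __len__(self) -> int:
        return len(self.entities)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssertionSet):
            return NotImplemented
        return (self.entities == other.entities
                and sorted(self.assertions, key=_assertion_key)
                == sorted(other.assertions, key=_assertion_key))


def _assertion_key(a: Assertion) -> tuple[str, str, str]:
    return (a.subject, a.predicate, a.object)


# --------------------------------------------------------------------------
# Building-block levels
# --------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class BuildingBlockLevel:
    """One of the six canonical building-block levels, 1 = finest."""

    ordinal: int
    name: str = field(compare=False)
    tag: str = field(compare=False)  # snake-case identifier used in category names


#: Canonical six-level inventory, finest to coarsest.
BUILDING_BLOCK_LEVELS: tuple[BuildingBlockLevel, ...] = (
    BuildingBlockLevel(1, "atom", "atom"),
    BuildingBlockLevel(2, "molecule", "molecule"),
    BuildingBlockLevel(3, "single-membrane-enclosed entity",
                       "single_membrane_enclosed_entity"),
    BuildingBlockLevel(4, "membrane-within-membrane entity",
                       "eukaryotic_cell"),
    BuildingBlockLevel(5, "epithelially-delimited compartment",
                       "epithelially_delimited_compartment"),
    BuildingBlockLevel(6, "epithelially-delimited multi-cellular organism",
                       "multi_cellular_organism"),
)

LEVEL_BY_ORDINAL: dict[int, BuildingBlockLevel] = {
    lv.ordinal: lv for lv in BUILDING_BLOCK_LEVELS}


def _plural(tag: str) -> str:
    if tag.endswith("entity"):
        return tag[:-len("entity")] + "entities"
    return tag + "s"


# --------------------------------------------------------------------------
# Causal unity
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CausalUnityType:
    name: str
    base: bool  # member of the Smith-et-al three-type subset
    supervenes_on: frozenset[str] = frozenset()
    includes: frozenset[str] = frozenset()


def causal_unity_registry(subset: str = "full") -> list[CausalUnityType]:
    """The five-entry causal-unity registry.

    Three base types (internal physical forces, physical covering,
    engineered assembly) come from BFO's characterisation of bona fide
    objects; two further types (bearing a function, common
    historical/evolutionary origin) cover functional and
    historical/evolutionary units.  ``subset`` selects ``"full"``,
    ``"base"``, or ``"added"``.
    """
    registry = [
        CausalUnityType("internal-physical-forces", base=True),
        CausalUnityType("physical-covering", base=True,
                        supervenes_on=frozenset({"internal-physical-forces"})),
        CausalUnityType("engineered-assembly", base=True,
                        supervenes_on=frozenset({"internal-physical-forces"})),
        CausalUnityType("bearing-function", base=False,
                        includes=frozenset({"engineered-assembly"})),
        CausalUnityType("common-origin", base=False),
    ]
    if subset == "full":
        return registry
    if subset == "base":
        return [c for c in registry if c.base]
    if subset == "added":
        return [c for c in registry if not c.base]
    raise ValueError(f"unknown subset: {subset!r}")


# --------------------------------------------------------------------------
# Frames of reference
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameOfReference:
    """A frame of reference against which bona fideness is judged.

    Spatio-structural frames carry a building-block level; the functional
    and historical/evolutionary frames do not.  ``context_tag`` is set only
    in printed-total mode, where the level-3 frame is split into an
    organelle context and a prokaryotic-cell context.
    """

    kind: str  # spatio-structural | functional | historical-evolutionary
    level: Optional[BuildingBlockLevel] = None
    context_tag: Optional[str] = None

    @property
    def name(self) -> str:
        if self.kind != "spatio-structural":
            return self.kind
        assert self.level is not None
        base = self.level.tag
        return f"{base}[{self.context_tag}]" if self.context_tag else base


class FrameworkConfig:
    """Framework configuration: registry mode and optional extra levels."""

    MODES = ("canonical", "printed_total")

    def __init__(self, mode: str = "canonical") -> None:
        if mode not in self.MODES:
            raise ValueError(
                f"unknown mode {mode!r}; expected one of {self.MODES}")
        self.mode = mode

    @classmethod
    def from_mapping(cls, data: Mapping) -> "FrameworkConfig":
        return cls(mode=data.get("mode", "canonical"))


def frame_inventory(config: FrameworkConfig) -> list[FrameOfReference]:
    """The ordered frame inventory for a configuration.

    Canonical mode: six spatio-structural frames (finest to coarsest by
    building-block level) plus one functional and one
    historical/evolutionary frame.  Printed-total mode splits the
    single-membrane-enclosed frame into organelle and prokaryotic-cell
    contexts, yielding seven spatio-structural reference contexts.
    """
    frames: list[FrameOfReference] = []
    for lv in BUILDING_BLOCK_LEVELS:
        if config.mode == "printed_total" and lv.ordinal == 3:
            frames.append(FrameOfReference("spatio-structural", lv, "organelle"))
            frames.append(FrameOfReference("spatio-structural", lv,
                                           "prokaryotic_cell"))
        else:
            frames.append(FrameOfReference("spatio-structural", lv))
    frames.append(FrameOfReference("functional"))
    frames.append(FrameOfReference("historical-evolutionary"))
    return frames


def spatio_structural_frames(config: FrameworkConfig) -> list[FrameOfReference]:
    return [f for f in frame_inventory(config) if f.kind == "spatio-structural"]


# --------------------------------------------------------------------------
# Category taxonomy (the extended 'material entity' branch)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoryNode:
    name: str
    parent: Optional[str]
    frame_tag: Optional[str] = None
    disjoint_group: Optional[str] = None
    label: str = ""


class CategoryTaxonomy:
    """Single-parent tree of material-entity categories.

    Disjointness is metadata: siblings sharing a ``disjoint_group`` id must
    not share an instance within a single frame-indexed classification.
    The three children of the root and the six level-entity classes are
    deliberately *not* disjoint (frame-dependence makes cross-frame
    co-instantiation legal).
    """

    def __init__(self) -> None:
        self.nodes: dict[str, CategoryNode] = {}

    @property
    def root(self) -> str:
        return "material_entity"

    def add(self, name: str, parent: Optional[str],
            frame_tag: Optional[str] = None,
            disjoint_group: Optional[str] = None,
            label: str = "") -> None:
        if name in self.nodes:
            raise ValueError(f"duplicate category: {name!r}")
        if parent is not None and parent not in self.nodes:
            raise ValueError(f"unknown parent: {parent!r}")
        self.nodes[name] = CategoryNode(name, parent, frame_tag,
                                        disjoint_group, label or name)

    def parent(self, name: str) -> Optional[str]:
        return self.nodes[name].parent

    def children(self, name: str) -> list[str]:
        return sorted(n for n, node in self.nodes.items()
                      if node.parent == name)

    def ancestors(self, name: str) -> list[str]:
        out = []
        cur = self.nodes[name].parent
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent
        return out

    def descends_from(self, name: str, ancestor: str) -> bool:
        return name == ancestor or ancestor in self.ancestors(name)

    def disjoint_siblings(self, name: str) -> set[str]:
        node = self.nodes[name]
        if node.disjoint_group is None:
            return set()
        return {n for n, other in self.nodes.items()
                if n != name and other.parent == node.parent
                and other.disjoint_group == node.disjoint_group}

    def validate_tree(self) -> None:
        """Assert single-rootedness and acyclicity by traversal."""
        roots = [n for n, node in self.nodes.items() if node.parent is None]
        if roots != [self.root]:
            raise ValueError(f"expected single root, found {roots}")
        for name in self.nodes:
            seen = {name}
            cur = self.nodes[name].parent
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle through {cur!r}")
                seen.add(cur)
                cur = self.nodes[cur].parent


# Category-name helpers (canonical snake-case strings; display labels keep
# the original punctuation).

def level_entity(level: BuildingBlockLevel) -> str:
    return f"{level.tag}_level_entity"


def building_block_category(level: BuildingBlockLevel) -> str:
    # the building block itself, e.g. 'molecule', 'eukaryotic_cell'
    return {
        1: "atom", 2: "molecule",
        3: "single_membrane_enclosed_entity", 4: "eukaryotic_cell",
        5: "epithelially_delimited_compartment",
        6: "epithelially_delimited_multi_cellular_organism",
    }[level.ordinal]


def cluster_category(level: BuildingBlockLevel) -> str:
    return f"bona_fide_cluster_of_{_plural(building_block_category(level))}"


def fiat_part_category(level: BuildingBlockLevel) -> str:
    return f"fiat_{level.tag}_part"


def fiat_cluster_category(level: BuildingBlockLevel) -> str:
    return f"fiat_{level.tag}_cluster"


def group_of_objects_category(level: BuildingBlockLevel) -> str:
    return f"group_of_{level.tag}_level_objects"


def group_of_fiat_category(level: BuildingBlockLevel) -> str:
    return f"group_of_fiat_{level.tag}_level_entities"


def portion_entity_category(level: BuildingBlockLevel) -> str:
    return f"portion_of_{level.tag}_entity"


def self_connected_portion_category(level: BuildingBlockLevel) -> str:
    return f"self_connected_portion_of_{level.tag}_matter"


def scattered_portions_category(level: BuildingBlockLevel) -> str:
    return f"scattered_portions_of_{level.tag}_matter"


#: Display labels preserving conventional punctuation for a few categories
#: whose snake-case form loses it.
DISPLAY_LABELS = {
    "material_entity": "material entity",
    "spatio_structural_entity": "spatio-structural entity",
    "functional_entity": "functional entity",
    "historical_evolutionary_entity": "historical/evolutionary entity",
    "portion_of_matter_entity": "portion of matter entity",
    "functional_unit": "functional unit",
    "fiat_functional_unit_part": "fiat functional unit part",
    "historical_evolutionary_unit": "historical/evolutionary unit",
    "fiat_historical_evolutionary_unit_part":
        "fiat historical/evolutionary unit part",
}


def build_taxonomy(config: FrameworkConfig) -> CategoryTaxonomy:
    """Generate the full extended 'material entity' category tree.

    material entity
      spatio-structural entity
        <six level-entity classes, each with object/fiat subtrees>
        portion of matter entity   (per-level portion classes, levels 1-5)
      functional entity            (unit / fiat unit part)
      historical/evolutionary entity (unit / fiat unit part)

    The three children of the root are not disjoint, nor are the six
    level-entity classes; per-frame object vs fiat subclasses are disjoint.
    """
    tax = CategoryTaxonomy()
    add = tax.add
    add("material_entity", None, label=DISPLAY_LABELS["material_entity"])
    add("spatio_structural_entity", "material_entity",
        label=DISPLAY_LABELS["spatio_structural_entity"])
    add("functional_entity", "material_entity",
        label=DISPLAY_LABELS["functional_entity"])
    add("historical_evolutionary_entity", "material_entity",
        label=DISPLAY_LABELS["historical_evolutionary_entity"])

    for lv in BUILDING_BLOCK_LEVELS:
        tag = lv.tag
        le = level_entity(lv)
        add(le, "spatio_structural_entity", frame_tag=tag)
        obj = f"{tag}_level_object"
        fiat = f"fiat_{tag}_level_entity"
        add(obj, le, frame_tag=tag, disjoint_group=f"{tag}:object_vs_fiat")
        add(fiat, le, frame_tag=tag, disjoint_group=f"{tag}:object_vs_fiat")
        add(building_block_category(lv), obj, frame_tag=tag,
            disjoint_group=f"{tag}:bb_vs_cluster")
        add(cluster_category(lv), obj, frame_tag=tag,
            disjoint_group=f"{tag}:bb_vs_cluster")
        sc = f"self_connected_fiat_{tag}_entity"
        scat = f"scattered_fiat_{tag}_entity"
        add(sc, fiat, frame_tag=tag, disjoint_group=f"{tag}:connectedness")
        add(scat, fiat, frame_tag=tag, disjoint_group=f"{tag}:connectedness")
        add(fiat_part_category(lv), sc, frame_tag=tag)
        add(fiat_cluster_category(lv), sc, frame_tag=tag)
        add(group_of_objects_category(lv), scat, frame_tag=tag)
        add(group_of_fiat_category(lv), scat, frame_tag=tag)

    # Portions of matter exist for every level except the coarsest
    # (there is nothing coarser to represent an organism-level portion in).
    add("portion_of_matter_entity", "spatio_structural_entity",
        label=DISPLAY_LABELS["portion_of_matter_entity"])
    for lv in BUILDING_BLOCK_LEVELS[:-1]:
        pe = portion_entity_category(lv)
        add(pe, "portion_of_matter_entity", frame_tag=lv.tag)
        add(self_connected_portion_category(lv), pe, frame_tag=lv.tag,
            disjoint_group=f"{lv.tag}:portion_connectedness")
        add(scattered_portions_category(lv), pe, frame_tag=lv.tag,
            disjoint_group=f"{lv.tag}:portion_connectedness")

    add("functional_unit", "functional_entity",
        disjoint_group="functional:unit_vs_fiat",
        label=DISPLAY_LABELS["functional_unit"])
    add("fiat_functional_unit_part", "functional_entity",
        disjoint_group="functional:unit_vs_fiat",
        label=DISPLAY_LABELS["fiat_functional_unit_part"])
    add("historical_evolutionary_unit", "historical_evolutionary_entity",
        disjoint_group="histev:unit_vs_fiat",
        label=DISPLAY_LABELS["historical_evolutionary_unit"])
    add("fiat_historical_evolutionary_unit_part",
        "historical_evolutionary_entity",
        disjoint_group="histev:unit_vs_fiat",
        label=DISPLAY_LABELS["fiat_historical_evolutionary_unit_part"])

    tax.validate_tree()
    return tax
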