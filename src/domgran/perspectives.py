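"""Granular perspectives: the default registry and the constraint validator.

A granular perspective pairs exactly one granulation criterion (what to
granulate: a granulation relation with its domain and range categories)
with exactly one granularity type (how to granulate: nrG, non-scale-
dependent single-relation granulation, or sgrG, scale-dependent grain size
by resolution).  The framework's default registry comprises:

* the compositional building-block (CBB) perspective — six fixed levels,
  direct proper parthood between building blocks — the backbone;
* one compositional building-block cluster (CBB-C) perspective per
  spatio-structural reference context (two levels each);
* seven general region-based perspective types instantiated per
  spatio-structural reference context;
* compositional functional-unit (CFU) and historical/evolutionary-unit
  (CH/EU) perspectives with data-driven levels;
* the resolution-based representation (RBR) perspective (six levels) and
  the two countability-representation (RBCR) perspectives (two levels
  each), plus the function-based (F-BR) and history/evolution-based
  (H/E-BR) representation perspectives.

An intransitive granulation relation (domain and range categories differ)
forces a perspective to exactly two levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .classification import (
    CO_C,
    CO_NC,
    ClassificationContext,
    ClassificationResult,
    representation_chain,
)
from .core import (
    FrameOfReference,
    FrameworkConfig,
    building_block_category,
    cluster_category,
    fiat_cluster_category,
    fiat_part_category,
    group_of_fiat_category,
    group_of_objects_category,
    level_entity,
    spatio_structural_frames,
)


# --------------------------------------------------------------------------
# Perspective model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GranulationCriterion:
    """(relation, domain category, range category); categories may carry a
    ``^frame`` index, which is ignored when deciding transitivity."""

    relation: str
    domain_category: str
    range_category: str

    def _strip(self, name: str) -> str:
        return name.split("^", 1)[0]

    @property
    def intransitive(self) -> bool:
        """Domain and range categories differ (frame indices aside)."""
        return (self._strip(self.domain_category)
                != self._strip(self.range_category))


@dataclass(frozen=True)
class GranularPerspective:
    id: str
    family: str
    criterion: GranulationCriterion
    granularity_type: str  # nrG | sgrG
    level_count_policy: str  # fixed(n) | unbounded | data-driven
    levels: tuple[str, ...] = ()
    frame: Optional[FrameOfReference] = None

    @property
    def fixed_level_count(self) -> Optional[int]:
        if self.level_count_policy.startswith("fixed("):
            return int(self.level_count_policy[6:-1])
        return None


@dataclass
class LevelAssignment:
    """Flat (unit, perspective, level ordinal) entries.

    Compositional perspectives granulate entities directly, so the unit is
    an entity id.  Representation-based perspectives (RBR, RBCR, F-BR,
    H/E-BR) granulate frame-specific *representations* of entities; their
    units are written ``entity@frame`` — one unit per granular
    representation, mirroring the one-URI-per-representation modelling.
    """

    entries: set[tuple[str, str, int]] = field(default_factory=set)

    def add(self, unit: str, perspective: str, level: int) -> None:
        self.entries.add((unit, perspective, level))

    def for_perspective(self, pid: str) -> set[tuple[str, int]]:
        return {(e, lv) for e, p, lv in self.entries if p == pid}

    def perspectives_of(self, entity: str) -> set[str]:
        """Perspectives holding the entity or any of its representations."""
        prefix = entity + "@"
        return {p for e, p, _ in self.entries
                if e == entity or e.startswith(prefix)}

    def populated_levels(self, pid: str) -> set[int]:
        return {lv for _, p, lv in self.entries if p == pid}


class RegistryError(ValueError):
    pass


class PerspectiveRegistry:
    """The perspective inventory; (criterion, type) pairs must be unique."""

    def __init__(self) -> None:
        self.perspectives: dict[str, GranularPerspective] = {}
        self._keys: set[tuple[GranulationCriterion, str]] = set()

    def add(self, p: GranularPerspective) -> None:
        key = (p.criterion, p.granularity_type)
        if key in self._keys:
            raise RegistryError(
                f"duplicate (criterion, granularity type) for {p.id!r}")
        if p.id in self.perspectives:
            raise RegistryError(f"duplicate perspective id {p.id!r}")
        self._keys.add(key)
        self.perspectives[p.id] = p

    def __len__(self) -> int:
        return len(self.perspectives)

    def __getitem__(self, pid: str) -> GranularPerspective:
        return self.perspectives[pid]

    def __iter__(self):
        return iter(self.perspectives.values())

    def by_family(self, family: str) -> list[GranularPerspective]:
        return [p for p in self if p.family == family]

    def region_based(self) -> list[GranularPerspective]:
        return [p for p in self if p.family == "region-based"]


#: The seven general region-based perspective types: (key, domain, range,
#: level policy).  Domain/range are templates over a building-block level.
REGION_BASED_TYPES = (
    ("building_block_cluster",
     lambda lv: f"{fiat_part_category(lv)}|{group_of_fiat_category(lv)}",
     lambda lv: f"{group_of_fiat_category(lv)}|{fiat_cluster_category(lv)}",
     "fixed(2)"),
    ("building_block_part",
     lambda lv: fiat_part_category(lv),
     lambda lv: building_block_category(lv),
     "fixed(2)"),
    ("fiat_building_block_aggregate",
     lambda lv: building_block_category(lv),
     lambda lv: (f"{fiat_cluster_category(lv)}"
                 f"|scattered_fiat_{lv.tag}_entity"),
     "fixed(2)"),
    ("fiat_building_block_part",
     lambda lv: fiat_part_category(lv),
     lambda lv: fiat_part_category(lv),
     "unbounded"),
    ("fiat_building_block_cluster",
     lambda lv: fiat_cluster_category(lv),
     lambda lv: fiat_cluster_category(lv),
     "unbounded"),
    ("group_of_building_block_level_objects",
     lambda lv: group_of_objects_category(lv),
     lambda lv: group_of_objects_category(lv),
     "data-driven"),
    ("group_of_fiat_building_block_level_entities",
     lambda lv: group_of_fiat_category(lv),
     lambda lv: group_of_fiat_category(lv),
     "unbounded"),
)


def build_default_registry(config: FrameworkConfig) -> PerspectiveRegistry:
    """Construct the full default perspective registry for a configuration.

    In printed-total mode the level-3 frame splits into organelle and
    prokaryotic-cell contexts, so the seven region-based types instantiate
    over seven spatio-structural reference contexts (49 specific
    region-based perspectives); canonical mode yields six contexts (42).
    """
    reg = PerspectiveRegistry()
    frames = spatio_structural_frames(config)

    cbb_levels = tuple(building_block_category(f.level) for f in frames
                       if f.context_tag != "prokaryotic_cell")
    reg.add(GranularPerspective(
        "CBB", "CBB",
        GranulationCriterion("directProperPartOf",
                             "building_block", "building_block"),
        "nrG", "fixed(6)", cbb_levels))

    for f in frames:
        lv = f.level
        reg.add(GranularPerspective(
            f"CBB-C@{f.name}", "CBB-C",
            GranulationCriterion(
                "directProperPartOf",
                f"{building_block_category(lv)}^{f.name}",
                f"{cluster_category(lv)}^{f.name}"),
            "nrG", "fixed(2)",
            (building_block_category(lv), cluster_category(lv)), frame=f))
        for key, dom, rng, policy in REGION_BASED_TYPES:
            reg.add(GranularPerspective(
                f"RB-{key}@{f.name}", "region-based",
                GranulationCriterion("properPartOf",
                                     f"{dom(lv)}^{f.name}",
                                     f"{rng(lv)}^{f.name}"),
                "nrG", policy, frame=f))

    reg.add(GranularPerspective(
        "CFU", "CFU",
        GranulationCriterion("directProperFunctionalPartOf",
                             "functional_unit", "functional_unit"),
        "nrG", "data-driven"))
    reg.add(GranularPerspective(
        "CH/EU", "CH/EU",
        GranulationCriterion("dirPropHistEvolPartOf",
                             "historical_evolutionary_unit",
                             "historical_evolutionary_unit"),
        "nrG", "data-driven"))

    canonical = [f for f in frames if f.context_tag != "prokaryotic_cell"]
    reg.add(GranularPerspective(
        "RBR", "RBR",
        GranulationCriterion("hasCoarserGranRep",
                             "spatio_structural_entity",
                             "spatio_structural_entity"),
        "sgrG", "fixed(6)",
        tuple(level_entity(f.level) for f in canonical)))
    reg.add(GranularPerspective(
        "RBCR-c2nc", "RBCR-countable-to-noncountable",
        GranulationCriterion("co_n-c_GranRep",
                             "building_block_level_entity",
                             "portion_of_matter_entity"),
        "sgrG", "fixed(2)",
        ("building_block_level_entity", "portion_of_matter_entity")))
    reg.add(GranularPerspective(
        "RBCR-nc2c", "RBCR-noncountable-to-countable",
        GranulationCriterion("co_c_GranRep",
                             "portion_of_matter_entity",
                             "building_block_level_entity"),
        "sgrG", "fixed(2)",
        ("portion_of_matter_entity", "building_block_level_entity")))
    reg.add(GranularPerspective(
        "F-BR", "F-BR",
        GranulationCriterion("FuncGranRep",
                             "spatio_structural_entity",
                             "functional_entity"),
        "sgrG", "fixed(2)",
        ("spatio_structural_entity", "functional_entity")))
    reg.add(GranularPerspective(
        "H/E-BR", "H/E-BR",
        GranulationCriterion("Hist/EvGranRep",
                             "spatio_structural_entity",
                             "historical_evolutionary_entity"),
        "sgrG", "fixed(2)",
        ("spatio_structural_entity", "historical_evolutionary_entity")))
    return reg


# --------------------------------------------------------------------------
# Level assignment
# --------------------------------------------------------------------------

def _functional_depth(eid: str, context: ClassificationContext,
                      bearers: set[str]) -> int:
    """1 + length of the longest chain of unit-bearing proper parts."""
    depth = 1
    frontier = {p for p in context.parts_of(eid) if p in bearers}
    while frontier:
        depth += 1
        frontier = {q for p in frontier
                    for q in context.parts_of(p) if q in bearers}
        if depth > len(bearers):  # safety on cyclic input
            break
    return depth


def assign_entity_levels(eid: str,
                         classification: ClassificationResult,
                         registry: PerspectiveRegistry,
                         context: ClassificationContext
                         ) -> LevelAssignment:
    """Candidate level entries for one classified entity.

    An entity receives at most one level per perspective.  Entities
    classified in all three basic frames land in at least three
    perspectives (CBB or a region-based one, F-BR, H/E-BR).
    """
    out = LevelAssignment()
    if not classification.per_frame:
        return out

    lvl = classification.intrinsic_level
    if lvl is not None and "CBB" in registry.perspectives:
        out.add(eid, "CBB", lvl.ordinal)

    ss_any = False
    func_cat = histev_cat = None
    for frame, cat in classification.per_frame.items():
        if frame.kind == "functional":
            func_cat = cat
            continue
        if frame.kind == "historical-evolutionary":
            histev_cat = cat
            continue
        ss_any = True
        L = frame.level
        fname = frame.name
        if "RBR" in registry.perspectives:
            out.add(f"{eid}@{fname}", "RBR", L.ordinal)

        def pid(stem: str) -> Optional[str]:
            full = f"{stem}@{fname}"
            return full if full in registry.perspectives else None

        bb = building_block_category(L)
        if cat == bb:
            if pid("CBB-C"):
                out.add(eid, pid("CBB-C"), 1)
            if pid("RB-building_block_part"):
                out.add(eid, pid("RB-building_block_part"), 2)
            if pid("RB-fiat_building_block_aggregate"):
                out.add(eid, pid("RB-fiat_building_block_aggregate"), 1)
        elif cat == cluster_category(L):
            if pid("CBB-C"):
                out.add(eid, pid("CBB-C"), 2)
        elif cat == fiat_part_category(L):
            if pid("RB-building_block_part"):
                out.add(eid, pid("RB-building_block_part"), 1)
            if pid("RB-building_block_cluster"):
                out.add(eid, pid("RB-building_block_cluster"), 1)
            if pid("RB-fiat_building_block_part"):
                nested = 1 + sum(
                    1 for w in context.wholes_of(eid)
                    if context.classify_in_frame(w, frame) == cat)
                out.add(eid, pid("RB-fiat_building_block_part"), nested)
        elif cat == fiat_cluster_category(L):
            if pid("RB-building_block_cluster"):
                out.add(eid, pid("RB-building_block_cluster"), 2)
            if pid("RB-fiat_building_block_aggregate"):
                out.add(eid, pid("RB-fiat_building_block_aggregate"), 2)
            if pid("RB-fiat_building_block_cluster"):
                nested = 1 + sum(
                    1 for w in context.wholes_of(eid)
                    if context.classify_in_frame(w, frame) == cat)
                out.add(eid, pid("RB-fiat_building_block_cluster"), nested)
        elif cat == group_of_objects_category(L):
            p = pid("RB-group_of_building_block_level_objects")
            if p:
                nested = 1 + sum(
                    1 for w in context.wholes_of(eid)
                    if context.classify_in_frame(w, frame) == cat)
                out.add(eid, p, nested)
        elif cat == group_of_fiat_category(L):
            p = pid("RB-group_of_fiat_building_block_level_entities")
            if p:
                out.add(eid, p, 1)

    if func_cat is not None:
        if ss_any and "F-BR" in registry.perspectives:
            out.add(f"{eid}@spatio-structural", "F-BR", 1)
            out.add(f"{eid}@functional", "F-BR", 2)
        if func_cat == "functional_unit" and "CFU" in registry.perspectives:
            out.add(eid, "CFU",
                    _functional_depth(eid, context, context._functions))
    if histev_cat is not None:
        if ss_any and "H/E-BR" in registry.perspectives:
            out.add(f"{eid}@spatio-structural", "H/E-BR", 1)
            out.add(f"{eid}@historical-evolutionary", "H/E-BR", 2)
        if (histev_cat == "historical_evolutionary_unit"
                and "CH/EU" in registry.perspectives):
            out.add(eid, "CH/EU",
                    _functional_depth(eid, context, context._origins))

    # countability flips along the representation chain populate the RBCR
    # perspectives: each flipping link fills both levels with the two
    # frame-specific representations of the entity
    chain = representation_chain(eid, classification, context.taxonomy)
    for fine, coarse, rel, _, _ in chain.links:
        if rel == CO_NC and "RBCR-c2nc" in registry.perspectives:
            out.add(f"{eid}@{fine.name}", "RBCR-c2nc", 1)
            out.add(f"{eid}@{coarse.name}", "RBCR-c2nc", 2)
        elif rel == CO_C and "RBCR-nc2c" in registry.perspectives:
            out.add(f"{eid}@{fine.name}", "RBCR-nc2c", 1)
            out.add(f"{eid}@{coarse.name}", "RBCR-nc2c", 2)
    return out


def populate_registry(registry: PerspectiveRegistry,
                      context: ClassificationContext,
                      classifications: dict[str, ClassificationResult]
                      ) -> tuple[LevelAssignment, list[str]]:
    """Instantiate the registry on a classified dataset.

    Merges per-entity candidate entries, keeps only the maximal member of
    any nested chain within one level (level members must be pairwise
    disjoint in extent, and in a parthood tree overlap is containment),
    then drops perspectives whose population covers fewer than two levels:
    a one-level population is not a granulation, so such a perspective is
    not instantiated on the dataset (dropped ids are returned as warnings).
    """
    merged = LevelAssignment()
    for eid, cls in classifications.items():
        merged.entries |= assign_entity_levels(
            eid, cls, registry, context).entries

    # prune nested entity members per (perspective, level); representation
    # units ("entity@frame") are distinct individuals and are kept as-is
    groups: dict[tuple[str, int], set[str]] = {}
    for e, pid, lv in merged.entries:
        if "@" not in e:
            groups.setdefault((pid, lv), set()).add(e)
    drop = {(e, pid, lv)
            for (pid, lv), members in groups.items()
            for e in members
            if context.wholes_of(e) & members}
    merged.entries -= drop

    warnings = []
    for p in registry:
        levels = merged.populated_levels(p.id)
        if levels and len(levels) < 2:
            warnings.append(p.id)
            merged.entries = {e for e in merged.entries if e[1] != p.id}
    return merged, warnings


def rbr_level_population(
        classifications: dict[str, ClassificationResult]
) -> dict[int, int]:
    """Representation count per RBR level (one per spatio-structural frame,
    counting each entity's frame-specific granular representation)."""
    counts: dict[int, int] = {}
    for cls in classifications.values():
        for frame in cls.per_frame:
            if frame.kind != "spatio-structural":
                continue
            if frame.context_tag == "prokaryotic_cell":
                continue
            counts[frame.level.ordinal] = counts.get(
                frame.level.ordinal, 0) + 1
    return counts


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

@dataclass
class ConstraintReport:
    checks: dict[str, bool]
    witnesses: dict[str, list] = field(default_factory=dict)

    @property
    def all_pass(self) -> bool:
        return all(self.checks.values())


def validate_perspective(p: GranularPerspective,
                         assignment: LevelAssignment,
                         extents: dict[str, frozenset[str]] | None = None
                         ) -> ConstraintReport:
    """Check the formal perspective constraints against a population.

    At least two populated levels; strictly ordered level indices; each
    entity in at most one level; entities within a level pairwise disjoint
    in extent (where extents are known); an intransitive granulation
    relation caps the perspective at exactly two levels.
    """
    entries = assignment.for_perspective(p.id)
    levels = {lv for _, lv in entries}
    checks: dict[str, bool] = {}
    wit: dict[str, list] = {}

    checks["min_two_levels"] = len(levels) >= 2
    if not checks["min_two_levels"]:
        wit["min_two_levels"] = sorted(levels)

    checks["strict_total_order"] = all(isinstance(lv, int) and lv >= 1
                                       for lv in levels)

    by_entity: dict[str, set[int]] = {}
    for e, lv in entries:
        by_entity.setdefault(e, set()).add(lv)
    dups = {e: sorted(ls) for e, ls in by_entity.items() if len(ls) > 1}
    checks["one_level_per_entity"] = not dups
    if dups:
        wit["one_level_per_entity"] = sorted(dups.items())

    overlap = []
    if extents:
        by_level: dict[int, list[str]] = {}
        for e, lv in entries:
            if e in extents:
                by_level.setdefault(lv, []).append(e)
        for lv, members in by_level.items():
            members.sort()
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    if extents[a] & extents[b]:
                        overlap.append((lv, a, b))
    checks["level_members_disjoint"] = not overlap
    if overlap:
        wit["level_members_disjoint"] = overlap

    if p.criterion.intransitive:
        ok = len(levels) <= 2 and (p.fixed_level_count in (None, 2))
        checks["intransitive_two_levels"] = ok
        if not ok:
            wit["intransitive_two_levels"] = sorted(levels)
    else:
        checks["intransitive_two_levels"] = True
    if len(levels) > 2:
        checks["transitivity_required"] = not p.criterion.intransitive
    else:
        checks["transitivity_required"] = True

    return ConstraintReport(checks, wit)


def validate_registry(registry: PerspectiveRegistry,
                      assignments: LevelAssignment) -> ConstraintReport:
    """Framework-level checks: criterion uniqueness and backbone overlap.

    Every populated perspective must share at least one entity with a
    backbone (CBB / CFU / CH-EU) perspective, directly or through a chain
    of entity-sharing perspectives.
    """
    checks: dict[str, bool] = {}
    wit: dict[str, list] = {}

    seen: dict[tuple, str] = {}
    dups = []
    for p in registry:
        key = (p.criterion, p.granularity_type)
        if key in seen:
            dups.append((seen[key], p.id))
        seen[key] = p.id
    checks["criterion_uniqueness"] = not dups
    if dups:
        wit["criterion_uniqueness"] = dups

    populated = {p.id for p in registry
                 if assignments.populated_levels(p.id)}
    # representation units ("entity@frame") count as their entity for
    # overlap purposes
    members = {pid: {e.split("@", 1)[0]
                     for e, _ in assignments.for_perspective(pid)}
               for pid in populated}
    backbone = {pid for pid in ("CBB", "CFU", "CH/EU") if pid in populated}
    connected = set(backbone)
    changed = True
    while changed:
        changed = False
        for pid in populated - connected:
            if any(members[pid] & members[c] for c in connected):
                connected.add(pid)
                changed = True
    isolated = sorted(populated - connected)
    checks["backbone_connectivity"] = not isolated
    if isolated:
        wit["backbone_connectivity"] = isolated

    return ConstraintReport(checks, wit)
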