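"""Perspective registry construction, population, and constraints."""

import pytest

import domgran as dg
from domgran.core import FrameworkConfig
from domgran.perspectives import (
    GranulationCriterion,
    GranularPerspective,
    LevelAssignment,
    PerspectiveRegistry,
    REGION_BASED_TYPES,
    RegistryError,
    assign_entity_levels,
    build_default_registry,
    rbr_level_population,
    validate_perspective,
    validate_registry,
)


@pytest.fixture(scope="module")
def canonical_registry():
    return build_default_registry(FrameworkConfig("canonical"))


@pytest.fixture(scope="module")
def printed_registry():
    return build_default_registry(FrameworkConfig("printed_total"))


class TestRegistryConstruction:
    def test_seven_general_region_based_types(self):
        assert len(REGION_BASED_TYPES) == 7

    def test_region_based_counts_per_mode(self, canonical_registry,
                                          printed_registry):
        assert len(canonical_registry.region_based()) == 42
        assert len(printed_registry.region_based()) == 49

    def test_backbone_level_counts(self, canonical_registry):
        assert len(canonical_registry["CBB"].levels) == 6
        assert len(canonical_registry["RBR"].levels) == 6
        for pid in ("RBCR-c2nc", "RBCR-nc2c", "F-BR", "H/E-BR"):
            assert canonical_registry[pid].fixed_level_count == 2
        for p in canonical_registry.by_family("CBB-C"):
            assert p.fixed_level_count == 2

    def test_intransitive_criteria_fixed_at_two_levels(self,
                                                       printed_registry):
        for p in printed_registry:
            if p.criterion.intransitive:
                assert p.fixed_level_count == 2, p.id

    def test_criterion_uniqueness_enforced(self, canonical_registry):
        duplicate = GranularPerspective(
            "CBB-again", "CBB",
            GranulationCriterion("directProperPartOf",
                                 "building_block", "building_block"),
            "nrG", "fixed(6)")
        with pytest.raises(RegistryError, match="duplicate"):
            canonical_registry_copy = build_default_registry(
                FrameworkConfig("canonical"))
            canonical_registry_copy.add(duplicate)

    def test_rebuild_is_identical(self, printed_registry):
        again = build_default_registry(FrameworkConfig("printed_total"))
        assert list(again.perspectives) == list(
            printed_registry.perspectives)


class TestAssignment:
    def test_cell_in_at_least_three_perspectives(self, populated):
        _, assignments, _ = populated
        assert len(assignments.perspectives_of("m")) >= 3

    def test_cell_in_exactly_one_backbone_level(self, populated):
        _, assignments, _ = populated
        levels = [lv for e, p, lv in assignments.entries
                  if e == "m" and p == "CBB"]
        assert levels == [4]

    def test_at_most_one_level_per_unit_and_perspective(self, populated):
        _, assignments, _ = populated
        seen = {}
        for unit, pid, lv in assignments.entries:
            assert seen.setdefault((unit, pid), lv) == lv

    def test_unclassified_entity_gets_no_entries(self, canonical_registry,
                                                 context):
        from domgran.classification import ClassificationResult
        empty = ClassificationResult("ghost", {}, None, {})
        out = assign_entity_levels("ghost", empty, canonical_registry,
                                   context)
        assert not out.entries

    def test_rbr_population_spans_six_levels(self, classifications):
        counts = rbr_level_population(classifications)
        assert set(counts) == {1, 2, 3, 4, 5, 6}
        assert all(n > 0 for n in counts.values())


class TestValidation:
    def test_all_populated_perspectives_pass(self, populated, cumulative):
        registry, assignments, _ = populated
        _, tree = cumulative
        for p in registry:
            if not assignments.populated_levels(p.id):
                continue
            report = validate_perspective(p, assignments, tree.extent)
            assert report.all_pass, (p.id, report.checks, report.witnesses)

    def test_dropped_perspectives_are_reported(self, populated):
        registry, assignments, warnings = populated
        for pid in warnings:
            assert not assignments.populated_levels(pid)

    def test_minimum_two_levels_everywhere(self, populated):
        registry, assignments, _ = populated
        for p in registry:
            levels = assignments.populated_levels(p.id)
            assert not levels or len(levels) >= 2

    def test_one_populated_level_fails(self, canonical_registry):
        assignment = LevelAssignment({("a", "CBB", 2), ("b", "CBB", 2)})
        report = validate_perspective(canonical_registry["CBB"], assignment)
        assert not report.checks["min_two_levels"]

    def test_three_level_intransitive_perspective_fails(
            self, canonical_registry):
        assignment = LevelAssignment({("a", "RBCR-c2nc", 1),
                                      ("b", "RBCR-c2nc", 2),
                                      ("c", "RBCR-c2nc", 3)})
        report = validate_perspective(canonical_registry["RBCR-c2nc"],
                                      assignment)
        assert not report.checks["intransitive_two_levels"]

    def test_overlapping_level_members_fail(self, canonical_registry,
                                            cumulative):
        _, tree = cumulative
        assignment = LevelAssignment({("i", "CBB", 5), ("m", "CBB", 5),
                                      ("g", "CBB", 2)})
        report = validate_perspective(canonical_registry["CBB"], assignment,
                                      tree.extent)
        assert not report.checks["level_members_disjoint"]
        assert (5, "i", "m") in report.witnesses["level_members_disjoint"]

    def test_registry_checks_pass_on_worked_example(self, populated):
        registry, assignments, _ = populated
        report = validate_registry(registry, assignments)
        assert report.all_pass

    def test_isolated_perspective_breaks_connectivity(self,
                                                      canonical_registry):
        assignment = LevelAssignment({
            ("a", "CBB", 1), ("b", "CBB", 2),
            ("x", "RBCR-c2nc", 1), ("y", "RBCR-c2nc", 2)})
        report = validate_registry(canonical_registry, assignment)
        assert not report.checks["backbone_connectivity"]


class TestModesEndToEnd:
    def test_printed_total_population(self, cumulative):
        from domgran.classification import ClassificationContext
        from domgran.perspectives import populate_registry
        aset, tree = cumulative
        config = FrameworkConfig("printed_total")
        ctx = ClassificationContext(aset, config)
        registry = build_default_registry(config)
        assignments, _ = populate_registry(registry, ctx,
                                           ctx.classify_all())
        report = validate_registry(registry, assignments)
        assert report.all_pass
        for p in registry:
            if assignments.populated_levels(p.id):
                sub = validate_perspective(p, assignments, tree.extent)
                assert sub.all_pass, (p.id, sub.witnesses)
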