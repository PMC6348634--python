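"""Granular partitions, granularity trees, cuts, and organisation."""

import itertools

import pytest

import domgran as dg
from domgran.core import Assertion, AssertionSet, EntityInstance
from domgran.partition import (
    BinaryRelationInstance,
    PartitionError,
    build_granularity_tree,
    check_partial_order,
    check_strict_partial_order,
    complete_cut,
    diagnose_organization,
    extract_cuts,
    summation_check,
    transitive_closure,
    validate_granular_partition,
)


def brute_force_properties(pairs, universe):
    """Independent triple-enumeration oracle for order properties."""
    return {
        "reflexive": all((x, x) in pairs for x in universe),
        "irreflexive": all((x, x) not in pairs for x in universe),
        "antisymmetric": all(
            not ((a, b) in pairs and (b, a) in pairs and a != b)
            for a in universe for b in universe),
        "transitive": all(
            (a, c) in pairs
            for a, b1 in pairs for b2, c in pairs if b1 == b2),
    }


class TestOrderChecks:
    def test_partial_order_accepts_divisibility(self):
        universe = frozenset(str(n) for n in range(1, 13))
        pairs = frozenset((str(a), str(b))
                          for a in range(1, 13) for b in range(1, 13)
                          if b % a == 0)
        assert check_partial_order(
            BinaryRelationInstance(pairs, universe)).all_hold

    def test_partial_order_rejects_symmetry_with_witness(self):
        rel = BinaryRelationInstance(
            frozenset({("a", "a"), ("b", "b"), ("a", "b"), ("b", "a")}),
            frozenset({"a", "b"}))
        report = check_partial_order(rel)
        assert not report.holds("antisymmetric")
        assert ("a", "b") in report.witnesses["antisymmetric"]

    def test_strict_order_rejects_reflexive_pair(self):
        rel = BinaryRelationInstance(
            frozenset({("a", "a")}), frozenset({"a", "b"}))
        report = check_strict_partial_order(rel)
        assert not report.holds("irreflexive")

    def test_empty_universe_warns(self):
        report = check_partial_order(
            BinaryRelationInstance(frozenset(), frozenset()))
        assert report.all_hold
        assert report.warnings

    def test_pairs_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            BinaryRelationInstance(frozenset({("a", "b")}),
                                   frozenset({"a"}))

    def test_agreement_with_oracle_on_small_relations(self):
        universe = ["a", "b", "c"]
        all_pairs = list(itertools.product(universe, universe))
        # every relation over a 3-element universe with <=3 pairs
        for k in range(4):
            for chosen in itertools.combinations(all_pairs, k):
                rel = BinaryRelationInstance(frozenset(chosen),
                                             frozenset(universe))
                expect = brute_force_properties(set(chosen), universe)
                got = check_partial_order(rel)
                strict = check_strict_partial_order(rel)
                assert got.holds("reflexive") == expect["reflexive"]
                assert got.holds("transitive") == expect["transitive"]
                assert (got.holds("antisymmetric")
                        == expect["antisymmetric"])
                assert strict.holds("irreflexive") == expect["irreflexive"]

    def test_transitive_closure(self):
        closed = transitive_closure({("a", "b"), ("b", "c")})
        assert ("a", "c") in closed


class TestPartitionValidation:
    def test_valid_partition(self):
        cells = {"w": {"x", "y"}, "a": {"x"}, "b": {"y"}}
        report = validate_granular_partition(
            cells, {("a", "w"), ("b", "w")})
        assert report.valid

    def test_two_roots_rejected(self):
        cells = {"w": {"x"}, "v": {"y"}, "a": {"x"}, "b": {"y"}}
        report = validate_granular_partition(
            cells, {("a", "w"), ("b", "v")})
        assert not report.conditions["unique_root"]
        assert report.witnesses["unique_root"] == [("v", "w")]

    def test_cycle_rejected(self):
        cells = {"a": {"x"}, "b": {"x"}}
        report = validate_granular_partition(cells, {("a", "b"), ("b", "a")})
        assert not report.conditions["finite_chains"]

    def test_partial_overlap_rejected(self):
        cells = {"w": {"x", "y", "z"}, "a": {"x", "y"}, "b": {"y", "z"}}
        report = validate_granular_partition(
            cells, {("a", "w"), ("b", "w")})
        assert not report.conditions["no_partial_overlap"]
        assert ("a", "b") in report.witnesses["no_partial_overlap"]

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError):
            validate_granular_partition({"a": set()}, set())


def _aset(edges, extra_entities=()):
    ids = {x for e in edges for x in e} | set(extra_entities)
    aset = AssertionSet(EntityInstance(i) for i in sorted(ids))
    for child, parent in edges:
        aset.add_assertion(Assertion(child, "directProperPartOf", parent))
    return aset


class TestTreeBuilding:
    def test_depths_and_extents(self):
        aset = _aset([("a", "w"), ("b", "w"), ("c", "a")])
        tree = build_granularity_tree(aset, "w")
        assert tree.depth == {"w": 0, "a": 1, "b": 1, "c": 2}
        assert tree.extent["w"] == frozenset({"b", "c"})
        assert tree.leaves() == ["b", "c"]

    def test_multi_parent_rejected(self):
        aset = _aset([("a", "w"), ("a", "v"), ("v", "w")])
        with pytest.raises(PartitionError, match="two parents"):
            build_granularity_tree(aset, "w")

    def test_cycle_rejected(self):
        aset = _aset([("a", "b"), ("b", "a")], extra_entities=["w"])
        with pytest.raises(PartitionError, match="cycle"):
            build_granularity_tree(aset, "w")

    def test_unknown_root_rejected(self):
        with pytest.raises(PartitionError, match="unknown root"):
            build_granularity_tree(_aset([("a", "w")]), "nope")


class TestCuts:
    def test_strict_cuts_partition_the_nodes(self, cumulative):
        _, tree = cumulative
        cuts = extract_cuts(tree)
        seen = [m for c in cuts for m in c.members]
        assert sorted(seen) == sorted(n for n in tree.nodes
                                      if n != tree.root)
        assert len(seen) == len(set(seen))

    def test_complete_cut_partitions_root_extent(self, cumulative):
        _, tree = cumulative
        for idx in range(1, tree.max_depth + 1):
            members = complete_cut(tree, idx)
            extents = [tree.extent[m] for m in sorted(members)]
            union = frozenset().union(*extents)
            assert union == tree.extent[tree.root]
            total = sum(len(e) for e in extents)
            assert total == len(union)  # pairwise disjoint

    def test_complete_cut_index_out_of_range(self, cumulative):
        _, tree = cumulative
        with pytest.raises(IndexError):
            complete_cut(tree, tree.max_depth + 1)

    def test_summation_rejects_foreign_cut(self, cumulative, constitutive):
        _, tree = cumulative
        _, other = constitutive
        with pytest.raises(ValueError):
            summation_check(tree, extract_cuts(other)[0])


class TestWorkedExample:
    def test_four_cuts_in_both_variants(self, cumulative, constitutive):
        for _, tree in (cumulative, constitutive):
            assert len(extract_cuts(tree)) == 4

    def test_builder_matches_expected_tree(self, cumulative):
        aset, expected = cumulative
        tree = build_granularity_tree(aset, "whole")
        assert tree.depth == expected.depth
        assert tree.parent == expected.parent

    def test_constitutive_cuts_all_sum(self, constitutive):
        _, tree = constitutive
        for cut in extract_cuts(tree):
            ok, missing = summation_check(tree, cut)
            assert ok and not missing

    def test_cumulative_summation_failures(self, cumulative):
        _, tree = cumulative
        results = {c.index: summation_check(tree, c) for c
                   in extract_cuts(tree)}
        assert results[1][0]  # the organ cut sums to the whole
        assert not results[3][0]  # the organelle-depth cut does not
        # extracellular molecules g, h are never covered below cut 1
        assert {"g", "h"} <= set(results[3][1])
        assert any(not ok for ok, _ in results.values())

    def test_diagnosis(self, cumulative, constitutive):
        for (aset, tree), expected in ((constitutive, "constitutive"),
                                       (cumulative,
                                        "cumulative-constitutive")):
            types = dg.worked_example_types(
                "constitutive" if expected == "constitutive"
                else "cumulative")
            assert diagnose_organization(tree, types) == expected

    def test_diagnosis_requires_typed_nodes(self, cumulative):
        _, tree = cumulative
        with pytest.raises(ValueError, match="untyped"):
            diagnose_organization(tree, {})
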