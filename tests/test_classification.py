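"""Frame-dependent classification and representation chains."""

import pytest

from domgran.classification import (
    CO_C,
    CO_NC,
    FUNC_REP,
    HAS_COARSER,
    HISTEV_REP,
    ClassificationResult,
    representation_chain,
)
from domgran.core import (
    FrameOfReference,
    FrameworkConfig,
    LEVEL_BY_ORDINAL,
    spatio_structural_frames,
)


def frame(ordinal):
    return FrameOfReference("spatio-structural", LEVEL_BY_ORDINAL[ordinal])


class TestIntrinsicLevel:
    @pytest.mark.parametrize("eid,ordinal", [
        ("g", 2),       # extracellular molecule
        ("x", 2),       # intra-organelle molecule
        ("v", 3),       # organelle: membrane without membrane parts
        ("o", 3),       # cell without organelles: single-membrane
        ("m", 4),       # cell with organelles: membrane-within-membrane
        ("i", 5),       # organ: epithelium inside an epithelial whole
        ("whole", 6),   # outermost epithelially-delimited entity
    ])
    def test_covering_decides_level(self, context, eid, ordinal):
        assert context.intrinsic_level(eid).ordinal == ordinal

    def test_uncovered_entity_has_no_level(self):
        from domgran.classification import intrinsic_level
        from domgran.core import Assertion, AssertionSet, EntityInstance
        aset = AssertionSet([EntityInstance("agg"), EntityInstance("m1")])
        aset.add_assertion(Assertion("m1", "directProperPartOf", "agg"))
        aset.add_assertion(
            Assertion("m1", "hasPhysicalCovering", "shared-electron-shell"))
        assert intrinsic_level("agg", aset) is None
        assert intrinsic_level("m1", aset).ordinal == 2


class TestClassifyInFrame:
    def test_cell_across_all_frames(self, context):
        expected = {
            1: "bona_fide_cluster_of_atoms",
            2: "bona_fide_cluster_of_molecules",
            3: "bona_fide_cluster_of_single_membrane_enclosed_entities",
            4: "eukaryotic_cell",
            5: "fiat_epithelially_delimited_compartment_part",
            6: "fiat_multi_cellular_organism_part",
        }
        for ordinal, cat in expected.items():
            assert context.classify_in_frame("m", frame(ordinal)) == cat

    def test_free_molecule_becomes_portion_of_matter(self, context):
        # outside every organelle and cell, an extracellular molecule is
        # non-countable molecule matter at intermediate frames
        assert (context.classify_in_frame("g", frame(3))
                == "self_connected_portion_of_molecule_matter")
        assert (context.classify_in_frame("g", frame(6))
                == "fiat_multi_cellular_organism_part")

    def test_functional_frame(self, context):
        functional = FrameOfReference("functional")
        assert context.classify_in_frame("m", functional) == "functional_unit"
        assert (context.classify_in_frame("g", functional)
                == "fiat_functional_unit_part")

    def test_historical_frame(self, context):
        histev = FrameOfReference("historical-evolutionary")
        assert (context.classify_in_frame("m", histev)
                == "historical_evolutionary_unit")


class TestMultipleInstantiation:
    def test_cell_instantiates_every_frame(self, context):
        result = context.multiple_instantiation("m")
        assert len(result.per_frame) == 8  # six structural + two causal
        assert result.intrinsic_level.ordinal == 4

    def test_countability_tracks_portion_descent(self, context):
        result = context.multiple_instantiation("g")
        by_ordinal = {f.level.ordinal: f for f in result.per_frame
                      if f.kind == "spatio-structural"}
        assert result.countable_in[by_ordinal[2]]
        assert not result.countable_in[by_ordinal[3]]
        assert result.countable_in[by_ordinal[6]]

    def test_classify_all_is_deterministic(self, context):
        first = context.classify_all()
        second = context.classify_all()
        assert list(first) == sorted(first)
        assert {e: r.per_frame for e, r in first.items()} \
            == {e: r.per_frame for e, r in second.items()}


class TestRepresentationChain:
    def test_cell_chain_is_fully_linked(self, context):
        result = context.multiple_instantiation("m")
        chain = representation_chain("m", result, context.taxonomy)
        assert len(chain.links) == 5
        assert not chain.gaps
        rels = [rel for _, _, rel, _, _ in chain.links]
        assert rels[:3] == [HAS_COARSER, HAS_COARSER, HAS_COARSER]

    def test_free_molecule_chain_flips_countability_twice(self, context):
        result = context.multiple_instantiation("g")
        chain = representation_chain("g", result, context.taxonomy)
        rels = [rel for _, _, rel, _, _ in chain.links]
        assert CO_NC in rels  # molecule -> portion of molecule matter
        assert CO_C in rels   # portion -> fiat organism part
        assert rels.index(CO_NC) < rels.index(CO_C)

    def test_side_links_cover_both_causal_frames(self, context):
        result = context.multiple_instantiation("m")
        chain = representation_chain("m", result, context.taxonomy)
        rels = {rel for rel, _ in chain.side_links}
        assert rels == {FUNC_REP, HISTEV_REP}

    def test_frame_gap_truncates_chain(self, context):
        frames = spatio_structural_frames(FrameworkConfig("canonical"))
        synthetic = ClassificationResult(
            "z",
            {frames[1]: "molecule",
             frames[4]: "fiat_epithelially_delimited_compartment_part"},
            LEVEL_BY_ORDINAL[2],
            {frames[1]: True, frames[4]: True})
        chain = representation_chain("z", synthetic)
        assert not chain.links
        assert chain.gaps == [frames[4]]
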