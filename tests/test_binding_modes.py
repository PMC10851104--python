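"""Representative selection, binding modes, consensus mapping, hotspots."""

import pytest

from histonet import binding_modes as bm
from histonet import structure_io, synthetic
from histonet.exceptions import (
    HistonetError,
    MissingResolutionError,
    VariantMissingError,
)
from histonet.interfaces import extract_interfaces

from conftest import alignments_for, poly_ala_alignment


def _meta(structure_id, partner, interface, resolution=2.5, has_mutations=False,
          core=8, lost_bp=0, partner_len=50):
    return bm.ComplexMetadata(
        structure_id=structure_id,
        resolution=resolution,
        has_mutations=has_mutations,
        core_histone_count=core,
        n_unanchored_bp=lost_bp,
        dna_length=147,
        partners=[bm.PartnerInfo(partner, partner_len, frozenset(interface))],
    )


class TestSelectRepresentatives:
    def test_redundant_pair_keeps_highest_resolution(self):
        iface = set(range(20))
        near = set(range(19)) | {99}  # Jaccard 18/21 ≈ 0.857
        result = bm.select_representatives(
            [_meta("S1", "PX", iface, resolution=3.0),
             _meta("S2", "PX", near, resolution=2.0)]
        )
        assert result.selected == {"S2"}

    def test_mutation_free_preferred_over_resolution(self):
        iface = set(range(20))
        result = bm.select_representatives(
            [_meta("S1", "PX", iface, resolution=2.0, has_mutations=True),
             _meta("S2", "PX", iface, resolution=3.0)]
        )
        assert result.selected == {"S2"}

    def test_subnucleosomal_dropped(self):
        result = bm.select_representatives(
            [_meta("SUB", "PX", {1, 2, 3}, core=6)]
        )
        assert result.selected == set()
        assert "SUB" in result.dropped["subnucleosomal"]

    def test_unanchored_dna_dropped(self):
        """>20 bp of DNA displaced beyond the 5 Å octamer contact."""
        result = bm.select_representatives(
            [_meta("LOST", "PX", {1, 2, 3}, lost_bp=25)]
        )
        assert result.selected == set()
        assert "LOST" in result.dropped["unanchored_dna"]

    def test_exactly_20_lost_bp_survives(self):
        result = bm.select_representatives(
            [_meta("EDGE", "PX", {1, 2, 3}, lost_bp=20)]
        )
        assert result.selected == {"EDGE"}

    def test_short_partner_dropped(self):
        result = bm.select_representatives(
            [_meta("PEP", "PX", {1, 2}, partner_len=8)]
        )
        assert result.selected == set()
        assert ("PEP", "PX") in result.dropped["short_partner"]

    def test_distinct_binding_modes_both_kept(self):
        result = bm.select_representatives(
            [_meta("M1", "PX", set(range(10))),
             _meta("M2", "PX", set(range(100, 110)))]
        )
        assert result.selected == {"M1", "M2"}

    def test_missing_resolution_in_contested_group(self):
        iface = set(range(20))
        with pytest.raises(MissingResolutionError, match="S2"):
            bm.select_representatives(
                [_meta("S1", "PX", iface, resolution=2.0),
                 _meta("S2", "PX", iface, resolution=None)]
            )

    def test_idempotent(self):
        metas = [
            _meta("S1", "PX", set(range(20)), resolution=3.0),
            _meta("S2", "PX", set(range(20)), resolution=2.0),
            _meta("M1", "PY", set(range(10))),
            _meta("SUB", "PZ", {1}, core=5),
        ]
        first = bm.select_representatives(metas)
        survivors = [m for m in metas if m.structure_id in first.selected]
        second = bm.select_representatives(survivors)
        assert second.selected == first.selected


def _mode_bundle(tmp_path, targets, structure_id, seed):
    spec = synthetic.ToyComplexSpec(
        structure_id=structure_id, seed=seed,
        histone_chain_length=8, dna_length=10,
    )
    spec.partners.append(
        synthetic.PartnerSpec("Regulatory protein RP1", 10, targets)
    )
    pdb, _, _ = synthetic.generate_toy_complex(spec, tmp_path)
    st = structure_io.apply_residue_mapping(
        structure_io.parse_structure(pdb), "identity"
    )
    ann = {a.chain_id: a for a in structure_io.classify_chains(st)}
    return st, ann


class TestBindingModes:
    @pytest.mark.parametrize(
        "targets,expected",
        [
            ([("I", 3, 1, 4.6), ("J", 5, 2, 4.8)], "dna_only"),
            ([("C", 3, 1, 4.6)], "histone_only"),
            ([("D", 3, 1, 4.6), ("I", 5, 2, 4.7)], "both"),
        ],
    )
    def test_planted_modes(self, tmp_path, targets, expected):
        st, ann = _mode_bundle(tmp_path, targets, f"MODE{expected}", 21)
        labels = bm.classify_binding_modes(st, ann)
        assert len(labels) == 1
        assert labels[0].mode == expected

    def test_contactless_partner_labeled_none(self, tmp_path, caplog):
        import logging

        st, ann = _mode_bundle(tmp_path, [("A", 3, 1, 6.0)], "MODEnone", 22)
        with caplog.at_level(logging.WARNING, logger="histonet.binding_modes"):
            labels = bm.classify_binding_modes(st, ann)
        assert labels[0].mode == "none"
        assert bm.mode_fractions(labels) == {
            "dna_only": 0.0, "histone_only": 0.0, "both": 0.0
        }

    def test_mode_fractions_partition(self):
        labels = (
            [bm.BindingModeLabel(f"S{i}", "P", "dna_only") for i in range(13)]
            + [bm.BindingModeLabel(f"T{i}", "P", "histone_only") for i in range(4)]
            + [bm.BindingModeLabel(f"U{i}", "P", "both") for i in range(3)]
        )
        fractions = bm.mode_fractions(labels)
        assert fractions == {"dna_only": 0.65, "histone_only": 0.20, "both": 0.15}
        assert sum(fractions.values()) == pytest.approx(1.0)


class TestConsensusMapping:
    def test_gap_free(self):
        aln = poly_ala_alignment([("V1", "A" * 20)])
        assert bm.consensus_position(aln, "V1", 10) == 10

    def test_two_upstream_gaps_offset(self):
        aln = poly_ala_alignment([("V1", "--" + "A" * 18), ("V2", "A" * 20)])
        assert bm.consensus_position(aln, "V1", 10) == 12

    def test_beyond_aligned_length(self):
        aln = poly_ala_alignment([("V1", "A" * 5)])
        with pytest.raises(HistonetError):
            bm.consensus_position(aln, "V1", 6)

    def test_variant_missing(self):
        aln = poly_ala_alignment([("V1", "A" * 5)])
        with pytest.raises(VariantMissingError):
            bm.consensus_position(aln, "V9", 1)


class TestHistoneHotspots:
    def test_two_partners_two_structures_count_two(self):
        records = [
            bm.ConsensusContact("S1", "PX", "H3", 77, 4),
            bm.ConsensusContact("S2", "PY", "H3", 77, 6),
        ]
        aln = {"H3": poly_ala_alignment([("V1", "A" * 100)])}
        profile = bm.profile_histone_hotspots(records, aln)
        row = profile[(profile.histone_type == "H3") & (profile.position == 77)]
        assert int(row.unique_partners.iloc[0]) == 2
        assert float(row.mean_contacts.iloc[0]) == pytest.approx(5.0)

    def test_partner_via_two_chains_counts_once(self, tmp_path):
        """Two chains of one partner protein touching the same histone
        position yield a unique-partner count of one."""
        spec = synthetic.ToyComplexSpec(
            structure_id="TWOCH", seed=23, histone_chain_length=8, dna_length=0
        )
        spec.partners.append(
            synthetic.PartnerSpec("Dimeric reader", 10, [("A", 4, 1, 4.6)])
        )
        spec.partners.append(
            synthetic.PartnerSpec("Dimeric reader", 10, [("A", 4, 2, 4.8)])
        )
        pdb, _, _ = synthetic.generate_toy_complex(spec, tmp_path)
        st = structure_io.apply_residue_mapping(
            structure_io.parse_structure(pdb), "identity"
        )
        ann = {a.chain_id: a for a in structure_io.classify_chains(st)}
        extraction = extract_interfaces(st, ann)
        alignments = alignments_for(st, ann)
        records = bm.consensus_contacts(extraction, alignments)
        assert {r.partner_id for r in records} == {"DIMERIC_READER"}
        profile = bm.profile_histone_hotspots(records, alignments)
        row = profile[(profile.histone_type == "H3") & (profile.position == 4)]
        assert int(row.unique_partners.iloc[0]) == 1

    def test_untouched_positions_zero(self):
        aln = {"H4": poly_ala_alignment([("V1", "A" * 10)])}
        profile = bm.profile_histone_hotspots([], aln)
        assert (profile.unique_partners == 0).all()
        assert (profile.mean_contacts == 0.0).all()
        assert len(profile) == 10


class TestDnaHotspots:
    def _bundle(self, tmp_path, targets, dna_length, structure_id, seed):
        spec = synthetic.ToyComplexSpec(
            structure_id=structure_id, seed=seed,
            histone_chain_length=6, dna_length=dna_length,
        )
        spec.partners.append(
            synthetic.PartnerSpec("Regulatory protein RP1", 10, targets)
        )
        pdb, _, _ = synthetic.generate_toy_complex(spec, tmp_path)
        st = structure_io.apply_residue_mapping(
            structure_io.parse_structure(pdb), "identity"
        )
        ann = {a.chain_id: a for a in structure_io.classify_chains(st)}
        return st, ann, extract_interfaces(st, ann)

    def test_single_strand_contact(self, tmp_path):
        st, ann, ex = self._bundle(tmp_path, [("I", 20, 1, 4.6)], 31, "DNA1", 31)
        records, bp_range = bm.dna_bp_contacts(st, ann, ex)
        # dyad of a 31-bp duplex is bp 16
        assert len(records) == 1
        assert records[0].bp_rel == 20 - 16
        profile = bm.profile_dna_hotspots(records, bp_range)
        assert int(profile.loc[profile.position == 4, "unique_partners"].iloc[0]) == 1

    def test_both_strands_of_one_pair_count_once(self, tmp_path):
        # strand I position 4 pairs with strand J position 28 (n=31)
        st, ann, ex = self._bundle(
            tmp_path, [("I", 4, 1, 4.6), ("J", 28, 2, 4.8)], 31, "DNA2", 32
        )
        records, bp_range = bm.dna_bp_contacts(st, ann, ex)
        profile = bm.profile_dna_hotspots(records, bp_range)
        row = profile[profile.position == 4 - 16]
        assert int(row.unique_partners.iloc[0]) == 1

    def test_dyad_defaults_to_midpoint_147(self, tmp_path):
        st, ann, ex = self._bundle(tmp_path, [("I", 74, 1, 4.6)], 147, "DNA3", 33)
        records, bp_range = bm.dna_bp_contacts(st, ann, ex)
        assert records[0].bp_rel == 0  # 147-bp duplex: dyad = bp 74
        assert bp_range == (1 - 74, 147 - 74)

    def test_strand_swap_mirrors_profile(self, tmp_path):
        st, ann, ex = self._bundle(
            tmp_path, [("I", 5, 1, 4.6), ("J", 9, 2, 4.7)], 31, "DNA4", 34
        )
        records, _ = bm.dna_bp_contacts(st, ann, ex)
        swapped = st.copy()
        for chain in swapped.chains:
            if chain.chain_id == "I":
                chain.chain_id = "J"
            elif chain.chain_id == "J":
                chain.chain_id = "I"
        swapped.chains.sort(key=lambda c: c.chain_id)
        ann2 = dict(ann)
        ex2 = extract_interfaces(swapped, ann2)
        records2, _ = bm.dna_bp_contacts(swapped, ann2, ex2)
        assert {(r.partner_id, -r.bp_rel) for r in records2} == {
            (r.partner_id, r.bp_rel) for r in records
        }

    def test_strand_length_mismatch_error(self, tmp_path):
        st, ann, ex = self._bundle(tmp_path, [("I", 3, 1, 4.6)], 20, "DNA5", 35)
        st.chain("J").residues = st.chain("J").residues[:10]
        with pytest.raises(bm.StrandMismatchError):
            bm.dna_bp_contacts(st, ann, ex)


class TestFunctionalComparison:
    def test_shared_positions_flagged(self):
        records = [
            bm.ConsensusContact("S1", "PX", "H2A", 56, 3),
            bm.ConsensusContact("S2", "PY", "H2A", 56, 2),
            bm.ConsensusContact("S2", "PY", "H2A", 60, 1),
        ]
        out = bm.compare_modes_by_function(
            records, {"S1": "remodeller", "S2": "remodeller"}
        )
        assert out["remodeller"]["shared_positions"] == {("H2A", 56)}
        assert ("H2A", 60) in out["remodeller"]["positions"]

    def test_single_structure_no_shared(self):
        records = [bm.ConsensusContact("S1", "PX", "H3", 10, 1)]
        out = bm.compare_modes_by_function(records, {"S1": "chaperone"})
        assert out["chaperone"]["shared_positions"] == set()

    def test_unannotated_grouped_unclassified(self, caplog):
        import logging

        records = [bm.ConsensusContact("S9", "PX", "H3", 10, 1)]
        with caplog.at_level(logging.WARNING, logger="histonet.binding_modes"):
            out = bm.compare_modes_by_function(records, {})
        assert "unclassified" in out


class TestComplexMetadataDerivation:
    def test_toy_metadata(self, toy_bundle):
        meta = bm.build_complex_metadata(
            toy_bundle["structure"], toy_bundle["annotations"],
            toy_bundle["extraction"], resolution=2.1,
        )
        assert meta.core_histone_count == 8
        assert meta.dna_length == toy_bundle["spec"].dna_length
        # one HDI plant anchors one nucleotide on strand I; strand J has none
        assert meta.n_unanchored_bp == toy_bundle["spec"].dna_length
        (partner,) = meta.partners
        assert partner.partner_id == "REGULATORY_PROTEIN_RP1"
        assert partner.length == 12
        assert len(partner.interface) == 2  # A5 (HPI) and I3 (DPI)
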