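"""Mutation curation, interface mapping, ddG calling and group comparison."""

import numpy as np
import pandas as pd
import pytest

from histonet import mutations as mut
from histonet.exceptions import (
    DegenerateGroupsError,
    HistonetError,
    MissingColumnError,
)
from histonet.networks import Network


def _frame(rows):
    base = {
        "cancer_type": "Breast Cancer", "variant_class": "missense",
        "sequencing_type": "wxs", "somatic_status": "matched",
        "sample_tmb": 2.0, "in_dbsnp": False,
    }
    return pd.DataFrame([{**base, **r} for r in rows])


class TestParsing:
    def test_protein_change_decomposition(self):
        df = _frame([
            {"gene": "H2AC11", "protein_change": "R29P", "sample_id": "s1"},
            {"gene": "H3C1", "protein_change": "K27M", "sample_id": "s2"},
        ])
        records, rejects = mut.parse_mutations(df)
        assert len(rejects) == 0
        assert tuple(records.loc[0, ["wt_aa", "position", "mut_aa"]]) == ("R", 29, "P")
        assert tuple(records.loc[1, ["wt_aa", "position", "mut_aa"]]) == ("K", 27, "M")

    def test_malformed_change_rejected_not_dropped(self):
        df = _frame([
            {"gene": "H4C1", "protein_change": "R29", "sample_id": "s1"},
            {"gene": "H4C1", "protein_change": "K31R", "sample_id": "s2"},
        ])
        records, rejects = mut.parse_mutations(df)
        assert len(records) == 1 and len(rejects) == 1
        assert rejects.loc[0, "reject_reason"] == "unparseable protein change"

    def test_missing_column_named(self):
        df = _frame([{"gene": "H4C1", "protein_change": "K31R",
                      "sample_id": "s1"}]).drop(columns=["somatic_status"])
        with pytest.raises(MissingColumnError, match="somatic_status"):
            mut.parse_mutations(df)


class TestCombinedSet:
    def test_planted_filter_counts(self):
        rows = [
            {"gene": "H3C1", "protein_change": f"K{i}R", "sample_id": f"s{i}"}
            for i in range(1, 6)
        ]
        rows += [
            {"gene": "H3C1", "protein_change": f"K{i}R", "sample_id": f"t{i}",
             "sequencing_type": "targeted"} for i in range(6, 9)
        ]
        rows.append({"gene": "H3C1", "protein_change": "K9R", "sample_id": "u1",
                     "somatic_status": "unmatched"})
        rows.append({"gene": "H3C1", "protein_change": "K10*", "sample_id": "v1",
                     "variant_class": "nonsense"})
        records, _ = mut.parse_mutations(_frame(rows))
        combined = mut.build_combined_set(records)
        assert combined.n_records == 5

    def test_external_union_dedup(self):
        records, _ = mut.parse_mutations(_frame([
            {"gene": "H3C1", "protein_change": "K27M", "sample_id": "s1"},
        ]))
        external, _ = mut.parse_mutations(_frame([
            {"gene": "H3C1", "protein_change": "K27M", "sample_id": "s1"},
            {"gene": "H3C1", "protein_change": "G34R", "sample_id": "s2"},
        ]))
        combined = mut.build_combined_set(records, external)
        assert combined.n_records == 2

    def test_empty_input(self):
        records, _ = mut.parse_mutations(pd.DataFrame(columns=mut.REQUIRED_COLUMNS))
        assert mut.build_combined_set(records).n_records == 0


class TestRefinedSet:
    def _combined(self, rows):
        records, _ = mut.parse_mutations(_frame(rows))
        return mut.build_combined_set(records)

    def test_tmb_strictly_above_cutoff_dropped(self):
        rows = [
            {"gene": "H3C1", "protein_change": "K27M", "sample_id": f"hi{i}",
             "sample_tmb": 11.0} for i in range(3)
        ] + [
            {"gene": "H3C1", "protein_change": "G34R", "sample_id": f"ok{i}",
             "sample_tmb": 10.0} for i in range(3)
        ]
        refined = mut.build_refined_set(self._combined(rows))
        assert set(refined.records["protein_change"]) == {"G34R"}

    def test_recurrence_threshold(self):
        rows = [
            {"gene": "H4C1", "protein_change": "R45C", "sample_id": f"a{i}"}
            for i in range(3)
        ] + [
            {"gene": "H4C1", "protein_change": "R39L", "sample_id": f"b{i}"}
            for i in range(2)
        ]
        refined = mut.build_refined_set(self._combined(rows))
        assert set(refined.records["protein_change"]) == {"R45C"}
        assert refined.recurrence()[("H4C1", "R", 45, "C")] == 3

    def test_dbsnp_dropped(self):
        rows = [
            {"gene": "H4C1", "protein_change": "R45C", "sample_id": f"a{i}",
             "in_dbsnp": True} for i in range(4)
        ]
        assert mut.build_refined_set(self._combined(rows)).n_records == 0

    def test_filter_monotonicity(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(60):
            rows.append({
                "gene": "H3C1",
                "protein_change": f"K{rng.integers(1, 20)}R",
                "sample_id": f"s{rng.integers(1, 30)}",
                "sequencing_type": str(rng.choice(["wxs", "targeted"])),
                "somatic_status": str(rng.choice(["matched", "unmatched"])),
                "sample_tmb": float(rng.uniform(0, 20)),
                "in_dbsnp": bool(rng.random() < 0.2),
            })
        records, _ = mut.parse_mutations(_frame(rows))
        combined = mut.build_combined_set(records)
        refined = mut.build_refined_set(combined)
        assert refined.n_records <= combined.n_records <= len(records)


def _interface_network():
    net = Network("residue")
    net.add_node("H3C1/27", "histone:H3")
    net.add_node("H3C1/56", "histone:H3")
    net.add_node("H4C1/31", "histone:H4")
    net.add_node("PX/100", "partner")
    net.add_node("DNA/5", "dna")
    net.add_edge("H3C1/27", "H4C1/31", "HHI", {"structural:1X"})
    net.add_edge("H3C1/27", "DNA/5", "HDI", {"structural:1X"})
    net.add_edge("H3C1/56", "PX/100", "HPI", {"structural:1X"})
    return net


class TestInterfaceMapping:
    def _set(self, changes):
        rows = [
            {"gene": g, "protein_change": pc, "sample_id": f"s{i}"}
            for i, (g, pc) in enumerate(changes)
        ]
        records, _ = mut.parse_mutations(_frame(rows))
        return mut.MutationSet("refined", records)

    def test_multi_interface_mutation_in_both_lists(self):
        mset = self._set([("H3C1", "K27M")])
        mapped = mut.map_mutations_to_interfaces(mset, _interface_network())
        assert len(mapped["HHI"]) == 1 and len(mapped["HDI"]) == 1
        assert len(mapped["HPI"]) == 0
        assert len(mapped["multi"]) == 1 and len(mapped["triple"]) == 0

    def test_non_interface_unmapped(self):
        mset = self._set([("H3C1", "A99V")])
        mapped = mut.map_mutations_to_interfaces(mset, _interface_network())
        assert len(mapped["unmapped"]) == 1
        assert all(len(mapped[c]) == 0 for c in ("HHI", "HDI", "HPI"))

    def test_empty_set(self):
        mset = mut.MutationSet(
            "refined", pd.DataFrame(columns=mut.REQUIRED_COLUMNS
                                    + ["wt_aa", "position", "mut_aa"])
        )
        mapped = mut.map_mutations_to_interfaces(mset, _interface_network())
        assert all(len(df) == 0 for df in mapped.values())

    def test_consistency_with_bruteforce_scan(self):
        """Class membership equals a brute-force scan over the edge table."""
        net = _interface_network()
        mset = self._set(
            [("H3C1", "K27M"), ("H3C1", "V56L"), ("H4C1", "R31C"),
             ("H4C1", "A99V")]
        )
        mapped = mut.map_mutations_to_interfaces(mset, net)
        for cls in ("HHI", "HDI", "HPI"):
            expected = set()
            for _, row in mset.records.iterrows():
                node = f"{row.gene}/{row.position}"
                for a, b, d in net.graph.edges(data=True):
                    if d["interaction_class"] == cls and node in (a, b):
                        expected.add((row.gene, row.position))
            got = {
                (r.gene, r.position) for r in mapped[cls].itertuples()
            }
            assert got == expected


class TestPhyschem:
    @pytest.mark.parametrize(
        "aa,cat",
        [("K", "positive"), ("R", "positive"), ("H", "positive"),
         ("E", "negative"), ("D", "negative"),
         ("S", "polar_uncharged"), ("C", "polar_uncharged"),
         ("G", "nonpolar_aliphatic"), ("P", "nonpolar_aliphatic"),
         ("F", "nonpolar_aromatic"), ("Y", "nonpolar_aromatic")],
    )
    def test_categories(self, aa, cat):
        assert mut.classify_physchem(aa) == cat

    def test_total_over_standard_aas(self):
        assert len(mut.PHYSCHEM) == 20

    def test_nonstandard_error(self):
        with pytest.raises(HistonetError):
            mut.classify_physchem("X")

    def test_r_to_l_bookkeeping(self):
        mapped = pd.DataFrame({"wt_aa": ["R"] * 10, "mut_aa": ["L"] * 10})
        profile = mut.profile_interface_change(mapped).set_index("category")
        assert profile.loc["positive", "wild_type"] == 10
        assert profile.loc["positive", "mutant"] == 0
        assert profile.loc["nonpolar_aliphatic", "mutant"] == 10


class TestDdg:
    def _mutation(self):
        return {"gene": "HISTONE_H3.1", "wt_aa": "R", "position": 5,
                "mut_aa": "L"}

    def test_hhi_predictor_sees_partnerless_structure(self, toy_bundle):
        seen = {}

        def spy(structure, chain_id, position, wt, mutant, mode):
            seen["chains"] = set(structure.chain_ids())
            seen["mode"] = mode
            return 1.0

        spy.predictor_id = "spy"
        record = mut.predict_ddg(
            self._mutation(), toy_bundle["structure"],
            toy_bundle["annotations"], "HHI", predictor=spy,
        )
        assert record is not None
        assert "P" not in seen["chains"]
        assert {"A", "B", "I", "J"} <= seen["chains"]
        assert seen["mode"] == "protein-protein"

    def test_hpi_predictor_sees_full_complex(self, toy_bundle):
        seen = {}

        def spy(structure, chain_id, position, wt, mutant, mode):
            seen["chains"] = set(structure.chain_ids())
            return 1.0

        spy.predictor_id = "spy"
        mut.predict_ddg(
            self._mutation(), toy_bundle["structure"],
            toy_bundle["annotations"], "HPI", predictor=spy,
        )
        assert "P" in seen["chains"]

    def test_hdi_mode_is_protein_dna(self, toy_bundle):
        seen = {}

        def spy(structure, chain_id, position, wt, mutant, mode):
            seen["mode"] = mode
            return 0.5

        spy.predictor_id = "spy"
        mut.predict_ddg(
            self._mutation(), toy_bundle["structure"],
            toy_bundle["annotations"], "HDI", predictor=spy,
        )
        assert seen["mode"] == "protein-DNA"

    def test_surrogate_deterministic(self, toy_bundle):
        records = [
            mut.predict_ddg(
                self._mutation(), toy_bundle["structure"],
                toy_bundle["annotations"], "HHI",
            )
            for _ in range(2)
        ]
        assert records[0].ddg == records[1].ddg
        assert records[0].predictor_id == "surrogate-physchem-v1"

    def test_absent_position_skipped(self, toy_bundle):
        mutation = {"gene": "HISTONE_H3.1", "wt_aa": "R", "position": 9999,
                    "mut_aa": "L"}
        assert mut.predict_ddg(
            mutation, toy_bundle["structure"], toy_bundle["annotations"], "HHI"
        ) is None


class TestDisruptiveSelection:
    def _rec(self, cls, ddg, gene="H3C1", pos=27, structure="S1"):
        return mut.DdgRecord(gene, "K", pos, "M", cls, ddg, "surrogate", structure)

    def test_thresholds(self):
        records = [
            self._rec("HDI", 1.2, pos=27),
            self._rec("HHI", 1.4, pos=31),
            self._rec("HPI", 2.0, pos=35),
        ]
        recurrence = {("H3C1", "K", 27, "M"): 4, ("H3C1", "K", 31, "M"): 4,
                      ("H3C1", "K", 35, "M"): 2}
        out = mut.select_disruptive(records, recurrence)
        assert set(out["interaction_class"]) == {"HDI"}
        assert out.loc[0, "mean_ddg"] == pytest.approx(1.2)

    def test_order_and_duplicate_invariance(self):
        records = [
            self._rec("HHI", 2.0, structure="S1"),
            self._rec("HHI", 1.0, structure="S2"),
            self._rec("HHI", 2.0, structure="S1"),  # duplicate row
        ]
        recurrence = {("H3C1", "K", 27, "M"): 3}
        fwd = mut.select_disruptive(records, recurrence)
        rev = mut.select_disruptive(records[::-1], recurrence)
        assert fwd.equals(rev)
        assert fwd.loc[0, "mean_ddg"] == pytest.approx(1.5)  # mean of 2.0, 1.0


class TestTukey:
    def test_separated_groups_flagged(self):
        rng = np.random.default_rng(1)
        groups = {"H2A": rng.normal(0, 1, 12), "H3": rng.normal(5, 1, 12)}
        out = mut.compare_ddg_groups(groups)
        assert bool(out["pairs"]["sig_0.005"].iloc[0])
        assert out["medians"]["H3"] > out["medians"]["H2A"]

    def test_single_group_error(self):
        with pytest.raises(DegenerateGroupsError):
            mut.compare_ddg_groups({"H3": [1.0, 2.0]})

    def test_tiny_group_error(self):
        with pytest.raises(DegenerateGroupsError):
            mut.compare_ddg_groups({"H3": [1.0, 2.0], "H4": [1.0]})
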