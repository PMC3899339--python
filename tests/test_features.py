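"""Feature computations: CAI, domain stats, centralities, homology
counts, phyletic age, expression stats, and table assembly."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esstrans.features import (
    DomainHit,
    build_feature_table,
    cai_weights,
    compute_cai,
    compute_doc,
    compute_dot,
    cross_species_homology_counts,
    expression_stats,
    graph_centralities,
    paralog_count,
    phyletic_age,
)


class TestCAI:
    def test_all_weights_one(self):
        w = {"GCT": 1.0, "GCC": 1.0}
        assert compute_cai(["GCT", "GCC", "GCT"], w) == pytest.approx(1.0)

    def test_geometric_mean_by_hand(self):
        # sqrt(1.0 * 0.25) = 0.5
        assert compute_cai(["GCT", "GCC"], {"GCT": 1.0, "GCC": 0.25}) == pytest.approx(0.5)

    def test_single_codon(self):
        assert compute_cai(["GCT"], {"GCT": 0.5}) == pytest.approx(0.5)

    def test_excluded_codons_skipped(self):
        # ATG (Met) and TGG (Trp) have no synonyms; TAA is a stop
        assert compute_cai("ATGGCTTAA", {"GCT": 0.25}) == pytest.approx(0.25)

    def test_unknown_codon_named_in_error(self):
        with pytest.raises(ValueError, match="GCC"):
            compute_cai(["GCC"], {"GCT": 1.0})

    def test_no_usable_codons(self):
        with pytest.raises(ValueError):
            compute_cai(["ATG"], {"GCT": 1.0})

    @settings(deadline=None, max_examples=30)
    @given(st.permutations(["GCT", "GCC", "GCA", "CGT", "CGC", "TTA"]))
    def test_order_invariance(self, codons):
        w = {"GCT": 1.0, "GCC": 0.5, "GCA": 0.25, "CGT": 0.9, "CGC": 0.3, "TTA": 0.7}
        ref = compute_cai(sorted(codons), w)
        assert compute_cai(codons, w) == pytest.approx(ref, rel=1e-12)

    def test_weights_from_reference_set(self):
        # GCT appears 3x, GCC 1x within Ala family -> weights 1.0 and 1/3
        w = cai_weights(["GCTGCTGCTGCC"])
        assert w["GCT"] == pytest.approx(1.0)
        assert w["GCC"] == pytest.approx(1 / 3)
        # unseen synonym gets the 0.5 pseudo-count
        assert w["GCA"] == pytest.approx(0.5 / 3)
        assert all(0 < v <= 1 for v in w.values())


class TestDomainFeatures:
    def test_doc_single_hit(self):
        assert compute_doc([DomainHit("g", "D1", 100, 200)]) == pytest.approx(0.5)

    def test_doc_aggregates_sum_over_sum(self):
        hits = [DomainHit("g", "D1", 50, 100), DomainHit("g", "D2", 30, 60)]
        assert compute_doc(hits) == pytest.approx(80 / 160)

    def test_no_hits_missing(self):
        assert math.isnan(compute_doc([]))
        assert compute_dot([]) is None

    def test_doc_scale_consistency(self):
        hits = [DomainHit("g", "D1", 50, 100), DomainHit("g", "D2", 30, 60)]
        doubled = [DomainHit("g", h.domain_id, 2 * h.bit_score, h.domain_length) for h in hits]
        assert compute_doc(doubled) == pytest.approx(2 * compute_doc(hits))

    def test_invalid_length_rejected(self):
        with pytest.raises(ValueError):
            DomainHit("g", "D1", 10, 0)

    @pytest.mark.parametrize(
        "hits,expected",
        [
            ([DomainHit("g", "D1", 10, 5)], "D1"),
            ([DomainHit("g", "D2", 40, 5), DomainHit("g", "D1", 90, 5)], "D1"),
            ([DomainHit("g", "D2", 50, 5), DomainHit("g", "D1", 50, 5)], "D1"),  # tie: lexicographic
        ],
    )
    def test_dot_top_score_lexicographic_ties(self, hits, expected):
        assert compute_dot(hits) == expected


class TestCentralities:
    def test_triangle(self):
        out = graph_centralities([("a", "b"), ("b", "c"), ("a", "c")], ["a", "b", "c"])
        for node in "abc":
            row = out.loc[node]
            assert row["DC"] == pytest.approx(1.0)
            assert row["CCo"] == pytest.approx(1.0)
            assert row["CC"] == pytest.approx(1.0)
            assert row["BC"] == pytest.approx(0.0)

    def test_path_center(self):
        out = graph_centralities([("a", "b"), ("b", "c")], ["a", "b", "c"])
        row = out.loc["b"]
        assert row["DC"] == pytest.approx(1.0)
        assert row["CCo"] == pytest.approx(0.0)
        assert row["CC"] == pytest.approx(1.0)
        assert row["BC"] == pytest.approx(1.0)

    def test_isolated_node_all_zero(self):
        out = graph_centralities([("a", "b")], ["a", "b", "z"])
        assert (out.loc["z"] == 0).all()

    def test_self_loops_and_duplicates_dropped(self):
        out = graph_centralities([("a", "a"), ("a", "b"), ("a", "b")], ["a", "b"])
        assert out.loc["a", "DC"] == pytest.approx(1.0)

    def test_unknown_node_rejected(self):
        with pytest.raises(ValueError, match="outside the universe"):
            graph_centralities([("a", "q")], ["a", "b"])


class TestHomology:
    def test_paralog_counting(self):
        edges = [("g1", "g2"), ("g1", "g3"), ("g4", "g1"), ("g2", "g3")]
        assert paralog_count(edges, "g1") == 3
        assert paralog_count(edges, "g5") == 0

    def test_duplicate_edges_deduplicated(self):
        assert paralog_count([("g1", "g2"), ("g1", "g2"), ("g2", "g1")], "g1") == 1

    def test_cross_species_counts(self):
        gene_species = {"t": "A", "e1": "B", "e2": "B", "e3": "C", "u1": "D"}
        labels = {"B": {"e1": 1, "e2": 0}, "C": {"e3": 1}}
        edges = [("t", "e1"), ("t", "e2"), ("t", "e3")]
        assert cross_species_homology_counts(edges, gene_species, labels, "t") == (2, 2, 1)

    def test_no_homologs(self):
        assert cross_species_homology_counts([], {"t": "A"}, {}, "t") == (0, 0, 0)

    def test_unlabeled_species_counts_in_ns_only(self):
        gene_species = {"t": "A", "u1": "D"}
        assert cross_species_homology_counts([("t", "u1")], gene_species, {}, "t") == (1, 0, 0)

    def test_own_species_excluded(self):
        gene_species = {"t": "A", "p": "A"}
        labels = {"A": {"p": 1}}
        assert cross_species_homology_counts([("t", "p")], gene_species, labels, "t") == (0, 0, 0)

    def test_removing_species_never_increases_counts(self):
        gene_species = {"t": "A", "e1": "B", "e2": "B", "e3": "C", "e4": "D"}
        labels = {"B": {"e1": 1, "e2": 0}, "C": {"e3": 1}, "D": {"e4": 0}}
        edges = [("t", g) for g in ("e1", "e2", "e3", "e4")]
        full = cross_species_homology_counts(edges, gene_species, labels, "t")
        for drop in ("B", "C", "D"):
            sub_edges = [(a, b) for a, b in edges if gene_species[b] != drop]
            sub = cross_species_homology_counts(sub_edges, gene_species, labels, "t")
            assert all(s <= f for s, f in zip(sub, full))


class TestAgeAndExpression:
    CLADES = ["species_typical", "clade2", "clade3", "clade4", "cellular_organisms"]

    def test_age_innermost_only(self):
        assert phyletic_age({"species_typical": True}, self.CLADES) == 1
        assert phyletic_age({}, self.CLADES) == 1

    def test_age_all_clades(self):
        assert phyletic_age({c: True for c in self.CLADES}, self.CLADES) == 5

    def test_age_gap_takes_outermost(self):
        presence = {"species_typical": True, "clade3": False, "cellular_organisms": True}
        assert phyletic_age(presence, self.CLADES) == 5

    def test_empty_clade_order_rejected(self):
        with pytest.raises(ValueError):
            phyletic_age({}, [])

    def test_expression_constant(self):
        assert expression_stats([5, 5, 5]) == pytest.approx((5.0, 0.0))

    def test_expression_by_hand(self):
        me, mef = expression_stats([2, 4])
        assert me == pytest.approx(3.0)
        assert mef == pytest.approx(math.sqrt(2) / 3)

    def test_single_value(self):
        me, mef = expression_stats([7])
        assert me == 7.0 and math.isnan(mef)

    def test_all_missing(self):
        me, mef = expression_stats([float("nan")])
        assert math.isnan(me) and math.isnan(mef)


class TestBuildFeatureTable:
    def test_schema_and_missingness_rules(self):
        genes = [f"g{i}" for i in range(20)]
        table = build_feature_table(
            "SPX",
            genes,
            ppi_edges=[("g0", "g1"), ("g1", "g2")],
            ppi_nodes=genes[:10],  # g10.. outside the PPI universe
            expression=pd.DataFrame({"c1": [2.0], "c2": [4.0]}, index=["g0"]),
        )
        assert list(table.columns) == [
            "species_id", "mE", "mEF", "DoC", "DC", "CCo", "CC", "BC",
            "PL", "CAI", "NP", "NS", "NEH", "NNH", "Age", "DoT",
        ]
        assert table.loc["g5", "DC"] == 0.0  # in universe, no edges
        assert np.isnan(table.loc["g15", "DC"])  # outside universe
        assert table.loc["g0", "mE"] == pytest.approx(3.0)
        assert np.isnan(table.loc["g1", "mE"])

    def test_duplicate_gene_rejected(self):
        with pytest.raises(ValueError, match="duplicated gene_id"):
            build_feature_table("SPX", ["g1", "g1"])

    def test_empty_inputs_still_valid(self):
        table = build_feature_table("SPX", ["g1", "g2"])
        assert table.drop(columns="species_id").isna().all().all()
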