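"""Feature building, SNV annotation, aggregation and coverage arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rigsa
from rigsa.mapping import (
    Feature,
    GeneModel,
    RegulatoryElement,
    aggregate_snv_gene_map,
    annotate_features_with_snvs,
    build_flanked_features,
    compute_coverage,
    derive_ri_from_contacts,
    merge_intervals,
    process_ri_dataset,
)


def _variants(positions, chrom=1):
    """1-based positions -> minimal sorted variant table."""
    return pd.DataFrame(
        {
            "rsid": [f"rs{i}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": sorted(positions),
            "a1": "A",
            "a2": "G",
            "maf": 0.2,
        }
    )


class TestFlankedFeatures:
    def test_zero_flanks_emit_bodies_only(self, toy_genes):
        feats = build_flanked_features(toy_genes, 0, 0)
        assert [f.kind for f in feats] == ["body", "body"]

    def test_plus_strand_upstream_flank_is_five_prime_of_body(self):
        g = GeneModel("g", 1, 100_000, 120_000, "+")
        feats = {f.kind: f for f in build_flanked_features([g], 10, 5)}
        assert (feats["flank_up"].start, feats["flank_up"].end) == (90_000, 100_000)
        assert (feats["flank_down"].start, feats["flank_down"].end) == (120_000, 125_000)

    def test_minus_strand_upstream_flank_lies_three_prime_in_reference_coords(self):
        g = GeneModel("g", 1, 100_000, 120_000, "-")
        feats = {f.kind: f for f in build_flanked_features([g], 10, 5)}
        assert (feats["flank_up"].start, feats["flank_up"].end) == (120_000, 130_000)
        assert (feats["flank_down"].start, feats["flank_down"].end) == (95_000, 100_000)

    def test_flanks_clip_at_chromosome_start(self):
        g = GeneModel("g", 1, 4_000, 10_000, "+")
        feats = {f.kind: f for f in build_flanked_features([g], 10, 0)}
        assert feats["flank_up"].start == 0

    def test_negative_flank_rejected(self, toy_genes):
        with pytest.raises(ValueError):
            build_flanked_features(toy_genes, -1, 0)


class TestDeriveRiFromContacts:
    # promoter of gA (+, body 100k-120k) is [98k, 100k)
    def test_pair_missing_all_promoters_contributes_nothing(self, toy_genes):
        pairs = [((1, 500_000, 501_000), (1, 600_000, 601_000))]
        assert derive_ri_from_contacts(pairs, toy_genes) == []

    def test_locus_paired_with_promoter_becomes_element(self, toy_genes):
        pairs = [((1, 500_000, 502_000), (1, 99_000, 99_500))]
        elems = derive_ri_from_contacts(pairs, toy_genes)
        assert [(e.gene_id, e.start, e.end) for e in elems] == [("gA", 500_000, 502_000)]

    def test_promoter_overlapping_two_genes_yields_two_elements(self):
        genes = [
            GeneModel("g1", 1, 100_000, 120_000, "+"),
            GeneModel("g2", 1, 96_000, 98_500, "+"),
        ]
        # locus B overlaps g1's promoter [98k,100k) and g2's body is nearby
        pairs = [((1, 500_000, 502_000), (1, 98_600, 99_500))]
        elems = derive_ri_from_contacts(pairs, genes)
        assert {e.gene_id for e in elems} == {"g1"}

    def test_symmetric_rule_on_two_gene_toy(self):
        # locus A overlaps g1's promoter, locus B overlaps g2's promoter:
        # the symmetric rule emits B as an element of g1 and A as one of g2
        genes = [
            GeneModel("g1", 1, 100_000, 120_000, "+"),
            GeneModel("g2", 1, 500_000, 520_000, "+"),
        ]
        pairs = [((1, 98_000, 99_000), (1, 498_000, 499_000))]
        elems = derive_ri_from_contacts(pairs, genes)
        got = {(e.gene_id, e.start) for e in elems}
        assert got == {("g1", 498_000), ("g2", 98_000)}

    def test_interchromosomal_pairs_dropped_not_raised(self, toy_genes):
        pairs = [((2, 500_000, 502_000), (1, 99_000, 99_500))]
        assert derive_ri_from_contacts(pairs, toy_genes) == []


class TestProcessRiDataset:
    def test_overlapping_elements_merge_per_gene(self, toy_genes):
        raw = [
            RegulatoryElement("gA", 1, 100, 200, "e1"),
            RegulatoryElement("gA", 1, 150, 300, "e2"),
        ]
        out = process_ri_dataset(raw, toy_genes)
        assert [(e.start, e.end) for e in out] == [(100, 300)]

    def test_identical_intervals_for_two_genes_both_retained(self, toy_genes):
        raw = [
            RegulatoryElement("gA", 1, 100, 200, "e1"),
            RegulatoryElement("gB", 1, 100, 200, "e2"),
        ]
        out = process_ri_dataset(raw, toy_genes)
        assert {e.gene_id for e in out} == {"gA", "gB"}

    def test_chromosome_mismatch_and_unknown_gene_removed(self, toy_genes):
        raw = [
            RegulatoryElement("gA", 2, 100, 200, "e1"),  # wrong chromosome
            RegulatoryElement("gZ", 1, 100, 200, "e2"),  # not in background
        ]
        assert process_ri_dataset(raw, toy_genes) == []


class TestAnnotation:
    def test_boundary_snvs_follow_halfopen_convention(self):
        # feature [1000, 2000) in 0-based coords; 1-based SNV positions
        feat = Feature("f", "g", 1, 1000, 2000, "body")
        variants = _variants([1000, 1001, 2000, 2001])
        ann = annotate_features_with_snvs([feat], variants)[0]
        # pos0 = pos-1: 999 (out), 1000 (in), 1999 (in), 2000 (out)
        assert list(ann.snv_ids) == ["rs1", "rs2"]

    def test_exclusion_region_blanks_snvs_and_genes(self):
        body = Feature("g", "g", 6, 28_500_000, 33_000_000, "body")
        other = Feature("h", "h", 6, 40_000_000, 41_000_000, "body")
        variants = _variants([30_000_000, 40_500_000], chrom=6)
        anns = annotate_features_with_snvs(
            [body, other], variants, exclusion_region=rigsa.mapping.MHC_REGION
        )
        names = {a.feature.name: list(a.snv_ids) for a in anns}
        assert "g" not in names  # gene overlapping the region is excluded
        assert names["h"] == ["rs1"]

    def test_empty_features_are_retained(self, toy_genes):
        feats = build_flanked_features(toy_genes, 0, 0)
        anns = annotate_features_with_snvs(feats, _variants([1]))
        assert len(anns) == 2
        assert all(len(a.snv_ids) == 0 for a in anns)


class TestAggregation:
    def test_augmentation_subset_of_baseline_is_idempotent(self):
        f = Feature("g", "g", 1, 0, 5000, "body")
        variants = _variants([100, 2000, 4000])
        base = annotate_features_with_snvs([f], variants)
        sub = annotate_features_with_snvs([Feature("g_e", "g", 1, 0, 2500, "element")], variants)
        merged = aggregate_snv_gene_map(base, sub, "m")
        only = aggregate_snv_gene_map(base, None, "m")
        assert np.array_equal(merged.genes["g"].snv_ids, only.genes["g"].snv_ids)
        assert merged.genes["g"].intragenic.all()

    def test_origin_is_per_gene(self):
        variants = _variants([1_500])
        body_g2 = Feature("g2", "g2", 1, 1_000, 2_000, "body")
        elem_g1 = Feature("g1_e", "g1", 1, 1_200, 1_800, "element")
        base = annotate_features_with_snvs([body_g2], variants)
        aug = annotate_features_with_snvs([elem_g1], variants)
        m = aggregate_snv_gene_map(base, aug, "m")
        assert m.genes["g2"].intragenic.all()  # body SNV
        assert not m.genes["g1"].intragenic.any()  # element-only SNV

    def test_aggregation_is_order_independent(self):
        variants = _variants([100, 900, 1500, 2500])
        feats = [
            Feature("g", "g", 1, 0, 1000, "body"),
            Feature("g_e1", "g", 1, 800, 1600, "element"),
            Feature("g_e2", "g", 1, 2000, 3000, "element"),
        ]
        anns = annotate_features_with_snvs(feats, variants)
        a = aggregate_snv_gene_map(anns[:1], anns[1:], "m")
        b = aggregate_snv_gene_map(anns[:1], anns[1:][::-1], "m")
        assert np.array_equal(a.genes["g"].snv_ids, b.genes["g"].snv_ids)
        assert np.array_equal(a.genes["g"].intragenic, b.genes["g"].intragenic)
        # no SNV mapped twice to the same gene
        assert len(set(a.genes["g"].snv_ids)) == len(a.genes["g"].snv_ids)


class TestCoverage:
    def _ann(self, feats, variants):
        return annotate_features_with_snvs(feats, variants)

    def test_single_body_with_snv(self):
        feats = [Feature("g", "g", 1, 0, 100, "body")]
        anns = self._ann(feats, _variants([50]))
        assert compute_coverage(anns, {"rs0"}).coverage_bp == 100

    def test_union_not_sum(self):
        feats = [
            Feature("g", "g", 1, 0, 100, "body"),
            Feature("g_e", "g", 1, 50, 150, "element"),
        ]
        anns = self._ann(feats, _variants([50, 120]))
        assert compute_coverage(anns, {"rs0", "rs1"}).coverage_bp == 150

    def test_feature_without_sumstat_snv_contributes_nothing(self):
        feats = [
            Feature("g", "g", 1, 0, 100, "body"),
            Feature("g_e", "g", 1, 200, 300, "element"),
        ]
        anns = self._ann(feats, _variants([50, 250]))
        assert compute_coverage(anns, {"rs0"}).coverage_bp == 100

    def test_shared_base_pairs_count_once_per_gene(self):
        feats = [
            Feature("g1", "g1", 1, 0, 100, "body"),
            Feature("g2", "g2", 1, 0, 100, "body"),
        ]
        anns = self._ann(feats, _variants([50]))
        assert compute_coverage(anns, {"rs0"}).coverage_bp == 200

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_per_basepair_counter_on_random_toys(self, data):
        n_feat = data.draw(st.integers(1, 6))
        feats = []
        for i in range(n_feat):
            s = data.draw(st.integers(0, 900))
            e = data.draw(st.integers(s + 1, 1000))
            gene = data.draw(st.sampled_from(["g1", "g2"]))
            feats.append(Feature(f"f{i}", gene, 1, s, e, "element"))
        positions = sorted(data.draw(st.sets(st.integers(1, 1000), min_size=1, max_size=15)))
        variants = _variants(positions)
        present = set(
            data.draw(st.sets(st.sampled_from(list(variants["rsid"])), max_size=len(positions)))
        )
        anns = annotate_features_with_snvs(feats, variants)
        got = compute_coverage(anns, present).coverage_bp
        # brute force: count covered base pairs per gene over qualifying features
        pos_in = {r: p - 1 for r, p in zip(variants["rsid"], variants["pos"])}
        expect = 0
        for gene in ("g1", "g2"):
            covered = np.zeros(1001, dtype=bool)
            for f in feats:
                if f.gene_id != gene:
                    continue
                if any(f.start <= pos_in[r] < f.end for r in present):
                    covered[f.start : f.end] = True
            expect += int(covered.sum())
        assert got == expect

    def test_monotone_along_flank_ladder(self, enriched_fixture):
        panel, arch, ss = enriched_fixture
        ids = set(ss["rsid"])
        prev = -1
        for kb in (0, 1, 2, 5, 10, 50, 100):
            feats = build_flanked_features(arch.genes, kb, kb)
            anns = annotate_features_with_snvs(feats, panel.variants)
            cov = compute_coverage(anns, ids).coverage_bp
            assert cov >= prev
            prev = cov


def test_merge_intervals_basic():
    assert merge_intervals([(5, 10), (0, 6), (20, 30)]) == [(0, 10), (20, 30)]
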