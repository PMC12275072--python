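"""Co-occupancy matrices, UpSet counts, link tables, differential mode."""

import pytest

import loopanno as la


def _iv(chrom, start, end, name=None):
    return la.GenomicInterval(chrom, start, end, name=name)


class TestConsensusRegions:
    def test_overlapping_runs_merge(self):
        got = la.consensus_regions(
            [[_iv("c", 100, 200), _iv("c", 150, 300), _iv("c", 400, 500)]]
        )
        assert [(r.start, r.end) for r in got] == [(100, 300), (400, 500)]

    def test_bookended_kept_separate(self):
        got = la.consensus_regions([[_iv("c", 100, 200), _iv("c", 200, 300)]])
        assert [(r.start, r.end) for r in got] == [(100, 200), (200, 300)]

    def test_union_across_sets(self):
        got = la.consensus_regions(
            [[_iv("c", 0, 100)], [_iv("c", 50, 150)], [_iv("d", 0, 10)]]
        )
        assert [(r.chrom, r.start, r.end) for r in got] == [
            ("c", 0, 150), ("d", 0, 10),
        ]


class TestOverlapMatrix:
    def test_bin_mode_manual_tiling(self):
        m = la.compute_overlap_matrix(
            [[_iv("c", 0, 100)], [_iv("c", 50, 150)]], ["A", "B"],
            mode="bin", bin_size=100,
        )
        assert list(m.membership.index) == ["c:0-100", "c:100-150"]
        assert m.membership.loc["c:0-100"].tolist() == [True, True]
        assert m.membership.loc["c:100-150"].tolist() == [False, True]

    def test_regions_mode_uses_consensus(self):
        m = la.compute_overlap_matrix(
            [[_iv("c", 0, 100)], [_iv("c", 50, 150)]], ["A", "B"], mode="regions"
        )
        assert list(m.membership.index) == ["c:0-150"]
        assert m.membership.iloc[0].all()

    def test_disjoint_sets_give_block_membership(self):
        m = la.compute_overlap_matrix(
            [[_iv("c", 0, 100)], [_iv("c", 500, 600)]], ["A", "B"], mode="regions"
        )
        assert m.membership.values.tolist() == [[True, False], [False, True]]

    def test_bin_mode_requires_bin_size(self):
        with pytest.raises(ValueError, match="bin_size"):
            la.compute_overlap_matrix([[_iv("c", 0, 10)]], ["A"], mode="bin")

    def test_every_region_has_a_member(self):
        m = la.compute_overlap_matrix(
            [[_iv("c", 0, 100)]], ["A"], mode="regions",
            regions=[_iv("c", 0, 50), _iv("c", 500, 600)],
        )
        assert list(m.membership.index) == ["c:0-50"]


class TestUpsetCounts:
    def _windows(self):
        return la.make_promoter_windows([la.TssRecord("G", "c", 1000, "+")], 500)

    def test_hand_tally_promoter_vs_distal(self):
        m = la.compute_overlap_matrix(
            [
                [_iv("c", 500, 1200), _iv("c", 5000, 5100), _iv("c", 8000, 8100)],
                [_iv("c", 5050, 5200), _iv("c", 8050, 8150)],
            ],
            ["A", "B"], mode="regions",
        )
        counts = la.upset_counts(m, self._windows())
        as_dict = {
            (r.combination, r.region_class): r.count for r in counts.itertuples()
        }
        assert as_dict == {("A", "promoter"): 1, ("A&B", "distal"): 2}

    def test_counts_sum_to_retained_regions(self):
        m = la.compute_overlap_matrix(
            [[_iv("c", i * 100, i * 100 + 50) for i in range(5)],
             [_iv("c", 120, 470)]],
            ["A", "B"], mode="regions",
        )
        counts = la.upset_counts(m, self._windows())
        assert counts["count"].sum() == len(m.regions)

    def test_no_windows_all_distal(self):
        m = la.compute_overlap_matrix([[_iv("c", 0, 10)]], ["A"], mode="regions")
        counts = la.upset_counts(m, [])
        assert set(counts.region_class) == {"distal"}

    def test_empty_matrix_empty_counts(self):
        m = la.compute_overlap_matrix([[]], ["A"], mode="regions", regions=[])
        assert la.upset_counts(m, []).empty


class TestCircosLinks:
    def _annos(self, t1):
        return la.annotate_peaks(t1.peaks, t1.interactions, t1.tss).annotations

    def test_link_from_engine_output(self, t1):
        windows = la.make_promoter_windows(t1.tss, 2500)
        links = la.circos_links({"EBF1": self._annos(t1)}, windows)
        got = {(l.dataset, l.distal_region.label, l.promoter_gene, l.count)
               for l in links}
        assert ("EBF1", "P1", "G1", 1) in got
        # proximal annotations contribute no links
        assert not any(l.distal_region.label == "P2" for l in links)

    def test_gene_filter(self, t1):
        windows = la.make_promoter_windows(t1.tss, 2500)
        links = la.circos_links(
            {"X": self._annos(t1)}, windows, gene_filter=["G2"]
        )
        assert {l.distal_region.label for l in links} == {"P3"}

    def test_skip_promoter_promoter_drops_own_promoter_links(self, t1):
        # a peak inside G1's promoter window, looped to G1's promoter
        peak = _iv("chrT", 98000, 98400, name="PP")
        loop = la.Interaction(
            _iv("chrT", 95000, 100000), _iv("chrT", 100000, 105000), row_id=9,
            score=2.0,
        )
        res = la.annotate_peaks([peak], [loop], t1.tss,
                                la.AnnotationOptions(bin_size=5000))
        windows = la.make_promoter_windows(t1.tss, 2500)
        with_prom = la.circos_links(
            {"X": res.annotations}, windows, use_promoters=True
        )
        assert any(l.distal_region.label == "PP" for l in with_prom)
        skipped = la.circos_links(
            {"X": res.annotations}, windows, use_promoters=True,
            skip_promoter_promoter=True,
        )
        assert not any(l.distal_region.label == "PP" for l in skipped)

    def test_invariant_to_dataset_order(self, t1):
        windows = la.make_promoter_windows(t1.tss, 2500)
        annos = self._annos(t1)
        a = la.circos_links({"A": annos, "B": annos}, windows)
        b = la.circos_links({"B": annos, "A": annos}, windows)
        assert a == b


class TestClassifyDifferential:
    def _anno(self, gene, name="P"):
        return la.Annotation(
            peak=_iv("c", 0, 100, name=name), gene_symbol=gene,
            annotation_type="interaction", distance_to_tss=5000,
            interaction_row=0, interaction_score=1.0,
        )

    def test_sign_rules(self):
        expr = [
            la.ExpressionRecord("UP", 2.5, 0.01),
            la.ExpressionRecord("DOWN", -2.0, 0.01),
            la.ExpressionRecord("NS", 2.0, 0.6),
        ]
        annos = [self._anno("UP", "P1"), self._anno("DOWN", "P2"),
                 self._anno("NS", "P3"), self._anno("MISSING", "P4")]
        change = {"P1": 2.0, "P2": 2.0, "P3": 2.0, "P4": 2.0}
        table = la.classify_differential(annos, change, expr)
        assert list(table.category) == [
            "activating", "repressive", "unresolved", "unresolved",
        ]

    def test_three_way_partition(self):
        expr = [la.ExpressionRecord("G", 3.0, 0.001)]
        annos = [self._anno("G", f"P{i}") for i in range(4)]
        change = {"P0": 1.0, "P1": -1.0, "P2": 0.0}
        table = la.classify_differential(annos, change, expr)
        assert sorted(table.category) == [
            "activating", "repressive", "unresolved", "unresolved",
        ]
        assert len(table) == len(annos)

    def test_degenerate_thresholds_resolve_everything(self):
        expr = [la.ExpressionRecord("G", 0.2, 0.9)]
        table = la.classify_differential(
            [self._anno("G")], {"P": 1.0}, expr,
            la.DifferentialOptions(padj_threshold=1.0, log2fc_threshold=0.0),
        )
        assert table.category.iloc[0] == "activating"


class TestNetworkExport:
    def test_round_trip_single_edge(self, tmp_path):
        anno = la.Annotation(
            peak=_iv("c", 0, 100, name="P1"), gene_symbol="G1",
            annotation_type="interaction", distance_to_tss=100,
            interaction_row=0, interaction_score=12.0,
        )
        path = tmp_path / "g.xgmml"
        la.export_network([anno], path)
        nodes, edges = la.load_network(path)
        assert nodes == {("peak:P1", "peak"), ("gene:G1", "gene")}
        assert edges == [("peak:P1", "gene:G1", 12.0)]

    def test_shared_gene_three_nodes_two_edges(self, tmp_path, t1_result):
        loops = [a for a in t1_result.annotations
                 if a.annotation_type == "interaction"]
        extra = la.Annotation(
            peak=_iv("chrT", 1, 2, name="PX"), gene_symbol="G1",
            annotation_type="interaction", interaction_row=5,
        )
        path = tmp_path / "g.xgmml"
        la.export_network([loops[0], extra], path)
        nodes, edges = la.load_network(path)
        assert len(nodes) == 3 and len(edges) == 2
        # score-less edge defaults to weight 1
        assert {w for _, _, w in edges} == {12.0, 1.0}

    def test_empty_graph_is_valid(self, tmp_path):
        path = tmp_path / "g.xgmml"
        la.export_network([], path)
        nodes, edges = la.load_network(path)
        assert nodes == set() and edges == []
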