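"""Core engine: promoter windows, anchor matching, proximity fallback."""

import numpy as np
import pytest

import loopanno as la
from conftest import brute_force_pairs, engine_pairs


class TestPromoterWindows:
    def test_default_window_around_tss(self):
        (w,) = la.make_promoter_windows(
            [la.TssRecord("G1", "chrT", 100000, "+")], 2500
        )
        assert (w.window.start, w.window.end) == (97500, 102500)

    def test_window_clipped_at_chromosome_start(self):
        (w,) = la.make_promoter_windows([la.TssRecord("G", "c", 1000, "+")], 2500)
        assert (w.window.start, w.window.end) == (0, 3500)

    def test_genes_sharing_a_tss_get_identical_windows(self):
        ws = la.make_promoter_windows(
            [la.TssRecord("A", "c", 5000, "+"), la.TssRecord("B", "c", 5000, "-")],
            2500,
        )
        assert ws[0].window.start == ws[1].window.start
        assert ws[0].window.end == ws[1].window.end

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            la.make_promoter_windows([], 0)


class TestInferBinSize:
    def _loops(self, widths):
        out = []
        for i in range(0, len(widths), 2):
            out.append(
                la.Interaction(
                    la.GenomicInterval("c", 0, widths[i]),
                    la.GenomicInterval("c", 100000, 100000 + widths[i + 1]),
                    row_id=i // 2,
                )
            )
        return out

    def test_uniform_widths(self):
        assert la.infer_bin_size(self._loops([5000] * 6)) == 5000

    def test_mode_wins(self):
        assert la.infer_bin_size(self._loops([5000, 5000, 5000, 10000])) == 5000

    def test_tie_breaks_to_smallest(self):
        assert la.infer_bin_size(self._loops([5000, 5000, 10000, 10000])) == 5000

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            la.infer_bin_size([])


class TestExpandInterval:
    IV = la.GenomicInterval("c", 100000, 105000)

    def test_bin_expansion(self):
        out = la.expand_interval(self.IV, "bin", 1, 5000)
        assert (out.start, out.end) == (95000, 110000)

    def test_distance_expansion(self):
        out = la.expand_interval(self.IV, "distance", 2000)
        assert (out.start, out.end) == (98000, 107000)

    def test_clipped_at_zero(self):
        out = la.expand_interval(la.GenomicInterval("c", 1000, 2000), "distance", 5000)
        assert (out.start, out.end) == (0, 7000)

    def test_off_is_identity(self):
        assert la.expand_interval(self.IV, "off", 99) is self.IV

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            la.expand_interval(self.IV, "bp", 1)


class TestInteractionAnnotation:
    def test_t1_loop_assignments(self, t1):
        options = la.AnnotationOptions().resolve(t1.interactions)
        windows = la.make_promoter_windows(t1.tss, options.promoter_window)
        annos = la.annotate_by_interaction(
            t1.peaks, t1.interactions, windows, options
        )
        got = {
            (a.peak.label, a.gene_symbol, a.distance_to_tss, a.interaction_score)
            for a in annos
        }
        assert got == {("P1", "G1", -53750, 12.0), ("P3", "G2", -202150, 8.0)}

    def test_bin_expansion_recruits_neighboring_peak(self, t1):
        extra = la.GenomicInterval("chrT", 51000, 51400, name="PX")
        options = la.AnnotationOptions(
            close_peak_type="bin", close_peak_value=1
        ).resolve(t1.interactions)
        windows = la.make_promoter_windows(t1.tss, options.promoter_window)
        annos = la.annotate_by_interaction(
            list(t1.peaks) + [extra], t1.interactions, windows, options
        )
        assert ("PX", "G1") in {(a.peak.label, a.gene_symbol) for a in annos}

    def test_no_interactions_no_annotations(self, t1):
        options = la.AnnotationOptions(bin_size=5000).resolve([])
        windows = la.make_promoter_windows(t1.tss, options.promoter_window)
        assert la.annotate_by_interaction(t1.peaks, [], windows, options) == []

    def test_expansion_is_monotone(self):
        """Growing close_peak/close_promoter never removes an annotation."""
        rng = np.random.default_rng(7)
        for seed in range(10):
            spec = la.FixtureSpec(n_genes=3, n_planted_links=3,
                                  n_distractor_loops=2, seed=seed)
            fx = la.make_toy_annotation_set(spec)
            windows = la.make_promoter_windows(fx.tss, 2500)
            prev: set = set()
            for value in (0, 1, 2):
                options = la.AnnotationOptions(
                    close_peak_type="bin", close_peak_value=value,
                    close_promoter_type="bin",
                    close_promoter_value=int(rng.integers(0, 2)),
                ).resolve(fx.interactions)
                got = {
                    (a.peak.label, a.gene_symbol, a.interaction_row)
                    for a in la.annotate_by_interaction(
                        fx.peaks, fx.interactions, windows, options
                    )
                }
                assert prev <= got
                prev = got


class TestProximityAnnotation:
    def test_nearest_tss_wins(self, t1):
        annos = la.annotate_by_proximity(
            [la.GenomicInterval("chrT", 99000, 99400, name="P2")], t1.tss
        )
        (a,) = annos
        assert (a.gene_symbol, a.annotation_type, a.distance_to_tss) == (
            "G1", "proximal", -800,
        )

    def test_equidistant_tie_breaks_lexicographically(self):
        tss = [la.TssRecord("B", "c", 1000, "+"), la.TssRecord("A", "c", 3000, "+")]
        (a,) = la.annotate_by_proximity(
            [la.GenomicInterval("c", 1900, 2100)], tss
        )
        assert a.gene_symbol == "A"

    def test_peak_on_geneless_chromosome_dropped(self, t1):
        annos = la.annotate_by_proximity(
            [la.GenomicInterval("chrZ", 0, 100, name="PZ")], t1.tss
        )
        assert annos == []

    def test_empty_tss_is_an_error(self):
        with pytest.raises(ValueError):
            la.annotate_by_proximity([la.GenomicInterval("c", 0, 10)], [])


class TestCombined:
    def test_t1_final_assignment_and_unannotated(self, t1_result):
        got = {
            (a.peak.label, a.gene_symbol, a.annotation_type)
            for a in t1_result.annotations
        }
        assert got == {
            ("P1", "G1", "interaction"),
            ("P2", "G1", "proximal"),
            ("P3", "G2", "interaction"),
        }
        assert [p.label for p in t1_result.unannotated] == ["P4"]

    def test_distal_proximal_candidate_dropped_by_threshold(self, t1_result):
        # P1's closest TSS lies 53.75 kb away, far beyond 2 x bin size
        p1 = [a for a in t1_result.annotations if a.peak.label == "P1"]
        assert all(a.annotation_type == "interaction" for a in p1)
        assert all(
            a.annotation_type != "proximal"
            or abs(a.distance_to_tss) < t1_result.options.interaction_threshold
            for a in t1_result.annotations
        )

    def test_proximity_disabled_leaves_only_loops(self, t1):
        res = la.annotate_peaks(
            t1.peaks, t1.interactions, t1.tss,
            la.AnnotationOptions(proximity_enabled=False),
        )
        assert {a.annotation_type for a in res.annotations} == {"interaction"}
        assert "P2" in {p.label for p in res.unannotated}

    def test_matches_brute_force_on_t1(self, t1, t1_result):
        expected = brute_force_pairs(
            t1.peaks, t1.interactions, t1.tss, t1_result.options
        )
        assert engine_pairs(t1_result) == expected


class TestInteractionCentric:
    def test_t1_per_anchor_lists(self, t1):
        windows = la.make_promoter_windows(t1.tss, 2500)
        table = la.annotate_interaction_centric(t1.interactions, t1.peaks, windows)
        i1 = table.iloc[0]
        assert i1["anchor1_peaks"] == ["P1"] and i1["anchor2_genes"] == ["G1"]
        i3 = table.iloc[2]
        assert i3["anchor1_peaks"] == [] and i3["anchor1_genes"] == []
        assert i3["anchor2_peaks"] == ["P4"] and i3["anchor2_genes"] == []

    def test_gene_columns_populated_without_peaks(self, t1):
        windows = la.make_promoter_windows(t1.tss, 2500)
        table = la.annotate_interaction_centric(t1.interactions, [], windows)
        assert table.iloc[0]["anchor2_genes"] == ["G1"]


class TestGeneList:
    def test_sorted_unique(self, t1_result):
        assert t1_result.gene_list() == ["G1", "G2"]

    def test_empty(self):
        assert la.gene_list([]) == []

    def test_duplicates_collapse(self, t1_result):
        doubled = list(t1_result.annotations) * 5
        assert la.gene_list(doubled) == ["G1", "G2"]


class TestOutputFormats:
    def test_keep_layout_one_row_per_annotation(self, t1_result):
        frame = t1_result.to_frame()
        assert len(frame) == 3
        assert list(frame.peak_name) == ["P1", "P2", "P3"]

    def test_concat_layout_one_row_per_peak(self, t1):
        extra_loop = la.Interaction(
            la.GenomicInterval("chrT", 45000, 50000),
            la.GenomicInterval("chrT", 297500, 302500),
            row_id=3, score=1.0,
        )
        res = la.annotate_peaks(
            t1.peaks, list(t1.interactions) + [extra_loop], t1.tss
        )
        frame = res.to_concat_frame()
        assert len(frame) == len({a.peak.label for a in res.annotations})
        p1 = frame[frame.peak_name == "P1"].iloc[0]
        assert p1["gene_symbol"] == "G1,G2"
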