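"""Shared fixtures and the independent brute-force annotation oracle.

The oracle re-derives annotations by plain all-pairs enumeration with
inline arithmetic (no interval trees, no package helpers), so agreement
with the engine is a genuine two-route check.
"""

from __future__ import annotations

import numpy as np
import pytest

import loopanno as la


@pytest.fixture
def t1():
    return la.fixture_t1()


@pytest.fixture
def t1_result(t1):
    return la.annotate_peaks(t1.peaks, t1.interactions, t1.tss)


def _overlap(a_chrom, a_start, a_end, b_chrom, b_start, b_end):
    return a_chrom == b_chrom and a_start < b_end and a_end > b_start


def _pad(start, end, kind, value, bin_size):
    if kind == "off" or value == 0:
        return start, end
    pad = value if kind == "distance" else value * bin_size
    return max(0, start - pad), end + pad


def brute_force_pairs(peaks, interactions, tss, options):
    """All (peak label, gene, type, interaction row) tuples by enumeration.

    ``options`` must already be resolved (bin_size / threshold set).
    Replicates the combination rule: interaction annotations always kept;
    the closest-TSS annotation kept only below the interaction threshold
    and only when the same (peak, gene) pair is not already loop-supported.
    """
    out = set()
    pw = options.promoter_window
    for it in interactions:
        anchors = (
            (it.anchor1, it.anchor2),
            (it.anchor2, it.anchor1),
        )
        for peak_anchor, prom_anchor in anchors:
            ps, pe = _pad(peak_anchor.start, peak_anchor.end,
                          options.close_peak_type, options.close_peak_value,
                          options.bin_size)
            qs, qe = _pad(prom_anchor.start, prom_anchor.end,
                          options.close_promoter_type, options.close_promoter_value,
                          options.bin_size)
            for p in peaks:
                if not _overlap(p.chrom, p.start, p.end, peak_anchor.chrom, ps, pe):
                    continue
                for t in tss:
                    ws, we = max(0, t.tss - pw), t.tss + pw
                    if _overlap(t.chrom, ws, we, prom_anchor.chrom, qs, qe):
                        out.add((p.label, t.gene_symbol, "interaction", it.row_id))
    if options.proximity_enabled and tss:
        loop_pairs = {(label, gene) for label, gene, _, _ in out}
        for p in peaks:
            mid = (p.start + p.end) // 2
            candidates = [
                (abs(mid - t.tss), t.gene_symbol) for t in tss if t.chrom == p.chrom
            ]
            if not candidates:
                continue
            dist, gene = min(candidates)
            if dist < options.interaction_threshold and (p.label, gene) not in loop_pairs:
                out.add((p.label, gene, "proximal", None))
    return out


def engine_pairs(result):
    return {
        (a.peak.label, a.gene_symbol, a.annotation_type,
         a.interaction_row if a.annotation_type == "interaction" else None)
        for a in result.annotations
    }


def random_instance(rng: np.random.Generator):
    """An arbitrary (unstructured) annotation problem for oracle checks."""
    chroms = ["c1", "c2"]
    length = 500_000
    n_genes = int(rng.integers(2, 21))
    n_peaks = int(rng.integers(1, 51))
    n_loops = int(rng.integers(1, 51))
    tss = [
        la.TssRecord(
            f"g{i}",
            chroms[int(rng.integers(2))],
            int(rng.integers(0, length)),
            "+" if rng.integers(2) == 0 else "-",
        )
        for i in range(n_genes)
    ]
    peaks = []
    for i in range(n_peaks):
        start = int(rng.integers(0, length - 2000))
        peaks.append(
            la.GenomicInterval(
                chroms[int(rng.integers(2))], start,
                start + int(rng.integers(100, 2000)), name=f"p{i}",
            )
        )
    loops = []
    for i in range(n_loops):
        anchor = []
        for _ in range(2):
            s = int(rng.integers(0, length - 8000))
            anchor.append(
                la.GenomicInterval(
                    chroms[int(rng.integers(2))], s, s + int(rng.integers(1000, 8000))
                )
            )
        loops.append(la.Interaction(anchor[0], anchor[1], row_id=i,
                                    score=float(rng.uniform(0, 10))))
    kinds = ["off", "distance", "bin"]
    options = la.AnnotationOptions(
        promoter_window=int(rng.integers(500, 5001)),
        bin_size=5000,
        interaction_threshold=int(rng.integers(0, 20_001)),
        close_peak_type=kinds[int(rng.integers(3))],
        close_peak_value=int(rng.integers(0, 3)),
        close_promoter_type=kinds[int(rng.integers(3))],
        close_promoter_value=int(rng.integers(0, 3)),
        proximity_enabled=bool(rng.integers(2)),
    )
    return peaks, loops, tss, options
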