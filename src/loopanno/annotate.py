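"""Interaction-based annotation of genomic regions to target genes.

The core rule: a peak overlapping one anchor of a chromatin interaction is
assigned to a gene whose promoter window (default TSS +/- 2,500 bp) overlaps
the *other* anchor. Because loop callers report anchors as fixed-width bins,
peaks closer to a TSS than the interaction threshold (default 2 x bin size)
cannot be resolved by loops; for those, closest-TSS proximity annotation is
applied in addition to any interaction-based annotations.

Anchors may optionally be expanded to admit neighboring bins, either by a
distance in bp or by a number of bins (``close_peak`` / ``close_promoter``
options), which loosens the bin-resolution constraint of the loop caller.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .intervals import (
    GenomicInterval,
    Interaction,
    IntervalIndex,
    TssRecord,
    signed_distance,
)

logger = logging.getLogger(__name__)

EXPAND_TYPES = ("off", "distance", "bin")


@dataclass
class AnnotationOptions:
    """Tunable parameters of the annotation engine.

    promoter_window
        Half-width in bp of the promoter interval around each TSS.
    bin_size
        Anchor bin width in bp; inferred from the interactions when None.
    interaction_threshold
        Distance in bp below which proximity annotation supplements the
        interaction-based annotation; defaults to ``2 * bin_size``.
    close_peak_type / close_peak_value
        Anchor expansion on the peak side: "off", "distance" (bp) or "bin"
        (bin count).
    close_promoter_type / close_promoter_value
        Same, on the promoter side.
    multiple_anno
        "concat" writes one output row per peak with comma-joined genes;
        "keep" writes one row per annotation.
    proximity_enabled
        When False, no proximal annotations are produced at all.
    """

    promoter_window: int = 2500
    bin_size: Optional[int] = None
    interaction_threshold: Optional[int] = None
    close_peak_type: str = "off"
    close_peak_value: int = 0
    close_promoter_type: str = "off"
    close_promoter_value: int = 0
    multiple_anno: str = "concat"
    proximity_enabled: bool = True

    def __post_init__(self) -> None:
        if self.promoter_window <= 0:
            raise ValueError("promoter_window must be > 0")
        if self.interaction_threshold is not None and self.interaction_threshold < 0:
            raise ValueError("interaction_threshold must be >= 0")
        for name in ("close_peak_type", "close_promoter_type"):
            if getattr(self, name) not in EXPAND_TYPES:
                raise ValueError(f"{name} must be one of {EXPAND_TYPES}")
        if self.close_peak_value < 0 or self.close_promoter_value < 0:
            raise ValueError("close_*_value must be >= 0")
        if self.multiple_anno not in ("concat", "keep"):
            raise ValueError("multiple_anno must be 'concat' or 'keep'")

    def resolve(self, interactions: Sequence[Interaction]) -> "AnnotationOptions":
        """Return a copy with bin_size and interaction_threshold filled in."""
        bin_size = self.bin_size
        needs_bin = bin_size is None and (
            self.interaction_threshold is None
            or self.close_peak_type == "bin"
            or self.close_promoter_type == "bin"
        )
        if needs_bin:
            if not interactions:
                raise ValueError(
                    "bin_size is required (cannot be inferred without interactions)"
                )
            bin_size = infer_bin_size(interactions)
        threshold = self.interaction_threshold
        if threshold is None:
            threshold = 2 * bin_size
        return replace(self, bin_size=bin_size, interaction_threshold=threshold)


@dataclass(frozen=True)
class PromoterWindow:
    """Promoter interval of one gene: TSS +/- window, clipped at 0."""

    gene: TssRecord
    window: GenomicInterval


@dataclass(frozen=True)
class Annotation:
    """One (peak, gene) assignment.

    ``annotation_type`` is "interaction" (via a loop) or "proximal"
    (closest TSS). Interaction annotations carry the supporting bedpe row id
    and its score; proximal annotations carry neither. ``distance_to_tss``
    is the strand-aware signed midpoint distance (None for trans
    peak/gene pairs). ``method`` tags alternative proximity schemes (e.g.
    regulatory-domain annotation).
    """

    peak: GenomicInterval
    gene_symbol: str
    annotation_type: str
    distance_to_tss: Optional[int] = None
    entrez_id: Optional[str] = None
    interaction_score: Optional[float] = None
    interaction_row: Optional[int] = None
    method: Optional[str] = None

    def __post_init__(self) -> None:
        if self.annotation_type == "interaction" and self.interaction_row is None:
            raise ValueError("interaction annotation requires interaction_row")
        if self.annotation_type == "proximal" and self.interaction_score is not None:
            raise ValueError("proximal annotation cannot carry an interaction score")


def make_promoter_windows(
    tss: Iterable[TssRecord], window: int
) -> list[PromoterWindow]:
    """Build strand-independent promoter windows ``[tss-window, tss+window)``.

    Windows are clipped at the chromosome start; genes sharing a TSS each get
    their own (identical) window.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    out = []
    for t in tss:
        start = max(0, t.tss - window)
        out.append(
            PromoterWindow(
                gene=t,
                window=GenomicInterval(t.chrom, start, t.tss + window, name=t.gene_symbol),
            )
        )
    return out


def infer_bin_size(interactions: Sequence[Interaction]) -> int:
    """Modal anchor width over both anchors; ties go to the smallest width."""
    if not interactions:
        raise ValueError("cannot infer bin size from an empty interaction list")
    widths = Counter()
    for it in interactions:
        widths[it.anchor1.width] += 1
        widths[it.anchor2.width] += 1
    best = max(widths.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    logger.info("inferred bin size %d bp from %d anchors", best, 2 * len(interactions))
    return best


def expand_interval(
    iv: GenomicInterval, type: str, value: int, bin_size: Optional[int] = None
) -> GenomicInterval:
    """Pad an interval to admit neighboring bins; clipped at 0.

    ``type`` "off" returns the interval unchanged, "distance" pads by
    ``value`` bp on both sides, "bin" pads by ``value * bin_size``.
    """
    if type == "off" or value == 0:
        return iv
    if type == "distance":
        pad = value
    elif type == "bin":
        if bin_size is None:
            raise ValueError("bin expansion requires bin_size")
        pad = value * bin_size
    else:
        raise ValueError(f"unknown expansion type {type!r}")
    return GenomicInterval(
        iv.chrom, max(0, iv.start - pad), iv.end + pad, name=iv.name,
        score=iv.score, strand=iv.strand,
    )


def _peak_key(peak: GenomicInterval):
    return (peak.chrom, peak.start, peak.end, peak.label)


def annotate_by_interaction(
    peaks: Sequence[GenomicInterval],
    interactions: Sequence[Interaction],
    promoter_windows: Sequence[PromoterWindow],
    options: AnnotationOptions,
) -> list[Annotation]:
    """Assign peaks to genes through interaction anchors.

    For every interaction, both anchor orientations are tested: peaks
    overlapping one (optionally expanded) anchor are linked to genes whose
    promoter window overlaps the other (optionally expanded) anchor.
    Duplicate (peak, gene, interaction) triples collapse to one annotation.
    """
    options = options.resolve(interactions)
    peak_index = IntervalIndex(peaks)
    window_index = IntervalIndex(w.window for w in promoter_windows)
    gene_by_window: dict[tuple, list[TssRecord]] = {}
    for w in promoter_windows:
        gene_by_window.setdefault(
            (w.window.chrom, w.window.start, w.window.end), []
        ).append(w.gene)

    seen: set[tuple] = set()
    out: list[Annotation] = []
    for it in interactions:
        for peak_anchor, prom_anchor in ((it.anchor1, it.anchor2), (it.anchor2, it.anchor1)):
            pa = expand_interval(
                peak_anchor, options.close_peak_type, options.close_peak_value,
                options.bin_size,
            )
            qa = expand_interval(
                prom_anchor, options.close_promoter_type, options.close_promoter_value,
                options.bin_size,
            )
            hit_peaks = peak_index.query(pa)
            if not hit_peaks:
                continue
            genes: list[TssRecord] = []
            for win in window_index.query(qa):
                genes.extend(gene_by_window[(win.chrom, win.start, win.end)])
            for peak in hit_peaks:
                for gene in genes:
                    key = (_peak_key(peak), gene.gene_symbol, it.row_id)
                    if key in seen:
                        continue
                    seen.add(key)
                    dist = (
                        signed_distance(peak, gene)
                        if peak.chrom == gene.chrom
                        else None
                    )
                    out.append(
                        Annotation(
                            peak=peak,
                            gene_symbol=gene.gene_symbol,
                            entrez_id=gene.entrez_id,
                            annotation_type="interaction",
                            distance_to_tss=dist,
                            interaction_score=it.score,
                            interaction_row=it.row_id,
                        )
                    )
    out.sort(key=_annotation_sort_key)
    return out


def annotate_by_proximity(
    peaks: Sequence[GenomicInterval], tss: Sequence[TssRecord]
) -> list[Annotation]:
    """Closest-TSS annotation: each peak gets exactly one gene.

    Ties on |distance| break toward the lexicographically smaller gene
    symbol. Peaks on chromosomes without any TSS are left out (logged).
    """
    if not tss:
        raise ValueError("proximity annotation requires a non-empty TSS table")
    by_chrom: dict[str, list[TssRecord]] = {}
    for t in tss:
        by_chrom.setdefault(t.chrom, []).append(t)
    out: list[Annotation] = []
    for peak in peaks:
        candidates = by_chrom.get(peak.chrom)
        if not candidates:
            logger.info("peak %s has no TSS on its chromosome", peak.label)
            continue
        best = min(
            candidates,
            key=lambda t: (abs(signed_distance(peak, t)), t.gene_symbol),
        )
        out.append(
            Annotation(
                peak=peak,
                gene_symbol=best.gene_symbol,
                entrez_id=best.entrez_id,
                annotation_type="proximal",
                distance_to_tss=signed_distance(peak, best),
            )
        )
    out.sort(key=_annotation_sort_key)
    return out


def combine_annotations(
    interaction_annos: Sequence[Annotation],
    proximity_annos: Sequence[Annotation],
    options: AnnotationOptions,
    peaks: Sequence[GenomicInterval],
) -> tuple[list[Annotation], list[GenomicInterval]]:
    """Merge interaction and proximal annotations under the threshold rule.

    All interaction annotations are kept. A proximal annotation survives only
    when |distance| < interaction_threshold (and proximity is enabled), and is
    dropped when the same (peak, gene) already has an interaction annotation.
    Returns ``(annotations, unannotated_peaks)``.
    """
    if options.interaction_threshold is None:
        raise ValueError("options must be resolved (interaction_threshold set)")
    kept = list(interaction_annos)
    have_pair = {(_peak_key(a.peak), a.gene_symbol) for a in interaction_annos}
    if options.proximity_enabled:
        for a in proximity_annos:
            if a.distance_to_tss is None:
                continue
            if abs(a.distance_to_tss) >= options.interaction_threshold:
                continue
            if (_peak_key(a.peak), a.gene_symbol) in have_pair:
                continue
            kept.append(a)
    kept.sort(key=_annotation_sort_key)
    annotated = {_peak_key(a.peak) for a in kept}
    unannotated = sorted(
        (p for p in peaks if _peak_key(p) not in annotated),
        key=lambda p: p.sort_key(),
    )
    return kept, unannotated


def _annotation_sort_key(a: Annotation):
    return (_peak_key(a.peak), a.annotation_type, a.gene_symbol,
            a.interaction_row if a.interaction_row is not None else -1)


def annotate_interaction_centric(
    interactions: Sequence[Interaction],
    peaks: Sequence[GenomicInterval],
    promoter_windows: Sequence[PromoterWindow],
) -> pd.DataFrame:
    """One row per interaction, listing peaks and genes at each anchor."""
    peak_index = IntervalIndex(peaks)
    window_index = IntervalIndex(w.window for w in promoter_windows)
    gene_by_window: dict[tuple, list[str]] = {}
    for w in promoter_windows:
        gene_by_window.setdefault(
            (w.window.chrom, w.window.start, w.window.end), []
        ).append(w.gene.gene_symbol)

    rows = []
    for it in interactions:
        row: dict = {"row_id": it.row_id, "score": it.score}
        for i, anchor in ((1, it.anchor1), (2, it.anchor2)):
            row[f"anchor{i}"] = f"{anchor.chrom}:{anchor.start}-{anchor.end}"
            row[f"anchor{i}_peaks"] = sorted(
                {p.label for p in peak_index.query(anchor)}
            )
            genes: set[str] = set()
            for win in window_index.query(anchor):
                genes.update(gene_by_window[(win.chrom, win.start, win.end)])
            row[f"anchor{i}_genes"] = sorted(genes)
        rows.append(row)
    cols = ["row_id", "anchor1", "anchor2", "anchor1_peaks", "anchor1_genes",
            "anchor2_peaks", "anchor2_genes", "score"]
    return pd.DataFrame(rows, columns=cols)


def gene_list(annotations: Iterable[Annotation]) -> list[str]:
    """Sorted unique gene symbols across annotations."""
    return sorted({a.gene_symbol for a in annotations})


@dataclass
class AnnotationResult:
    """Annotations plus unannotated peaks from one engine run."""

    annotations: list[Annotation]
    unannotated: list[GenomicInterval]
    options: AnnotationOptions
    peaks: list[GenomicInterval] = field(default_factory=list)

    def gene_list(self) -> list[str]:
        return gene_list(self.annotations)

    def to_frame(self) -> pd.DataFrame:
        """One row per annotation (the ``multiple_anno keep`` layout)."""
        rows = []
        for a in self.annotations:
            rows.append(
                {
                    "peak_chrom": a.peak.chrom,
                    "peak_start": a.peak.start,
                    "peak_end": a.peak.end,
                    "peak_name": a.peak.label,
                    "gene_symbol": a.gene_symbol,
                    "entrez_id": a.entrez_id if a.entrez_id is not None else "",
                    "distance_to_tss": a.distance_to_tss,
                    "annotation_type": a.annotation_type,
                    "interaction_score": a.interaction_score,
                    "interaction_row": a.interaction_row,
                }
            )
        frame = pd.DataFrame(
            rows,
            columns=[
                "peak_chrom", "peak_start", "peak_end", "peak_name",
                "gene_symbol", "entrez_id", "distance_to_tss",
                "annotation_type", "interaction_score", "interaction_row",
            ],
        )
        for col in ("distance_to_tss", "interaction_row"):
            frame[col] = frame[col].astype("Int64")
        return frame

    def to_concat_frame(self) -> pd.DataFrame:
        """One row per peak, annotation fields comma-joined."""
        keep = self.to_frame()
        if keep.empty:
            return pd.DataFrame(
                columns=[
                    "peak_chrom", "peak_start", "peak_end", "peak_name",
                    "gene_symbol", "entrez_id", "distance_to_tss",
                    "annotation_type", "interaction_score", "interaction_row",
                ]
            )

        def _join(series):
            return ",".join("" if pd.isna(v) else str(v) for v in series)

        grouped = keep.groupby(
            ["peak_chrom", "peak_start", "peak_end", "peak_name"], sort=True
        ).agg(
            {
                "gene_symbol": _join,
                "entrez_id": _join,
                "distance_to_tss": _join,
                "annotation_type": _join,
                "interaction_score": _join,
                "interaction_row": _join,
            }
        )
        return grouped.reset_index()

    def write(self, path) -> None:
        frame = (
            self.to_concat_frame()
            if self.options.multiple_anno == "concat"
            else self.to_frame()
        )
        frame.to_csv(path, sep="\t", index=False)


def annotate_peaks(
    peaks: Sequence[GenomicInterval],
    interactions: Sequence[Interaction],
    tss: Sequence[TssRecord],
    options: Optional[AnnotationOptions] = None,
) -> AnnotationResult:
    """Run the full pipeline: promoter windows -> interaction annotation ->
    proximity fallback -> combined output."""
    options = (options or AnnotationOptions()).resolve(interactions)
    windows = make_promoter_windows(tss, options.promoter_window)
    via_loops = annotate_by_interaction(peaks, interactions, windows, options)
    via_proximity = (
        annotate_by_proximity(peaks, tss) if options.proximity_enabled and tss else []
    )
    combined, unannotated = combine_annotations(
        via_loops, via_proximity, options, peaks
    )
    return AnnotationResult(
        annotations=combined,
        unannotated=unannotated,
        options=options,
        peaks=sorted(peaks, key=lambda p: p.sort_key()),
    )
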