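"""Evaluation against functionally validated enhancer-gene pairs.

Pooled CRISPR-interference screens (CRISPRi-FlowFISH style) yield tested
(element, gene) pairs with an FDR; pairs with FDR < 0.05 are the functional
truth set. An annotation method "identifies" a truth pair when it assigns
any peak overlapping the element (>= 1 bp) to that gene. Recall is reported
per TSS-distance bin, distal detection per gene (>= 1 identified functional
enhancer beyond a minimum distance), and precision as the fraction of
annotated-and-tested elements that were functional, averaged per gene and
then across genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .annotate import Annotation
from .intervals import GenomicInterval, Interaction, IntervalIndex, TssRecord, signed_distance

logger = logging.getLogger(__name__)

SIGNIFICANCE_FDR = 0.05

#: distance bin edges mirroring the ranges discussed for enhancer recall
DEFAULT_BIN_EDGES = (0, 10_000, 25_000, 50_000, math.inf)


@dataclass(frozen=True)
class EnhancerGenePair:
    """A tested (element, gene) pair from a functional screen."""

    element: GenomicInterval
    gene_symbol: str
    distance: int
    fdr: float
    significant: bool
    effect: Optional[float] = None

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError("fdr must be in [0, 1]")


def read_pairs(path) -> pd.DataFrame:
    """Read a tested-pair TSV: elem_chrom, elem_start, elem_end, gene_symbol,
    fdr and optional effect."""
    df = pd.read_csv(path, sep="\t")
    for col in ("elem_chrom", "elem_start", "elem_end", "gene_symbol", "fdr"):
        if col not in df.columns:
            raise ValueError(f"pair table missing required column {col!r}")
    return df


def filter_pairs(
    pairs: pd.DataFrame,
    tss: Sequence[TssRecord],
    gene_bodies: Optional[Sequence[GenomicInterval]] = None,
    max_distance: int = 3_000_000,
    promoter_window: int = 2500,
) -> list[EnhancerGenePair]:
    """Apply the screen-side filters and set the significance flag.

    Pairs farther than ``max_distance`` from the target TSS are removed, as
    are elements overlapping any promoter window or gene-body interval.
    Pairs whose gene is absent from the TSS table are dropped with a
    warning. ``significant`` is FDR < 0.05.
    """
    tss_by_gene: dict[str, list[TssRecord]] = {}
    for t in tss:
        tss_by_gene.setdefault(t.gene_symbol, []).append(t)
    from .annotate import make_promoter_windows

    window_index = IntervalIndex(
        w.window for w in make_promoter_windows(tss, promoter_window)
    )
    body_index = IntervalIndex(gene_bodies or ())
    out: list[EnhancerGenePair] = []
    for row in pairs.itertuples(index=False):
        candidates = tss_by_gene.get(str(row.gene_symbol))
        if not candidates:
            logger.warning("gene %s absent from TSS table; pair dropped", row.gene_symbol)
            continue
        element = GenomicInterval(
            str(row.elem_chrom), int(row.elem_start), int(row.elem_end),
            name=getattr(row, "elem_name", None),
        )
        dists = [
            abs(signed_distance(element, t))
            for t in candidates
            if t.chrom == element.chrom
        ]
        if not dists:
            logger.warning("gene %s on another chromosome; pair dropped", row.gene_symbol)
            continue
        distance = min(dists)
        if distance > max_distance:
            continue
        if window_index.any_overlap(element) or body_index.any_overlap(element):
            continue
        fdr = float(row.fdr)
        effect = getattr(row, "effect", None)
        out.append(
            EnhancerGenePair(
                element=element,
                gene_symbol=str(row.gene_symbol),
                distance=distance,
                fdr=fdr,
                significant=fdr < SIGNIFICANCE_FDR,
                effect=None if effect is None or pd.isna(effect) else float(effect),
            )
        )
    return out


def _bin_label(lo: float, hi: float) -> str:
    hi_txt = "inf" if math.isinf(hi) else str(int(hi))
    return f"[{int(lo)},{hi_txt})"


def _bins(bin_edges: Sequence[float]) -> list[tuple[float, float]]:
    edges = list(bin_edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin_edges must be strictly increasing with >= 2 edges")
    return list(zip(edges[:-1], edges[1:]))


def _identified(pair: EnhancerGenePair, anno_index: dict[str, IntervalIndex]) -> bool:
    idx = anno_index.get(pair.gene_symbol)
    return idx is not None and idx.any_overlap(pair.element)


def _annotation_index(annotations: Sequence[Annotation]) -> dict[str, IntervalIndex]:
    by_gene: dict[str, IntervalIndex] = {}
    for a in annotations:
        by_gene.setdefault(a.gene_symbol, IntervalIndex()).add(a.peak)
    return by_gene


def recall_by_distance(
    annotations: Sequence[Annotation],
    truth: Sequence[EnhancerGenePair],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> dict[str, float]:
    """Fraction of functional truth pairs identified, per distance bin.

    Bins with no truth pair report NaN.
    """
    anno_index = _annotation_index(annotations)
    out: dict[str, float] = {}
    for lo, hi in _bins(bin_edges):
        members = [p for p in truth if p.significant and lo <= p.distance < hi]
        label = _bin_label(lo, hi)
        if not members:
            out[label] = math.nan
        else:
            hits = sum(_identified(p, anno_index) for p in members)
            out[label] = hits / len(members)
    return out


def per_gene_distal_detection(
    annotations: Sequence[Annotation],
    truth: Sequence[EnhancerGenePair],
    min_distance: int = 10_000,
) -> tuple[int, int, pd.DataFrame]:
    """Genes with >= 1 identified functional distal enhancer.

    Only genes with at least one significant truth pair beyond
    ``min_distance`` are counted; a gene is a hit when at least one such
    pair is identified. Returns (hit count, gene count, per-gene table).
    """
    anno_index = _annotation_index(annotations)
    qualifying: dict[str, list[EnhancerGenePair]] = {}
    for p in truth:
        if p.significant and p.distance > min_distance:
            qualifying.setdefault(p.gene_symbol, []).append(p)
    rows = []
    hits = 0
    for gene in sorted(qualifying):
        hit = any(_identified(p, anno_index) for p in qualifying[gene])
        hits += hit
        rows.append({"gene_symbol": gene, "n_distal_truth": len(qualifying[gene]),
                     "detected": bool(hit)})
    table = pd.DataFrame(rows, columns=["gene_symbol", "n_distal_truth", "detected"])
    return hits, len(qualifying), table


def precision_by_distance(
    annotations: Sequence[Annotation],
    tested_elements: Sequence[EnhancerGenePair],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> dict[str, dict[str, float]]:
    """Fraction of annotated-and-tested elements that were functional.

    For each distance bin: per gene, the fraction of that gene's tested
    pairs which the method annotated AND which were significant, over all
    annotated tested pairs; the per-gene fractions are then averaged across
    genes ("mean" key). A pooled fraction over all matched pairs is also
    reported ("pooled" key). Bins without any annotated tested pair give
    NaN.
    """
    anno_index = _annotation_index(annotations)
    out: dict[str, dict[str, float]] = {}
    for lo, hi in _bins(bin_edges):
        per_gene: dict[str, list[bool]] = {}
        for p in tested_elements:
            if not (lo <= p.distance < hi):
                continue
            if _identified(p, anno_index):
                per_gene.setdefault(p.gene_symbol, []).append(p.significant)
        label = _bin_label(lo, hi)
        if not per_gene:
            out[label] = {"mean": math.nan, "pooled": math.nan, "n_genes": 0}
            continue
        fractions = [sum(v) / len(v) for v in per_gene.values()]
        pooled_hits = sum(sum(v) for v in per_gene.values())
        pooled_n = sum(len(v) for v in per_gene.values())
        out[label] = {
            "mean": sum(fractions) / len(fractions),
            "pooled": pooled_hits / pooled_n,
            "n_genes": len(per_gene),
        }
    return out


def filter_top_interactions(
    interactions: Sequence[Interaction],
    fraction: float,
    higher_is_better: bool = True,
) -> list[Interaction]:
    """Keep the top ``floor(fraction * n)`` interactions by score (min 1).

    ``higher_is_better=False`` ranks ascending (q-value style). Ties break
    by the stable input ``row_id``. Missing scores are an error.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if any(it.score is None for it in interactions):
        raise ValueError("all interactions must carry a score for ranking")
    n_keep = max(1, math.floor(fraction * len(interactions))) if interactions else 0
    ranked = sorted(
        interactions,
        key=lambda it: (-it.score if higher_is_better else it.score, it.row_id),
    )
    kept = ranked[:n_keep]
    kept.sort(key=lambda it: it.row_id)
    return kept
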