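"""Multi-dataset co-occupancy analysis and differential-mode integration.

Overlaps between peak sets (e.g. ChIP-seq of several transcription factors)
are summarized either over fixed genomic bins or over a consensus region set,
split into promoter-resident and distal regions. Link tables for circular
(Circos-style) plots, activating/repressive classification against gene
expression changes, and Cytoscape xGMML network export live here; the
bit-exact deliverables are the tables, plotting is left to the caller.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .annotate import Annotation, PromoterWindow
from .intervals import ExpressionRecord, GenomicInterval, IntervalIndex

XGMML_NS = "http://www.cs.rpi.edu/XGMML"


def consensus_regions(bed_sets: Sequence[Sequence[GenomicInterval]]) -> list[GenomicInterval]:
    """Union of all input intervals with overlapping (>=1 bp) runs merged.

    Bookended intervals are kept separate. Output is sorted by coordinate.
    """
    if not bed_sets:
        raise ValueError("need at least one region set")
    ivs = sorted(
        (iv for s in bed_sets for iv in s), key=lambda iv: (iv.chrom, iv.start, iv.end)
    )
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


@dataclass
class OverlapMatrix:
    """Boolean region x dataset membership table.

    ``membership`` is indexed by region label with one boolean column per
    dataset; every retained region overlaps at least one dataset.
    """

    regions: list[GenomicInterval]
    dataset_names: list[str]
    membership: pd.DataFrame
    mode: str


def compute_overlap_matrix(
    bed_sets: Sequence[Sequence[GenomicInterval]],
    dataset_names: Sequence[str],
    mode: str = "regions",
    bin_size: Optional[int] = None,
    regions: Optional[Sequence[GenomicInterval]] = None,
) -> OverlapMatrix:
    """Membership of each dataset in genomic bins or consensus regions.

    ``mode="bin"`` tiles each chromosome from coordinate 0 in ``bin_size``
    windows (bins past the last covered coordinate are never occupied and
    are dropped); ``mode="regions"`` uses ``regions`` or, by default, the
    consensus of the inputs. Regions with no member are dropped.
    """
    if len(set(dataset_names)) != len(dataset_names):
        raise ValueError("dataset names must be unique")
    if len(dataset_names) != len(bed_sets):
        raise ValueError("one name per bed set required")
    if mode == "bin":
        if bin_size is None:
            raise ValueError("bin mode requires bin_size")
        extents: dict[str, int] = {}
        for s in bed_sets:
            for iv in s:
                extents[iv.chrom] = max(extents.get(iv.chrom, 0), iv.end)
        probe_regions = [
            GenomicInterval(chrom, start, min(start + bin_size, extents[chrom]))
            for chrom in sorted(extents)
            for start in range(0, extents[chrom], bin_size)
        ]
    elif mode == "regions":
        probe_regions = list(regions) if regions is not None else consensus_regions(bed_sets)
        probe_regions = sorted(probe_regions, key=lambda iv: iv.sort_key())
    else:
        raise ValueError(f"unknown mode {mode!r}")

    indexes = [IntervalIndex(s) for s in bed_sets]
    kept_regions: list[GenomicInterval] = []
    rows = []
    for region in probe_regions:
        member = [idx.any_overlap(region) for idx in indexes]
        if any(member):
            kept_regions.append(region)
            rows.append(member)
    membership = pd.DataFrame(
        rows, index=[r.label for r in kept_regions], columns=list(dataset_names),
        dtype=bool,
    )
    return OverlapMatrix(
        regions=kept_regions,
        dataset_names=list(dataset_names),
        membership=membership,
        mode=mode,
    )


def upset_counts(
    matrix: OverlapMatrix, promoter_windows: Sequence[PromoterWindow] = ()
) -> pd.DataFrame:
    """Dataset-combination counts, split into promoter and distal regions.

    A region is "promoter" when it overlaps any promoter window, else
    "distal". Combinations are encoded as the sorted member names joined
    with ``&``. The counts over all rows sum to the number of retained
    regions.
    """
    window_index = IntervalIndex(w.window for w in promoter_windows)
    counts: dict[tuple[str, str], int] = {}
    for region, (_, member) in zip(matrix.regions, matrix.membership.iterrows()):
        combo = "&".join(sorted(n for n in matrix.dataset_names if member[n]))
        klass = "promoter" if window_index.any_overlap(region) else "distal"
        counts[(combo, klass)] = counts.get((combo, klass), 0) + 1
    rows = [
        {"combination": combo, "region_class": klass, "count": n}
        for (combo, klass), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["combination", "region_class", "count"])


@dataclass(frozen=True)
class CircosLink:
    """One (dataset, distal region, gene) link with its support count."""

    dataset: str
    distal_region: GenomicInterval
    promoter_gene: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")


def circos_links(
    per_dataset_annotations: Mapping[str, Sequence[Annotation]],
    promoter_windows: Sequence[PromoterWindow] = (),
    use_promoters: bool = False,
    skip_promoter_promoter: bool = False,
    gene_filter: Optional[Iterable[str]] = None,
) -> list[CircosLink]:
    """Region-to-gene link table from interaction-type annotations.

    By default only distal regions (not overlapping any promoter window)
    produce links; ``use_promoters`` admits promoter-resident regions too.
    ``skip_promoter_promoter`` drops links from a region that lies inside
    the promoter window of its own target gene. ``gene_filter`` restricts
    to the listed genes. Output order is independent of dataset input order.
    """
    window_index = IntervalIndex(w.window for w in promoter_windows)
    own_window = {w.gene.gene_symbol: w.window for w in promoter_windows}
    wanted = set(gene_filter) if gene_filter is not None else None
    tallies: dict[tuple, int] = {}
    region_by_key: dict[tuple, GenomicInterval] = {}
    for dataset in sorted(per_dataset_annotations):
        for a in per_dataset_annotations[dataset]:
            if a.annotation_type != "interaction":
                continue
            if wanted is not None and a.gene_symbol not in wanted:
                continue
            in_promoter = window_index.any_overlap(a.peak)
            if in_promoter and not use_promoters:
                continue
            if skip_promoter_promoter:
                win = own_window.get(a.gene_symbol)
                if win is not None and a.peak.overlaps(win):
                    continue
            key = (dataset, a.peak.chrom, a.peak.start, a.peak.end, a.peak.label,
                   a.gene_symbol)
            tallies[key] = tallies.get(key, 0) + 1
            region_by_key[key] = a.peak
    return [
        CircosLink(
            dataset=key[0],
            distal_region=region_by_key[key],
            promoter_gene=key[5],
            count=n,
        )
        for key, n in sorted(tallies.items())
    ]


def circos_links_frame(links: Sequence[CircosLink]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "dataset": [l.dataset for l in links],
            "region_chrom": [l.distal_region.chrom for l in links],
            "region_start": [l.distal_region.start for l in links],
            "region_end": [l.distal_region.end for l in links],
            "gene_symbol": [l.promoter_gene for l in links],
            "count": [l.count for l in links],
        }
    )


@dataclass
class DifferentialOptions:
    """Significance thresholds for calling a gene differentially expressed."""

    padj_threshold: float = 0.05
    log2fc_threshold: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.padj_threshold <= 1.0):
            raise ValueError("padj_threshold must be in (0, 1]")


def classify_differential(
    annotations: Sequence[Annotation],
    peak_change: Mapping[str, float],
    expression: Sequence[ExpressionRecord],
    opts: Optional[DifferentialOptions] = None,
) -> pd.DataFrame:
    """Label annotations activating / repressive / unresolved.

    An annotation is resolvable when its gene is significantly
    differentially expressed (padj < threshold and |log2FC| > threshold)
    and the peak has a nonzero signed occupancy change: sign concordance
    of peak change and expression change means activating, discordance
    repressive; everything else is unresolved. The three categories
    partition the input.
    """
    opts = opts or DifferentialOptions()
    expr = {e.gene_symbol: e for e in expression}
    rows = []
    for a in annotations:
        e = expr.get(a.gene_symbol)
        change = peak_change.get(a.peak.label)
        category = "unresolved"
        log2fc = padj = None
        if e is not None:
            log2fc, padj = e.log2fc, e.padj
            if (
                change is not None
                and change != 0
                and e.padj < opts.padj_threshold
                and abs(e.log2fc) > opts.log2fc_threshold
            ):
                concordant = (change > 0) == (e.log2fc > 0)
                category = "activating" if concordant else "repressive"
        rows.append(
            {
                "peak_name": a.peak.label,
                "gene_symbol": a.gene_symbol,
                "annotation_type": a.annotation_type,
                "peak_change": change,
                "log2fc": log2fc,
                "padj": padj,
                "category": category,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["peak_name", "gene_symbol", "annotation_type", "peak_change",
                 "log2fc", "padj", "category"],
    )


def export_network(annotations: Sequence[Annotation], path) -> None:
    """Write a Cytoscape-loadable xGMML graph of peaks and genes.

    Nodes are the distinct peaks and genes (typed via a ``type`` attribute);
    each annotation becomes an edge weighted by its interaction score when
    present, else 1.
    """
    graph = ET.Element("graph", {"label": "annotations", "xmlns": XGMML_NS,
                                 "directed": "1"})
    nodes: dict[str, str] = {}
    for a in annotations:
        nodes.setdefault(f"peak:{a.peak.label}", "peak")
        nodes.setdefault(f"gene:{a.gene_symbol}", "gene")
    for node_id in sorted(nodes):
        node = ET.SubElement(graph, "node", {"id": node_id,
                                             "label": node_id.split(":", 1)[1]})
        ET.SubElement(node, "att", {"name": "type", "value": nodes[node_id],
                                    "type": "string"})
    for a in sorted(annotations, key=lambda a: (a.peak.label, a.gene_symbol,
                                                a.interaction_row or -1)):
        weight = a.interaction_score if a.interaction_score is not None else 1.0
        edge = ET.SubElement(
            graph, "edge",
            {"source": f"peak:{a.peak.label}", "target": f"gene:{a.gene_symbol}",
             "label": f"{a.peak.label}-{a.gene_symbol}"},
        )
        ET.SubElement(edge, "att", {"name": "weight", "value": repr(float(weight)),
                                    "type": "real"})
    tree = ET.ElementTree(graph)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")


def load_network(path) -> tuple[set[tuple[str, str]], list[tuple[str, str, float]]]:
    """Parse an exported xGMML file back into (nodes, edges)."""
    root = ET.parse(path).getroot()
    ns = {"x": XGMML_NS}
    nodes = set()
    for node in root.findall("x:node", ns):
        att = node.find("x:att", ns)
        nodes.add((node.get("id"), att.get("value")))
    edges = []
    for edge in root.findall("x:edge", ns):
        att = edge.find("x:att", ns)
        edges.append((edge.get("source"), edge.get("target"), float(att.get("value"))))
    return nodes, edges
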