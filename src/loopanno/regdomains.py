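"""Theoretical distance limits of proximity-based annotation.

Two proximity schemes are modelled per gene:

* **closest-TSS**: an element is annotated to a gene only while it is closer
  to that gene's TSS than to any neighbor's, so the reach toward each
  neighbor is half the TSS-to-TSS distance (floor);
* **basal-plus-extension regulatory domains**: a strand-aware basal domain
  (default -5 kb/+1 kb around the TSS) extended in each direction to the
  nearest neighboring gene's basal boundary, up to a cap (default 1 Mb) and
  clipped to the chromosome, permitting multi-gene annotation.

Distance limits are reported strand-aware (upstream/downstream of the gene)
plus the direction-free maximum; terminal genes are bounded by the
chromosome ends when sizes are supplied and are otherwise marked unbounded
and excluded from medians.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .annotate import Annotation
from .intervals import GenomicInterval, IntervalIndex, TssRecord, signed_distance

DEFAULT_BASAL_UP = 5000
DEFAULT_BASAL_DOWN = 1000
DEFAULT_EXTENSION_CAP = 1_000_000


@dataclass(frozen=True)
class RegulatoryDomain:
    """Basal and extended (full) regulatory domain of one gene."""

    gene: TssRecord
    basal: GenomicInterval
    full: GenomicInterval

    def __post_init__(self) -> None:
        if not (self.full.start <= self.basal.start and self.basal.end <= self.full.end):
            raise ValueError(f"basal domain not contained in full domain for {self.gene.gene_symbol}")


@dataclass(frozen=True)
class DistanceLimit:
    """Per-gene upper annotation distances; None marks an unbounded side."""

    gene: TssRecord
    upstream_limit: Optional[int]
    downstream_limit: Optional[int]

    @property
    def max_limit(self) -> Optional[int]:
        if self.upstream_limit is None or self.downstream_limit is None:
            return None
        return max(self.upstream_limit, self.downstream_limit)


def _sorted_by_chrom(tss: Sequence[TssRecord]) -> dict[str, list[TssRecord]]:
    by_chrom: dict[str, list[TssRecord]] = {}
    for t in tss:
        by_chrom.setdefault(t.chrom, []).append(t)
    for genes in by_chrom.values():
        genes.sort(key=lambda t: (t.tss, t.gene_symbol))
    return by_chrom


def _orient(t: TssRecord, left: Optional[int], right: Optional[int]):
    """Map leftward/rightward genomic reach to upstream/downstream by strand."""
    return (left, right) if t.strand == "+" else (right, left)


def proximity_limits(
    tss: Sequence[TssRecord], chrom_sizes: Optional[dict[str, int]] = None
) -> list[DistanceLimit]:
    """Closest-TSS annotation limits: half the distance to each neighbor.

    Terminal genes reach to the chromosome boundary when ``chrom_sizes`` is
    given, else that side is unbounded (None).
    """
    out: list[DistanceLimit] = []
    for chrom, genes in _sorted_by_chrom(tss).items():
        if chrom_sizes is not None and chrom not in chrom_sizes:
            raise ValueError(f"chromosome {chrom} absent from chrom sizes")
        for i, t in enumerate(genes):
            if i > 0:
                left = (t.tss - genes[i - 1].tss) // 2
            elif chrom_sizes is not None:
                left = t.tss
            else:
                left = None
            if i < len(genes) - 1:
                right = (genes[i + 1].tss - t.tss) // 2
            elif chrom_sizes is not None:
                right = chrom_sizes[chrom] - t.tss
            else:
                right = None
            up, down = _orient(t, left, right)
            out.append(DistanceLimit(gene=t, upstream_limit=up, downstream_limit=down))
    out.sort(key=lambda d: (d.gene.chrom, d.gene.tss, d.gene.gene_symbol))
    return out


def great_domains(
    tss: Sequence[TssRecord],
    basal_up: int = DEFAULT_BASAL_UP,
    basal_down: int = DEFAULT_BASAL_DOWN,
    extension_cap: int = DEFAULT_EXTENSION_CAP,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> list[RegulatoryDomain]:
    """Basal-plus-extension regulatory domains.

    The basal domain is ``[tss - basal_up, tss + basal_down)`` for plus-strand
    genes and mirrored for minus strand. The full domain extends each side to
    the nearest other gene's basal boundary, at most ``extension_cap`` bp
    from the TSS and clipped to ``[0, chrom length)``; extension never
    shrinks the basal domain, so overlapping basal domains are permitted.
    """
    if basal_up <= 0 or basal_down <= 0:
        raise ValueError("basal_up and basal_down must be > 0")
    out: list[RegulatoryDomain] = []
    for chrom, genes in _sorted_by_chrom(tss).items():
        chrom_len = chrom_sizes.get(chrom) if chrom_sizes else None
        basals = []
        for t in genes:
            if t.strand == "+":
                bs, be = t.tss - basal_up, t.tss + basal_down
            else:
                bs, be = t.tss - basal_down, t.tss + basal_up
            basals.append((max(0, bs), be))
        for i, t in enumerate(genes):
            bs, be = basals[i]
            left_stops = [e for j, (_, e) in enumerate(basals) if j != i and e <= t.tss]
            right_stops = [s for j, (s, _) in enumerate(basals) if j != i and s >= t.tss]
            left = max(left_stops) if left_stops else 0
            right = min(right_stops) if right_stops else (
                chrom_len if chrom_len is not None else t.tss + extension_cap
            )
            left = max(left, t.tss - extension_cap, 0)
            right = min(right, t.tss + extension_cap)
            if chrom_len is not None:
                right = min(right, chrom_len)
            full_start = min(bs, left)
            full_end = max(be, right)
            out.append(
                RegulatoryDomain(
                    gene=t,
                    basal=GenomicInterval(chrom, bs, be, name=t.gene_symbol),
                    full=GenomicInterval(chrom, full_start, full_end, name=t.gene_symbol),
                )
            )
    out.sort(key=lambda d: (d.gene.chrom, d.gene.tss, d.gene.gene_symbol))
    return out


def great_limits(domains: Sequence[RegulatoryDomain]) -> list[DistanceLimit]:
    """Strand-aware distances from the TSS to the full-domain edges."""
    out = []
    for d in domains:
        left = d.gene.tss - d.full.start
        right = d.full.end - d.gene.tss
        up, down = _orient(d.gene, left, right)
        out.append(DistanceLimit(gene=d.gene, upstream_limit=up, downstream_limit=down))
    return out


def annotate_great(
    peaks: Sequence[GenomicInterval], domains: Sequence[RegulatoryDomain]
) -> list[Annotation]:
    """Annotate each peak to every gene whose full domain it overlaps."""
    domain_index = IntervalIndex(d.full for d in domains)
    genes_by_full: dict[tuple, list[TssRecord]] = {}
    for d in domains:
        genes_by_full.setdefault((d.full.chrom, d.full.start, d.full.end), []).append(d.gene)
    out: list[Annotation] = []
    seen: set[tuple] = set()
    for peak in sorted(peaks, key=lambda p: p.sort_key()):
        for full in domain_index.query(peak):
            for gene in genes_by_full[(full.chrom, full.start, full.end)]:
                key = (peak.chrom, peak.start, peak.end, peak.label, gene.gene_symbol)
                if key in seen:
                    continue
                seen.add(key)
                out.append(
                    Annotation(
                        peak=peak,
                        gene_symbol=gene.gene_symbol,
                        entrez_id=gene.entrez_id,
                        annotation_type="proximal",
                        distance_to_tss=signed_distance(peak, gene),
                        method="regdomain",
                    )
                )
    return out


def limits_frame(limits: Sequence[DistanceLimit]) -> pd.DataFrame:
    """Per-gene table of the distance limits (violin-plot ready)."""
    return pd.DataFrame(
        {
            "gene_symbol": [d.gene.gene_symbol for d in limits],
            "chrom": [d.gene.chrom for d in limits],
            "tss": [d.gene.tss for d in limits],
            "strand": [d.gene.strand for d in limits],
            "upstream_limit": [d.upstream_limit for d in limits],
            "downstream_limit": [d.downstream_limit for d in limits],
            "max_limit": [d.max_limit for d in limits],
        }
    )


def summarize_limits(limits: Sequence[DistanceLimit]) -> dict:
    """Medians over genes with bounded limits.

    Returns median upstream, downstream and per-gene max limits, plus the
    median of the pooled directional limits, along with the per-gene table.
    Medians of even-length samples are the mean of the central pair.
    """
    ups = [d.upstream_limit for d in limits if d.upstream_limit is not None]
    downs = [d.downstream_limit for d in limits if d.downstream_limit is not None]
    maxes = [d.max_limit for d in limits if d.max_limit is not None]
    if not maxes:
        raise ValueError("no gene has bounded limits in both directions")
    return {
        "median_upstream": statistics.median(ups),
        "median_downstream": statistics.median(downs),
        "median_max": statistics.median(maxes),
        "median_pooled": statistics.median(ups + downs),
        "n_bounded": len(maxes),
        "table": limits_frame(limits),
    }


def write_domains_bed(domains: Sequence[RegulatoryDomain], basal_path, full_path) -> None:
    from .io import write_bed

    write_bed([d.basal for d in domains], basal_path)
    write_bed([d.full for d in domains], full_path)
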