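"""Genomic interval primitives shared by every module.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
A transcription start site (TSS) is a 0-based point. Two intervals on the same
chromosome overlap iff ``a.start < b.end and a.end > b.start``; bookended
intervals (``a.end == b.start``) do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """One genomic region (one BED row).

    Parameters
    ----------
    chrom : str
        Chromosome label; must be non-empty.
    start, end : int
        0-based half-open coordinates; ``0 <= start < end``.
    name : str, optional
        Region name. When absent, :attr:`label` synthesizes
        ``"<chrom>:<start>-<end>"``.
    score : float, optional
    strand : str, optional
        One of ``+``, ``-``, ``.``.
    """

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand is not None and self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def label(self) -> str:
        return self.name if self.name is not None else f"{self.chrom}:{self.start}-{self.end}"

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor of the interval midpoint (the peak-position summary)."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and self.end > other.start
        )

    def sort_key(self):
        return (self.chrom, self.start, self.end, self.label)


@dataclass(frozen=True)
class TssRecord:
    """A gene's transcription start site (0-based point) with strand."""

    gene_symbol: str
    chrom: str
    tss: int
    strand: str
    entrez_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.gene_symbol}")
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"invalid strand {self.strand!r} for {self.gene_symbol}; must be + or -"
            )


@dataclass(frozen=True)
class Interaction:
    """One chromatin interaction: a pair of anchors (one bedpe row).

    ``score`` carries the user-selected statistic (e.g. a loop caller's
    q-value or contact strength); ``row_id`` is the 0-based input row index
    and uniquely identifies the interaction.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    row_id: int
    score: Optional[float] = None


@dataclass(frozen=True)
class ExpressionRecord:
    """Differential-expression result for one gene."""

    gene_symbol: str
    log2fc: float
    padj: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.padj <= 1.0):
            raise ValueError(f"padj outside [0,1] for {self.gene_symbol}")


def signed_distance(peak: GenomicInterval, tss: TssRecord) -> int:
    """Strand-aware signed distance from a peak midpoint to a TSS.

    Negative values lie upstream of the gene (5' of the TSS), positive values
    downstream, so the sign is flipped for minus-strand genes.
    """
    if peak.chrom != tss.chrom:
        raise ValueError(
            f"chromosome mismatch: peak on {peak.chrom}, TSS of "
            f"{tss.gene_symbol} on {tss.chrom}"
        )
    mid = peak.midpoint
    return mid - tss.tss if tss.strand == "+" else tss.tss - mid


class IntervalIndex:
    """Per-chromosome interval tree with deterministic query results.

    Queries return stored intervals that half-open-overlap the probe, sorted
    by ``(start, end, label)``.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in sorted(self._trees):
            for node in sorted(self._trees[chrom]):
                yield node.data

    def query(self, probe: GenomicInterval) -> list[GenomicInterval]:
        tree = self._trees.get(probe.chrom)
        if tree is None:
            return []
        hits = [node.data for node in tree.overlap(probe.start, probe.end)]
        hits.sort(key=lambda iv: (iv.start, iv.end, iv.label))
        return hits

    def any_overlap(self, probe: GenomicInterval) -> bool:
        tree = self._trees.get(probe.chrom)
        return tree is not None and tree.overlaps(probe.start, probe.end)
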