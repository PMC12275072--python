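"""Readers and writers for the flat-file formats the package consumes.

BED and bedpe are parsed line by line so malformed rows can be rejected with
their line number, and comment/``track``/``browser`` lines skipped, as peak
and loop files in the wild require. Tabular inputs with headers (TSS,
expression, enhancer-gene pair tables, chromosome sizes) go through pandas.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .intervals import ExpressionRecord, GenomicInterval, Interaction, TssRecord

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_SKIP_PREFIXES = ("#", "track", "browser")


def _data_lines(path: PathLike):
    """Yield (1-based line number, stripped line) skipping comments/blanks."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if any(line.startswith(p) for p in _SKIP_PREFIXES):
                continue
            yield lineno, line


def _parse_coord(text: str, what: str, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise ValueError(f"non-integer {what} {text!r} at line {lineno}") from None


def read_bed(path: PathLike) -> list[GenomicInterval]:
    """Read a BED file (>=3 tab-separated columns) into intervals.

    Column 4 supplies the name when present; otherwise the name defaults to
    ``"<chrom>:<start>-<end>"`` via :attr:`GenomicInterval.label`. Column 5
    (score) and 6 (strand) are kept when parseable.
    """
    out: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 3:
            raise ValueError(f"expected >=3 tab-separated columns at line {lineno}")
        start = _parse_coord(cols[1], "start", lineno)
        end = _parse_coord(cols[2], "end", lineno)
        if start >= end:
            raise ValueError(f"start >= end at line {lineno}")
        name = cols[3] if len(cols) > 3 and cols[3] not in ("", ".") else None
        score: Optional[float] = None
        if len(cols) > 4 and cols[4] not in ("", "."):
            try:
                score = float(cols[4])
            except ValueError:
                score = None
        strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-", ".") else None
        out.append(GenomicInterval(cols[0], start, end, name=name, score=score, strand=strand))
    if not out:
        logger.warning("no records read from %s", path)
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end), iv.label]
            if iv.score is not None or iv.strand is not None:
                fields.append("." if iv.score is None else repr(iv.score))
            if iv.strand is not None:
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


def _looks_numeric(text: str) -> bool:
    try:
        int(text)
        return True
    except ValueError:
        return False


def read_bedpe(path: PathLike, score_col: Optional[int] = None) -> list[Interaction]:
    """Read chromatin interactions from 2D-bed (bedpe).

    The first six columns give the two anchors; any further columns are
    tolerated. ``score_col`` is 1-based; when given, that column must be
    numeric on every data row. A leading header line is auto-detected (its
    coordinate columns are non-numeric) and skipped.

    ``row_id`` on the returned interactions is the 0-based data-row index,
    which downstream code uses as the stable interaction identifier.
    """
    out: list[Interaction] = []
    first = True
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 6:
            raise ValueError(f"expected >=6 columns at line {lineno}")
        if first and not (_looks_numeric(cols[1]) and _looks_numeric(cols[2])):
            logger.info("skipping header line in %s", path)
            first = False
            continue
        first = False
        a1 = GenomicInterval(
            cols[0],
            _parse_coord(cols[1], "start1", lineno),
            _parse_coord(cols[2], "end1", lineno),
        )
        a2 = GenomicInterval(
            cols[3],
            _parse_coord(cols[4], "start2", lineno),
            _parse_coord(cols[5], "end2", lineno),
        )
        score: Optional[float] = None
        if score_col is not None:
            if score_col < 1 or score_col > len(cols):
                raise ValueError(f"score column {score_col} absent at line {lineno}")
            try:
                score = float(cols[score_col - 1])
            except ValueError:
                raise ValueError(
                    f"non-numeric score {cols[score_col - 1]!r} at line {lineno}"
                ) from None
        out.append(Interaction(a1, a2, row_id=len(out), score=score))
    if not out:
        logger.warning("no interactions read from %s", path)
    return out


def write_bedpe(interactions: Sequence[Interaction], path: PathLike) -> None:
    with open(path, "w") as fh:
        for it in interactions:
            fields = [
                it.anchor1.chrom, str(it.anchor1.start), str(it.anchor1.end),
                it.anchor2.chrom, str(it.anchor2.start), str(it.anchor2.end),
            ]
            if it.score is not None:
                fields.append(repr(it.score))
            fh.write("\t".join(fields) + "\n")


def read_tss_table(path: PathLike) -> list[TssRecord]:
    """Read a headered TSV of TSS positions.

    Required columns: ``gene_symbol``, ``chrom``, ``tss``, ``strand``;
    ``entrez_id`` is optional. Duplicate ``(gene_symbol, chrom, tss)`` rows
    collapse to one record.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_symbol", "chrom", "tss", "strand"):
        if col not in df.columns:
            raise ValueError(f"TSS table missing required column {col!r}")
    df = df.drop_duplicates(subset=["gene_symbol", "chrom", "tss"])
    records = []
    for row in df.itertuples(index=False):
        strand = str(row.strand)
        if strand not in ("+", "-"):
            raise ValueError(f"invalid strand {strand!r} for gene {row.gene_symbol}")
        entrez = getattr(row, "entrez_id", None)
        if entrez is not None and (pd.isna(entrez) or entrez == ""):
            entrez = None
        records.append(
            TssRecord(
                gene_symbol=str(row.gene_symbol),
                chrom=str(row.chrom),
                tss=int(row.tss),
                strand=strand,
                entrez_id=entrez,
            )
        )
    return records


def write_tss_table(records: Sequence[TssRecord], path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "gene_symbol": [r.gene_symbol for r in records],
            "entrez_id": [r.entrez_id if r.entrez_id is not None else "" for r in records],
            "chrom": [r.chrom for r in records],
            "tss": [r.tss for r in records],
            "strand": [r.strand for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_expression_table(path: PathLike) -> list[ExpressionRecord]:
    """Read a headered TSV with columns gene_symbol, log2fc, padj."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_symbol", "log2fc", "padj"):
        if col not in df.columns:
            raise ValueError(f"expression table missing required column {col!r}")
    return [
        ExpressionRecord(str(r.gene_symbol), float(r.log2fc), float(r.padj))
        for r in df.itertuples(index=False)
    ]


def read_chrom_sizes(path: PathLike) -> dict[str, int]:
    """Read a two-column (chrom, length) TSV without header."""
    sizes: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 2:
            raise ValueError(f"expected 2 columns at line {lineno}")
        sizes[cols[0]] = _parse_coord(cols[1], "length", lineno)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def read_gene_list(path: PathLike) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
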