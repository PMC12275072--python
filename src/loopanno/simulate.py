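"""Deterministic synthetic fixtures: toy genomes, binned loops, truth tables.

The generator emulates the output of a loop caller run on promoter-directed
HiChIP/PLAC-seq data: cis interactions whose anchors are exact bin-aligned
intervals of a fixed width (default 5 kb), a subset of which are anchored in
a gene's promoter window. Planted (peak, gene) links place an ATAC-scale
peak (200-1000 bp) inside a distal anchor whose partner anchor covers the
gene's promoter; distractor loops touch no promoter window; background
peaks overlap no anchor and lie beyond the interaction threshold from every
TSS. The planted truth table is therefore exactly what the annotation
engine should recover.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Interaction, TssRecord
from . import io as gio


@dataclass
class FixtureSpec:
    """Parameters of one synthetic fixture.

    Defaults give one 1 Mb chromosome with three genes, two planted
    peak-gene links through 5 kb binned loops, one distractor loop and one
    background peak — the smallest configuration that exercises every
    annotation path.
    """

    n_chroms: int = 1
    chrom_length: int = 1_000_000
    n_genes: int = 3
    n_planted_links: int = 2
    n_distractor_loops: int = 1
    n_background_peaks: int = 1
    bin_size: int = 5000
    promoter_window: int = 2500
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_chroms, self.n_genes, self.n_planted_links,
                  self.n_distractor_loops, self.n_background_peaks)
        if any(c < 0 for c in counts) or self.n_chroms < 1:
            raise ValueError("all counts must be >= 0 (and n_chroms >= 1)")
        if self.n_planted_links > self.n_genes * 5:
            raise ValueError("n_planted_links must be <= 5 * n_genes")
        if self.bin_size <= 0 or self.chrom_length < self.bin_size:
            raise ValueError("need chrom_length >= bin_size > 0")


@dataclass
class ToyFixture:
    """A generated annotation problem plus its planted truth."""

    tss: list[TssRecord]
    peaks: list[GenomicInterval]
    interactions: list[Interaction]
    truth: pd.DataFrame
    chrom_sizes: dict[str, int]
    spec: FixtureSpec | None = None


def _round_robin(n: int, k: int) -> list[int]:
    return [n // k + (1 if i < n % k else 0) for i in range(k)]


def make_toy_annotation_set(spec: FixtureSpec) -> ToyFixture:
    """Generate TSS table, peaks, interactions and the planted truth table.

    Identical specs (including seed) yield identical output. Raises when the
    requested counts cannot be placed on the chromosomes.
    """
    rng = np.random.default_rng(spec.seed)
    threshold = 2 * spec.bin_size
    n_bins = spec.chrom_length // spec.bin_size

    tss: list[TssRecord] = []
    peaks: list[GenomicInterval] = []
    interactions: list[Interaction] = []
    truth_rows: list[dict] = []

    genes_per = _round_robin(spec.n_genes, spec.n_chroms)
    links_per = _round_robin(spec.n_planted_links, spec.n_chroms)
    distract_per = _round_robin(spec.n_distractor_loops, spec.n_chroms)
    background_per = _round_robin(spec.n_background_peaks, spec.n_chroms)

    gene_counter = 0
    peak_counter = 0
    for ci in range(spec.n_chroms):
        chrom = f"chr{ci + 1}"
        # --- genes: TSS bins spaced >= 4 bins apart, TSS centered in its bin
        gene_bins: list[int] = []
        candidates = list(range(1, n_bins - 1))
        rng.shuffle(candidates)
        for b in candidates:
            if len(gene_bins) == genes_per[ci]:
                break
            if all(abs(b - g) >= 4 for g in gene_bins):
                gene_bins.append(b)
        if len(gene_bins) < genes_per[ci]:
            raise ValueError(
                f"cannot place {genes_per[ci]} genes with 4-bin spacing on {chrom}"
            )
        gene_bins.sort()
        chrom_genes: list[TssRecord] = []
        for b in gene_bins:
            gene_counter += 1
            strand = "+" if rng.integers(2) == 0 else "-"
            pos = b * spec.bin_size + spec.bin_size // 2
            rec = TssRecord(
                gene_symbol=f"G{gene_counter}", chrom=chrom, tss=pos, strand=strand,
                entrez_id=str(10000 + gene_counter),
            )
            chrom_genes.append(rec)
            tss.append(rec)

        used_bins = set(gene_bins)
        # bins overlapping any promoter window (windows can spill into neighbors)
        promoter_bins = set()
        for g in chrom_genes:
            lo = max(0, g.tss - spec.promoter_window) // spec.bin_size
            hi = (g.tss + spec.promoter_window - 1) // spec.bin_size
            promoter_bins.update(range(lo, hi + 1))

        def far_from_all_tss(b: int) -> bool:
            lo, hi = b * spec.bin_size, (b + 1) * spec.bin_size
            return all(lo >= g.tss + threshold or hi <= g.tss - threshold
                       for g in chrom_genes)

        def draw_bin(need_far: bool) -> int:
            pool = [
                b for b in range(n_bins)
                if b not in used_bins and b not in promoter_bins
                and (not need_far or far_from_all_tss(b))
            ]
            if not pool:
                raise ValueError(f"no free bin left on {chrom} for this fixture spec")
            b = int(pool[rng.integers(len(pool))])
            used_bins.add(b)
            return b

        def bin_iv(b: int) -> GenomicInterval:
            return GenomicInterval(chrom, b * spec.bin_size, (b + 1) * spec.bin_size)

        def place_peak(b: int) -> GenomicInterval:
            nonlocal peak_counter
            peak_counter += 1
            width = int(rng.integers(200, 1001))
            start = b * spec.bin_size + int(rng.integers(0, spec.bin_size - width))
            return GenomicInterval(chrom, start, start + width, name=f"P{peak_counter}")

        # --- planted links: distal anchor bin + promoter anchor bin
        for k in range(links_per[ci]):
            gene = chrom_genes[k % len(chrom_genes)] if chrom_genes else None
            if gene is None:
                raise ValueError(f"cannot plant links on gene-less chromosome {chrom}")
            distal = draw_bin(need_far=True)
            peak = place_peak(distal)
            peaks.append(peak)
            score = float(np.round(rng.uniform(1.0, 20.0), 3))
            interactions.append(
                Interaction(
                    anchor1=bin_iv(distal),
                    anchor2=bin_iv(gene.tss // spec.bin_size),
                    row_id=len(interactions),
                    score=score,
                )
            )
            truth_rows.append(
                {
                    "peak_name": peak.label,
                    "gene_symbol": gene.gene_symbol,
                    "elem_chrom": peak.chrom,
                    "elem_start": peak.start,
                    "elem_end": peak.end,
                    "distance": abs(peak.midpoint - gene.tss),
                    "significant": True,
                }
            )

        # --- distractor loops: neither anchor touches a promoter window
        for _ in range(distract_per[ci]):
            b1 = draw_bin(need_far=False)
            b2 = draw_bin(need_far=False)
            interactions.append(
                Interaction(
                    anchor1=bin_iv(b1), anchor2=bin_iv(b2),
                    row_id=len(interactions),
                    score=float(np.round(rng.uniform(1.0, 20.0), 3)),
                )
            )

        # --- background peaks: no anchor overlap, far from every TSS
        for _ in range(background_per[ci]):
            peaks.append(place_peak(draw_bin(need_far=True)))

    truth = pd.DataFrame(
        truth_rows,
        columns=["peak_name", "gene_symbol", "elem_chrom", "elem_start",
                 "elem_end", "distance", "significant"],
    )
    peaks.sort(key=lambda p: p.sort_key())
    return ToyFixture(
        tss=tss,
        peaks=peaks,
        interactions=interactions,
        truth=truth,
        chrom_sizes={f"chr{i + 1}": spec.chrom_length for i in range(spec.n_chroms)},
        spec=spec,
    )


def make_benchmark_truth(
    spec: FixtureSpec, frac_significant: float, n_pairs: int = 20
) -> pd.DataFrame:
    """Tested enhancer-gene pairs at controlled distances.

    Pair distances cycle through one representative per default recall bin
    (5, 15, 35 and 75 kb). ``floor(frac_significant * n_pairs)`` pairs get
    FDR 0.01 (< 0.05, significant), the rest FDR 0.5. Deterministic for a
    given spec seed.
    """
    if not (0.0 <= frac_significant <= 1.0):
        raise ValueError("frac_significant must be in [0, 1]")
    fixture = make_toy_annotation_set(spec)
    rng = np.random.default_rng(spec.seed + 1)
    distances = [5_000, 15_000, 35_000, 75_000]
    n_sig = int(np.floor(frac_significant * n_pairs))
    rows = []
    for i in range(n_pairs):
        gene = fixture.tss[i % len(fixture.tss)]
        d = distances[i % len(distances)]
        side = 1 if rng.integers(2) == 0 else -1
        width = 500
        center = gene.tss + side * d
        if center - width // 2 < 0:
            center = gene.tss + d
        rows.append(
            {
                "elem_chrom": gene.chrom,
                "elem_start": center - width // 2,
                "elem_end": center + width // 2,
                "gene_symbol": gene.gene_symbol,
                "fdr": 0.01 if i < n_sig else 0.5,
                "effect": float(np.round(rng.normal(-0.5, 0.2), 3)),
                "distance": d,
            }
        )
    return pd.DataFrame(rows)


def fixture_t1() -> ToyFixture:
    """The canonical hand-checkable fixture used throughout the docs.

    One 1 Mb chromosome ``chrT`` with three genes (G1 +/100000, G2 -/300000,
    G3 +/900000), three 5 kb-binned loops (two promoter-anchored, one not)
    and four peaks. The combined engine annotates P1 and P3 through loops,
    P2 by proximity, and leaves P4 unannotated.
    """
    tss = [
        TssRecord("G1", "chrT", 100_000, "+", entrez_id="1001"),
        TssRecord("G2", "chrT", 300_000, "-", entrez_id="1002"),
        TssRecord("G3", "chrT", 900_000, "+", entrez_id="1003"),
    ]
    peaks = [
        GenomicInterval("chrT", 46_000, 46_500, name="P1"),
        GenomicInterval("chrT", 99_000, 99_400, name="P2"),
        GenomicInterval("chrT", 502_000, 502_300, name="P3"),
        GenomicInterval("chrT", 700_000, 700_200, name="P4"),
    ]
    interactions = [
        Interaction(
            GenomicInterval("chrT", 45_000, 50_000),
            GenomicInterval("chrT", 100_000, 105_000),
            row_id=0, score=12.0,
        ),
        Interaction(
            GenomicInterval("chrT", 500_000, 505_000),
            GenomicInterval("chrT", 295_000, 300_000),
            row_id=1, score=8.0,
        ),
        Interaction(
            GenomicInterval("chrT", 600_000, 605_000),
            GenomicInterval("chrT", 700_000, 705_000),
            row_id=2, score=3.0,
        ),
    ]
    truth = pd.DataFrame(
        [
            {"peak_name": "P1", "gene_symbol": "G1", "elem_chrom": "chrT",
             "elem_start": 46_000, "elem_end": 46_500, "distance": 53_750,
             "significant": True},
            {"peak_name": "P2", "gene_symbol": "G1", "elem_chrom": "chrT",
             "elem_start": 99_000, "elem_end": 99_400, "distance": 800,
             "significant": True},
            {"peak_name": "P3", "gene_symbol": "G2", "elem_chrom": "chrT",
             "elem_start": 502_000, "elem_end": 502_300, "distance": 202_150,
             "significant": True},
        ]
    )
    return ToyFixture(
        tss=tss, peaks=peaks, interactions=interactions, truth=truth,
        chrom_sizes={"chrT": 1_000_000},
        spec=FixtureSpec(n_genes=3, n_planted_links=2, seed=1),
    )


def write_fixture(fixture: ToyFixture, directory, force: bool = False) -> dict[str, Path]:
    """Write tss.tsv, peaks.bed, interactions.bedpe, truth.tsv, chrom.sizes.

    Refuses to write into an existing non-empty directory unless ``force``.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not force:
        raise FileExistsError(f"{directory} exists and is not empty (use force=True)")
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "tss": directory / "tss.tsv",
        "peaks": directory / "peaks.bed",
        "interactions": directory / "interactions.bedpe",
        "truth": directory / "truth.tsv",
        "chrom_sizes": directory / "chrom.sizes",
    }
    gio.write_tss_table(fixture.tss, paths["tss"])
    gio.write_bed(fixture.peaks, paths["peaks"])
    gio.write_bedpe(fixture.interactions, paths["interactions"])
    fixture.truth.to_csv(paths["truth"], sep="\t", index=False)
    gio.write_chrom_sizes(fixture.chrom_sizes, paths["chrom_sizes"])
    return paths
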