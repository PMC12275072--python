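"""End-to-end runs of the three annotation modes with deterministic outputs.

* **basic** — annotate each peak file independently; write per-file
  annotation table, gene list and unannotated-peak list.
* **multiple** — basic outputs plus co-occupancy: overlap matrix, UpSet
  combination counts and Circos link tables across the peak sets.
* **differential** — basic outputs plus activating/repressive
  classification against a gene expression table, and up-/down-associated
  network exports.

Output files carry no timestamps and all row orders are fixed, so re-running
a mode on identical inputs is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import io as gio
from .annotate import (
    AnnotationOptions,
    AnnotationResult,
    annotate_peaks,
    make_promoter_windows,
)
from .cooccupancy import (
    DifferentialOptions,
    circos_links,
    circos_links_frame,
    classify_differential,
    compute_overlap_matrix,
    export_network,
    upset_counts,
)

logger = logging.getLogger(__name__)

MODES = ("basic", "multiple", "differential")


@dataclass
class RunConfig:
    """Everything one mode run needs; validated on construction via check()."""

    mode: str
    peak_paths: list
    interaction_path: str
    tss_path: str
    options: AnnotationOptions = field(default_factory=AnnotationOptions)
    diff_options: DifferentialOptions = field(default_factory=DifferentialOptions)
    expression_path: Optional[str] = None
    in_regions_path: Optional[str] = None
    gene_filter_path: Optional[str] = None
    score_col: Optional[int] = None
    overlap_mode: str = "regions"
    upset_plot: bool = False
    circos_plot: bool = False
    circos_use_promoters: bool = False
    skip_promoter_promoter: bool = False
    outdir: str = "."

    def check(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not self.peak_paths:
            raise ValueError("at least one peak file is required")
        if self.mode == "multiple" and len(self.peak_paths) < 2:
            raise ValueError("multiple mode requires >= 2 peak files")
        if self.mode == "differential" and self.expression_path is None:
            raise ValueError("differential mode requires an expression table")


def _load_inputs(config: RunConfig):
    peak_sets = {Path(p).stem: gio.read_bed(p) for p in config.peak_paths}
    interactions = gio.read_bedpe(config.interaction_path, score_col=config.score_col)
    tss = gio.read_tss_table(config.tss_path)
    return peak_sets, interactions, tss


def _write_basic_outputs(
    name: str, result: AnnotationResult, outdir: Path, log_lines: list[str]
) -> None:
    result.write(outdir / f"{name}.annotated.tsv")
    with open(outdir / f"{name}.genes.txt", "w") as fh:
        for gene in result.gene_list():
            fh.write(gene + "\n")
    with open(outdir / f"{name}.unannotated.txt", "w") as fh:
        for peak in result.unannotated:
            fh.write(peak.label + "\n")
    log_lines.append(
        f"{name}: {len(result.peaks)} peaks, {len(result.annotations)} annotations, "
        f"{len(result.gene_list())} genes, {len(result.unannotated)} unannotated"
    )


def _write_log(config: RunConfig, log_lines: list[str], outdir: Path) -> None:
    opts = config.options
    header = [
        f"mode={config.mode}",
        f"promoter_window={opts.promoter_window}",
        f"bin_size={opts.bin_size}",
        f"interaction_threshold={opts.interaction_threshold}",
        f"close_peak={opts.close_peak_type}:{opts.close_peak_value}",
        f"close_promoter={opts.close_promoter_type}:{opts.close_promoter_value}",
        f"multiple_anno={opts.multiple_anno}",
        f"proximity_enabled={opts.proximity_enabled}",
    ]
    with open(outdir / "run_log.txt", "w") as fh:
        for line in header + log_lines:
            fh.write(line + "\n")
            logger.info("%s", line)


def run_basic(config: RunConfig) -> dict[str, AnnotationResult]:
    """Annotate each peak file and write its output triplet."""
    config.check()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    peak_sets, interactions, tss = _load_inputs(config)
    log_lines: list[str] = []
    results: dict[str, AnnotationResult] = {}
    for name in sorted(peak_sets):
        result = annotate_peaks(peak_sets[name], interactions, tss, config.options)
        results[name] = result
        config.options = result.options  # resolved bin size / threshold for the log
        _write_basic_outputs(name, result, outdir, log_lines)
    _write_log(config, log_lines, outdir)
    return results


def run_multiple(config: RunConfig) -> dict:
    """Basic outputs per file plus overlap matrix, UpSet counts, Circos links."""
    config.check()
    outdir = Path(config.outdir)
    results = run_basic(config)
    peak_sets, interactions, tss = _load_inputs(config)
    names = sorted(peak_sets)
    windows = make_promoter_windows(tss, config.options.promoter_window)

    in_regions = (
        gio.read_bed(config.in_regions_path) if config.in_regions_path else None
    )
    matrix = compute_overlap_matrix(
        [peak_sets[n] for n in names],
        names,
        mode=config.overlap_mode,
        bin_size=config.options.bin_size,
        regions=in_regions,
    )
    matrix.membership.to_csv(outdir / "overlap_matrix.tsv", sep="\t")

    counts = upset_counts(matrix, windows)
    counts.to_csv(outdir / "upset_counts.tsv", sep="\t", index=False)

    gene_filter = (
        gio.read_gene_list(config.gene_filter_path) if config.gene_filter_path else None
    )
    links = circos_links(
        {n: results[n].annotations for n in names},
        promoter_windows=windows,
        use_promoters=config.circos_use_promoters,
        skip_promoter_promoter=config.skip_promoter_promoter,
        gene_filter=gene_filter,
    )
    circos_links_frame(links).to_csv(outdir / "circos_links.tsv", sep="\t", index=False)
    return {"results": results, "matrix": matrix, "upset_counts": counts,
            "circos_links": links}


def run_differential(config: RunConfig) -> dict:
    """Basic outputs plus expression-aware classification and networks.

    The per-peak signed occupancy change is taken from each peak's BED score
    column; peaks without a score are unresolved.
    """
    config.check()
    outdir = Path(config.outdir)
    results = run_basic(config)
    expression = gio.read_expression_table(config.expression_path)
    expressed = {e.gene_symbol for e in expression}

    tables = {}
    for name in sorted(results):
        result = results[name]
        if expressed.isdisjoint(result.gene_list()):
            logger.warning(
                "%s: no annotated gene found in the expression table; "
                "all annotations unresolved", name,
            )
        peak_change = {
            p.label: p.score for p in result.peaks if p.score is not None
        }
        table = classify_differential(
            result.annotations, peak_change, expression, config.diff_options
        )
        table.to_csv(outdir / f"{name}.differential.tsv", sep="\t", index=False)
        tables[name] = table

        up_rows = set(table.index[table["category"] == "activating"])
        down_rows = set(table.index[table["category"] == "repressive"])
        up = [a for i, a in enumerate(result.annotations) if i in up_rows]
        down = [a for i, a in enumerate(result.annotations) if i in down_rows]
        export_network(up, outdir / f"{name}.network_up.xgmml")
        export_network(down, outdir / f"{name}.network_down.xgmml")
    return {"results": results, "tables": tables}


def run(config: RunConfig) -> dict:
    if config.mode == "basic":
        return {"results": run_basic(config)}
    if config.mode == "multiple":
        return run_multiple(config)
    return run_differential(config)
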