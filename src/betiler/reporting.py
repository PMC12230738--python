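"""Tabular outputs, summaries, coverage tracks, and library QC utilities."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .be_outcome import SEVERITY
from .guide_design import GuideRNA

log = logging.getLogger("betiler")

LIBRARY_FILENAMES = {
    "target": "Target_Library",
    "positive": "Positive_Control_Library",
    "negative": "Negative_Control_Library",
}

CORE_COLUMNS = [
    "guide_id",
    "protospacer",
    "pam",
    "chrom",
    "start",
    "end",
    "strand",
    "source_label",
    "library_type",
    "n_offtargets",
    "max_offtarget_cfd",
    "on_target_score_surrogate",
]

OUTCOME_CLASSES = list(SEVERITY) + ["no_edit"]


def build_library_table(
    guides: Sequence[GuideRNA],
    annotation_blocks: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Flatten guides (+ per-editor annotation) into one library table.

    Genomic coordinates are converted to 1-based inclusive for output, the
    spreadsheet convention. Per-editor columns are prefixed ``<editor>.``.
    The on-target column is explicitly labelled surrogate: it comes from the
    built-in heuristic scorer, not a trained efficiency model.
    """
    rows = []
    for g in guides:
        s, e = g.protospacer_interval
        rows.append(
            {
                "guide_id": g.guide_id,
                "protospacer": g.protospacer,
                "pam": g.pam,
                "chrom": g.chrom,
                "start": s + 1,
                "end": e,
                "strand": g.strand,
                "source_label": g.source_label,
                "library_type": g.library_type.value,
                "n_offtargets": g.n_offtargets,
                "max_offtarget_cfd": g.max_offtarget_cfd,
                "on_target_score_surrogate": g.on_target_score,
            }
        )
    table = pd.DataFrame(rows, columns=CORE_COLUMNS)
    for editor, block in (annotation_blocks or {}).items():
        renamed = block.drop(columns=["guide_id"]).add_prefix(f"{editor}.")
        if len(renamed) != len(table):
            raise ValueError(
                f"annotation block for {editor} has {len(renamed)} rows, "
                f"library has {len(table)}"
            )
        table = pd.concat([table.reset_index(drop=True), renamed.reset_index(drop=True)], axis=1)
    return table


def write_library_tables(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    editors: Sequence[str] = (),
) -> list[Path]:
    """Write one workbook per library type, plus CSV siblings.

    ``tables`` maps library type (target/positive/negative) to its table.
    Each workbook holds a core sheet plus one annotation sheet per editor;
    the CSV sibling carries all columns flat so downstream tooling never
    needs a spreadsheet reader.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for lib_type, table in tables.items():
        stem = LIBRARY_FILENAMES[lib_type]
        xlsx = out_dir / f"{stem}.xlsx"
        with pd.ExcelWriter(xlsx, engine="openpyxl") as writer:
            core = table[[c for c in CORE_COLUMNS if c in table.columns]]
            core.to_excel(writer, sheet_name="library", index=False)
            for editor in editors:
                cols = ["guide_id"] + [
                    c for c in table.columns if c.startswith(f"{editor}.")
                ]
                if len(cols) > 1:
                    sheet = table[cols].rename(
                        columns=lambda c: c.removeprefix(f"{editor}.")
                    )
                    sheet.to_excel(writer, sheet_name=editor[:31], index=False)
        csv = out_dir / f"{stem}.csv"
        table.to_csv(csv, index=False)
        written.extend([xlsx, csv])
    return written


def read_library_table(path: str | Path) -> pd.DataFrame:
    """Read back a CSV library table written by write_library_tables."""
    return pd.read_csv(path)


def summarize_library(
    tables: dict[str, pd.DataFrame], editors: Sequence[str] = ()
) -> dict:
    """Per-gene guide counts and per-editor outcome-class breakdowns.

    The class counts (including no_edit) partition each library: they sum to
    the number of guides per editor.
    """
    summary: dict = {"libraries": {}}
    for lib_type, table in tables.items():
        entry: dict = {"n_sgrnas": int(len(table))}
        if len(table):
            per_gene = table.groupby("source_label").size().to_dict()
        else:
            per_gene = {}
        entry["per_gene"] = {str(k): int(v) for k, v in per_gene.items()}
        entry["per_editor_outcomes"] = {}
        for editor in editors:
            col = f"{editor}.aggregated_outcome"
            if col not in table.columns:
                continue
            counts = {c: 0 for c in OUTCOME_CLASSES}
            for value, n in table[col].value_counts().items():
                counts[str(value)] = int(n)
            entry["per_editor_outcomes"][editor] = counts
        summary["libraries"][lib_type] = entry
    return summary


def write_summary(summary: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return path


def write_coverage_tracks(
    table: pd.DataFrame, out_prefix: str | Path
) -> tuple[Path, Path]:
    """Static per-gene coverage tracks: sgRNA BED + per-base coverage BedGraph.

    Replaces an interactive genome-browser view with the same information:
    where each guide sits and how many guides cover each base.
    """
    out_prefix = Path(out_prefix)
    bed = out_prefix.with_suffix(".guides.bed")
    bedgraph = out_prefix.with_suffix(".coverage.bedgraph")
    with bed.open("w") as fh:
        for _, row in table.iterrows():
            fh.write(
                f"{row['chrom']}\t{int(row['start']) - 1}\t{int(row['end'])}\t"
                f"{row['guide_id']}\t0\t{row['strand']}\n"
            )
    cov: dict[str, dict[int, int]] = {}
    for _, row in table.iterrows():
        chrom_cov = cov.setdefault(row["chrom"], {})
        for p in range(int(row["start"]) - 1, int(row["end"])):
            chrom_cov[p] = chrom_cov.get(p, 0) + 1
    with bedgraph.open("w") as fh:
        for chrom in sorted(cov):
            positions = sorted(cov[chrom])
            run_start = None
            run_val = None
            prev = None
            for p in positions:
                v = cov[chrom][p]
                if run_start is None:
                    run_start, run_val, prev = p, v, p
                elif p == prev + 1 and v == run_val:
                    prev = p
                else:
                    fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{run_val}\n")
                    run_start, run_val, prev = p, v, p
            if run_start is not None:
                fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{run_val}\n")
    return bed, bedgraph


# ---------------------------------------------------------------------------
# Library QC utilities
# ---------------------------------------------------------------------------


def gini_index(counts: Sequence[float] | np.ndarray) -> float:
    """Gini inequality index of a read-count vector.

    G = sum_i sum_j |x_i - x_j| / (2 n sum_i x_i), computed on the vector as
    given (no normalisation). 0 means perfectly uniform representation.
    """
    x = np.asarray(counts, dtype=float)
    if x.size == 0:
        raise ValueError("empty count vector")
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero count vector")
    # O(n log n) equivalent of the double sum
    xs = np.sort(x)
    n = xs.size
    ranks = np.arange(1, n + 1)
    return float(((2 * ranks - n - 1) * xs).sum() / (n * total))


def positional_representation(
    counts_by_slot: pd.DataFrame,
    count_col: str = "count",
    slot_col: str = "slot",
) -> pd.DataFrame:
    """Per-slot descriptive statistics of guide read counts.

    Expects one row per guide with its oligomer slot (1..k) and read count,
    e.g. a count table joined to the prepared-library manifest. Returns mean,
    median and n per slot; purely descriptive, no test statistic.
    """
    for col in (slot_col, count_col):
        if col not in counts_by_slot.columns:
            raise ValueError(f"missing required column {col!r}")
    grouped = counts_by_slot.groupby(slot_col)[count_col]
    out = grouped.agg(["mean", "median", "count"]).reset_index()
    return out.rename(columns={"count": "n"})
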