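"""End-to-end orchestration: design -> annotate -> assemble.

Thin glue over the stage modules, shared by the command-line interface and
by scripted use. Each stage's contract lives in its own module; this module
only fixes the order of operations and the audit bookkeeping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import be_outcome, genome_model, guide_design, offtarget, oligo_assembly, reporting
from .be_outcome import BaseEditor
from .genome_model import GenomeAssembly, TargetRegion, TranscriptModel
from .guide_design import CasVariant, GuideRNA, LibraryType

log = logging.getLogger("betiler")


@dataclass
class DesignResult:
    regions: list[TargetRegion]
    guides: list[GuideRNA]
    removed_offtarget: list
    table: pd.DataFrame
    library_type: str = "target"


def design_library(
    genome: GenomeAssembly,
    transcripts: Sequence[TranscriptModel],
    entries: Sequence[str],
    cas: CasVariant,
    editors: Sequence[BaseEditor],
    flank_nt: int = 0,
    canonical_only: bool = False,
    blacklist=None,
    library_type: LibraryType = LibraryType.TARGET,
    max_mismatches: int = 3,
    cfd_threshold: float = 0.2,
    max_offtargets: int = 0,
    offtarget_filter: bool = True,
    score_on_target: bool = True,
) -> DesignResult:
    """Resolve targets, scan guides, filter off-targets, score and annotate."""
    regions = genome_model.resolve_targets(
        entries,
        transcripts,
        genome,
        flank_nt=flank_nt,
        canonical_only=canonical_only,
        blacklist=blacklist,
    )
    guides = guide_design.scan_regions(regions, genome, cas, library_type)
    removed: list = []
    if offtarget_filter and cas.is_spcas9_family:
        guides, removed = offtarget.filter_by_offtargets(
            guides,
            genome,
            cas,
            max_offtargets=max_offtargets,
            cfd_threshold=cfd_threshold,
            max_mismatches=max_mismatches,
        )
    elif offtarget_filter:
        log.warning(
            "off-target filtering is only available for SpCas9-family variants; skipped"
        )
    if score_on_target and cas.is_spcas9_family:
        for g in guides:
            g.on_target_score = offtarget.on_target_score(g, genome)
    blocks = be_outcome.annotate_library(guides, editors, genome, transcripts)
    table = reporting.build_library_table(guides, blocks)
    return DesignResult(
        regions=regions,
        guides=guides,
        removed_offtarget=removed,
        table=table,
        library_type=library_type.value,
    )


@dataclass
class AssemblyAudit:
    """Counts reconciling input guides with the final manifest."""

    n_input: int = 0
    n_dedup_dropped: int = 0
    n_restriction_dropped: int = 0
    n_padding_added: int = 0
    n_padding_removed: int = 0
    n_sensor_dropped: int = 0
    n_manifest: int = 0

    def balanced(self) -> bool:
        return (
            self.n_input
            - self.n_dedup_dropped
            - self.n_restriction_dropped
            - self.n_padding_removed
            + self.n_padding_added
            - self.n_sensor_dropped
            == self.n_manifest
        )


@dataclass
class AssemblyResult:
    final_table: pd.DataFrame
    oligos: list
    audit: AssemblyAudit
    padding_report: oligo_assembly.PaddingReport
    order_file: Path | None = None
    manifest_file: Path | None = None


def assemble_library(
    target_table: pd.DataFrame,
    negative_table: pd.DataFrame | None = None,
    positive_table: pd.DataFrame | None = None,
    n_negative: int = 0,
    positive_requests: list[tuple[str, str, int]] | None = None,
    k: int = 3,
    primer_pair: str = "pairA",
    mode: str = "standard",
    seed: int = 0,
    genome: GenomeAssembly | None = None,
    out_dir: str | Path | None = None,
) -> AssemblyResult:
    """Merge libraries, dedup, filter sites, pad, and emit order-ready oligos.

    ``mode`` is "standard" (k spacers per golden-gate oligomer) or "sensor"
    (one oligo per guide, requires ``genome`` for sensor extraction). A
    single ``seed`` governs control selection, padding, and shuffling.
    """
    if mode not in ("standard", "sensor"):
        raise ValueError(f"unknown assembly mode {mode!r}")
    if mode == "sensor" and genome is None:
        raise ValueError("sensor mode requires the genome for sensor extraction")

    selected_neg, selected_pos = oligo_assembly.select_controls(
        negative_table,
        positive_table,
        n_negative=n_negative,
        positive_requests=positive_requests,
        seed=seed,
    )
    pieces = [t for t in (target_table, selected_pos, selected_neg) if len(t)]
    merged = pd.concat(pieces, ignore_index=True) if pieces else target_table
    audit = AssemblyAudit(n_input=len(merged))

    unique, dup_dropped = oligo_assembly.deduplicate(merged)
    audit.n_dedup_dropped = len(dup_dropped)

    if mode == "standard":
        template = oligo_assembly.default_oligomer_template(k=k, primer_pair=primer_pair)
    else:
        template = oligo_assembly.default_sensor_template(primer_pair=primer_pair)
        k = 1
    kept, site_dropped = oligo_assembly.filter_restriction_sites(unique, template)
    audit.n_restriction_dropped = len(site_dropped)

    # padding pools: unused controls that survive the same spacer checks
    def _pool(full: pd.DataFrame | None, selected: pd.DataFrame) -> pd.DataFrame:
        if full is None or not len(full):
            return kept.iloc[0:0]
        pool = full[~full["guide_id"].isin(selected.get("guide_id", pd.Series(dtype=str)))]
        pool = pool[~pool["protospacer"].isin(kept["protospacer"])]
        pool_kept, _ = oligo_assembly.filter_restriction_sites(pool, template)
        return pool_kept

    neg_pool = _pool(negative_table, selected_neg)
    pos_pool = _pool(positive_table, selected_pos)

    final_table, padding = oligo_assembly.pad_to_multiple(
        kept, neg_pool, pos_pool, k=k, seed=seed
    )
    audit.n_padding_added = len(padding.added_negative) + len(padding.added_positive)
    audit.n_padding_removed = len(padding.removed_target)

    if mode == "standard":
        oligos = oligo_assembly.assemble_oligomers(
            final_table, template, seed=seed, primer_pair=primer_pair
        )
    else:
        oligos, sensor_dropped = oligo_assembly.assemble_sensor_oligos(
            final_table, template, genome
        )
        audit.n_sensor_dropped = len(sensor_dropped)
        if len(sensor_dropped):
            final_table = final_table[
                ~final_table["guide_id"].isin(sensor_dropped["guide_id"])
            ].reset_index(drop=True)
    audit.n_manifest = len(final_table)

    result = AssemblyResult(
        final_table=final_table,
        oligos=oligos,
        audit=audit,
        padding_report=padding,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.order_file = oligo_assembly.write_order_file(
            oligos, out_dir / "oligo_order.txt"
        )
        result.manifest_file = oligo_assembly.write_prepared_library(
            final_table, oligos, out_dir / "Prepared_library.csv"
        )
        changes = {
            "added_negative": padding.added_negative,
            "added_positive": padding.added_positive,
            "removed_target": padding.removed_target,
            "duplicates_dropped": int(audit.n_dedup_dropped),
            "restriction_dropped": int(audit.n_restriction_dropped),
            "sensor_dropped": int(audit.n_sensor_dropped),
        }
        import json

        (out_dir / "change_report.json").write_text(json.dumps(changes, indent=2) + "\n")
    return result
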