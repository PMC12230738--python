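"""Per-editor mutational-outcome prediction for designed guides.

For each guide x base editor the maximally edited allele is constructed:
every occurrence of the editor's reference base within the activity window
is substituted simultaneously (one combined multi-base allele), optionally
sparing Cs in GC motifs, which APOBEC-1 cytosine deaminases disfavour.
The allele is then classified against every overlapping transcript by
splicing-aware retranslation of the mutated coding sequence, and the
per-isoform consequences are aggregated into six classes:

    splice > nonsense > missense > synonymous > noncoding, plus no_edit
    for guides with no editable base in the window.

Window positions are 1-based protospacer coordinates with position 1 at the
5' (PAM-distal) end — the convention of the base-editing literature, where
e.g. BE4 is maximally active around positions 4-8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from Bio.Seq import Seq

from .genome_model import GenomeAssembly, TranscriptModel
from .guide_design import GuideRNA

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: aggregation severity, most severe first; no_edit handled separately
SEVERITY = ("splice", "nonsense", "missense", "synonymous", "noncoding")

SPLICE_FLANK = 2  # intronic nt adjacent to each exon boundary (GT/AG positions)
ANNOTATION_FLANK = 8  # intron flank within which a transcript is "overlapping"


@dataclass(frozen=True)
class BaseEditor:
    """A base editor: deaminase chemistry plus an activity window.

    ``window_start``/``window_end`` are 1-based protospacer positions
    (position 1 = PAM-distal 5' nucleotide). ``exclude_gc`` spares Cs
    immediately preceded by G on the protospacer strand.
    """

    name: str
    window_start: int
    window_end: int
    ref_base: str
    alt_base: str
    exclude_gc: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.window_start <= self.window_end:
            raise ValueError(f"{self.name}: invalid window")
        if self.ref_base == self.alt_base:
            raise ValueError(f"{self.name}: ref_base equals alt_base")
        if self.ref_base not in "AC":
            raise ValueError(f"{self.name}: ref_base must be A or C")


#: common editors; extensible through load_base_editors
BUILTIN_BASE_EDITORS: dict[str, BaseEditor] = {
    "BE4": BaseEditor(name="BE4", window_start=4, window_end=8,
                      ref_base="C", alt_base="T", exclude_gc=True),
    "ABE8e": BaseEditor(name="ABE8e", window_start=4, window_end=8,
                        ref_base="A", alt_base="G"),
}


def load_base_editors(config_path: str | Path | None = None) -> dict[str, BaseEditor]:
    """Built-in editors, optionally extended from YAML.

    Schema per entry: ``{window: [4, 8], edit: "C>T", exclude_gc: false}``.
    """
    editors = dict(BUILTIN_BASE_EDITORS)
    if config_path is not None:
        raw = yaml.safe_load(Path(config_path).read_text()) or {}
        for name, cfg in raw.items():
            ref, alt = cfg["edit"].split(">")
            editors[name] = BaseEditor(
                name=name,
                window_start=int(cfg["window"][0]),
                window_end=int(cfg["window"][1]),
                ref_base=ref.strip().upper(),
                alt_base=alt.strip().upper(),
                exclude_gc=bool(cfg.get("exclude_gc", False)),
            )
    return editors


@dataclass
class PredictedEdit:
    """The maximally edited allele for one guide x editor pair."""

    guide_id: str
    editor_name: str
    substitutions: list[tuple[int, str, str]]  # (genomic pos, ref, alt), ref strand
    n_edited_bases: int
    chrom: str = ""
    per_transcript: list[tuple[str, tuple[str, ...], bool, bool]] = field(
        default_factory=list
    )  # (transcript_id, consequences, is_canonical, is_pick)
    aggregated_outcome: str = "no_edit"

    @property
    def variant_key(self) -> str:
        """Canonical key shared by guides inserting the same substitution set."""
        if not self.substitutions:
            return f"{self.editor_name}:no_edit:{self.guide_id}"
        subs = ";".join(
            f"{self.chrom}:g.{pos + 1}{ref}>{alt}"
            for pos, ref, alt in sorted(self.substitutions)
        )
        return subs


# ---------------------------------------------------------------------------
# Edit enumeration
# ---------------------------------------------------------------------------


def _protospacer_position_to_genomic(guide: GuideRNA, pos: int) -> int:
    """Map a 1-based protospacer position to a 0-based genomic coordinate."""
    s, e = guide.protospacer_interval
    if guide.strand == "+":
        return s + pos - 1
    return e - pos


def enumerate_edits(
    guide: GuideRNA, editor: BaseEditor, genome: GenomeAssembly
) -> PredictedEdit:
    """Construct the maximally edited allele within the activity window.

    Every occurrence of the editor's ref base at protospacer positions
    window_start..window_end is substituted simultaneously. With
    ``exclude_gc``, a C immediately preceded by G on the protospacer strand
    is spared; for position 1 the immediately 5' genomic base on the
    protospacer strand is consulted. Substitutions are reported on the
    reference strand (complemented for minus-strand guides).
    """
    subs: list[tuple[int, str, str]] = []
    L = len(guide.protospacer)
    w_end = min(editor.window_end, L)
    for pos in range(editor.window_start, w_end + 1):
        base = guide.protospacer[pos - 1]
        if base != editor.ref_base:
            continue
        if editor.exclude_gc and editor.ref_base == "C":
            if pos > 1:
                prev = guide.protospacer[pos - 2]
            else:
                gpos = _protospacer_position_to_genomic(guide, 0)  # one nt 5'
                chrom_len = genome.length(guide.chrom)
                if 0 <= gpos < chrom_len:
                    prev = genome.fetch(guide.chrom, gpos, gpos + 1)
                    if guide.strand == "-":
                        prev = prev.translate(COMPLEMENT)
                else:
                    prev = ""
            if prev == "G":
                continue
        gpos = _protospacer_position_to_genomic(guide, pos)
        if guide.strand == "+":
            ref, alt = editor.ref_base, editor.alt_base
        else:
            ref = editor.ref_base.translate(COMPLEMENT)
            alt = editor.alt_base.translate(COMPLEMENT)
        genome_ref = genome.fetch(guide.chrom, gpos, gpos + 1)
        if genome_ref != ref:
            raise ValueError(
                f"guide {guide.guide_id}: genome base {genome_ref} at {gpos} "
                f"does not match protospacer-derived ref {ref}"
            )
        subs.append((gpos, ref, alt))
    subs.sort()
    return PredictedEdit(
        guide_id=guide.guide_id,
        editor_name=editor.name,
        substitutions=subs,
        n_edited_bases=len(subs),
        chrom=guide.chrom,
        aggregated_outcome="no_edit" if not subs else "noncoding",
    )


# ---------------------------------------------------------------------------
# Consequence annotation
# ---------------------------------------------------------------------------


def _splice_site_positions(transcript: TranscriptModel) -> set[int]:
    """Genomic positions of the 2 intronic nt flanking each internal exon edge."""
    sites: set[int] = set()
    exons = transcript.exons
    for i, (s, e) in enumerate(exons):
        if i > 0:  # acceptor side: intronic bases just 5' of the exon
            sites.update(range(s - SPLICE_FLANK, s))
        if i < len(exons) - 1:  # donor side: intronic bases just 3' of the exon
            sites.update(range(e, e + SPLICE_FLANK))
    return sites


def _cds_genomic_positions(transcript: TranscriptModel) -> list[int]:
    """Genomic positions of CDS bases in reading-frame order."""
    pos = [p for s, e in transcript.cds for p in range(s, e)]
    return pos[::-1] if transcript.strand == "-" else pos


def classify_against_transcript(
    edit: PredictedEdit, transcript: TranscriptModel, genome: GenomeAssembly
) -> tuple[str, ...]:
    """All consequence classes the edited allele produces on one transcript.

    splice: any substitution in the 2 intronic nt adjacent to an exon edge.
    Coding substitutions are applied together to the spliced CDS which is
    retranslated: a lost start codon or a gained stop is nonsense; any other
    amino-acid change is missense; an unchanged protein with a changed CDS
    base is synonymous. Substitutions touching only UTR/intron are noncoding.
    """
    classes: list[str] = []
    splice_sites = _splice_site_positions(transcript)
    exonic = {p for s, e in transcript.exons for p in range(s, e)}
    cds_positions = _cds_genomic_positions(transcript)
    cds_index = {p: i for i, p in enumerate(cds_positions)}

    for pos, ref, _alt in edit.substitutions:
        actual = genome.fetch(transcript.chrom, pos, pos + 1)
        if actual != ref:
            raise ValueError(
                f"substitution ref {ref} at {transcript.chrom}:{pos} does not "
                f"match genome base {actual}"
            )

    if any(pos in splice_sites for pos, _, _ in edit.substitutions):
        classes.append("splice")

    coding = [(pos, alt) for pos, _, alt in edit.substitutions if pos in cds_index]
    if coding:
        cds_seq = list(transcript.cds_sequence(genome))
        for pos, alt in coding:
            if transcript.strand == "-":
                alt = alt.translate(COMPLEMENT)
            cds_seq[cds_index[pos]] = alt
        mutated = "".join(cds_seq)
        original = transcript.cds_sequence(genome)
        if mutated != original:
            orig_prot = str(Seq(original).translate())
            mut_prot = str(Seq(mutated).translate())
            # proteins include the terminal stop as '*'
            if mut_prot[0] != orig_prot[0] and orig_prot[0] == "M" and mut_prot[0] != "M":
                classes.append("nonsense")  # start codon lost
            elif "*" in mut_prot[:-1] and "*" not in orig_prot[:-1]:
                classes.append("nonsense")  # stop gained
            elif mut_prot != orig_prot:
                classes.append("missense")
            else:
                classes.append("synonymous")
        else:
            classes.append("synonymous")
    noncoding_touch = [
        pos
        for pos, _, _ in edit.substitutions
        if pos not in cds_index and pos not in splice_sites
    ]
    if noncoding_touch and not coding:
        classes.append("noncoding")
    del exonic
    return tuple(dict.fromkeys(classes))


def _overlapping_transcripts(
    edit: PredictedEdit, transcripts: Sequence[TranscriptModel]
) -> list[TranscriptModel]:
    out = []
    positions = [pos for pos, _, _ in edit.substitutions]
    for t in transcripts:
        if t.chrom != edit.chrom:
            continue
        windows = [(s - ANNOTATION_FLANK, e + ANNOTATION_FLANK) for s, e in t.exons]
        if any(s <= p < e for p in positions for s, e in windows):
            out.append(t)
    return out


def aggregate_outcome(
    per_transcript: Sequence[tuple[str, tuple[str, ...], bool, bool]],
) -> str:
    """Most severe class on the picked transcript; noncoding when none overlap."""
    if not per_transcript:
        return "noncoding"
    picked = [classes for _, classes, _, is_pick in per_transcript if is_pick]
    classes = picked[0] if picked else per_transcript[0][1]
    if not classes:
        return "noncoding"
    return min(classes, key=SEVERITY.index)


def annotate_consequence(
    edit: PredictedEdit,
    transcripts: Sequence[TranscriptModel],
    genome: GenomeAssembly,
    pick_rule: str = "canonical_else_longest_cds",
) -> PredictedEdit:
    """Classify the edit against every overlapping transcript and aggregate.

    A transcript overlaps when its exons extended by an 8-nt intron flank
    contain any substitution. The pick rule (a stand-in for VEP's --pick)
    selects the canonical transcript when it overlaps, else the overlapping
    transcript with the longest CDS; the aggregated outcome is the most
    severe class on the picked transcript. Edits overlapping no transcript
    are noncoding; empty substitution sets stay no_edit.
    """
    if not edit.substitutions:
        edit.per_transcript = []
        edit.aggregated_outcome = "no_edit"
        return edit
    overlapping = _overlapping_transcripts(edit, transcripts)
    if not overlapping:
        edit.per_transcript = []
        edit.aggregated_outcome = "noncoding"
        return edit

    if pick_rule != "canonical_else_longest_cds":
        raise ValueError(f"unknown pick rule: {pick_rule!r}")
    canonical = [t for t in overlapping if t.is_canonical]
    if canonical:
        pick = canonical[0]
    else:
        pick = sorted(overlapping, key=lambda t: (-t.cds_length(), t.transcript_id))[0]

    per_transcript = []
    for t in overlapping:
        classes = classify_against_transcript(edit, t, genome)
        if not classes:
            classes = ("noncoding",)
        is_pick = t.transcript_id == pick.transcript_id
        per_transcript.append((t.transcript_id, classes, t.is_canonical, is_pick))
    edit.per_transcript = per_transcript
    edit.aggregated_outcome = aggregate_outcome(per_transcript)
    return edit


def predict_outcome(
    guide: GuideRNA,
    editor: BaseEditor,
    genome: GenomeAssembly,
    transcripts: Sequence[TranscriptModel],
) -> PredictedEdit:
    """enumerate_edits followed by annotate_consequence."""
    edit = enumerate_edits(guide, editor, genome)
    return annotate_consequence(edit, transcripts, genome)


# ---------------------------------------------------------------------------
# Library-level annotation
# ---------------------------------------------------------------------------


def annotate_library(
    guides: Sequence[GuideRNA],
    editors: Sequence[BaseEditor],
    genome: GenomeAssembly,
    transcripts: Sequence[TranscriptModel],
) -> dict[str, pd.DataFrame]:
    """One annotation table per editor, aligned row-for-row with the guides.

    Columns: guide_id, substitutions (HGVS-like g. notation), variant_key
    (shared by guides inserting the same substitution set), n_edited_bases,
    per-isoform consequence strings, canonical/pick transcript ids, and the
    aggregated outcome.
    """
    if not editors:
        raise ValueError("at least one base editor required")
    blocks: dict[str, pd.DataFrame] = {}
    for editor in editors:
        rows = []
        for guide in guides:
            edit = predict_outcome(guide, editor, genome, transcripts)
            per_iso = "; ".join(
                f"{tid}:{'+'.join(classes)}" for tid, classes, _, _ in edit.per_transcript
            )
            canonical_ids = [tid for tid, _, c, _ in edit.per_transcript if c]
            pick_ids = [tid for tid, _, _, p in edit.per_transcript if p]
            rows.append(
                {
                    "guide_id": guide.guide_id,
                    "substitutions": ";".join(
                        f"{edit.chrom}:g.{pos + 1}{ref}>{alt}"
                        for pos, ref, alt in edit.substitutions
                    ),
                    "variant_key": edit.variant_key,
                    "n_edited_bases": edit.n_edited_bases,
                    "per_isoform_consequences": per_iso,
                    "canonical_transcript": ",".join(canonical_ids),
                    "pick_transcript": ",".join(pick_ids),
                    "aggregated_outcome": edit.aggregated_outcome,
                }
            )
        blocks[editor.name] = pd.DataFrame(rows)
    return blocks
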