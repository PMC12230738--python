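"""Genome and annotation loading, target resolution, and the synthetic fixture.

All internal coordinates are 0-based half-open. User-facing region strings
("chrom:start-end") and spreadsheet coordinates are 1-based inclusive, the
Ensembl convention; conversion happens only at the boundary.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO

log = logging.getLogger("betiler")

DNA_ALPHABET = set("ACGTN")

STOP_CODONS = ("TAA", "TAG", "TGA")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised when a genome or annotation file violates a structural invariant."""


class TargetResolutionError(ValueError):
    """Raised when user target entries cannot be resolved into valid regions."""


class RegionOrigin(str, Enum):
    GENE_CDS = "gene_cds"
    USER_REGION = "user_region"
    CONTROL_LOCUS = "control_locus"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeAssembly:
    """A reference genome held in memory as uppercase chromosome strings."""

    sequences: dict[str, str]
    assembly_label: str = ""

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not name:
                raise AnnotationError("empty chromosome name")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise AnnotationError(
                    f"chromosome {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of the 0-based half-open interval [start, end)."""
        return self.sequences[chrom][start:end]


@dataclass
class TranscriptModel:
    """One mRNA isoform: exon structure plus coding intervals.

    Exon and CDS intervals are 0-based half-open genomic tuples, sorted by
    start regardless of strand. A strand of "-" means the spliced transcript
    reads the reverse complement from the last interval backwards.
    """

    transcript_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    is_canonical: bool = False

    def validate(self, genome: GenomeAssembly) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.transcript_id}: strand must be + or -")
        chrom_len = genome.length(self.chrom)
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise AnnotationError(f"{self.transcript_id}: empty exon [{s},{e})")
            if s < prev_end:
                raise AnnotationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            if e > chrom_len or s < 0:
                raise AnnotationError(
                    f"{self.transcript_id}: exon [{s},{e}) outside {self.chrom} "
                    f"(length {chrom_len})"
                )
            prev_end = e
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise AnnotationError(
                    f"{self.transcript_id}: CDS [{cs},{ce}) not contained in any exon"
                )
        total = self.cds_length()
        if total > 0 and total % 3 != 0:
            raise AnnotationError(
                f"{self.transcript_id}: CDS length {total} is not a multiple of 3"
            )

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def cds_sequence(self, genome: GenomeAssembly) -> str:
        """Spliced coding sequence in reading-frame orientation (5'->3' mRNA)."""
        parts = [genome.fetch(self.chrom, s, e) for s, e in self.cds]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq

    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class TargetRegion:
    """A resolved genomic interval to be tiled with guides."""

    label: str
    chrom: str
    start: int
    end: int
    flank_nt: int = 0
    origin: RegionOrigin = RegionOrigin.USER_REGION

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise TargetResolutionError(
                f"region {self.label}: start {self.start} >= end {self.end}"
            )


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------


def load_genome(fasta_path: str | Path, assembly_label: str = "") -> GenomeAssembly:
    """Load a FASTA genome; sequences are uppercased, duplicate headers rejected."""
    path = Path(fasta_path)
    if not path.exists():
        raise FileNotFoundError(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise AnnotationError(f"duplicate FASTA header: {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise AnnotationError(f"no FASTA records parsed from {path}")
    return GenomeAssembly(sequences=sequences, assembly_label=assembly_label or path.stem)


def _canonical_fallback(models: list[TranscriptModel]) -> None:
    """Flag one canonical transcript per gene: longest CDS, ties by transcript_id."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_name, []).append(m)
    for gene, iso in by_gene.items():
        if any(m.is_canonical for m in iso):
            continue
        pick = sorted(iso, key=lambda m: (-m.cds_length(), m.transcript_id))[0]
        pick.is_canonical = True
        log.debug("no canonical tag for %s; flagged %s (longest CDS)", gene, pick.transcript_id)


def load_annotation(gff3_path: str | Path, genome: GenomeAssembly) -> list[TranscriptModel]:
    """Parse a GFF3 into one validated TranscriptModel per mRNA feature.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    The canonical flag is read from an ``Ensembl_canonical``-style tag when
    present; otherwise the transcript with the longest CDS per gene is flagged.
    """
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[TranscriptModel] = []
    for mrna in db.features_of_type("mRNA"):
        gene_name = mrna.attributes.get("gene_name", [None])[0]
        if gene_name is None:
            parents = list(db.parents(mrna, featuretype="gene"))
            if parents:
                gene_name = parents[0].attributes.get(
                    "Name", parents[0].attributes.get("gene_name", [parents[0].id])
                )[0]
            else:
                gene_name = mrna.id
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS"))
        tags = mrna.attributes.get("tag", []) + mrna.attributes.get("Ensembl_canonical", [])
        canonical = any("canonical" in t.lower() or t == "1" for t in tags)
        model = TranscriptModel(
            transcript_id=mrna.id,
            gene_name=gene_name,
            chrom=mrna.seqid,
            strand=mrna.strand,
            exons=exons,
            cds=cds,
            is_canonical=canonical,
        )
        if model.chrom not in genome.sequences:
            raise AnnotationError(
                f"{model.transcript_id}: chromosome {model.chrom!r} not in genome"
            )
        model.validate(genome)
        models.append(model)
    _canonical_fallback(models)
    return models


# ---------------------------------------------------------------------------
# Target resolution
# ---------------------------------------------------------------------------


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _subtract_intervals(
    intervals: list[tuple[int, int]], mask: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Trim every interval to its parts outside the (sorted, merged) mask."""
    out: list[tuple[int, int]] = []
    for s, e in intervals:
        cur = s
        for ms, me in mask:
            if me <= cur or ms >= e:
                continue
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def parse_region_string(entry: str) -> tuple[str, int, int]:
    """Parse "chrom:start-end" (1-based inclusive) into 0-based half-open."""
    try:
        chrom, span = entry.rsplit(":", 1)
        start_s, end_s = span.replace(",", "").split("-")
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise TargetResolutionError(f"malformed region string {entry!r}") from exc
    if start < 1 or end < start:
        raise TargetResolutionError(f"invalid coordinates in region string {entry!r}")
    return chrom, start - 1, end


def _load_blacklist(bed_path: str | Path) -> dict[str, list[tuple[int, int]]]:
    mask: dict[str, list[tuple[int, int]]] = {}
    for line in Path(bed_path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end = line.split("\t")[:3]
        mask.setdefault(chrom, []).append((int(start), int(end)))
    return {c: _merge_intervals(iv) for c, iv in mask.items()}


def resolve_targets(
    entries: Sequence[str],
    annotation: Sequence[TranscriptModel],
    genome: GenomeAssembly,
    flank_nt: int = 0,
    canonical_only: bool = False,
    blacklist: str | Path | dict[str, list[tuple[int, int]]] | None = None,
    max_total_span_nt: int = 1_500_000,
    origin_overrides: dict[str, RegionOrigin] | None = None,
) -> list[TargetRegion]:
    """Resolve gene names and region strings into non-overlapping TargetRegions.

    Gene entries expand to the union of CDS intervals over all isoforms (or
    the canonical isoform only), each extended by ``flank_nt`` and merged per
    gene. Region entries are taken verbatim plus flanks. Regions intersecting
    the blacklist are trimmed to their non-blacklisted parts. Overlap between
    regions resolved from *different* entries is an error, since it would
    produce duplicate guides.
    """
    if flank_nt < 0:
        raise TargetResolutionError("flank_nt must be >= 0")
    if isinstance(blacklist, (str, Path)):
        blacklist = _load_blacklist(blacklist)
    blacklist = blacklist or {}
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in annotation:
        by_gene.setdefault(m.gene_name, []).append(m)

    regions: list[TargetRegion] = []
    per_entry: list[list[TargetRegion]] = []
    for entry in entries:
        if ":" in entry and "-" in entry.rsplit(":", 1)[-1]:
            chrom, start, end = parse_region_string(entry)
            if chrom not in genome.sequences:
                raise TargetResolutionError(f"unknown chromosome in {entry!r}")
            if end > genome.length(chrom):
                raise TargetResolutionError(
                    f"region {entry!r} extends beyond {chrom} (length {genome.length(chrom)})"
                )
            raw = [(start, end)]
            origin = RegionOrigin.USER_REGION
            label = entry
        else:
            if entry not in by_gene:
                raise TargetResolutionError(f"unknown gene name: {entry!r}")
            models = by_gene[entry]
            if canonical_only:
                models = [m for m in models if m.is_canonical]
            raw = [iv for m in models for iv in m.cds]
            if not raw:
                raise TargetResolutionError(f"gene {entry!r} has no coding sequence")
            chrom = models[0].chrom
            origin = RegionOrigin.GENE_CDS
            label = entry
        if origin_overrides and label in origin_overrides:
            origin = origin_overrides[label]

        chrom_len = genome.length(chrom)
        flanked = []
        for s, e in raw:
            fs, fe = s - flank_nt, e + flank_nt
            if fs < 0 or fe > chrom_len:
                log.warning("region %s clipped at chromosome bounds", label)
            flanked.append((max(0, fs), min(chrom_len, fe)))
        merged = _merge_intervals(flanked)
        kept = _subtract_intervals(merged, blacklist.get(chrom, []))
        if not kept:
            log.warning("entry %r lies entirely within the blacklist; skipped", label)
            per_entry.append([])
            continue
        if kept != merged:
            log.info("entry %r trimmed against blacklist", label)
        entry_regions = [
            TargetRegion(label=label, chrom=chrom, start=s, end=e,
                         flank_nt=flank_nt, origin=origin)
            for s, e in kept
        ]
        per_entry.append(entry_regions)
        regions.extend(entry_regions)

    # regions from different entries must not overlap (duplicate-guide guard)
    for i, group_a in enumerate(per_entry):
        for group_b in per_entry[i + 1:]:
            for a in group_a:
                for b in group_b:
                    if a.chrom == b.chrom and a.start < b.end and b.start < a.end:
                        raise TargetResolutionError(
                            f"resolved regions overlap: {a.label!r} "
                            f"[{a.start},{a.end}) and {b.label!r} [{b.start},{b.end})"
                        )

    total = sum(r.end - r.start for r in regions)
    if total > max_total_span_nt:
        raise TargetResolutionError(
            f"total target span {total} nt exceeds the cap of {max_total_span_nt} nt"
        )
    return regions


def write_bed(regions: Sequence[TargetRegion], path: str | Path) -> Path:
    """Write regions as 0-based half-open BED, name column = label."""
    path = Path(path)
    with path.open("w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")
    return path


def read_bed(path: str | Path) -> list[TargetRegion]:
    """Read a BED file written by :func:`write_bed` back into TargetRegions."""
    regions = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        label = fields[3] if len(fields) > 3 else f"{chrom}:{start + 1}-{end}"
        regions.append(TargetRegion(label=label, chrom=chrom, start=start, end=end))
    return regions


# ---------------------------------------------------------------------------
# Synthetic fixture generator
# ---------------------------------------------------------------------------


@dataclass
class FixturePaths:
    """File paths plus the loci the fixture designates for control design."""

    fasta: Path
    gff3: Path
    blacklist: Path
    essential_gene: str = "ESS1"
    safe_harbor_region: str = ""  # "chrom:start-end", 1-based inclusive


def _random_codons(rng: random.Random, n: int) -> str:
    """n random sense codons (no stop)."""
    codons = []
    while len(codons) < n:
        codon = "".join(rng.choice("ACGT") for _ in range(3))
        if codon not in STOP_CODONS:
            codons.append(codon)
    return "".join(codons)


def _random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def generate_fixture(
    out_dir: str | Path,
    seed: int = 1,
    n_genes: int = 3,
    chrom_length: int = 9000,
) -> FixturePaths:
    """Write a deterministic toy genome, GFF3 annotation and blacklist BED.

    The genome has two chromosomes: ``chr1`` carries ``n_genes`` two-isoform
    genes (each with three codon-aligned CDS chunks separated by GT..AG
    introns; isoform B skips the middle chunk), the first of which is the
    designated essential gene ``ESS1``. ``chr2`` carries the intergenic
    safe-harbor locus ``SAFE1`` used for negative-control design, plus a
    small blacklist interval. Every transcript passes annotation validation
    by construction: the CDS starts with ATG, ends at a stop codon, and
    contains no internal stop.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)

    chr1: list[str] = []
    gff_lines = ["##gff-version 3"]
    pos = 0

    def emit(chunk: str) -> tuple[int, int]:
        nonlocal pos
        start = pos
        chr1.append(chunk)
        pos += len(chunk)
        return start, pos

    for g in range(n_genes):
        gene_name = "ESS1" if g == 0 else f"GENE{g + 1}"
        strand = "+" if g % 2 == 0 else "-"
        emit(_random_dna(rng, rng.randint(120, 200)))  # intergenic spacer

        # codon-aligned CDS chunks: removing the middle one keeps the frame
        n1, n2, n3 = rng.randint(8, 14), rng.randint(6, 10), rng.randint(8, 14)
        chunk1 = "ATG" + _random_codons(rng, n1 - 1)
        chunk2 = _random_codons(rng, n2)
        chunk3 = _random_codons(rng, n3 - 1) + rng.choice(STOP_CODONS)
        utr5 = _random_dna(rng, rng.randint(10, 30))
        utr3 = _random_dna(rng, rng.randint(10, 30))
        intron1 = "GT" + _random_dna(rng, rng.randint(40, 80)) + "AG"
        intron2 = "GT" + _random_dna(rng, rng.randint(40, 80)) + "AG"

        if strand == "+":
            parts = [utr5 + chunk1, intron1, chunk2, intron2, chunk3 + utr3]
        else:
            # lay down the reverse complement so the - strand reads the mRNA
            parts = [
                revcomp(chunk3 + utr3),
                revcomp(intron2),
                revcomp(chunk2),
                revcomp(intron1),
                revcomp(utr5 + chunk1),
            ]
        coords = [emit(p) for p in parts]

        if strand == "+":
            exon1 = coords[0]
            exon2 = coords[2]
            exon3 = coords[4]
            cds1 = (exon1[0] + len(utr5), exon1[1])
            cds2 = exon2
            cds3 = (exon3[0], exon3[0] + len(chunk3))
        else:
            exon1 = coords[4]  # genomically last part holds utr5+chunk1 (revcomp)
            exon2 = coords[2]
            exon3 = coords[0]
            cds1 = (exon1[0], exon1[1] - len(utr5))
            cds2 = exon2
            cds3 = (exon3[1] - len(chunk3), exon3[1])
        # isoform A: all three chunks; isoform B: skips the middle chunk
        iso = [
            (f"{gene_name}.t1", [exon1, exon2, exon3], [cds1, cds2, cds3], True),
            (f"{gene_name}.t2", [exon1, exon3], [cds1, cds3], False),
        ]
        gene_start = min(exon3[0], exon1[0])
        gene_end = max(exon3[1], exon1[1])
        gff_lines.append(
            f"chr1\tbetiler\tgene\t{gene_start + 1}\t{gene_end}\t.\t{strand}\t.\t"
            f"ID=gene:{gene_name};Name={gene_name}"
        )
        for tid, exons, cds, canonical in iso:
            exons = sorted(exons)
            cds = sorted(cds)
            tag = ";tag=Ensembl_canonical" if canonical else ""
            gff_lines.append(
                f"chr1\tbetiler\tmRNA\t{exons[0][0] + 1}\t{exons[-1][1]}\t.\t{strand}\t.\t"
                f"ID={tid};Parent=gene:{gene_name};gene_name={gene_name}{tag}"
            )
            for i, (s, e) in enumerate(exons, 1):
                gff_lines.append(
                    f"chr1\tbetiler\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                    f"ID={tid}.exon{i};Parent={tid}"
                )
            for i, (s, e) in enumerate(cds, 1):
                # every CDS chunk is codon-aligned by construction -> phase 0
                gff_lines.append(
                    f"chr1\tbetiler\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\t"
                    f"ID={tid}.cds{i};Parent={tid}"
                )

    if pos < chrom_length:
        emit(_random_dna(rng, chrom_length - pos))
    chr1_seq = "".join(chr1)

    chr2_len = 1200
    chr2_seq = _random_dna(rng, chr2_len)
    safe_start, safe_end = 200, 500  # intergenic safe-harbor locus on chr2
    bl_start, bl_end = 800, 900

    fasta = out_dir / "fixture_genome.fa"
    with fasta.open("w") as fh:
        for name, seq in (("chr1", chr1_seq), ("chr2", chr2_seq)):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    gff3 = out_dir / "fixture_annotation.gff3"
    gff3.write_text("\n".join(gff_lines) + "\n")

    blacklist = out_dir / "fixture_blacklist.bed"
    blacklist.write_text(f"chr2\t{bl_start}\t{bl_end}\tblacklist1\n")

    return FixturePaths(
        fasta=fasta,
        gff3=gff3,
        blacklist=blacklist,
        essential_gene="ESS1",
        safe_harbor_region=f"chr2:{safe_start + 1}-{safe_end}",
    )
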