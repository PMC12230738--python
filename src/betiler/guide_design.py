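"""Protospacer scanning against a Cas variant's PAM set.

Both strands of every resolved target region are scanned for full-length
protospacers with a 3'-adjacent PAM matching one of the variant's IUPAC
patterns. A guide belongs to a region if its protospacer overlaps the region
by at least one nucleotide, so feature boundaries remain reachable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import yaml

from .genome_model import GenomeAssembly, TargetRegion, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class LibraryType(str, Enum):
    TARGET = "target"
    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class CasVariant:
    """A Cas9-family nuclease defined by its PAM requirement.

    Only 3'-PAM architectures are supported; ``is_spcas9_family`` gates
    CFD off-target filtering and on-target scoring downstream.
    """

    name: str
    pam_patterns: tuple[str, ...]
    pam_side: str = "3prime"
    protospacer_length: int = 20
    is_spcas9_family: bool = True

    def __post_init__(self) -> None:
        if self.pam_side != "3prime":
            raise ValueError(
                f"{self.name}: only 3'-PAM Cas variants are supported in this release"
            )
        if not self.pam_patterns:
            raise ValueError(f"{self.name}: at least one PAM pattern required")
        lengths = {len(p) for p in self.pam_patterns}
        if len(lengths) != 1:
            raise ValueError(f"{self.name}: PAM patterns must share one length")
        for p in self.pam_patterns:
            bad = set(p) - set(IUPAC)
            if bad:
                raise ValueError(f"{self.name}: non-IUPAC characters in PAM: {bad}")

    @property
    def pam_length(self) -> int:
        return len(self.pam_patterns[0])

    def pam_matches(self, pam: str) -> bool:
        if len(pam) != self.pam_length:
            return False
        return any(
            all(base in IUPAC[sym] for base, sym in zip(pam, pat))
            for pat in self.pam_patterns
        )

    def allowed_pams(self) -> frozenset[str]:
        """All concrete PAM sequences matching at least one pattern."""
        from itertools import product

        out: set[str] = set()
        for pat in self.pam_patterns:
            for combo in product(*(IUPAC[sym] for sym in pat)):
                out.add("".join(combo))
        return frozenset(out)


#: Shipped defaults; users may extend via YAML config (load_cas_variants).
BUILTIN_CAS_VARIANTS: dict[str, CasVariant] = {
    "SpCas9": CasVariant(name="SpCas9", pam_patterns=("NGG",)),
    "SpG": CasVariant(name="SpG", pam_patterns=("NGG", "NGA", "NGC", "NGT")),
    "SpRY": CasVariant(name="SpRY", pam_patterns=("NNN",)),
}


def load_cas_variants(config_path: str | Path | None = None) -> dict[str, CasVariant]:
    """Built-in Cas variants, optionally extended/overridden from a YAML file.

    YAML schema per entry::

        SpG-custom:
          pam_patterns: [NGG, NGA]
          protospacer_length: 20
          is_spcas9_family: true
    """
    variants = dict(BUILTIN_CAS_VARIANTS)
    if config_path is not None:
        raw = yaml.safe_load(Path(config_path).read_text()) or {}
        for name, cfg in raw.items():
            variants[name] = CasVariant(
                name=name,
                pam_patterns=tuple(cfg["pam_patterns"]),
                pam_side=cfg.get("pam_side", "3prime"),
                protospacer_length=int(cfg.get("protospacer_length", 20)),
                is_spcas9_family=bool(cfg.get("is_spcas9_family", True)),
            )
    return variants


@dataclass
class GuideRNA:
    """One designed sgRNA: protospacer + PAM at a fixed genomic locus.

    ``protospacer`` and ``pam`` are given in protospacer-strand orientation
    (5'->3'); for minus-strand guides they are the reverse complement of the
    reference. ``protospacer_interval`` is 0-based half-open on the reference.
    """

    guide_id: str
    protospacer: str
    pam: str
    chrom: str
    strand: str
    protospacer_interval: tuple[int, int]
    source_label: str
    library_type: LibraryType = LibraryType.TARGET
    n_offtargets: int | None = None
    max_offtarget_cfd: float | None = None
    on_target_score: float | None = None


def _guide_id(chrom: str, start: int, end: int, strand: str) -> str:
    return f"{chrom}:{start}-{end}:{strand}"


def scan_guides(
    region: TargetRegion,
    genome: GenomeAssembly,
    cas: CasVariant,
    library_type: LibraryType = LibraryType.TARGET,
) -> list[GuideRNA]:
    """Enumerate every guide whose protospacer overlaps ``region`` by >=1 nt.

    Output is sorted by (chrom, start, strand); protospacers containing N are
    dropped. Guides are emitted wherever the full protospacer + 3' PAM fits
    inside the chromosome, even when the PAM itself lies outside the region.
    """
    L = cas.protospacer_length
    P = cas.pam_length
    chrom_seq = genome.sequences[region.chrom]
    chrom_len = len(chrom_seq)
    if region.end > chrom_len or region.start < 0:
        raise ValueError(
            f"region {region.label} [{region.start},{region.end}) outside "
            f"{region.chrom} (length {chrom_len})"
        )

    guides: list[GuideRNA] = []
    # candidate protospacer starts: overlap region by >=1 nt and fit with PAM
    lo = max(0, region.start - L + 1)
    hi = min(region.end, chrom_len)  # exclusive bound on start+1 via overlap
    for start in range(lo, hi):
        end = start + L
        if end > chrom_len:
            break
        # + strand: PAM immediately 3' of the protospacer
        if end + P <= chrom_len:
            proto = chrom_seq[start:end]
            pam = chrom_seq[end : end + P]
            if "N" not in proto and cas.pam_matches(pam):
                guides.append(
                    GuideRNA(
                        guide_id=_guide_id(region.chrom, start, end, "+"),
                        protospacer=proto,
                        pam=pam,
                        chrom=region.chrom,
                        strand="+",
                        protospacer_interval=(start, end),
                        source_label=region.label,
                        library_type=library_type,
                    )
                )
        # - strand: protospacer occupies [start, end); PAM is the revcomp of
        # the P bases genomically 5' of it
        if start - P >= 0:
            proto = revcomp(chrom_seq[start:end])
            pam = revcomp(chrom_seq[start - P : start])
            if "N" not in proto and cas.pam_matches(pam):
                guides.append(
                    GuideRNA(
                        guide_id=_guide_id(region.chrom, start, end, "-"),
                        protospacer=proto,
                        pam=pam,
                        chrom=region.chrom,
                        strand="-",
                        protospacer_interval=(start, end),
                        source_label=region.label,
                        library_type=library_type,
                    )
                )
    guides.sort(key=lambda g: (g.chrom, g.protospacer_interval[0], g.strand))
    return guides


def scan_regions(
    regions: list[TargetRegion],
    genome: GenomeAssembly,
    cas: CasVariant,
    library_type: LibraryType = LibraryType.TARGET,
) -> list[GuideRNA]:
    """Scan a list of non-overlapping regions; concatenated per-region output."""
    out: list[GuideRNA] = []
    for region in regions:
        out.extend(scan_guides(region, genome, cas, library_type))
    return out
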