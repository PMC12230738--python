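"""Assembly of designed guides into order-ready oligonucleotide pools.

Two formats are supported: the multiplexed golden-gate format, where k
spacers are concatenated per oligomer between BsmBI landing sites for
type-IIS excision, and the sensor format, where each oligo carries one
spacer plus a ~40-nt copy of its genomic target site so editing outcomes
can be read out by sequencing the construct itself.

The shipped primer pairs, linkers and scaffold are placeholders satisfying
the structural invariants (correct BsmBI/EcoRI placement, site-free
elsewhere); laboratories should substitute the validated sequences of their
cloning protocol via template configuration. The computational contracts —
site counting on both strands, junction-reconstitution filtering, slot
layout, conservation accounting — are independent of the concrete sequences.

All assembly steps operate on library tables (pandas DataFrames) with at
least the columns ``guide_id``, ``protospacer``, ``library_type``; the
sensor path additionally needs ``chrom``, ``strand`` and the 1-based
``start``/``end`` coordinates of the protospacer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_model import GenomeAssembly, revcomp

log = logging.getLogger("betiler")

BSMBI_SITE = "CGTCTC"  # type IIS; reverse-complement strand reads GAGACG
ECORI_SITE = "GAATTC"  # palindromic

#: placeholder amplification primer pairs (site-free; verified in tests)
PRIMER_PAIRS: dict[str, tuple[str, str]] = {
    "pairA": ("AGGCACTTGCTCGTACGACG", "ATGTGGGCCCGGCACCTTAA"),
    "pairB": ("GTGTAACCCGTAGGGCACCT", "GTCGAGAGCAGTCCTTCGAC"),
}

#: standard SpCas9 sgRNA scaffold (site-free for BsmBI/EcoRI)
SGRNA_SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC"
)

#: site-free dummy spacer used to compute a template's designed site count
DUMMY_SPACER = "ACTGACTGACTGACTGACTG"


class AssemblyError(ValueError):
    """Raised when assembly preconditions are violated."""


def count_sites(sequence: str, sites: tuple[str, ...]) -> int:
    """Occurrences of recognition sites on both strands of ``sequence``.

    For each non-palindromic site both the site and its reverse complement
    are counted on the given strand (equivalent to scanning both strands);
    palindromic sites are counted once per locus.
    """
    total = 0
    seen: set[str] = set()
    for site in sites:
        rc = revcomp(site)
        motifs = {site} if rc == site else {site, rc}
        for motif in motifs:
            if motif in seen:
                continue
            seen.add(motif)
            start = 0
            while True:
                idx = sequence.find(motif, start)
                if idx == -1:
                    break
                total += 1
                start = idx + 1
    return total


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------


@dataclass
class OligomerTemplate:
    """Layout of a k-spacer golden-gate oligomer.

    sequence = left_primer + sum(linker_i + spacer_i) + terminal + right_primer
    Each linker sits 5' of its spacer slot and carries the designed BsmBI
    landing sites; ``designed_site_count`` is computed by assembling the
    template with site-free dummy spacers.
    """

    left_primer: str
    right_primer: str
    linkers: list[str]
    terminal: str
    k: int
    enzymes: tuple[str, ...] = (BSMBI_SITE,)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise AssemblyError("k must be >= 1")
        if len(self.linkers) != self.k:
            raise AssemblyError(f"expected {self.k} linkers, got {len(self.linkers)}")

    def assemble(self, spacers: list[str]) -> str:
        if len(spacers) != self.k:
            raise AssemblyError(f"expected {self.k} spacers, got {len(spacers)}")
        parts = [self.left_primer]
        for linker, spacer in zip(self.linkers, spacers):
            parts.append(linker)
            parts.append(spacer)
        parts.append(self.terminal)
        parts.append(self.right_primer)
        return "".join(parts)

    @property
    def designed_site_count(self) -> int:
        return count_sites(self.assemble([DUMMY_SPACER] * self.k), self.enzymes)


def default_oligomer_template(k: int = 3, primer_pair: str = "pairA") -> OligomerTemplate:
    """Placeholder k-slot template: one BsmBI site opening and closing each slot."""
    left, right = PRIMER_PAIRS[primer_pair]
    first = "T" + BSMBI_SITE + "A" + "CACCG"
    inner = "GTTTA" + revcomp(BSMBI_SITE) + "TCA" + BSMBI_SITE + "A" + "CACCG"
    terminal = "GTTTA" + revcomp(BSMBI_SITE) + "TG"
    linkers = [first] + [inner] * (k - 1)
    return OligomerTemplate(
        left_primer=left, right_primer=right, linkers=linkers, terminal=terminal, k=k
    )


@dataclass
class SensorTemplate:
    """Layout of a one-spacer sensor oligo.

    sequence = left_primer + bsmbi_arm + spacer + scaffold + sensor +
    ecori_arm + right_primer, where the sensor is the genomic window around
    the protospacer+PAM in protospacer-strand orientation.
    """

    left_primer: str
    right_primer: str
    bsmbi_arm: str
    scaffold: str
    ecori_arm: str
    sensor_upstream: int = 7
    sensor_pam: int = 3
    sensor_downstream: int = 10
    enzymes: tuple[str, ...] = (BSMBI_SITE, ECORI_SITE)

    def assemble(self, spacer: str, sensor: str) -> str:
        return (
            self.left_primer
            + self.bsmbi_arm
            + spacer
            + self.scaffold
            + sensor
            + self.ecori_arm
            + self.right_primer
        )

    def sensor_length(self, protospacer_length: int = 20) -> int:
        return (
            self.sensor_upstream
            + protospacer_length
            + self.sensor_pam
            + self.sensor_downstream
        )

    @property
    def designed_site_count(self) -> int:
        dummy_sensor = ("ACTG" * 10)[: self.sensor_length()]
        return count_sites(self.assemble(DUMMY_SPACER, dummy_sensor), self.enzymes)


def default_sensor_template(primer_pair: str = "pairA") -> SensorTemplate:
    left, right = PRIMER_PAIRS[primer_pair]
    return SensorTemplate(
        left_primer=left,
        right_primer=right,
        bsmbi_arm="TAT" + BSMBI_SITE + "A" + "CACCG",
        scaffold=SGRNA_SCAFFOLD,
        ecori_arm="CG" + ECORI_SITE + "GTAC",
    )


# ---------------------------------------------------------------------------
# Control selection
# ---------------------------------------------------------------------------


def select_controls(
    negative_table: pd.DataFrame | None,
    positive_table: pd.DataFrame | None,
    n_negative: int = 0,
    positive_requests: list[tuple[str, str, int]] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded random selection of negative and positive control guides.

    Negatives are drawn uniformly without replacement. Each positive request
    (editor, outcome, n) draws only from rows whose pick-isoform aggregated
    outcome for that editor (column ``<editor>.aggregated_outcome``) matches,
    and a guide granted to one request is excluded from the others. A
    shortfall raises, naming the request and the available count.

    Returns (selected_negatives, selected_positives); the pools left unused
    remain available for padding via their guide_ids.
    """
    rng = np.random.default_rng(seed)
    if n_negative > 0:
        if negative_table is None or len(negative_table) < n_negative:
            avail = 0 if negative_table is None else len(negative_table)
            raise AssemblyError(
                f"requested {n_negative} negative controls, only {avail} available"
            )
        idx = rng.choice(len(negative_table), size=n_negative, replace=False)
        selected_neg = negative_table.iloc[np.sort(idx)].copy()
    else:
        selected_neg = (
            negative_table.iloc[0:0].copy() if negative_table is not None else pd.DataFrame()
        )

    chosen_pos: list[pd.DataFrame] = []
    taken: set[str] = set()
    for editor, outcome, n in positive_requests or []:
        if n <= 0:
            continue
        if positive_table is None:
            raise AssemblyError(
                f"positive request ({editor}, {outcome}, {n}): no positive table supplied"
            )
        col = f"{editor}.aggregated_outcome"
        if col not in positive_table.columns:
            raise AssemblyError(
                f"positive table lacks column {col!r}; was the library annotated "
                f"with editor {editor}?"
            )
        pool = positive_table[
            (positive_table[col] == outcome)
            & ~positive_table["guide_id"].isin(taken)
        ]
        if len(pool) < n:
            raise AssemblyError(
                f"positive request ({editor}, {outcome}): requested {n}, "
                f"only {len(pool)} available"
            )
        idx = rng.choice(len(pool), size=n, replace=False)
        picked = pool.iloc[np.sort(idx)].copy()
        taken.update(picked["guide_id"])
        chosen_pos.append(picked)
    if chosen_pos:
        selected_pos = pd.concat(chosen_pos, ignore_index=True)
    else:
        selected_pos = (
            positive_table.iloc[0:0].copy() if positive_table is not None else pd.DataFrame()
        )
    return selected_neg, selected_pos


# ---------------------------------------------------------------------------
# Deduplication / filtering / padding
# ---------------------------------------------------------------------------

_TYPE_PRECEDENCE = {"target": 0, "positive": 1, "negative": 2}


def deduplicate(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop duplicate protospacers; target > positive > negative, then input order.

    Returns (unique, dropped); dropped rows carry a ``retained_twin`` column
    with the surviving guide_id.
    """
    order = table["library_type"].map(_TYPE_PRECEDENCE)
    ranked = table.assign(_rank=order, _input=np.arange(len(table)))
    ranked = ranked.sort_values(["_rank", "_input"], kind="stable")
    keep_mask = ~ranked["protospacer"].duplicated(keep="first")
    kept = ranked[keep_mask]
    dropped = ranked[~keep_mask].copy()
    twin = kept.set_index("protospacer")["guide_id"]
    dropped["retained_twin"] = dropped["protospacer"].map(twin)
    for gid, rid in zip(dropped["guide_id"], dropped["retained_twin"]):
        log.info("duplicate spacer: %s dropped in favour of %s", gid, rid)
    kept = kept.sort_values("_input").drop(columns=["_rank", "_input"])
    dropped = dropped.sort_values("_input").drop(columns=["_rank", "_input"])
    return kept.reset_index(drop=True), dropped.reset_index(drop=True)


def filter_restriction_sites(
    table: pd.DataFrame, template: OligomerTemplate | SensorTemplate
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove guides whose spacer creates or reconstitutes an extra site.

    A guide fails iff placing its spacer into *any* slot of the template
    (dummy spacers elsewhere) raises the recognition-site count — on either
    strand — above the template's designed count. This catches sites wholly
    inside the spacer as well as sites formed across spacer/linker junctions.
    """
    designed = template.designed_site_count
    keep_rows = []
    drop_rows = []
    for _, row in table.iterrows():
        spacer = row["protospacer"]
        if isinstance(template, OligomerTemplate):
            ok = True
            for slot in range(template.k):
                spacers = [DUMMY_SPACER] * template.k
                spacers[slot] = spacer
                if count_sites(template.assemble(spacers), template.enzymes) > designed:
                    ok = False
                    break
        else:
            dummy_sensor = ("ACTG" * 20)[: template.sensor_length(len(spacer))]
            ok = (
                count_sites(template.assemble(spacer, dummy_sensor), template.enzymes)
                <= designed
            )
        (keep_rows if ok else drop_rows).append(row)
    kept = pd.DataFrame(keep_rows).reset_index(drop=True) if keep_rows else table.iloc[0:0]
    removed = pd.DataFrame(drop_rows).reset_index(drop=True) if drop_rows else table.iloc[0:0]
    for gid in removed.get("guide_id", []):
        log.info("guide %s removed: extra restriction site in assembled oligomer", gid)
    return kept, removed


@dataclass
class PaddingReport:
    """Audit trail of library-size adjustments to reach a multiple of k."""

    added_negative: list[str] = field(default_factory=list)
    added_positive: list[str] = field(default_factory=list)
    removed_target: list[str] = field(default_factory=list)

    @property
    def net_change(self) -> int:
        return (
            len(self.added_negative) + len(self.added_positive) - len(self.removed_target)
        )


def pad_to_multiple(
    final_table: pd.DataFrame,
    negatives_pool: pd.DataFrame,
    positives_pool: pd.DataFrame,
    k: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, PaddingReport]:
    """Adjust the library size to a multiple of k, reporting every change.

    The deficit is filled first with seeded random draws from the unused
    negative pool, then from the unused positive pool; if both are exhausted,
    target guides are removed at random until |library| mod k = 0.
    """
    if k < 1:
        raise AssemblyError("k must be >= 1")
    rng = np.random.default_rng(seed)
    report = PaddingReport()
    table = final_table.reset_index(drop=True)
    deficit = (-len(table)) % k
    if deficit == 0:
        return table, report

    for pool, bucket in ((negatives_pool, report.added_negative),
                         (positives_pool, report.added_positive)):
        if deficit == 0:
            break
        if pool is None or len(pool) == 0:
            continue
        avail = pool[~pool["guide_id"].isin(table["guide_id"])]
        n_take = min(deficit, len(avail))
        if n_take > 0:
            idx = rng.choice(len(avail), size=n_take, replace=False)
            picked = avail.iloc[np.sort(idx)]
            table = pd.concat([table, picked], ignore_index=True)
            bucket.extend(picked["guide_id"])
            deficit -= n_take

    if deficit > 0:
        # padding pools exhausted: drop target guides to the multiple below
        n_remove = len(table) % k
        targets = table[table["library_type"] == "target"]
        if len(targets) < n_remove:
            raise AssemblyError("cannot reach a multiple of k: too few target guides")
        idx = rng.choice(len(targets), size=n_remove, replace=False)
        victims = set(targets.iloc[idx]["guide_id"])
        report.removed_target.extend(sorted(victims))
        table = table[~table["guide_id"].isin(victims)].reset_index(drop=True)

    if report.added_negative or report.added_positive or report.removed_target:
        log.info(
            "library padded to multiple of %d: +%d negative, +%d positive, "
            "-%d target",
            k,
            len(report.added_negative),
            len(report.added_positive),
            len(report.removed_target),
        )
    return table, report


# ---------------------------------------------------------------------------
# Oligomer instantiation
# ---------------------------------------------------------------------------


@dataclass
class Oligomer:
    oligo_id: str
    sequence: str
    members: list[str]  # guide_ids in slot order
    primer_pair: str = "pairA"


@dataclass
class SensorOligo:
    oligo_id: str
    guide_id: str
    sequence: str
    sensor: str


def assemble_oligomers(
    final_table: pd.DataFrame,
    template: OligomerTemplate,
    seed: int = 0,
    primer_pair: str = "pairA",
) -> list[Oligomer]:
    """Shuffle (seeded) and partition guides into k-spacer oligomers."""
    k = template.k
    if len(final_table) % k != 0:
        raise AssemblyError(
            f"library size {len(final_table)} is not a multiple of k={k}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(final_table))
    shuffled = final_table.iloc[order].reset_index(drop=True)
    oligomers = []
    for i in range(0, len(shuffled), k):
        group = shuffled.iloc[i : i + k]
        seq = template.assemble(list(group["protospacer"]))
        oligomers.append(
            Oligomer(
                oligo_id=f"oligo_{i // k + 1:05d}",
                sequence=seq,
                members=list(group["guide_id"]),
                primer_pair=primer_pair,
            )
        )
    return oligomers


def extract_sensor(
    row: pd.Series, genome: GenomeAssembly, template: SensorTemplate
) -> str | None:
    """Genomic sensor window around protospacer+PAM, protospacer-strand.

    Returns None when the window is clipped by a chromosome end.
    """
    chrom = row["chrom"]
    start = int(row["start"]) - 1  # table coordinates are 1-based inclusive
    end = int(row["end"])
    up, pam, down = template.sensor_upstream, template.sensor_pam, template.sensor_downstream
    chrom_len = genome.length(chrom)
    if row["strand"] == "+":
        lo, hi = start - up, end + pam + down
        if lo < 0 or hi > chrom_len:
            return None
        return genome.fetch(chrom, lo, hi)
    lo, hi = start - pam - down, end + up
    if lo < 0 or hi > chrom_len:
        return None
    return revcomp(genome.fetch(chrom, lo, hi))


def assemble_sensor_oligos(
    final_table: pd.DataFrame,
    template: SensorTemplate,
    genome: GenomeAssembly,
) -> tuple[list[SensorOligo], pd.DataFrame]:
    """One sensor oligo per guide; guides near chromosome ends are dropped.

    Returns (oligos, dropped_rows). Restriction filtering against
    {BsmBI, EcoRI} must be applied beforehand via filter_restriction_sites;
    sensors that still introduce extra sites (the sensor window itself may
    contain one) are dropped here with a warning.
    """
    designed = template.designed_site_count
    oligos: list[SensorOligo] = []
    dropped = []
    for i, (_, row) in enumerate(final_table.iterrows(), start=1):
        sensor = extract_sensor(row, genome, template)
        if sensor is None:
            log.warning(
                "guide %s dropped: sensor window clipped at chromosome end",
                row["guide_id"],
            )
            dropped.append(row)
            continue
        seq = template.assemble(row["protospacer"], sensor)
        if count_sites(seq, template.enzymes) > designed:
            log.warning(
                "guide %s eliminated: extra BsmBI/EcoRI site in sensor oligo",
                row["guide_id"],
            )
            dropped.append(row)
            continue
        oligos.append(
            SensorOligo(
                oligo_id=f"sensor_{i:05d}",
                guide_id=row["guide_id"],
                sequence=seq,
                sensor=sensor,
            )
        )
    dropped_df = (
        pd.DataFrame(dropped).reset_index(drop=True) if dropped else final_table.iloc[0:0]
    )
    return oligos, dropped_df


# ---------------------------------------------------------------------------
# Output files
# ---------------------------------------------------------------------------


def write_order_file(oligos: list[Oligomer] | list[SensorOligo], path: str | Path) -> Path:
    """Order-ready text file: one 5'->3' oligonucleotide sequence per line."""
    path = Path(path)
    with path.open("w") as fh:
        for oligo in oligos:
            fh.write(oligo.sequence + "\n")
    return path


def write_prepared_library(
    final_table: pd.DataFrame,
    oligos: list[Oligomer] | list[SensorOligo],
    path: str | Path,
) -> Path:
    """Prepared_library.csv: one row per retained guide with oligo id and slot."""
    slot_of: dict[str, tuple[str, int]] = {}
    for oligo in oligos:
        if isinstance(oligo, Oligomer):
            for slot, gid in enumerate(oligo.members, start=1):
                slot_of[gid] = (oligo.oligo_id, slot)
        else:
            slot_of[oligo.guide_id] = (oligo.oligo_id, 1)
    out = final_table.copy()
    out["oligo_id"] = out["guide_id"].map(lambda g: slot_of.get(g, ("", 0))[0])
    out["slot"] = out["guide_id"].map(lambda g: slot_of.get(g, ("", 0))[1])
    out = out[out["oligo_id"] != ""].reset_index(drop=True)
    path = Path(path)
    out.to_csv(path, index=False)
    return path
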