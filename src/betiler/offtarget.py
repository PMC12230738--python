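"""Genome-wide off-target enumeration and variant-adjusted CFD scoring.

The Cutting Frequency Determination (CFD) score of a candidate off-target
site is the product of per-position mismatch penalty factors and a PAM
factor. For engineered SpCas9 variants with relaxed PAM requirements the PAM
factor vector is adjusted conservatively: every PAM the variant can use is
assigned 100% cutting efficiency (factor 1.0) and every other PAM 0%, while
the mismatch tolerance profile is assumed to be shared across SpCas9
variants. Sites with a disallowed PAM therefore score exactly 0 and are
excluded at enumeration time, which is mathematically identical to scoring
them and cheaper.

The shipped per-position mismatch factor table
(``data/cfd_mismatch_penalties_synthetic.tsv``) is a synthetic stand-in
constructed to satisfy the scheme's structural constraints — matched bases
have factor 1, all factors lie in [0, 1], penalties grow toward the
PAM-proximal end, and wobble-like mismatches are better tolerated. Users
with an experimentally derived table can load their own via
:func:`load_penalty_matrix`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .genome_model import GenomeAssembly, revcomp
from .guide_design import CasVariant, GuideRNA

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


class ScoringError(ValueError):
    """Raised when the penalty matrix cannot score a base combination."""


# ---------------------------------------------------------------------------
# Penalty matrix
# ---------------------------------------------------------------------------


@dataclass
class MismatchPenaltyMatrix:
    """CFD penalty factors: per-position mismatch factors plus a PAM vector.

    ``mismatch_penalty`` maps (position, guide_base, offtarget_base) to a
    factor in [0, 1]; positions are 1-based from the 5' (PAM-distal) end of
    the protospacer, and both bases are given on the protospacer strand.
    ``pam_factor`` maps concrete PAM sequences to factors; PAMs absent from
    the map score 0.
    """

    mismatch_penalty: dict[tuple[int, str, str], float]
    pam_factor: dict[str, float]

    def __post_init__(self) -> None:
        for key, f in self.mismatch_penalty.items():
            if not 0.0 <= f <= 1.0:
                raise ScoringError(f"mismatch factor out of [0,1] at {key}: {f}")
        for pam, f in self.pam_factor.items():
            if not 0.0 <= f <= 1.0:
                raise ScoringError(f"PAM factor out of [0,1] for {pam}: {f}")

    def factor(self, position: int, guide_base: str, offtarget_base: str) -> float:
        if guide_base == offtarget_base:
            return 1.0
        try:
            return self.mismatch_penalty[(position, guide_base, offtarget_base)]
        except KeyError as exc:
            raise ScoringError(
                f"no penalty factor for position {position}, "
                f"{guide_base}->{offtarget_base}"
            ) from exc


def load_penalty_matrix(
    tsv_path: str | Path | None = None,
    cas: CasVariant | None = None,
) -> MismatchPenaltyMatrix:
    """Load mismatch factors from TSV and build the variant-adjusted PAM vector.

    The TSV has columns ``position  guide_base  offtarget_base  factor``.
    When ``cas`` is given, its allowable PAMs get factor 1.0 and all other
    PAMs 0 (absent from the map) — the variant-adjusted scheme.
    """
    if tsv_path is None:
        ref = importlib.resources.files("betiler").joinpath(
            "data/cfd_mismatch_penalties_synthetic.tsv"
        )
        text = ref.read_text()
    else:
        text = Path(tsv_path).read_text()
    mismatch: dict[tuple[int, str, str], float] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("position"):
            continue
        pos_s, gb, ob, f_s = line.split("\t")
        mismatch[(int(pos_s), gb, ob)] = float(f_s)
    pam_factor: dict[str, float] = {}
    if cas is not None:
        pam_factor = {pam: 1.0 for pam in cas.allowed_pams()}
    return MismatchPenaltyMatrix(mismatch_penalty=mismatch, pam_factor=pam_factor)


def build_synthetic_penalty_table(protospacer_length: int = 20) -> str:
    """Construct the synthetic mismatch factor table (TSV text).

    Stand-in for an experimentally derived CFD mismatch table. Construction:
    factor(p, g, t) = tolerance(g, t) * (1 - 0.8 * (p - 1) / (L - 1)),
    so PAM-distal mismatches (position 1) are well tolerated and PAM-proximal
    ones strongly penalised; transition-like mismatches (purine<->purine,
    pyrimidine<->pyrimidine) get tolerance 0.9, transversions 0.5.
    """
    lines = ["position\tguide_base\tofftarget_base\tfactor"]
    purines = {"A", "G"}
    L = protospacer_length
    for p in range(1, L + 1):
        weight = 1.0 - 0.8 * (p - 1) / (L - 1)
        for g in _BASES:
            for t in _BASES:
                if g == t:
                    continue
                same_class = (g in purines) == (t in purines)
                tol = 0.9 if same_class else 0.5
                lines.append(f"{p}\t{g}\t{t}\t{round(tol * weight, 4)}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# CFD scoring
# ---------------------------------------------------------------------------


@dataclass
class OffTargetHit:
    """One genomic site alignable to a guide within the mismatch budget."""

    chrom: str
    strand: str
    site_interval: tuple[int, int]
    site_sequence: str  # protospacer-strand orientation
    pam: str
    n_mismatches: int
    mismatch_positions: list[int]
    cfd: float


def cfd_score(
    guide: GuideRNA | str,
    hit: OffTargetHit | str,
    matrix: MismatchPenaltyMatrix,
    pam: str | None = None,
) -> float:
    """Product of per-position mismatch factors times the PAM factor.

    Positions are 1-based from the 5' (PAM-distal) end. A PAM absent from
    the matrix's allowed set contributes factor 0.
    """
    proto = guide.protospacer if isinstance(guide, GuideRNA) else guide
    if isinstance(hit, OffTargetHit):
        site, site_pam = hit.site_sequence, hit.pam
    else:
        site, site_pam = hit, pam
    if site_pam is None:
        raise ScoringError("PAM sequence required to score a site")
    if len(proto) != len(site):
        raise ScoringError("protospacer and site lengths differ")
    score = matrix.pam_factor.get(site_pam, 0.0)
    for i, (g, t) in enumerate(zip(proto, site), start=1):
        if score == 0.0:
            break
        if g != t:
            if g == "N" or t == "N":
                return 0.0  # ambiguous bases never match
            score *= matrix.factor(i, g, t)
    return score


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return arr


def _pam_allowed_mask(
    chrom_arr: np.ndarray, cas: CasVariant, L: int
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks over protospacer start positions with an allowed PAM.

    Returns (plus_mask, minus_mask), each of length len(chrom) - L + 1.
    """
    n = chrom_arr.size
    P = cas.pam_length
    n_starts = n - L + 1
    if n_starts <= 0:
        empty = np.zeros(0, dtype=bool)
        return empty, empty
    # per-position allowed-base masks from the IUPAC patterns
    from .guide_design import IUPAC

    def pattern_mask(patterns: Sequence[str], offset_fn, comp: bool) -> np.ndarray:
        mask = np.zeros(n_starts, dtype=bool)
        for pat in patterns:
            m = np.ones(n_starts, dtype=bool)
            for j, sym in enumerate(pat):
                bases = IUPAC[sym]
                if comp:
                    bases = "".join(b.translate(_COMP_TABLE) for b in bases)
                idx = offset_fn(j)
                col = np.zeros(n_starts, dtype=bool)
                valid = (idx >= 0) & (idx < n)
                if valid.any():
                    sub = chrom_arr[idx[valid]]
                    ok = np.zeros(sub.shape, dtype=bool)
                    for b in bases:
                        ok |= sub == ord(b)
                    col[valid] = ok
                m &= col
            mask |= m
        return mask

    starts = np.arange(n_starts)
    # + strand: PAM at [start+L, start+L+P)
    plus = pattern_mask(cas.pam_patterns, lambda j: starts + L + j, comp=False)
    # - strand: PAM revcomp of [start-P, start); pattern position j maps to
    # genomic start-1-j with complemented bases
    minus = pattern_mask(cas.pam_patterns, lambda j: starts - 1 - j, comp=True)
    return plus, minus


_COMP_TABLE = str.maketrans("ACGTN", "TGCAN")


def enumerate_offtargets(
    guide: GuideRNA,
    genome: GenomeAssembly,
    cas: CasVariant,
    max_mismatches: int = 3,
) -> list[OffTargetHit]:
    """Exhaustive genome scan for sites with an allowed PAM within the budget.

    Returns every window on either strand of any chromosome whose PAM the
    Cas variant accepts and whose Hamming distance to the protospacer is
    <= ``max_mismatches`` — including the on-target site itself. Windows
    containing N never match (conservative). Exact at fixture scale.
    """
    if max_mismatches > 4:
        raise ValueError("max_mismatches > 4 is not supported (tractability guard)")
    L = len(guide.protospacer)
    hits: list[OffTargetHit] = []
    proto_arr = _encode(guide.protospacer)
    proto_rc_arr = _encode(revcomp(guide.protospacer))
    n_arr_val = ord("N")

    for chrom, seq in genome.sequences.items():
        chrom_arr = _encode(seq)
        n = chrom_arr.size
        if n < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(chrom_arr, L)
        has_n = (windows == n_arr_val).any(axis=1)
        plus_mask, minus_mask = _pam_allowed_mask(chrom_arr, cas, L)

        # + strand: window read forward equals protospacer orientation
        mm_plus = (windows != proto_arr).sum(axis=1)
        cand = np.nonzero(plus_mask & ~has_n & (mm_plus <= max_mismatches))[0]
        for start in cand:
            start = int(start)
            end = start + L
            site = seq[start:end]
            pam = seq[end : end + cas.pam_length]
            mism = [i + 1 for i in range(L) if site[i] != guide.protospacer[i]]
            hits.append(
                OffTargetHit(
                    chrom=chrom,
                    strand="+",
                    site_interval=(start, end),
                    site_sequence=site,
                    pam=pam,
                    n_mismatches=len(mism),
                    mismatch_positions=mism,
                    cfd=0.0,  # filled by score_hits
                )
            )
        # - strand: protospacer-strand site is the revcomp of the window, so
        # compare the forward window against revcomp(protospacer)
        mm_minus = (windows != proto_rc_arr).sum(axis=1)
        cand = np.nonzero(minus_mask & ~has_n & (mm_minus <= max_mismatches))[0]
        for start in cand:
            start = int(start)
            if start - cas.pam_length < 0:
                continue  # PAM would fall off the chromosome
            end = start + L
            site = revcomp(seq[start:end])
            pam = revcomp(seq[start - cas.pam_length : start])
            mism = [i + 1 for i in range(L) if site[i] != guide.protospacer[i]]
            hits.append(
                OffTargetHit(
                    chrom=chrom,
                    strand="-",
                    site_interval=(start, end),
                    site_sequence=site,
                    pam=pam,
                    n_mismatches=len(mism),
                    mismatch_positions=mism,
                    cfd=0.0,
                )
            )
    hits.sort(key=lambda h: (h.chrom, h.site_interval[0], h.strand))
    return hits


def score_hits(
    guide: GuideRNA, hits: list[OffTargetHit], matrix: MismatchPenaltyMatrix
) -> list[OffTargetHit]:
    """Fill the cfd field of each hit in place; returns the same list."""
    for h in hits:
        h.cfd = cfd_score(guide, h, matrix)
    return hits


def _is_on_target(guide: GuideRNA, hit: OffTargetHit) -> bool:
    return (
        hit.chrom == guide.chrom
        and hit.strand == guide.strand
        and hit.site_interval == guide.protospacer_interval
    )


def filter_by_offtargets(
    guides: Sequence[GuideRNA],
    genome: GenomeAssembly,
    cas: CasVariant,
    max_offtargets: int = 0,
    cfd_threshold: float = 0.2,
    max_mismatches: int = 3,
    matrix: MismatchPenaltyMatrix | None = None,
) -> tuple[list[GuideRNA], list[tuple[GuideRNA, str]]]:
    """Drop guides with too many high-CFD off-target sites.

    A guide is removed iff the number of hits with cfd >= ``cfd_threshold``,
    excluding the on-target site (exact chrom/interval/strand match), exceeds
    ``max_offtargets``. Non-SpCas9-family variants skip filtering entirely
    (the CFD scheme is SpCas9-derived); every guide is kept with a warning.
    Each kept guide gets its ``n_offtargets`` / ``max_offtarget_cfd`` summary
    columns filled.
    """
    import logging

    log = logging.getLogger("betiler")
    if not cas.is_spcas9_family:
        log.warning(
            "off-target filtering skipped: %s is not an SpCas9-family variant",
            cas.name,
        )
        return list(guides), []
    if matrix is None:
        matrix = load_penalty_matrix(cas=cas)
    kept: list[GuideRNA] = []
    removed: list[tuple[GuideRNA, str]] = []
    for guide in guides:
        hits = enumerate_offtargets(guide, genome, cas, max_mismatches)
        score_hits(guide, hits, matrix)
        off = [h for h in hits if not _is_on_target(guide, h)]
        above = [h for h in off if h.cfd >= cfd_threshold]
        guide.n_offtargets = len(above)
        guide.max_offtarget_cfd = max((h.cfd for h in off), default=0.0)
        if len(above) > max_offtargets:
            reason = (
                f"{len(above)} off-target site(s) with CFD >= {cfd_threshold} "
                f"(limit {max_offtargets})"
            )
            log.info("guide %s removed: %s", guide.guide_id, reason)
            removed.append((guide, reason))
        else:
            kept.append(guide)
    return kept, removed


# ---------------------------------------------------------------------------
# On-target scoring
# ---------------------------------------------------------------------------

CONTEXT_LENGTH = 30  # 4 nt upstream + 20 protospacer + 3 PAM + 3 downstream


def extract_context(guide: GuideRNA, genome: GenomeAssembly) -> str | None:
    """30-nt scoring context around the protospacer, protospacer-strand.

    Layout: 4 nt upstream, the protospacer, the PAM, 3 nt downstream. Returns
    None (with a warning) when the window is clipped by a chromosome end.
    """
    import logging

    s, e = guide.protospacer_interval
    chrom_len = genome.length(guide.chrom)
    pam_len = len(guide.pam)
    if guide.strand == "+":
        lo, hi = s - 4, e + pam_len + 3
        if lo < 0 or hi > chrom_len:
            logging.getLogger("betiler").warning(
                "guide %s: context clipped at chromosome end", guide.guide_id
            )
            return None
        return genome.fetch(guide.chrom, lo, hi)
    lo, hi = s - pam_len - 3, e + 4
    if lo < 0 or hi > chrom_len:
        logging.getLogger("betiler").warning(
            "guide %s: context clipped at chromosome end", guide.guide_id
        )
        return None
    return revcomp(genome.fetch(guide.chrom, lo, hi))


def surrogate_on_target_score(context: str) -> float:
    """Deterministic heuristic on-target score in [0, 1] (labelled surrogate).

    Not a trained efficiency model. Combines two robust sequence features:
    GC content of the protospacer (optimum near 55%) and a penalty for
    homopolymer runs >= 4 nt (TTTT acts as a Pol III terminator). Scores are
    reproducible given the same 30-nt context.
    """
    proto = context[4:24]
    gc = (proto.count("G") + proto.count("C")) / len(proto)
    score = max(0.0, 1.0 - 2.2 * abs(gc - 0.55))
    for base in "ACGT":
        if base * 4 in proto:
            score *= 0.5 if base != "T" else 0.2
    return round(min(1.0, score), 4)


def on_target_score(
    guide: GuideRNA,
    genome: GenomeAssembly,
    scorer: Callable[[str], float] | None = surrogate_on_target_score,
) -> float | None:
    """Score a guide with a pluggable scorer over its 30-nt context.

    ``scorer=None`` disables scoring (returns None); a clipped context also
    yields None. External scorer outputs pass through unchanged.
    """
    if scorer is None:
        return None
    context = extract_context(guide, genome)
    if context is None or len(context) < CONTEXT_LENGTH:
        return None
    return scorer(context)
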