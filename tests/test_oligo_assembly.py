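"""Control selection, dedup, restriction filtering, padding, assembly."""

from __future__ import annotations

import re

import pandas as pd
import pytest

from betiler import (
    assemble_oligomers,
    assemble_sensor_oligos,
    count_sites,
    deduplicate,
    default_oligomer_template,
    default_sensor_template,
    filter_restriction_sites,
    pad_to_multiple,
    revcomp,
    select_controls,
    write_order_file,
    write_prepared_library,
)
from betiler.oligo_assembly import (
    BSMBI_SITE,
    DUMMY_SPACER,
    ECORI_SITE,
    PRIMER_PAIRS,
    SGRNA_SCAFFOLD,
    AssemblyError,
)


def _regex_site_oracle(seq: str, sites) -> int:
    """Independent overlapping-occurrence count on both strands via regex."""
    total = 0
    motifs = set()
    for s in sites:
        motifs.add(s)
        motifs.add(revcomp(s))
    for m in motifs:
        total += len(re.findall(f"(?={m})", seq))
    return total


def _table(spacers, types=None, prefix="g"):
    types = types or ["target"] * len(spacers)
    return pd.DataFrame(
        {
            "guide_id": [f"{prefix}{i}" for i in range(len(spacers))],
            "protospacer": spacers,
            "library_type": types,
        }
    )


def _make_spacers(n: int, seed: int = 20) -> list[str]:
    import random

    rng = random.Random(seed)
    out: list[str] = []
    while len(out) < n:
        s = "".join(rng.choice("ACGT") for _ in range(20))
        if s not in out and count_sites(s, (BSMBI_SITE, ECORI_SITE)) == 0:
            out.append(s)
    return out


RANDOM_SPACERS = _make_spacers(24)


class TestCountSites:
    def test_matches_regex_oracle_on_random_sequences(self):
        import random

        rng = random.Random(13)
        n_checked = 0
        for _ in range(60):
            seq = "".join(rng.choice("ACGT") for _ in range(150))
            # salt in some sites
            if rng.random() < 0.5:
                i = rng.randrange(100)
                seq = seq[:i] + BSMBI_SITE + seq[i:]
            if rng.random() < 0.3:
                i = rng.randrange(100)
                seq = seq[:i] + ECORI_SITE + seq[i:]
            for sites in ((BSMBI_SITE,), (BSMBI_SITE, ECORI_SITE)):
                assert count_sites(seq, sites) == _regex_site_oracle(seq, sites)
                n_checked += 1
        assert n_checked >= 100

    def test_palindromic_site_counted_once_per_locus(self):
        assert count_sites("AAGAATTCAA", (ECORI_SITE,)) == 1

    def test_reverse_strand_site_counted(self):
        assert count_sites("AA" + revcomp(BSMBI_SITE) + "AA", (BSMBI_SITE,)) == 1


class TestTemplates:
    def test_primer_pairs_and_scaffold_site_free(self):
        for left, right in PRIMER_PAIRS.values():
            assert count_sites(left, (BSMBI_SITE, ECORI_SITE)) == 0
            assert count_sites(right, (BSMBI_SITE, ECORI_SITE)) == 0
        assert count_sites(SGRNA_SCAFFOLD, (BSMBI_SITE, ECORI_SITE)) == 0
        assert count_sites(DUMMY_SPACER, (BSMBI_SITE, ECORI_SITE)) == 0

    @pytest.mark.parametrize("k", [1, 2, 3, 5])
    def test_oligomer_designed_site_count_is_2k(self, k):
        template = default_oligomer_template(k=k)
        assert template.designed_site_count == 2 * k

    def test_sensor_designed_counts(self):
        template = default_sensor_template()
        dummy_sensor = ("ACTG" * 10)[: template.sensor_length()]
        seq = template.assemble(DUMMY_SPACER, dummy_sensor)
        assert count_sites(seq, (BSMBI_SITE,)) == 1
        assert count_sites(seq, (ECORI_SITE,)) == 1
        assert template.sensor_length() == 40

    def test_oligomer_fixed_length(self):
        template = default_oligomer_template(k=3)
        a = template.assemble([s for s in RANDOM_SPACERS[:3]])
        b = template.assemble([s for s in RANDOM_SPACERS[3:6]])
        assert len(a) == len(b)


def _annotated_positive_table(n=10):
    outcomes = (["nonsense"] * 3 + ["missense"] * 4 + ["splice"] * 3)[:n]
    t = _table(RANDOM_SPACERS[:n], types=["positive"] * n, prefix="p")
    t["BE4.aggregated_outcome"] = outcomes
    return t


class TestSelectControls:
    def test_seeded_negative_selection_reproducible(self):
        neg = _table(RANDOM_SPACERS[:10], types=["negative"] * 10, prefix="n")
        a, _ = select_controls(neg, None, n_negative=4, seed=3)
        b, _ = select_controls(neg, None, n_negative=4, seed=3)
        assert a["guide_id"].tolist() == b["guide_id"].tolist()
        assert len(a) == 4

    def test_shortfall_names_outcome_and_count(self):
        pos = _annotated_positive_table()
        with pytest.raises(AssemblyError, match=r"nonsense.*requested 5, only 3"):
            select_controls(None, pos, positive_requests=[("BE4", "nonsense", 5)], seed=1)

    def test_requests_are_non_overlapping(self):
        pos = _annotated_positive_table()
        # two requests for the same outcome must draw disjoint guides
        _, sel = select_controls(
            None,
            pos,
            positive_requests=[("BE4", "missense", 2), ("BE4", "missense", 2)],
            seed=5,
        )
        assert len(sel) == 4
        assert sel["guide_id"].nunique() == 4

    def test_outcome_filtering_respected(self):
        pos = _annotated_positive_table()
        _, sel = select_controls(
            None, pos, positive_requests=[("BE4", "splice", 3)], seed=2
        )
        assert (sel["BE4.aggregated_outcome"] == "splice").all()


class TestDeduplicate:
    def test_precedence_target_over_negative(self):
        t = _table(
            [RANDOM_SPACERS[0], RANDOM_SPACERS[0]], types=["negative", "target"]
        )
        kept, dropped = deduplicate(t)
        assert kept["library_type"].tolist() == ["target"]
        assert dropped["library_type"].tolist() == ["negative"]
        assert dropped["retained_twin"].tolist() == [kept["guide_id"].iloc[0]]

    def test_all_unique_nothing_dropped(self):
        t = _table(RANDOM_SPACERS[:5])
        kept, dropped = deduplicate(t)
        assert len(kept) == 5 and len(dropped) == 0

    def test_triple_duplicate_keeps_exactly_one(self):
        t = _table([RANDOM_SPACERS[0]] * 3, types=["negative", "positive", "target"])
        kept, dropped = deduplicate(t)
        assert len(kept) == 1 and len(dropped) == 2
        assert kept["library_type"].iloc[0] == "target"


class TestRestrictionFilter:
    def test_internal_site_removed(self):
        bad = "ACGTACG" + BSMBI_SITE + "ACGTACG"
        t = _table([bad, RANDOM_SPACERS[0]])
        kept, removed = filter_restriction_sites(t, default_oligomer_template(k=2))
        assert removed["protospacer"].tolist() == [bad]
        assert kept["protospacer"].tolist() == [RANDOM_SPACERS[0]]

    def test_junction_reconstitution_removed(self):
        # inner linkers begin with G: a spacer ending GAGAC reconstitutes GAGACG
        template = default_oligomer_template(k=3)
        bad = "ACGTACGTACGTACG" + "GAGAC"
        assert count_sites(bad, template.enzymes) == 0  # site only at a junction
        t = _table([bad])
        kept, removed = filter_restriction_sites(t, template)
        assert len(removed) == 1 and len(kept) == 0
        # independent confirmation via exhaustive assembled-string scan
        spacers = [bad, DUMMY_SPACER, DUMMY_SPACER]
        assembled = template.assemble(spacers)
        assert _regex_site_oracle(assembled, template.enzymes) > template.designed_site_count

    def test_site_free_spacer_kept_in_all_slots(self):
        template = default_oligomer_template(k=3)
        t = _table(RANDOM_SPACERS[:6])
        kept, removed = filter_restriction_sites(t, template)
        assert len(removed) == 0 and len(kept) == 6

    def test_emitted_oligomers_site_counts_match_oracle(self):
        template = default_oligomer_template(k=3)
        t = _table(RANDOM_SPACERS[:12])
        kept, _ = filter_restriction_sites(t, template)
        oligos = assemble_oligomers(kept, template, seed=1)
        for oligo in oligos:
            assert (
                _regex_site_oracle(oligo.sequence, template.enzymes)
                == template.designed_site_count
            )


class TestPadding:
    def test_deficit_filled_from_negatives(self):
        lib = _table(RANDOM_SPACERS[:14], types=["target"] * 10 + ["negative"] * 4)
        pool = _table(RANDOM_SPACERS[14:20], types=["negative"] * 6, prefix="extra")
        padded, report = pad_to_multiple(lib, pool, pool.iloc[0:0], k=3, seed=1)
        assert len(padded) == 15
        assert len(report.added_negative) == 1
        assert report.added_positive == [] and report.removed_target == []

    def test_cascade_negatives_then_positives_then_removal(self):
        lib = _table(RANDOM_SPACERS[:10])  # 10 targets, k=4 -> deficit 2
        neg_pool = _table(RANDOM_SPACERS[10:11], types=["negative"], prefix="n")
        pos_pool = _table(RANDOM_SPACERS[11:12], types=["positive"], prefix="p")
        padded, report = pad_to_multiple(lib, neg_pool, pos_pool, k=4, seed=2)
        assert len(padded) == 12
        assert len(report.added_negative) == 1 and len(report.added_positive) == 1
        # exhausted pools: targets must be removed instead
        padded2, report2 = pad_to_multiple(
            lib, lib.iloc[0:0], lib.iloc[0:0], k=3, seed=2
        )
        assert len(padded2) == 9
        assert len(report2.removed_target) == 1
        assert report2.removed_target[0] in set(lib["guide_id"])

    def test_already_multiple_unchanged(self):
        lib = _table(RANDOM_SPACERS[:9])
        padded, report = pad_to_multiple(lib, lib.iloc[0:0], lib.iloc[0:0], k=3, seed=0)
        assert padded["guide_id"].tolist() == lib["guide_id"].tolist()
        assert report.net_change == 0


class TestAssembleOligomers:
    def test_partition_into_groups_of_k(self):
        template = default_oligomer_template(k=3)
        t = _table(RANDOM_SPACERS[:15])
        oligos = assemble_oligomers(t, template, seed=4)
        assert len(oligos) == 5
        members = [gid for o in oligos for gid in o.members]
        assert sorted(members) == sorted(t["guide_id"])
        assert all(len(o.members) == 3 for o in oligos)

    def test_k1_one_oligomer_per_guide(self):
        template = default_oligomer_template(k=1)
        t = _table(RANDOM_SPACERS[:4])
        oligos = assemble_oligomers(t, template, seed=0)
        assert len(oligos) == 4

    def test_fixed_seed_identical_assignment(self):
        template = default_oligomer_template(k=3)
        t = _table(RANDOM_SPACERS[:9])
        a = assemble_oligomers(t, template, seed=7)
        b = assemble_oligomers(t, template, seed=7)
        assert [o.members for o in a] == [o.members for o in b]
        assert [o.sequence for o in a] == [o.sequence for o in b]

    def test_non_multiple_rejected(self):
        template = default_oligomer_template(k=3)
        with pytest.raises(AssemblyError):
            assemble_oligomers(_table(RANDOM_SPACERS[:4]), template, seed=0)


class TestSensorOligos:
    def _sensor_table(self, genome, spcas9):
        from betiler import TargetRegion, scan_guides

        region = TargetRegion(label="x", chrom="chr1", start=200, end=600)
        guides = scan_guides(region, genome, spcas9)
        rows = []
        for g in guides:
            s, e = g.protospacer_interval
            rows.append(
                {
                    "guide_id": g.guide_id,
                    "protospacer": g.protospacer,
                    "library_type": "target",
                    "chrom": g.chrom,
                    "start": s + 1,
                    "end": e,
                    "strand": g.strand,
                }
            )
        return pd.DataFrame(rows)

    def test_sensor_reextractable_from_genome(self, genome, spcas9):
        template = default_sensor_template()
        table = self._sensor_table(genome, spcas9)
        oligos, _ = assemble_sensor_oligos(table, template, genome)
        assert oligos
        by_id = {row["guide_id"]: row for _, row in table.iterrows()}
        for o in oligos:
            row = by_id[o.guide_id]
            s = int(row["start"]) - 1
            e = int(row["end"])
            if row["strand"] == "+":
                expected = genome.fetch(row["chrom"], s - 7, e + 13)
            else:
                expected = revcomp(genome.fetch(row["chrom"], s - 13, e + 7))
            assert o.sensor == expected
            assert len(o.sensor) == 40
            # spacer+sensor embedded in sequence
            assert row["protospacer"] in o.sequence
            assert o.sensor in o.sequence

    def test_guide_near_chromosome_start_dropped(self, spcas9):
        from betiler import GenomeAssembly

        seq = "AT" + "ACGTTGCAACGGATCCTAGA" + "TGG" + "A" * 100
        genome = GenomeAssembly(sequences={"chr1": seq})
        table = pd.DataFrame(
            [
                {
                    "guide_id": "chr1:2-22:+",
                    "protospacer": "ACGTTGCAACGGATCCTAGA",
                    "library_type": "target",
                    "chrom": "chr1",
                    "start": 3,
                    "end": 22,
                    "strand": "+",
                }
            ]
        )
        oligos, dropped = assemble_sensor_oligos(table, default_sensor_template(), genome)
        assert oligos == [] and len(dropped) == 1

    def test_sensor_window_with_ecori_site_eliminated(self, spcas9):
        from betiler import GenomeAssembly

        proto = "ACGTTGCAACGGATCCTAGA"
        seq = "A" * 20 + proto + "TGG" + ECORI_SITE + "A" * 50
        genome = GenomeAssembly(sequences={"chr1": seq})
        table = pd.DataFrame(
            [
                {
                    "guide_id": "chr1:20-40:+",
                    "protospacer": proto,
                    "library_type": "target",
                    "chrom": "chr1",
                    "start": 21,
                    "end": 40,
                    "strand": "+",
                }
            ]
        )
        oligos, dropped = assemble_sensor_oligos(table, default_sensor_template(), genome)
        assert oligos == [] and len(dropped) == 1

    def test_emitted_sensor_site_counts_match_oracle(self, genome, spcas9):
        template = default_sensor_template()
        table = self._sensor_table(genome, spcas9)
        oligos, _ = assemble_sensor_oligos(table, template, genome)
        for o in oligos:
            assert (
                _regex_site_oracle(o.sequence, template.enzymes)
                == template.designed_site_count
            )


class TestOutputFiles:
    def test_order_file_one_sequence_per_line(self, tmp_path):
        template = default_oligomer_template(k=3)
        t = _table(RANDOM_SPACERS[:15])
        oligos = assemble_oligomers(t, template, seed=4)
        path = write_order_file(oligos, tmp_path / "order.txt")
        lines = path.read_text().splitlines()
        assert len(lines) == 5
        assert all(set(line) <= set("ACGT") for line in lines)

    def test_manifest_rows_and_slots(self, tmp_path):
        template = default_oligomer_template(k=3)
        t = _table(RANDOM_SPACERS[:15])
        oligos = assemble_oligomers(t, template, seed=4)
        path = write_prepared_library(t, oligos, tmp_path / "Prepared_library.csv")
        manifest = pd.read_csv(path)
        assert len(manifest) == 15
        assert set(manifest["slot"]) == {1, 2, 3}
        assert manifest.groupby("oligo_id").size().eq(3).all()
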