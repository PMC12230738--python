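# betiler

Design, annotate and assemble sgRNA tiling libraries for CRISPR
base-editing screens.

Base editors — a nickase Cas9 fused to a cytosine or adenine deaminase —
install C→T (or C→G) / A→G substitutions within a defined window of the
protospacer, so the mutational outcome of every guide can be predicted in
advance. A tiling screen queries every targetable position of a feature at
once, which makes library design the critical step: each guide must be
enumerated, checked for off-target promiscuity, annotated with the variant
it will install under each editor, and finally packed into synthesizable
DNA oligonucleotides with clean golden-gate cloning sites. `betiler` is a
library + CLI covering that whole path for molecular-biology labs running
base-editing screens:

1. **Target resolution** — genes (CDS union over isoforms, or canonical
   only) and/or raw regions, with flanks, blacklist exclusion and
   overlap/span validation; BED output.
2. **Guide scanning** — both strands, any 3'-PAM Cas variant defined by
   IUPAC PAM patterns (SpCas9 NGG, SpG NGN, SpRY NNN shipped;
   user-extensible via YAML).
3. **Off-target filtering** — exhaustive mismatch search scored with the
   variant-adjusted CFD scheme: CFD(site) = ∏ₚ f(p, gₚ, tₚ) · f_PAM, where
   the PAM factor vector is rebuilt per variant — every PAM the variant can
   use is assigned 100% cutting efficiency and every other PAM 0% (so under
   SpG a perfect-match NGA site scores 1.0 and a non-NGN site exactly 0).
   Guides exceeding the allowed count of hits above the CFD threshold are
   removed. A pluggable on-target scorer ships with a clearly-labelled
   heuristic surrogate.
4. **Outcome prediction** — per guide × editor, the maximally edited allele
   (all editable bases in the window, optional GC-motif sparing) is
   classified against every overlapping isoform by full retranslation and
   aggregated to splice > nonsense > missense > synonymous > noncoding,
   plus `no_edit` for empty-window guides.
5. **Oligo assembly** — merge target + control libraries, deduplicate,
   remove guides creating or reconstituting BsmBI (and, in sensor mode,
   EcoRI) sites, pad to a multiple of k guides per oligomer, and emit the
   order-ready sequence file plus a `Prepared_library.csv` manifest — in
   multiplexed golden-gate format or one-sensor-per-guide format.

A seeded fixture generator produces toy genomes with multi-isoform genes,
an essential-gene locus and a safe-harbor locus, so the full pipeline runs
and is tested without any external download.

## Worked example

Everything below runs on the built-in fixture; outputs shown are what the
commands print.

```bash
betiler fixture --seed 1 --out fx
# fixture written: fx/fixture_genome.fa, fx/fixture_annotation.gff3,
# fx/fixture_blacklist.bed (essential gene ESS1, safe harbor chr2:201-500)

printf 'ESS1\n'         > genes.txt     # target: the essential gene
printf 'GENE2\n'        > pos.txt       # positive-control source gene
printf 'chr2:201-500\n' > neg.txt       # negative controls: safe harbor

betiler design --genome fx/fixture_genome.fa --gff fx/fixture_annotation.gff3 \
    --genes genes.txt --flank 10 --editor BE4 --editor ABE8e --out target
# designed 29 guides (0 removed by off-target filter); outputs in target
```

29 guides tile the CDS (±10 nt flanks) of `ESS1`. `target/` now holds
`Target_Library.xlsx` / `.csv` (one annotation sheet per editor), the
resolved `target_regions.bed`, guide-location BED + coverage BedGraph
tracks, and `summary.json` with the per-editor outcome breakdown:

```json
"BE4":   {"missense": 3,  "no_edit": 11, "noncoding": 11, "nonsense": 1, "splice": 2, "synonymous": 1}
"ABE8e": {"missense": 10, "no_edit": 12, "noncoding": 4,  "nonsense": 0, "splice": 2, "synonymous": 1}
```

The counts sum to 29 per editor: the classes partition the library. A
typical row of the table —

```
guide_id                     chr1:157-177:-
protospacer            AGTGATGTACATATGGGATG
pam                                     AGG
BE4.aggregated_outcome              no_edit     # no C in the 4-8 window
ABE8e.aggregated_outcome           missense     # window A's edited to G
on_target_score_surrogate              0.67
```

— shows the same guide yielding `no_edit` under the cytosine editor but a
missense variant under the adenine editor. Design the control libraries the
same way (`--library-type positive` for `GENE2`, `--library-type negative`
for the safe-harbor region), then assemble:

```bash
betiler assemble --target target/Target_Library.csv \
    --neg neg/Negative_Control_Library.csv --pos pos/Positive_Control_Library.csv \
    --n-neg 4 --pos-request BE4:missense:2 --per-oligo 3 --seed 7 --out asm
# assembled 12 oligos from 36 guides (input 35, duplicates 0,
# restriction-filtered 0, padding +1/-0); outputs in asm
```

29 targets + 2 positives + 4 negatives = 35 guides; one extra negative is
drawn to reach 36 = 12 × 3, and the audit line reconciles every count. The
order file holds one 5'→3' sequence per line, each carrying three spacers
between BsmBI landing sites; `asm/Prepared_library.csv` maps every guide to
its oligomer and slot, and `asm/change_report.json` lists the padding
changes. Re-running with the same `--seed` reproduces both files
byte-for-byte. Add `--mode sensor --genome fx/fixture_genome.fa` for
one-oligo-per-guide sensor libraries instead.

For post-sequencing QC, `betiler report` computes the library's Gini index
(0 = perfectly uniform representation) and per-slot read-count summaries
from a `guide_id,count[,slot]` table joined to the manifest.

All of this is equally available as a library
(`betiler.design_library`, `betiler.assemble_library`, and the per-stage
functions they wrap); see `docs/methods.md` for the models, parameter
defaults and design decisions.

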