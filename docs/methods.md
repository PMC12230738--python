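# Methods

`betiler` designs sgRNA tiling libraries for CRISPR base-editing screens:
given a genome, a transcript annotation and a list of targets, it resolves
target intervals, scans both strands for protospacers next to a Cas
variant's PAM, filters guides on genome-wide off-target load with a
variant-adjusted CFD score, predicts the mutational outcome of each guide
under each base editor, and assembles the surviving guides into
order-ready oligonucleotide pools. This note records the models, the
parameters that matter, the numerical conventions, and the design choices
made where the design was genuinely open.

## Coordinates and sequence conventions

All internal coordinates are 0-based half-open. User-facing region strings
(`chrom:start-end`) and spreadsheet outputs are 1-based inclusive (the
Ensembl convention); conversion happens only at the I/O boundary, so no
intermediate computation ever mixes conventions. Protospacers and PAMs are
always reported in protospacer-strand orientation, 5'→3'; for minus-strand
guides they are the reverse complement of the reference. Protospacer
positions are 1-based with position 1 at the 5' (PAM-distal) end — the
convention of the base-editing literature, where e.g. a BE4-class editor is
maximally active around positions 4–8. Stable guide identifiers are derived
from coordinates (`chrom:start-end:strand`), never from counters, so
re-running a design can never renumber guides.

## Target resolution

Gene entries expand to the union of CDS intervals over all isoforms (or the
canonical isoform only, on request), each extended by a configurable flank
(`flank_nt`, default 0 nt) and merged per gene so each genomic base is
targeted once. Region entries are used verbatim plus flanks. Three rules are
enforced:

- **Blacklist**: regions intersecting a user-supplied blacklist BED are
  *trimmed* to their non-blacklisted parts rather than dropped whole.
  Trimming preserves the maximal targetable sequence; the choice is logged
  whenever it takes effect.
- **Cross-entry overlap is an error.** Two entries resolving to overlapping
  intervals would yield duplicate guides that later stages would silently
  deduplicate; failing early keeps the library contents predictable.
- **Total span cap**: 1.5 Mb by default, configurable.

When the annotation carries no canonical tag, the isoform with the longest
CDS is flagged canonical (ties broken by lexicographic transcript id). A
local annotation file needs some rule; longest-CDS is the common fallback.

## Guide scanning

Every position on both strands where a full-length protospacer (default
20 nt, configurable per Cas variant) plus a 3'-adjacent PAM fits inside the
chromosome and the PAM matches one of the variant's IUPAC patterns yields
exactly one guide. A guide belongs to a region if its protospacer overlaps
it by ≥1 nt, so feature boundaries (e.g. splice sites) remain reachable —
this is why flanks exist. Protospacers containing N are dropped. Only
3'-PAM (Cas9-family) architectures are supported; 5'-PAM enzymes are
rejected with a clear error. Shipped variants: SpCas9 (NGG), SpG
(NGG/NGA/NGC/NGT), SpRY (NNN); users can extend the set via YAML.

## Off-target model: variant-adjusted CFD

The CFD score of a candidate site is the product of per-position mismatch
penalty factors and a PAM factor. Two components:

- **PAM factor (the adjusted part).** The CFD scheme was developed for
  SpCas9/NGG. For engineered variants with relaxed PAM requirements the PAM
  factor vector is rebuilt from the variant definition: every PAM the
  variant can use gets factor 1.0 (100% cutting efficiency) and every other
  PAM gets 0. Under SpG, for example, a perfect-match site with an NGA PAM
  scores exactly 1.0 and any non-NGN PAM exactly 0. This is deliberately
  conservative and assumes all SpCas9 variants share the same mismatch
  tolerance profile.
- **Mismatch factors.** Shipped as a versioned TSV
  (`data/cfd_mismatch_penalties_synthetic.tsv`). The file is a synthetic
  stand-in, not an experimentally derived table: factor(p, g, t) =
  tolerance(g, t) × (1 − 0.8·(p−1)/19), with tolerance 0.9 for
  transition-like mismatches and 0.5 for transversions, so PAM-proximal
  mismatches are penalised most — the qualitative shape of measured CFD
  tables. Matched bases always have factor 1 and all factors lie in [0, 1].
  Laboratories with a measured table can load their own file with the same
  schema; every downstream contract is independent of the concrete values.

Off-target enumeration is an exhaustive scan: every window on either strand
of every chromosome with an *allowed* PAM and Hamming distance ≤
`max_mismatches` (default 3, capped at 4 for tractability) is returned,
including the on-target site. Excluding disallowed-PAM sites at enumeration
rather than scoring them 0 is mathematically identical and cheaper. Windows
containing N never match (conservative). The scan is vectorised with NumPy
sliding windows and is exact; it is intended for the fixture-scale genomes
this package targets, not for whole-mammalian-genome runs.

Filtering: a guide is removed iff the number of hits with CFD ≥
`cfd_threshold` (default 0.2), excluding the on-target site identified by
exact (chrom, interval, strand) match, exceeds `max_offtargets` (default 0).
Both thresholds are user-visible. Filtering applies only to SpCas9-family
variants — the CFD scheme is SpCas9-derived — and is skipped with a warning
otherwise. Raising either threshold can only grow the kept set (tested
property).

## On-target scoring

Trained on-target efficiency models are out of scope. The package exposes a
pluggable scorer over the standard 30-nt context (4 nt upstream +
protospacer + PAM + 3 nt downstream) and ships a deterministic heuristic
surrogate combining protospacer GC content (optimum near 55%) and a penalty
for homopolymer runs ≥ 4 nt (TTTT is a Pol III terminator). The output
column is named `on_target_score_surrogate` so it cannot be mistaken for a
trained-model score. Contexts clipped by a chromosome end score null.

## Mutational-outcome prediction

For each guide × editor, the *maximally edited allele* is constructed:
every occurrence of the editor's reference base (C for CBEs, A for ABEs) at
protospacer positions `window_start..window_end` is substituted
simultaneously, as one combined multi-nucleotide variant. Position-weighted
partial-edit alleles are a known refinement and deliberately not modelled.
With `exclude_gc` (APOBEC-1 CBEs disfavour editing C preceded by G), a C
immediately preceded by G *on the protospacer strand* is spared; whether
the genomic or protospacer strand should be consulted is ambiguous in the
field, and the protospacer strand was chosen because the deaminase acts on
the displaced (protospacer-identical) strand. For a window starting at
position 1 the immediately 5' genomic base is consulted, since the
deaminase sees genomic context, not the spacer boundary. Substitutions are
reported on the reference strand; guides with no editable base in the
window are labelled `no_edit` and are usable as internal negative controls.

Each allele is classified against every transcript whose exons, extended by
an 8-nt intron flank, contain a substitution:

- **splice** — any substitution in the 2 intronic nt adjacent to an exon
  boundary (the canonical GT/AG positions). The broader splice-region
  categories of full annotation engines are not replicated.
- otherwise the substitutions are applied to the spliced CDS which is
  retranslated in full: a lost start codon or a gained premature stop is
  **nonsense**; any other amino-acid change is **missense**; a changed CDS
  base with an unchanged protein is **synonymous**.
- substitutions touching only UTR/intron/intergenic sequence are
  **noncoding**.

A transcript can combine classes (e.g. splice + missense); all are
recorded. Per-guide aggregation picks one transcript — the canonical one if
it overlaps, else the overlapping transcript with the longest CDS (a
deliberate, documented stand-in for VEP's `--pick` ordering, flagged as
such in the output metadata) — and applies the severity order
splice > nonsense > missense > synonymous > noncoding within it. Guides
overlapping no transcript are noncoding; `no_edit` passes through.
Guides inserting identical substitution sets share a variant key
(HGVS-like `g.` notation) so redundant edits can be aggregated downstream.

## Oligonucleotide assembly

The assembly stage consumes the design stage's library tables and produces
a text file of order-ready sequences plus a `Prepared_library.csv`
manifest. Steps, in order:

1. **Control selection** — a user-defined number of negative controls is
   drawn uniformly without replacement (seeded); positive controls are
   drawn per request (editor, outcome, n) from rows whose pick-isoform
   outcome matches, with a guide granted to one request excluded from the
   others. Shortfalls are errors naming the request and availability.
2. **Deduplication** on protospacer sequence; precedence
   target > positive > negative, then input order, so the screen's subject
   matter survives collisions. Dropped rows record their retained twin.
3. **Restriction-site filtering.** A guide is removed iff placing its
   spacer into *any* slot of the template (site-free dummy spacers
   elsewhere) raises the BsmBI recognition count (CGTCTC / GAGACG, both
   strands; plus GAATTC in sensor mode) above the template's designed
   count. Checking every slot is strictly more conservative than checking
   only the slot eventually assigned, and catches sites reconstituted
   across spacer/linker junctions as well as sites wholly inside the
   spacer. The template's designed count is itself computed, not asserted,
   by assembling with dummy spacers.
4. **Padding to a multiple of k** (spacers per oligomer): deficits are
   filled first from unused negatives, then unused positives (both
   re-checked against steps 2–3); if the pools are exhausted, target guides
   are removed at random. Every added or removed guide id is reported.
5. **Assembly**: guides are shuffled (seeded) and partitioned into
   consecutive groups of k, instantiated into the template in slot order.
   In sensor mode each guide instead gets one ~203-nt oligo carrying its
   spacer, the sgRNA scaffold and a 40-nt genomic sensor window
   (7 nt upstream + 20 protospacer + 3 PAM + 10 downstream, protospacer
   strand; a centring convention, configurable). Guides whose sensor
   window is clipped by a chromosome end, or whose genomic sensor itself
   contains an extra BsmBI/EcoRI site, are dropped with a warning and
   counted in the audit.

A single user-visible seed governs selection, padding and shuffling, so
identical inputs and seed give byte-identical output files. The audit
identity |input| − duplicates − restriction-dropped − padding-removed +
padding-added − sensor-dropped = |manifest| is checked on every run.

The shipped primer pairs, linkers and sensor arms are placeholders that
satisfy the structural invariants (correct BsmBI/EcoRI placement, site-free
elsewhere); the exact validated sequences of a laboratory's cloning
protocol should be substituted via template configuration. The scaffold in
the sensor template is the standard SpCas9 sgRNA scaffold. The default
multiplexed template places one opening and one closing BsmBI site around
each of the k slots (designed count 2k).

## Reporting and QC

Library tables are written both as XLSX workbooks (one core sheet plus one
annotation sheet per editor; file names `Target_Library`,
`Positive_Control_Library`, `Negative_Control_Library`) and as flat CSV
siblings so downstream tooling never needs a spreadsheet reader. The
summary reports guides per gene and, per editor, outcome-class counts that
partition the library (the five consequence classes plus `no_edit`, which
needs its own bucket because empty-window guides edit nothing). Instead of
an interactive browser view the package writes static per-gene tracks: a
BED of guide locations and a BedGraph of per-base guide coverage — the same
information, no web stack.

Two count-table utilities support post-sequencing QC: the Gini index
G = Σᵢⱼ|xᵢ−xⱼ| / (2·n·Σx), computed on the vector exactly as given (no
normalisation — callers normalising counts first will get the Gini of the
normalised vector), and a per-slot descriptive summary (mean/median read
count per oligomer slot) for diagnosing positional amplification bias in
multi-spacer oligomers. The Gini implementation uses the O(n log n)
sorted-rank identity; tests verify it against the brute-force double sum.

## Synthetic fixture

`generate_fixture(out_dir, seed, n_genes, chrom_length)` writes a
deterministic toy genome (byte-identical under a fixed seed): `chr1`
carries `n_genes` two-isoform genes — three codon-aligned CDS chunks
separated by GT..AG introns, alternating strands, with isoform B skipping
the middle chunk — and `chr2` carries an intergenic safe-harbor locus for
negative-control design plus a small blacklist interval. Every generated
CDS starts with ATG, ends at a stop and contains no internal stop, so every
transcript passes annotation validation by construction. The first gene is
named `ESS1` and plays the essential-gene role in control design.

The fixture emulates the *structural* features the pipeline consumes
(multi-isoform genes, splice sites, both strands, UTRs, a blacklist). It
does not emulate mammalian genome scale, repeat content, chromatin, or
realistic off-target density; passing tests demonstrate correctness of the
algorithms on exact small instances, not performance or specificity on a
real genome. Default problem sizes (3 genes, ~10 kb of genome, tens of
guides per library) were chosen so every oracle can be exhaustive.

## Numerical and degenerate-input choices

- Mismatch counting is plain Hamming distance; budgets above 4 are
  rejected rather than silently slow.
- Ambiguous bases (N) never match anything: N-containing protospacers are
  not designed, N-containing windows are not off-target hits.
- An all-zero or empty count vector has no Gini index (error), as does a
  CDS whose length is not a multiple of 3 (validation error at load).
- Restriction-site counting counts overlapping occurrences on both strands;
  palindromic sites are counted once per locus.
- Seeds are plain integers fed to `numpy.random.default_rng` /
  `random.Random`; no global RNG state is used anywhere.

## Known limitations

- The mismatch penalty table is a labelled synthetic stand-in (see above);
  absolute CFD values are not comparable to published scores, though all
  ordering/monotonicity properties and the adjusted PAM vector semantics
  hold exactly.
- Off-target search is exhaustive-scan, suitable for fixture-scale genomes
  only; no index/alignment backend is provided.
- One maximally-edited allele per guide×editor; no per-position editing
  efficiencies, no partial-edit allele spectrum, no base-editor-specific
  off-target model.
- The consequence annotator covers the five aggregate classes plus
  `no_edit` only; it is not a general-purpose variant annotation engine.
- Golden-gate behaviour is modelled only as recognition-site counting; no
  ligation-fidelity or assembly-efficiency simulation.
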