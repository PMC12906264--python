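# Methods

## The problem and the staged model

Given assembled metagenome contigs containing a mixture of prokaryotic,
viral and eukaryotic DNA, the goal is one consolidated set of protein-coding
gene calls across domains. Single-domain predictors fail in complementary
ways: an ab initio prokaryotic caller applied to eukaryotic DNA emits many
short fragments (exon/intron boundaries break reading frames), while a
homology-based eukaryotic caller misses most prokaryotic genes but is
accurate on the ones it does call. The staged workflow exploits this
asymmetry: trust the eukaryote-oriented first pass wherever it calls,
remove those regions from play by hard-masking, and let a
prokaryote-oriented second pass fill in the remainder. The consolidated
set is then non-redundant by construction.

## Coordinate conventions

All internal coordinates are 0-based half-open `[start, end)`; GFF3 I/O
converts to/from 1-based inclusive at the boundary. Half-open intervals
make union, length and masking arithmetic free of off-by-one cases
(`length = end − start`, touching means `a.end == b.start`). Exon lists
are stored in ascending forward-strand order for all strands; strand is
consulted only at translation. Sequence case is preserved through masking
and I/O so upstream soft-masking survives, while all comparisons are
case-insensitive.

## Masking

`MaskPolicy.mode` decides what "the gene's region" means: `span` (default)
masks the whole genomic extent including introns; `exons` masks only
coding exons. Span is the default because unmasked introns inside
first-pass eukaryotic genes would invite spurious second-pass calls at
intron/exon junctions; the stricter exon reading is available. Intervals
are merged before substitution (touching intervals fuse; `merge_gap > 0`
can additionally fuse near-adjacent ones); merging makes the result
independent of call order and duplication, and masking idempotent. Only
one contig's sequence is mutated at a time, so memory is bounded by the
largest contig. The accounting report records masked bases and merged
interval counts per contig.

First-pass records whose coordinates overrun their contig (a dialect or
version mismatch symptom) are clipped to the contig end and counted in
provenance rather than rejected: clipping can only shrink the masked
region to sequence that exists.

## First-pass header dialect

Eukaryote-oriented predictors encode exact gene locations in their
prediction-FASTA headers; versions differ in field order and coordinate
base, so the parser takes a `HeaderDialect` (separator, coordinate base,
role→position map). The default is pipe-separated
`target|contig|strand|bitscore|evalue|n_exons|low|high|blocks`, with both
coordinates 0-based inclusive (half-open end = high + 1) and exon blocks
as colon-separated `low-high` pairs. Bitscore and E-value are carried
through but never used for filtering — no E-value threshold is applied
anywhere. Overlapping or redundant first-pass predictions need no
deduplication, because masking takes the interval union.

## Built-in second pass (six-frame ORF caller)

The built-in caller is a deliberate surrogate for real ab initio
predictors, not a reimplementation: for each stop codon in each of the six
frames, it reports the ORF from the furthest-upstream in-frame start codon
(ATG/GTG/TTG, after the previous in-frame stop) through the stop codon
inclusive, if it reaches `min_len_nt`. Defaults: 300 nt minimum (100
codons — conservative on purpose; the surrogate should under-call
relative to real tools), both strands, no edge-truncated partial ORFs,
and any codon containing a non-ACGT character disqualifies the ORF that
would contain it. That last rule is the mechanism coupling the two
passes: masked regions contain no legal codons, so second-pass calls can
never overlap first-pass regions (adding first-pass calls can only
decrease the second-pass count).

Minus-strand ORFs are found on the reverse complement and reported
reflected into forward-strand coordinates.

## Consolidation

The union of both passes keeps globally unique identifiers (second-pass
ids colliding with first-pass ids get a deterministic `sp_` prefix) and is
ordered by contig, start, then pass. As a safety net for exon-mode masking
and arbitrary external predictors, any second-pass call overlapping a
first-pass masked region by ≥ 1 base is dropped and counted; with
span-mode masking and the built-in caller this cannot trigger. The count
identity `|combined| = n_first + n_second − n_dropped` is enforced at
construction.

## Evaluation metrics

Gene length is always coding length (sum of exon lengths), so single-CDS
and spliced genes are comparable. Summaries report n, mean, median
(lower-middle element for even counts, for determinism) and total length
per category, per pass, or overall.

Against a truth annotation: a truth gene is *detected* when the union of
same-contig (and by default same-strand) predicted exon intervals covers
at least `overlap_frac` (default 0.5 — a conventional coverage criterion,
exposed as a parameter) of its coding length. The *fragmentation index*
is the mean number of distinct predicted calls with ≥ 1 coding-base
overlap per detected truth gene; 1.0 means genes are recovered whole.
`mean_len_ratio` is mean predicted over mean truth coding length.

Protein identity uses a global (Needleman–Wunsch) alignment with linear
gap costs (match +1, mismatch −1, gap −2) and is defined as
100 × matches / alignment columns, gap columns included. The dynamic
program maximises (score, fewest gap columns) lexicographically; given
the score and the gap count, the match count is algebraically determined,
so the reported identity is deterministic without any further tie-break.
Translation uses the bacterial/archaeal code (table 11) with the
initiator codon rendered as M and the terminal stop stripped; internal
stops raise unless a partial flag is set.

## Synthetic data

`simulate_metagenome` builds contigs of i.i.d. bases at a configurable GC
(default 0.50) and plants non-overlapping genes (30 nt spacing buffer):

* prokaryote/virus-like: single-CDS, ATG start, non-stop body codons,
  one terminal stop; lengths 300–1500 nt (codon multiples). Virus-like
  genes are generated identically and differ only in their truth label,
  existing to exercise per-category reporting.
* eukaryote-like: 2–5 exons of 150–450 nt (fungal-like scale) whose
  concatenation is a valid CDS, separated by 60–180 nt introns beginning
  GT and ending AG on the coding strand; strand chosen at random with
  coordinates reflected for minus-strand genes.

Default scale is 20 contigs of 20–100 kb with 200/60/20
prokaryote/eukaryote/virus genes — large enough for stable proportions,
small enough that every end-to-end test runs in seconds. All randomness
derives from one integer seed with an independent substream per
operation, so the degrader profile can change without perturbing contig
composition, and equal seeds give byte-identical output. Infeasible
packings fail loudly after a bounded number of placement attempts.

`degrade_predictions` models a first pass: each truth gene survives with
its category's recall (defaults 0.95 eukaryote, 0.25 prokaryote/virus),
survivors may be split into 2–3 fragments along their exons
(`fragmentation_prob`) and have their outer boundaries jittered by up to
`boundary_jitter_nt` without leaving the contig or emptying an exon.

What the simulator does **not** model: codon-usage and GC-skew realism,
repeat families, chimeric/misassembled contigs, sequencing error, genes
truncated at contig edges, and overlapping genes. Passing tests therefore
demonstrate the correctness of the staging/masking/consolidation
machinery and the direction of the headline effects, not predictor
accuracy on real assemblies.

## Reference experiments

Two seeded experiments (in `crossmask.bench`, recomputed by
`scripts/acceptance.py`) probe the scientific claims:

* **Fragmentation probe**: the naive caller runs directly on
  eukaryote-rich contigs (the default scale restricted to 60 eukaryotic
  genes, 20 contigs of 20–50 kb) and is scored against the eukaryotic
  truth. Here the caller uses a 150 nt minimum — real prokaryotic
  predictors call genes down to roughly 90–110 nt, and the probe should
  mimic their liberal calling — while the workflow's second pass keeps
  the conservative 300 nt default. Expected direction: fragmentation
  index well above 1 and mean length ratio well below 1.
* **Staged recovery**: full default-scale run with the mock first pass
  (recall 0.95/0.25/0.25, fragmentation 0.05, jitter 6 nt).
  Prokaryote+virus sensitivity is measured for the first pass alone and
  for the consolidated set; the second pass multiplies it several-fold,
  while eukaryotic counts and mean lengths of the consolidated set equal
  the first-pass values exactly (second-pass calls never carry the
  eukaryote label, and masking shields first-pass regions).

The mean second-pass protein identity versus truth (~79% at seed 1) is
below 100% chiefly because the naive caller extends ORFs upstream to the
furthest in-frame start, prepending residues the truth protein lacks.

## Numerical and degenerate-input choices

Empty inputs are valid everywhere (empty FASTA → empty list; empty gene
set → header-only GFF3; fully masked contigs → empty second pass).
Duplicate FASTA ids, non-IUPAC characters, inverted GFF coordinates,
unknown strands, and gene calls referencing absent contigs raise errors
naming the offender; a lenient flag downgrades the absent-contig case to
a counted warning. Summaries of empty groups use NaN means rather than
zero to keep "no genes" distinct from "zero-length genes".
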