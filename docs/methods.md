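# Methods

## Step 1 — chained global alignment

A contig is aligned to the reference by combining local alignments
("diagonals") into a global alignment. Diagonals come from a pluggable
engine: `bwa mem -a` or `minimap2 -a` externally, or the internal seeder,
which reports every maximal exact match of length ≥ k (default k = 15, the
bwa-mem seed default) on both strands as a gapless local alignment. The
internal seeder makes the whole pipeline self-contained and exactly
testable (its output is compared against a brute-force all-pairs scan in
the test suite); the external engines are the practical choice for
real assemblies, where gapped local alignments absorb dense variation.

Chaining is a dynamic program over *entry* and *exit* points. Each diagonal
contributes its start entry and end exit; additionally a within-diagonal
exit (entry) is placed where a diagonal's consumed-coordinate state aligns
horizontally or vertically with another diagonal's start (end). Points are
modelled as 0-based consumed-character states, as in the classical global
alignment matrix: a diagonal covering reference positions 4–10 and contig
positions 3–11 (1-based) has entry state (3, 2) and exit state (10, 11).
A valid traversal ORIGIN → … → TERMINUS alternates exit- and entry-class
points, pairs each entry with a later exit on the same diagonal, is
monotone in both coordinates, and repeats no point. Scoring: +1 per match
and −1 per mismatch/gap column inside diagonals (via per-diagonal prefix
sums), `gap_score` × (Δref + Δcontig) per jump (default −1), and jumps
from ORIGIN / to TERMINUS are charged only along the contig dimension —
ends-free on the reference, so placement is unconstrained, while the whole
contig is always consumed. With coordinate-monotone transitions and a
linear jump cost, processing points in coordinate order (exits before
entries at equal coordinates) gives the exact optimum; pass-through visits
of a diagonal at a single coordinate are excluded, which is score-neutral
because the jump cost is additive along any intermediate point. When a
reference (or contig) coordinate maps to several columns of an indel-bearing
diagonal, the first such column carries the within-diagonal point. Ties
between equal-scoring predecessors resolve toward the lexicographically
earlier diagonal id, then smaller coordinates, making output deterministic
(the underlying optimum is unaffected).

The best traversal over all (reference contig, orientation) partitions is
rendered as gapped rows: inter-diagonal jumps become a block of contig
insertions followed by a block of reference deletions (in that fixed
order), and unaligned contig ends become insertion columns. A contig with
no diagonals at all is reported and excluded downstream; this is a value,
not an error.

Two consequences of gapless seeding are worth noting. A substitution is
rendered as a 1-bp insertion plus a 1-bp deletion (score −2 rather than
−1), so the chain score is a lower bound on the exact semi-global
Needleman–Wunsch optimum — asserted as an invariant. And two variants
closer together than k leave no seedable stretch between them, so the
whole span renders as one paired gap block; downstream this merges such
variants into a single block record (see Limitations).

## Step 2 — windowed MSA

Tentative boundaries sit at multiples of `window_size` (default 10,000).
For each boundary independently, all 201 positions within ±100 bp are
scored by the proportion of Step-1 alignment columns at that reference
position that are gapped (positions covered by no alignment count 0); the
argmin wins, with ties broken toward the smallest offset, then leftward.
Window lengths therefore stay within [9,800, 10,200]; the terminal window
absorbs the sub-window remainder rather than creating a short tile.

Contig bases are routed to windows by their Step-1 column: a base goes to
the window of the reference position of its column; insertion columns
follow the nearest preceding reference-consuming column (leading
insertions go to the first overlapped window), so an insertion at a
boundary attaches to the left window. Slices concatenate to the full
aligned contig — conservation is asserted at every stage.

Each window is aligned independently (the stage is embarrassingly
parallel; scheduling cannot affect the result, which is asserted by
shuffling). The default engine is internal: each member is aligned to the
window's reference slice pairwise and the paths are merged
reference-anchored, with the insertion block after each reference position
sized to the longest insertion any member places there (members
left-align within a block, so no all-gap column arises). The pairwise path
comes from the package's own seed-and-chain aligner (k = 12 inside
windows), which scores +1/−1/−1 and keeps indels contiguous; pairs it
cannot seed fall back to a unit-cost edit-distance path (edlib). A plain
edit-distance path is deliberately not the default: with no gap-opening
cost it splits long indels around chance matches inside the gap.
Alternatively `mafft` (default options) can be selected per window.
Windows without members yield the bare reference row; a member whose
assigned slice is empty (a deletion spanning the window) gets an all-gap
row.

Per-window MSAs are concatenated per reference contig; rows are padded
with gaps outside a contig's first/last window. On disk the concatenated
MSA is SAM: M/I/D as usual, and columns where the reference is gapped but
a row is too (forced by a third row) are encoded with the `P` pad
operator. Rows are written over whole insertion blocks, which makes the
write→read cycle bit-exact on the shared column space (a property test).

## Step 3 — graph construction

Both builders consume per-contig pairwise extractions of the MSA in which
columns gapped in both rows are removed, pruned so the first and last
column are reference-identical matches.

**Simple** walks each pruned pairwise alignment column by column with
running reference/contig buffers. At every reference-identical match
column the buffers are gap-stripped and, if different, emitted as a
variant whose REF/ALT begin with the match that started the buffer
(1-based POS of that anchor); buffers then restart from the current match.
Identical records from different contigs merge with unioned support;
different ALTs at one (chrom, pos, REF) join into a multi-allelic line.
Overlapping records across contigs are allowed and expected.

**Universal** maintains a set R of (current sequence, source haplotype),
initialized to one empty reference-sourced element, and sweeps the MSA
left to right. Per column: contigs entering at this column (first column
where contig and reference are both non-gap) duplicate every element of R
with the entrant as source — unless |R| ≥ U1, in which case the contig is
dropped permanently and logged; every element then appends its source's
character; contigs exiting (last such column) trigger recombination —
each affected element is copied once per other still-active contig source,
then all affected elements switch their source to the reference (skipped,
reference-transition only, when |R| ≥ U1); R is deduplicated as a set
after every mutation. When the characters appended at a column are all
non-gap and reference-identical and every buffer holds ≥ 2 non-gap bases,
the buffers up to the second-last character are flushed: gap-stripped,
compared with the reference buffer (tracked separately, since exits can
leave several reference-sourced elements whose buffers differ), and
emitted as one record iff any sequence differs; buffers then retain only
the last base, which anchors the next record. A final flush runs at the
rightmost column. Because consecutive flushes share their anchor base,
records tile without overlapping — the defining contract, asserted on
every output. Before the sweep, contig-gap runs spanning more than U2
reference bases split the row into independent fragments (new entry/exit
positions), bounding the largest representable deletion.

Support semantics: an allele is attributed to the *current* sources of the
elements carrying it at flush time; recombinant alleles created at exits
are therefore attributed to the continuing contig.

## Synthetic data and oracles

Fixtures are references drawn i.i.d. at a chosen GC content plus contigs
that are slices of a mutated haplotype: SNPs, insertions and deletions at
per-bp rates, placed non-overlapping with a minimum spacing (default
10 bp), at least 20 bp from contig ends (so pruning cannot silently
consume a truth event), optionally outside caller-specified intervals;
whole contigs may be reverse-complemented, and unalignable decoy contigs
can be added. Regeneration from (seed, config) is byte-identical. Default
rates (SNP 10⁻³/bp, indels 2·10⁻⁴/bp each, lengths 1–10 bp) correspond to
the divergence range observed between human de novo assemblies and the
reference, where NM/length concentrates around 10⁻³–10⁻². What the
generator does *not* emulate: assembly base errors with nonuniform error
profiles, repeats and segmental duplications, large structural events that
break collinearity (inversions, translocations), and N-runs. Passing
tests therefore demonstrate algorithmic correctness on collinear,
moderately divergent input — not robustness to repeat-rich real genomes,
where the external aligner engines are the appropriate choice.

Oracles are kept independent of the code they check: chaining is compared
against exhaustive recursion over all valid traversals (point sets
re-derived by direct column scans); the internal seeder against an
all-pairs maximal-match scan; and the semi-global NW score (+1/−1/−1,
reference end gaps free, contig end gaps penalized) is computed over the
full DP matrix, vectorised row-wise — the linear gap penalty collapses the
left-neighbour recurrence into a running maximum — behind a 10⁷-cell
guard. A second, plain-Python NW lives in the test suite and must agree.
Truth scoring compares *normalized* variants (parsimony-trimmed, then
left-aligned against the reference), so anchor-shifted representations of
one indel compare equal; equivalence is defined by applied sequence, not
string identity.

## Numerical and design choices

- Coordinates are 0-based half-open internally; 1-based inclusive only at
  SAM/VCF boundaries. Gap character `-`; `N` is a base that matches only
  `N`.
- `gap_score` must be negative; the transition cost is
  `gap_score × (jump distance)`, the reading of the traversal scoring under
  which jumps are penalties.
- Boundary scan radius 100 with inclusive endpoints (201 candidates);
  `window_size > 2 × scan` is enforced so windows cannot invert.
- U1 = U2 = 5000 by default, user-adjustable; U1 is checked before entry
  duplication, so |R| can transiently exceed it between entry and the next
  flush (an internal 2×U1 assertion guards runaway growth).
- The divergence table reports NM as the exact Levenshtein distance
  between the oriented contig and its covered reference slice (edlib),
  not the gap-column count of the chained alignment, which overstates the
  distance when variants cluster within one seed length.
- Degenerate inputs: an empty diagonal set signals "no alignment" (the
  contig is skipped, not an error); an all-mismatch pairwise prunes to
  nothing and is skipped with a warning; alleles that would lack a
  reference-identical anchor (variant touching the very first column) are
  dropped with a warning rather than emitting invalid VCF.
- Problem sizes in the shipped tests — 1 Mb × 5 contigs for the window
  bound, 40–60 bp instances for exhaustive chaining checks, 2.5–50 kb
  fixtures elsewhere — were chosen so each property is checked at the
  smallest scale at which it is meaningful.

## Known limitations

- Variants spaced closer than the seed length k merge into one block
  record with the internal engines (the applied sequence is preserved;
  round-trip tests pass). MAFFT or an external gapped local aligner
  decomposes them.
- Gap penalties are linear, not affine or convex, in both the chainer and
  the internal window aligner.
- One global alignment per contig: chimeric contigs spanning reference
  contigs are placed on their best partition only.
- Inversions and translocations are not modelled; collinearity-breaking
  sequence is absorbed as insertions or dropped with the contig.
- Universal's U1 cap silently (but loggedly) discards whole contigs under
  extreme haplotype complexity; at desk scale it is never approached.
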