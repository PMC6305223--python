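"""Step 3: converting the concatenated MSA into a genome graph, serialized
as VCF.

Two conversion algorithms are provided. The *Simple* builder converts each
contig row one-to-one: a running pair of reference/contig buffers is flushed
at every reference-identical match column, emitting a left-anchored variant
whenever the gap-stripped buffers differ; the resulting VCF may contain
overlapping records. The *Universal* builder walks the MSA column by column
while maintaining a set R of current haplotypes (sequence buffer + source),
duplicating R when contigs enter, recombining haplotypes when contigs exit,
and flushing R into a (possibly multi-allelic) VCF record whenever all
current haplotypes return to a reference-identical state — guaranteeing a
VCF with pairwise non-overlapping variant alleles. The set size is capped
at U1 (contigs whose entry would exceed it are dropped and logged) and
contig-gap runs longer than U2 split the corresponding alignment in two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

from .io import GAP, SequenceRecord, VariantRecord, merge_variant_records, ungapped
from .windows import ConcatenatedMsa

logger = logging.getLogger("novograph")

REF_SOURCE = "ref"


@dataclass(frozen=True)
class GraphLimits:
    """Complexity caps: ``u1`` bounds the haplotype set size, ``u2`` the
    longest contiguous contig-gap run (deletion size, bp) before an
    alignment is split."""

    u1: int = 5000
    u2: int = 5000

    def __post_init__(self):
        if self.u1 <= 0 or self.u2 <= 0:
            raise ValueError("graph limits must be positive")


@dataclass
class PrunedPairwise:
    """A contig-vs-reference extraction of the MSA, trimmed so the first and
    last columns are non-gap and reference-identical. ``ref_offset`` is the
    0-based reference coordinate of the first column."""

    contig_id: str
    aligned_ref: str
    aligned_contig: str
    ref_offset: int


@dataclass(frozen=True)
class DroppedContig:
    contig_id: str
    reason: str
    column: int


# ---------------------------------------------------------------------------
# pairwise extraction and pruning
# ---------------------------------------------------------------------------

def extract_pairwise(msa: ConcatenatedMsa, contig_id: str) -> tuple[str, str, int]:
    """Contig row against reference row over the contig's aligned span, with
    columns gapped in both rows (forced by third rows) removed. Returns
    (aligned_ref, aligned_contig, 0-based reference offset of first column)."""
    row = msa.rows[contig_id]
    first, last = msa.aligned_span(contig_id)
    ref_offset = len(ungapped(msa.ref_row[:first]))
    ar, ac = [], []
    for a, b in zip(msa.ref_row[first : last + 1], row[first : last + 1]):
        if a == GAP and b == GAP:
            continue
        ar.append(a)
        ac.append(b)
    return "".join(ar), "".join(ac), ref_offset


def prune_pairwise(
    row: str, ref_row: str, ref_offset: int, contig_id: str = ""
) -> PrunedPairwise | None:
    """Trim both ends until the boundary columns are non-gap and
    reference-identical; None when no such column exists."""
    n = len(row)
    i = 0
    while i < n and not (row[i] != GAP and row[i] == ref_row[i]):
        i += 1
    if i == n:
        return None
    j = n - 1
    while j >= i and not (row[j] != GAP and row[j] == ref_row[j]):
        j -= 1
    offset = ref_offset + sum(1 for c in ref_row[:i] if c != GAP)
    return PrunedPairwise(
        contig_id=contig_id,
        aligned_ref=ref_row[i : j + 1],
        aligned_contig=row[i : j + 1],
        ref_offset=offset,
    )


# ---------------------------------------------------------------------------
# NovoGraph-Simple
# ---------------------------------------------------------------------------

def simple_contig_to_variants(p: PrunedPairwise, chrom: str) -> list[VariantRecord]:
    """Column-by-column conversion of one pruned pairwise alignment.

    At every reference-identical match column the running buffers are
    gap-stripped and, if they differ, emitted as a variant anchored at the
    match that started the buffer; the buffers then restart from the current
    match. A final flush runs at the end of the alignment."""
    out: list[VariantRecord] = []
    running_ref: list[str] = []
    running_contig: list[str] = []
    refpos = p.ref_offset  # 0-based position of the next reference base
    anchor_pos = p.ref_offset  # 0-based ref coordinate of the buffer start

    def flush() -> None:
        r = "".join(running_ref).replace(GAP, "")
        c = "".join(running_contig).replace(GAP, "")
        if r != c:
            if not r or not c:
                logger.warning(
                    "%s: unanchored allele at %s:%d skipped", p.contig_id, chrom, anchor_pos + 1
                )
            else:
                out.append(
                    VariantRecord(
                        chrom=chrom,
                        pos=anchor_pos + 1,
                        ref_allele=r,
                        alt_alleles=[c],
                        support=[[p.contig_id]],
                    )
                )

    for a, b in zip(p.aligned_ref, p.aligned_contig):
        if a == b and a != GAP:
            flush()
            running_ref.clear()
            running_contig.clear()
            anchor_pos = refpos
        running_ref.append(a)
        running_contig.append(b)
        if a != GAP:
            refpos += 1
    flush()
    return out


def build_simple_vcf(msa: ConcatenatedMsa) -> list[VariantRecord]:
    """Apply prune + Simple conversion to every contig row; identical
    variants from different contigs are merged and records sorted. The
    output may contain overlapping variants."""
    records: list[VariantRecord] = []
    for cid in sorted(msa.rows):
        ar, ac, off = extract_pairwise(msa, cid)
        pruned = prune_pairwise(ac, ar, off, contig_id=cid)
        if pruned is None:
            logger.warning("contig %s: no reference-identical column; skipped", cid)
            continue
        records.extend(simple_contig_to_variants(pruned, msa.ref_id))
    return merge_variant_records(records)


# ---------------------------------------------------------------------------
# NovoGraph-Universal
# ---------------------------------------------------------------------------

def split_on_long_gaps(
    row: str, ref_row: str, limits: GraphLimits, contig_id: str
) -> list[tuple[str, str]]:
    """Split a contig row at contig-gap runs whose deletion size (reference
    bases spanned) strictly exceeds U2; returns (fragment_id, row) pairs
    where each fragment keeps only its own span of the original row."""
    first = next((i for i, c in enumerate(row) if c != GAP), None)
    if first is None:
        return []
    last = len(row) - 1 - next(i for i, c in enumerate(reversed(row)) if c != GAP)
    breaks: list[tuple[int, int]] = []  # gap runs (start, end) exceeding U2
    i = first
    while i <= last:
        if row[i] != GAP:
            i += 1
            continue
        j = i
        while j <= last and row[j] == GAP:
            j += 1
        size = sum(1 for c in ref_row[i:j] if c != GAP)
        if size > limits.u2:
            breaks.append((i, j))
        i = j
    if not breaks:
        return [(contig_id, row)]
    fragments = []
    spans = []
    prev = first
    for s, e in breaks:
        spans.append((prev, s))
        prev = e
    spans.append((prev, last + 1))
    for idx, (s, e) in enumerate(spans):
        frag = GAP * s + row[s:e] + GAP * (len(row) - e)
        fragments.append((f"{contig_id}/part{idx}", frag))
    return fragments


def universal_build(
    msa: ConcatenatedMsa,
    limits: GraphLimits = GraphLimits(),
    stats: dict | None = None,
) -> tuple[list[VariantRecord], list[DroppedContig]]:
    """Column-by-column haplotype-set traversal of the MSA.

    Returns the merged variant records (pairwise non-overlapping by
    construction) and the log of contigs dropped by the U1 entry cap.
    When ``stats`` is a dict it receives ``max_set_size``, the largest
    post-deduplication size of the haplotype set R."""
    ref_row = msa.ref_row
    width = len(ref_row)
    rows: dict[str, str] = {}
    dropped: list[DroppedContig] = []
    for cid in sorted(msa.rows):
        for fid, frag in split_on_long_gaps(msa.rows[cid], ref_row, limits, cid):
            rows[fid] = frag

    entries_at: dict[int, list[str]] = {}
    exits_at: dict[int, list[str]] = {}
    for fid, row in rows.items():
        entry = next(
            (i for i in range(width) if row[i] != GAP and ref_row[i] != GAP), None
        )
        if entry is None:
            logger.warning("contig %s never aligns a base to a reference base; skipped", fid)
            continue
        exit_ = next(
            i for i in range(width - 1, -1, -1) if row[i] != GAP and ref_row[i] != GAP
        )
        entries_at.setdefault(entry, []).append(fid)
        exits_at.setdefault(exit_, []).append(fid)

    records: list[VariantRecord] = []
    R: set[tuple[str, str]] = {("", REF_SOURCE)}
    ref_buf = ""  # the reference's own buffer (exit handling can leave
    # several ref-sourced elements with non-reference buffers in R, so the
    # REF allele is tracked independently of R)
    refcount = 0  # reference bases consumed so far
    anchor_pos = 0  # 0-based reference coordinate of the buffer start
    inactive: set[str] = set()  # dropped at entry

    def emit(parts: dict[tuple[str, str], str], ref_allele: str, pos0: int) -> None:
        """VCF generator: gap-strip received sequences, write a record iff
        any non-reference sequence is present."""
        alts: dict[str, set[str]] = {}
        for (seq, src), s in parts.items():
            allele = s.replace(GAP, "")
            if allele != ref_allele:
                alts.setdefault(allele, set())
                if src != REF_SOURCE:
                    alts[allele].add(src.split("/part")[0])
        if not alts:
            return
        if not ref_allele or any(not a for a in alts):
            logger.warning("unanchored universal allele at %s:%d skipped", msa.ref_id, pos0 + 1)
            return
        alt_list = sorted(alts)
        records.append(
            VariantRecord(
                chrom=msa.ref_id,
                pos=pos0 + 1,
                ref_allele=ref_allele,
                alt_alleles=alt_list,
                support=[sorted(alts[a]) for a in alt_list],
            )
        )

    for c in range(width):
        # contig entries: duplicate R with the entering contig as source
        for fid in entries_at.get(c, ()):
            if len(R) >= limits.u1:
                dropped.append(DroppedContig(fid.split("/part")[0], "entry_prohibited_u1", c))
                inactive.add(fid)
                continue
            R |= {(seq, fid) for seq, _src in R}
        # extension
        R = {
            (seq + (ref_row[c] if src == REF_SOURCE else rows[src][c]), src)
            for seq, src in R
        }
        ref_buf += ref_row[c]
        # contig exits: recombination, then the exiting sources become 'ref'
        exiting = [fid for fid in exits_at.get(c, ()) if fid not in inactive]
        for fid in exiting:
            E = [(seq, src) for seq, src in R if src == fid]
            if len(R) < limits.u1:
                C = {
                    src
                    for _seq, src in R
                    if src != REF_SOURCE and src != fid and src not in exiting
                }
                R |= {(seq, c2) for (seq, _s) in E for c2 in sorted(C)}
            R = {(seq, REF_SOURCE if src == fid else src) for seq, src in R}
        if ref_row[c] != GAP:
            refcount += 1
        # flushing
        ref_char = ref_row[c]
        if (
            ref_char != GAP
            and all(seq[-1] == ref_char for seq, _src in R)
            and all(len(seq) - seq.count(GAP) >= 2 for seq, _src in R)
        ):
            emit(
                {(seq, src): seq[:-1] for seq, src in R},
                ref_buf[:-1].replace(GAP, ""),
                anchor_pos,
            )
            R = {(seq[-1], src) for seq, src in R}
            ref_buf = ref_buf[-1]
            anchor_pos = refcount - 1
        if stats is not None:
            stats["max_set_size"] = max(stats.get("max_set_size", 0), len(R))
        assert len(R) <= 2 * limits.u1, "haplotype set exceeded its cap"

    # final flush at the rightmost column
    if any(seq.replace(GAP, "") != ref_buf.replace(GAP, "") for seq, _src in R):
        emit({(seq, src): seq for seq, src in R}, ref_buf.replace(GAP, ""), anchor_pos)

    merged = merge_variant_records(records)
    for a, b in zip(merged, merged[1:]):
        assert a.pos + len(a.ref_allele) <= b.pos, "universal records overlap"
    return merged, dropped


# ---------------------------------------------------------------------------
# path enumeration (graph traversal oracle)
# ---------------------------------------------------------------------------

def apply_variants(
    ref_seq: str, picks: list[tuple[int, str, str]], start: int, end: int
) -> str:
    """Apply non-overlapping (pos1, ref_allele, alt) picks to the reference
    slice [start, end) (0-based half-open)."""
    picks = sorted(picks)
    out = []
    cur = start
    for pos1, ref_allele, alt in picks:
        p0 = pos1 - 1
        if p0 < cur or p0 + len(ref_allele) > end:
            raise ValueError(f"pick at {pos1} outside region or overlapping")
        if ref_seq[p0 : p0 + len(ref_allele)] != ref_allele:
            raise ValueError(f"REF mismatch at {pos1}")
        out.append(ref_seq[cur:p0])
        out.append(alt)
        cur = p0 + len(ref_allele)
    out.append(ref_seq[cur:end])
    return "".join(out)


def enumerate_graph_paths(
    records: list[VariantRecord],
    ref: SequenceRecord,
    region: tuple[int, int] | None = None,
    max_paths: int = 10**6,
) -> set[str]:
    """All sequences obtainable by choosing the reference or one alt at each
    non-overlapping site inside ``region`` (0-based half-open; default the
    whole reference contig). Refuses combinatorial blow-ups."""
    start, end = region if region is not None else (0, len(ref.sequence))
    sites = [
        r
        for r in sorted(records, key=lambda r: r.pos)
        if r.chrom == ref.id and r.pos - 1 >= start and r.pos - 1 + len(r.ref_allele) <= end
    ]
    for a, b in zip(sites, sites[1:]):
        if a.pos + len(a.ref_allele) > b.pos:
            raise ValueError("overlapping variant records; path enumeration undefined")
    n_paths = 1
    for r in sites:
        n_paths *= 1 + len(r.alt_alleles)
        if n_paths > max_paths:
            raise ValueError(f"more than {max_paths} paths; refusing to enumerate")
    paths = set()
    for choice in product(*[[r.ref_allele] + r.alt_alleles for r in sites]):
        picks = [
            (r.pos, r.ref_allele, alt)
            for r, alt in zip(sites, choice)
            if alt != r.ref_allele
        ]
        paths.add(apply_variants(ref.sequence, picks, start, end))
    return paths
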