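"""Reading and writing of the on-disk formats the pipeline touches.

FASTA in, SAM out/in for pairwise alignments and for the concatenated
multiple sequence alignment (where reference gaps are encoded with the
'P' CIGAR operator), and VCF 4.2 for the final graph.

Conventions
-----------
* Coordinates are 0-based half-open internally; 1-based inclusive only at
  the SAM/VCF boundary.
* The gap character is ``-``; ``N`` is a valid base that matches only ``N``.
* In a gapped column pair, (base, base) is M, (gap, base) with the gap on
  the reference is I, (base, gap) is D, and (gap, gap) — a column forced by
  a third row of the MSA — is P (pad, consumes neither sequence).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pysam

logger = logging.getLogger("novograph")

GAP = "-"
_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


class ConsistencyError(ValueError):
    """Records contradict the reference sequence they claim to describe."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def ungapped(row: str) -> str:
    return row.replace(GAP, "")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A named uppercase DNA sequence over {A,C,G,T,N}."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LocalAlignmentRecord:
    """A pairwise (local or global) alignment of a contig to one reference contig.

    ``contig_start``/``contig_end`` are 1-based inclusive on the *aligned*
    orientation of the contig (i.e. on its reverse complement when
    ``strand == '-'``). ``aligned_ref`` and ``aligned_contig`` are
    equal-length gapped rows.
    """

    contig_id: str
    ref_id: str
    strand: str
    ref_start: int
    ref_end: int
    contig_start: int
    contig_end: int
    aligned_ref: str
    aligned_contig: str
    score: int = 0

    def validate(self, reference: SequenceRecord, contig: SequenceRecord | None = None) -> None:
        if len(self.aligned_ref) != len(self.aligned_contig):
            raise ConsistencyError("aligned rows differ in length")
        if ungapped(self.aligned_ref) != reference.sequence[self.ref_start - 1 : self.ref_end]:
            raise ConsistencyError(
                f"{self.contig_id}: aligned_ref does not match reference "
                f"{self.ref_id}:{self.ref_start}-{self.ref_end}"
            )
        if contig is not None:
            oriented = contig.sequence if self.strand == "+" else revcomp(contig.sequence)
            if ungapped(self.aligned_contig) != oriented[self.contig_start - 1 : self.contig_end]:
                raise ConsistencyError(f"{self.contig_id}: aligned_contig does not match contig")
        for a, b in zip(self.aligned_ref, self.aligned_contig):
            if a == GAP and b == GAP:
                raise ConsistencyError("column with gaps in both rows")


@dataclass
class GappedAlignmentRecord:
    """One row of an MSA as it appears on disk in SAM.

    ``pos`` is the 1-based leftmost reference position consumed by the CIGAR;
    ``cigar`` uses M/I/D/P; ``sequence`` is the ungapped query.
    """

    query_id: str
    ref_id: str
    pos: int
    cigar: str
    sequence: str


@dataclass
class VariantRecord:
    """A left-anchored VCF site; ``support[i]`` lists contigs carrying alt i."""

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: list[str]
    support: list[list[str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into uppercase :class:`SequenceRecord` objects.

    Characters outside {A,C,G,T,N} are mapped to N with a logged warning;
    empty files, empty sequences and duplicate IDs raise :class:`FormatError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            if entry.name in seen:
                raise FormatError(f"duplicate FASTA id {entry.name!r} in {path}")
            seen.add(entry.name)
            seq = entry.sequence.upper() if entry.sequence else ""
            if not seq:
                raise FormatError(f"empty sequence for {entry.name!r} in {path}")
            if not set(seq) <= _VALID:
                n_bad = sum(c not in _VALID for c in seq)
                logger.warning(
                    "%s: %d non-ACGTN characters in %r mapped to N", path, n_bad, entry.name
                )
                seq = "".join(c if c in _VALID else "N" for c in seq)
            records.append(SequenceRecord(entry.name, seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# pairwise alignments <-> SAM
# ---------------------------------------------------------------------------

def _sam_header(refs: list[SequenceRecord]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": r.id, "LN": len(r.sequence)} for r in refs],
        }
    )


def _pairwise_cigar(aligned_ref: str, aligned_contig: str) -> list[tuple[int, int]]:
    """CIGAR (pysam op tuples) for a two-row gapped alignment, ops M/I/D."""
    ops: list[tuple[int, int]] = []
    for a, b in zip(aligned_ref, aligned_contig):
        if a != GAP and b != GAP:
            op = 0  # M
        elif a == GAP and b != GAP:
            op = 1  # I
        elif a != GAP and b == GAP:
            op = 2  # D
        else:
            raise ConsistencyError("column with gaps in both rows")
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    return ops


def edit_distance_of_rows(aligned_ref: str, aligned_contig: str) -> int:
    """NM-style edit distance: mismatches plus inserted plus deleted bases."""
    nm = 0
    for a, b in zip(aligned_ref, aligned_contig):
        if a == GAP and b == GAP:
            continue
        if a == GAP or b == GAP or a != b:
            nm += 1
    return nm


def write_pairwise_sam(
    records: list[LocalAlignmentRecord], refs: list[SequenceRecord], path: str | Path
) -> None:
    """Write pairwise contig-to-reference alignments as coordinate-sorted SAM."""
    header = _sam_header(refs)
    ordered = sorted(records, key=lambda r: (header.get_tid(r.ref_id), r.ref_start, r.contig_id))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in ordered:
            seg = pysam.AlignedSegment(header)
            seg.query_name = rec.contig_id
            seg.reference_id = header.get_tid(rec.ref_id)
            seg.reference_start = rec.ref_start - 1
            seg.flag = 16 if rec.strand == "-" else 0
            seg.mapping_quality = 60
            seg.cigartuples = _pairwise_cigar(rec.aligned_ref, rec.aligned_contig)
            seg.query_sequence = ungapped(rec.aligned_contig)
            seg.set_tag("NM", edit_distance_of_rows(rec.aligned_ref, rec.aligned_contig))
            seg.set_tag("AS", int(rec.score))
            out.write(seg)


def read_pairwise_sam(
    path: str | Path,
    refs: list[SequenceRecord],
    contigs: dict[str, SequenceRecord] | None = None,
) -> list[LocalAlignmentRecord]:
    """Read pairwise alignments (ours, or an external aligner's) from SAM/BAM.

    Gapped rows are reconstructed from CIGAR + SEQ + the reference; records
    without a stored sequence fall back to ``contigs`` (honouring hard clips).
    Unmapped and secondary records without sequence are skipped with a warning.
    """
    by_id = {r.id: r for r in refs}
    out: list[LocalAlignmentRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.cigartuples is None:
                continue
            if seg.reference_name not in by_id:
                raise FormatError(f"alignment references unknown contig {seg.reference_name!r}")
            ref = by_id[seg.reference_name]
            strand = "-" if seg.is_reverse else "+"
            seq = seg.query_sequence
            hard_left = seg.cigartuples[0][1] if seg.cigartuples[0][0] == 5 else 0
            if seq is None:
                if contigs is None or seg.query_name not in contigs:
                    logger.warning("skipping %s: no sequence stored or supplied", seg.query_name)
                    continue
                full = contigs[seg.query_name].sequence
                oriented = full if strand == "+" else revcomp(full)
                hard_right = seg.cigartuples[-1][1] if seg.cigartuples[-1][0] == 5 else 0
                seq = oriented[hard_left : len(oriented) - hard_right]
            aref: list[str] = []
            acon: list[str] = []
            rpos = seg.reference_start
            qpos = 0
            q_start = None
            for op, length in seg.cigartuples:
                if op in (0, 7, 8):  # M/=/X
                    if q_start is None:
                        q_start = qpos
                    aref.append(ref.sequence[rpos : rpos + length])
                    acon.append(seq[qpos : qpos + length])
                    rpos += length
                    qpos += length
                elif op == 1:  # I
                    if q_start is None:
                        q_start = qpos
                    aref.append(GAP * length)
                    acon.append(seq[qpos : qpos + length])
                    qpos += length
                elif op == 2:  # D
                    aref.append(ref.sequence[rpos : rpos + length])
                    acon.append(GAP * length)
                    rpos += length
                elif op == 4:  # S
                    qpos += length
                elif op in (5, 6):  # H, P consume nothing here
                    continue
                else:
                    raise FormatError(f"unsupported CIGAR op {op} in {seg.query_name}")
            q_start = q_start or 0
            score = seg.get_tag("AS") if seg.has_tag("AS") else 0
            out.append(
                LocalAlignmentRecord(
                    contig_id=seg.query_name,
                    ref_id=ref.id,
                    strand=strand,
                    ref_start=seg.reference_start + 1,
                    ref_end=rpos,
                    contig_start=hard_left + q_start + 1,
                    contig_end=hard_left + qpos,
                    aligned_ref="".join(aref),
                    aligned_contig="".join(acon),
                    score=int(score),
                )
            )
    return out


def read_local_alignments_tsv(path: str | Path) -> list[LocalAlignmentRecord]:
    """Read local alignments from a PAF-like TSV with explicit aligned row pairs.

    Columns: contig_id ref_id strand ref_start ref_end contig_start contig_end
    aligned_ref aligned_contig score (1-based inclusive coordinates).
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 10:
                raise FormatError(f"{path}:{lineno}: expected 10 columns, got {len(parts)}")
            out.append(
                LocalAlignmentRecord(
                    contig_id=parts[0],
                    ref_id=parts[1],
                    strand=parts[2],
                    ref_start=int(parts[3]),
                    ref_end=int(parts[4]),
                    contig_start=int(parts[5]),
                    contig_end=int(parts[6]),
                    aligned_ref=parts[7],
                    aligned_contig=parts[8],
                    score=int(parts[9]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# MSA <-> SAM with P operators
# ---------------------------------------------------------------------------

def gapped_rows_to_records(
    ref_id: str, ref_row: str, rows: dict[str, str]
) -> list[GappedAlignmentRecord]:
    """Convert MSA rows (common column space, containing a gapped reference
    row) into SAM records whose CIGARs use P for columns where both the
    reference and the query carry a gap.

    Each row is written over whole insertion blocks (maximal runs of
    reference-gap columns), so the block structure is recoverable.
    """
    n_cols = len(ref_row)
    is_ref_base = [c != GAP for c in ref_row]
    # reference coordinate (0-based, consumed count) before each column
    ref_before = [0] * (n_cols + 1)
    for i, b in enumerate(is_ref_base):
        ref_before[i + 1] = ref_before[i] + (1 if b else 0)
    # block extents: for a ref-gap column, start/end of its maximal run
    block_start = [0] * n_cols
    block_end = [0] * n_cols
    i = 0
    while i < n_cols:
        if is_ref_base[i]:
            i += 1
            continue
        j = i
        while j < n_cols and not is_ref_base[j]:
            j += 1
        for k in range(i, j):
            block_start[k], block_end[k] = i, j
        i = j

    records = []
    for qid, row in sorted(rows.items()):
        if len(row) != n_cols:
            raise ConsistencyError(f"row {qid!r} length {len(row)} != MSA width {n_cols}")
        first = next((i for i, c in enumerate(row) if c != GAP), None)
        if first is None:
            logger.warning("row %r is all-gap; not written", qid)
            continue
        last = max(i for i, c in enumerate(row) if c != GAP)
        if not is_ref_base[first]:
            first = block_start[first]
        if not is_ref_base[last]:
            last = block_end[last] - 1
        ops: list[tuple[int, int]] = []
        for i in range(first, last + 1):
            a, b = is_ref_base[i], row[i] != GAP
            if a and b:
                op = 0  # M
            elif a and not b:
                op = 2  # D
            elif not a and b:
                op = 1  # I
            else:
                op = 6  # P
            if ops and ops[-1][0] == op:
                ops[-1] = (op, ops[-1][1] + 1)
            else:
                ops.append((op, 1))
        # for a row starting inside an insertion block, the block does not
        # consume reference, so the position of the first M/D op is the same
        pos0 = ref_before[first]
        cigar = "".join(f"{n}{'MIDNSHP'[op]}" for op, n in ops)
        records.append(
            GappedAlignmentRecord(
                query_id=qid,
                ref_id=ref_id,
                pos=pos0 + 1,
                cigar=cigar,
                sequence=ungapped(row),
            )
        )
    return records


def write_msa_sam(
    rows: list[GappedAlignmentRecord], ref: SequenceRecord, path: str | Path
) -> None:
    """Write MSA rows (CIGARs over M/I/D/P) as a coordinate-sorted SAM file."""
    header = _sam_header([ref])
    n = len(ref.sequence)
    for rec in rows:
        consumed = sum(int(m.group(1)) for m in re.finditer(r"(\d+)([MD])", rec.cigar))
        if rec.pos < 1 or rec.pos - 1 + consumed > n:
            raise ConsistencyError(f"{rec.query_id}: alignment outside reference span")
        q = sum(int(m.group(1)) for m in re.finditer(r"(\d+)([MIS])", rec.cigar))
        if q != len(rec.sequence):
            raise FormatError(f"{rec.query_id}: CIGAR consumes {q} bases, sequence has {len(rec.sequence)}")
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in sorted(rows, key=lambda r: (r.pos, r.query_id)):
            seg = pysam.AlignedSegment(header)
            seg.query_name = rec.query_id
            seg.reference_id = 0
            seg.reference_start = rec.pos - 1
            seg.mapping_quality = 60
            seg.cigarstring = rec.cigar
            seg.query_sequence = rec.sequence
            out.write(seg)


def read_msa_sam(path: str | Path, ref: SequenceRecord) -> tuple[str, dict[str, str]]:
    """Read an MSA written by :func:`write_msa_sam` back into a common column
    space: returns (gapped reference row, {query_id: full-length gapped row}).

    Inverse of the write path on whole-block rows (bit-exact row recovery).
    """
    n = len(ref.sequence)
    parsed: list[tuple[str, int, list[tuple[int, int]], str]] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.cigartuples is None:
                continue
            if seg.reference_name != ref.id:
                raise FormatError(
                    f"record {seg.query_name!r} aligned to unknown reference {seg.reference_name!r}"
                )
            q = sum(l for op, l in seg.cigartuples if op in (0, 1, 4))
            if seg.query_sequence is None or q != len(seg.query_sequence):
                raise FormatError(f"{seg.query_name}: CIGAR/sequence length mismatch")
            parsed.append(
                (seg.query_name, seg.reference_start, seg.cigartuples, seg.query_sequence)
            )

    # first pass: insertion-block length after each reference position (0..n)
    blocks = [0] * (n + 1)
    for name, start, cig, _seq in parsed:
        rpos = start
        run = 0
        for op, length in cig:
            if op in (1, 6):  # I/P: part of the block after ref position rpos
                run += length
            elif op in (0, 2):
                if run:
                    if blocks[rpos] not in (0, run):
                        raise FormatError(
                            f"inconsistent insertion block at reference position {rpos}"
                        )
                    blocks[rpos] = max(blocks[rpos], run)
                    run = 0
                rpos += length
            else:
                raise FormatError(f"unexpected CIGAR op {op} in MSA SAM record {name}")
        if run:
            if blocks[rpos] not in (0, run):
                raise FormatError(f"inconsistent insertion block at reference position {rpos}")
            blocks[rpos] = max(blocks[rpos], run)

    # column layout: col_of_base[p] = column of reference base p
    width = n + sum(blocks)
    col_of_base = [0] * (n + 1)
    col = blocks[0]
    for p in range(n):
        col_of_base[p] = col
        col += 1 + blocks[p + 1]
    col_of_base[n] = width  # sentinel
    ref_row_chars = [GAP] * width
    for p in range(n):
        ref_row_chars[col_of_base[p]] = ref.sequence[p]
    ref_row = "".join(ref_row_chars)

    rows: dict[str, str] = {}
    for name, start, cig, seq in parsed:
        chars = [GAP] * width
        rpos = start
        qpos = 0
        # leading I/P run sits right-aligned against the block before `start`
        idx = 0
        lead = 0
        while idx < len(cig) and cig[idx][0] in (1, 6):
            lead += cig[idx][1]
            idx += 1
        if lead:
            if start == 0:
                block_cols = range(0, blocks[0])
            else:
                base_col = col_of_base[start - 1]
                block_cols = range(base_col + 1, base_col + 1 + blocks[start])
            if lead != len(block_cols):
                raise FormatError(f"{name}: leading insertion run does not fill its block")
            it = iter(block_cols)
            for op, length in cig[:idx]:
                for _ in range(length):
                    c = next(it)
                    if op == 1:
                        chars[c] = seq[qpos]
                        qpos += 1
        cur_run_cols: list[int] = []
        for op, length in cig[idx:]:
            if op in (0, 2):
                for _ in range(length):
                    c = col_of_base[rpos]
                    if op == 0:
                        chars[c] = seq[qpos]
                        qpos += 1
                    rpos += 1
                cur_run_cols = list(
                    range(col_of_base[rpos - 1] + 1, col_of_base[rpos - 1] + 1 + blocks[rpos])
                )
            else:  # I or P inside/after the row
                if len(cur_run_cols) < length:
                    raise FormatError(f"{name}: insertion run exceeds its block")
                use, cur_run_cols = cur_run_cols[:length], cur_run_cols[length:]
                for c in use:
                    if op == 1:
                        chars[c] = seq[qpos]
                        qpos += 1
        if name in rows:
            raise FormatError(f"duplicate MSA row {name!r}")
        rows[name] = "".join(chars)
    return ref_row, rows


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def merge_variant_records(records: list[VariantRecord]) -> list[VariantRecord]:
    """Collapse identical (chrom,pos,ref,alt) across contigs and join
    different alts at the same (chrom,pos,ref) into one multi-allelic record,
    sorted by (chrom, pos)."""
    merged: dict[tuple[str, int, str], dict[str, set[str]]] = {}
    for rec in records:
        key = (rec.chrom, rec.pos, rec.ref_allele)
        alts = merged.setdefault(key, {})
        supports = rec.support or [[] for _ in rec.alt_alleles]
        for alt, sup in zip(rec.alt_alleles, supports):
            if alt == rec.ref_allele:
                raise ConsistencyError(f"alt equals ref at {rec.chrom}:{rec.pos}")
            alts.setdefault(alt, set()).update(sup)
    out = []
    for (chrom, pos, ref), alts in sorted(merged.items()):
        alt_list = sorted(alts)
        out.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref_allele=ref,
                alt_alleles=alt_list,
                support=[sorted(alts[a]) for a in alt_list],
            )
        )
    return out


def write_vcf(
    records: list[VariantRecord], refs: list[SequenceRecord], path: str | Path
) -> None:
    """Write merged, coordinate-sorted VCF 4.2. Raises :class:`ConsistencyError`
    when a REF allele does not match the reference sequence."""
    by_id = {r.id: r for r in refs}
    merged = merge_variant_records(records)
    for rec in merged:
        if rec.chrom not in by_id:
            raise ConsistencyError(f"variant on unknown reference contig {rec.chrom!r}")
        ref_seq = by_id[rec.chrom].sequence
        if ref_seq[rec.pos - 1 : rec.pos - 1 + len(rec.ref_allele)] != rec.ref_allele:
            raise ConsistencyError(
                f"REF allele mismatch at {rec.chrom}:{rec.pos} "
                f"({rec.ref_allele!r} vs reference)"
            )
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for r in refs:
        header.contigs.add(r.id, length=len(r.sequence))
    header.add_meta(
        "INFO",
        items=[
            ("ID", "SUPPORT"), ("Number", "."), ("Type", "String"),
            ("Description", "Supporting contig IDs per ALT allele, |-separated"),
        ],
    )
    order = {r.id: i for i, r in enumerate(refs)}
    merged.sort(key=lambda r: (order[r.chrom], r.pos, r.ref_allele))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in merged:
            vr = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=tuple([rec.ref_allele] + rec.alt_alleles),
            )
            vr.info["SUPPORT"] = tuple("|".join(s) if s else "." for s in rec.support)
            out.write(vr)


def read_vcf(path: str | Path) -> list[VariantRecord]:
    out = []
    with pysam.VariantFile(str(path)) as fh:
        for rec in fh:
            support = rec.info.get("SUPPORT", tuple("." for _ in rec.alts or ()))
            if isinstance(support, str):
                support = (support,)
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_alleles=list(rec.alts or ()),
                    support=[[] if s == "." else s.split("|") for s in support],
                )
            )
    return out
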