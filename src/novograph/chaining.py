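"""Step 1: global contig-to-reference alignment by collinear chaining.

Local alignments ("diagonals") between a contig and the reference are
combined into the best-scoring global alignment by a dynamic program over
path *entry* and *exit* points: a valid traversal starts at ORIGIN, ends at
TERMINUS, alternates between exit and entry points, pairs each entry with an
exit on the same diagonal, and moves monotonically in both the reference and
the contig coordinate. Within-diagonal scores use +1 per match and -1 per
mismatch or gap column; jumps between diagonals are charged ``gap_score``
per skipped base in either dimension. Jumps from ORIGIN and to TERMINUS are
not charged along the reference dimension (ends-free alignment), but are
charged along the contig dimension, so the whole contig is always consumed.

Coordinates of points are 0-based "consumed-character" states: point (a, b)
means a reference and b contig characters have been consumed, as in the
classical Needleman-Wunsch matrix. A diagonal spanning reference positions
4..10 and contig positions 3..11 (1-based, the d1..d4 convention) has its
start-of-diagonal entry at state (3, 2) and end-of-diagonal exit at (10, 11).
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from itertools import accumulate
from pathlib import Path

import numpy as np

from .io import (
    GAP,
    ConsistencyError,
    LocalAlignmentRecord,
    SequenceRecord,
    revcomp,
    ungapped,
)

logger = logging.getLogger("novograph")

ORIGIN = "ORIGIN"
TERMINUS = "TERMINUS"
ENTRY_START = "ENTRY_START"
ENTRY_WITHIN = "ENTRY_WITHIN"
EXIT_END = "EXIT_END"
EXIT_WITHIN = "EXIT_WITHIN"


class ConfigurationError(RuntimeError):
    """A requested external alignment engine is not available."""


class NoAlignmentError(ValueError):
    """Chaining was asked to run on an empty diagonal set."""


# ---------------------------------------------------------------------------
# diagonals
# ---------------------------------------------------------------------------

@dataclass
class Diagonal:
    """A local alignment viewed as a (near-)diagonal of the global matrix.

    ``d1``/``d2`` are the 1-based start, ``d3``/``d4`` the 1-based stop
    coordinates on the reference and contig; ``ref_after``/``con_after``
    give the absolute consumed-character state after each alignment column,
    and ``prefix`` the cumulative +1/-1 column score.
    """

    id: str
    ref_id: str
    strand: str
    d1: int
    d2: int
    d3: int
    d4: int
    aligned_ref: str
    aligned_contig: str
    ref_after: np.ndarray = field(repr=False)
    con_after: np.ndarray = field(repr=False)
    prefix: np.ndarray = field(repr=False)

    @property
    def n_columns(self) -> int:
        return len(self.aligned_ref)

    def entry_state(self, col: int) -> tuple[int, int]:
        """Consumed state immediately before column ``col``."""
        if col == 0:
            return (self.d1 - 1, self.d2 - 1)
        return (int(self.ref_after[col - 1]), int(self.con_after[col - 1]))

    def exit_state(self, col: int) -> tuple[int, int]:
        """Consumed state immediately after column ``col``."""
        return (int(self.ref_after[col]), int(self.con_after[col]))

    def segment_score(self, entry_col: int, exit_col: int) -> int:
        s = int(self.prefix[exit_col])
        if entry_col > 0:
            s -= int(self.prefix[entry_col - 1])
        return s


def make_diagonal(rec: LocalAlignmentRecord, diag_id: str | None = None) -> Diagonal:
    """Turn a local alignment record into a scored diagonal (+1 match,
    -1 mismatch/gap per column)."""
    ar, ac = rec.aligned_ref, rec.aligned_contig
    if len(ar) != len(ac) or not ar:
        raise ConsistencyError("invalid aligned rows")
    ref_after = np.cumsum([c != GAP for c in ar]) + (rec.ref_start - 1)
    con_after = np.cumsum([c != GAP for c in ac]) + (rec.contig_start - 1)
    col_scores = [1 if (a == b and a != GAP) else -1 for a, b in zip(ar, ac)]
    return Diagonal(
        id=diag_id if diag_id is not None else f"{rec.contig_id}:{rec.ref_id}:{rec.strand}:{rec.ref_start}-{rec.ref_end}:{rec.contig_start}",
        ref_id=rec.ref_id,
        strand=rec.strand,
        d1=rec.ref_start,
        d2=rec.contig_start,
        d3=rec.ref_end,
        d4=rec.contig_end,
        aligned_ref=ar,
        aligned_contig=ac,
        ref_after=ref_after,
        con_after=con_after,
        prefix=np.array(list(accumulate(col_scores))),
    )


# ---------------------------------------------------------------------------
# entry / exit points
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathPoint:
    """A traversal point: a diagonal (or None for ORIGIN/TERMINUS), a
    consumed-character state and, for diagonal points, the alignment column
    the point precedes (entries) or follows (exits)."""

    diagonal_id: str | None
    ref_coord: int
    contig_coord: int
    kind: str
    col: int = -1

    @property
    def state(self) -> tuple[int, int]:
        return (self.ref_coord, self.contig_coord)


@dataclass
class Traversal:
    points: list[PathPoint]
    score: int


def _first_col_with(values: np.ndarray, target: int) -> int | None:
    """First index where the non-decreasing ``values`` equals ``target``."""
    i = int(np.searchsorted(values, target))
    if i < len(values) and int(values[i]) == target:
        return i
    return None


def build_point_sets(diagonals: list[Diagonal]) -> tuple[list[PathPoint], list[PathPoint]]:
    """The sets P_ENTRY and P_EXIT.

    Every diagonal contributes its start-of-diagonal entry and
    end-of-diagonal exit. Additionally, a within-diagonal exit is placed at
    the first column of ``d`` whose after-state aligns horizontally or
    vertically with another diagonal's start-of-diagonal entry state, and a
    within-diagonal entry symmetrically against other diagonals' exits.
    """
    if len({(d.ref_id, d.strand) for d in diagonals}) > 1:
        raise ValueError("diagonals must share reference contig and strand")
    entries: list[PathPoint] = []
    exits: list[PathPoint] = []
    start_refs = {d.id: d.d1 - 1 for d in diagonals}
    start_cons = {d.id: d.d2 - 1 for d in diagonals}
    end_refs = {d.id: d.d3 for d in diagonals}
    end_cons = {d.id: d.d4 for d in diagonals}

    for d in diagonals:
        seen_entries = set()
        seen_exits = set()
        s = d.entry_state(0)
        entries.append(PathPoint(d.id, s[0], s[1], ENTRY_START, 0))
        seen_entries.add(s)
        e = d.exit_state(d.n_columns - 1)
        exits.append(PathPoint(d.id, e[0], e[1], EXIT_END, d.n_columns - 1))
        seen_exits.add(e)

        # within-diagonal exits aligned with other diagonals' start entries
        for other_id in start_refs:
            if other_id == d.id:
                continue
            for values, target in (
                (d.ref_after, start_refs[other_id]),
                (d.con_after, start_cons[other_id]),
            ):
                col = _first_col_with(values, target)
                if col is not None and col < d.n_columns - 1:
                    st = d.exit_state(col)
                    if st not in seen_exits:
                        exits.append(PathPoint(d.id, st[0], st[1], EXIT_WITHIN, col))
                        seen_exits.add(st)
        # within-diagonal entries aligned with other diagonals' end exits
        for other_id in end_refs:
            if other_id == d.id:
                continue
            for values, target in (
                (d.ref_after, end_refs[other_id]),
                (d.con_after, end_cons[other_id]),
            ):
                prev = _first_col_with(values, target)
                if prev is not None and prev + 1 <= d.n_columns - 1:
                    col = prev + 1
                    st = d.entry_state(col)
                    if st not in seen_entries:
                        entries.append(PathPoint(d.id, st[0], st[1], ENTRY_WITHIN, col))
                        seen_entries.add(st)
    return entries, exits


# ---------------------------------------------------------------------------
# the chaining dynamic program
# ---------------------------------------------------------------------------

def transition_score(
    exit_pt: PathPoint, entry_pt: PathPoint, gap_score: int = -1
) -> int:
    """Cost of jumping from an exit to an entry point: ``gap_score`` per
    skipped base in either dimension. ORIGIN/TERMINUS jumps are free along
    the reference dimension (ends-free alignment) but charged along the
    contig dimension."""
    dref = entry_pt.ref_coord - exit_pt.ref_coord
    dcon = entry_pt.contig_coord - exit_pt.contig_coord
    if dref < 0 or dcon < 0:
        raise ValueError("transition violates coordinate monotonicity")
    if exit_pt.kind == ORIGIN or entry_pt.kind == TERMINUS:
        dref = 0
    return gap_score * (dref + dcon)


def chain(
    diagonals: list[Diagonal],
    ref_len: int,
    contig_len: int,
    gap_score: int = -1,
) -> Traversal:
    """Find the maximum-scoring valid traversal ORIGIN -> ... -> TERMINUS.

    Points are processed in coordinate order (exits before entries at equal
    coordinates); ties between equal-scoring predecessors are broken toward
    the lexicographically earlier diagonal id, then the smaller coordinates,
    which makes the result deterministic.
    """
    if not diagonals:
        raise NoAlignmentError("no diagonals to chain")
    by_id = {d.id: d for d in diagonals}
    if len(by_id) != len(diagonals):
        raise ValueError("duplicate diagonal ids")
    entries, exits = build_point_sets(diagonals)

    origin = PathPoint(None, 0, 0, ORIGIN)
    terminus = PathPoint(None, ref_len, contig_len, TERMINUS)
    points = entries + exits
    # exits sort before entries at equal coordinates so abutting jumps work
    kind_rank = {EXIT_END: 0, EXIT_WITHIN: 0, ENTRY_START: 1, ENTRY_WITHIN: 1}
    points.sort(
        key=lambda p: (p.ref_coord, p.contig_coord, kind_rank[p.kind], p.diagonal_id, p.col)
    )

    NEG = float("-inf")
    best: dict[PathPoint, float] = {}
    parent: dict[PathPoint, PathPoint | None] = {}
    entries_by_diag: dict[str, list[PathPoint]] = {}
    processed_exits: list[PathPoint] = []

    def pred_key(p: PathPoint) -> tuple:
        return ("" if p.diagonal_id is None else p.diagonal_id, p.ref_coord, p.contig_coord)

    from bisect import insort

    for p in points:
        if kind_rank[p.kind] == 1:  # entry: reachable from ORIGIN or any exit
            # ORIGIN first, then processed exits in deterministic order
            b = gap_score * p.contig_coord  # ORIGIN -> p, reference jump free
            par: PathPoint | None = origin
            pr, pc = p.ref_coord, p.contig_coord
            for x in processed_exits:
                if x.ref_coord > pr or x.contig_coord > pc or best[x] == NEG:
                    continue
                s = best[x] + gap_score * ((pr - x.ref_coord) + (pc - x.contig_coord))
                if s > b:
                    b, par = s, x
            best[p] = b
            parent[p] = par
            insort(entries_by_diag.setdefault(p.diagonal_id, []), p, key=pred_key)
        else:  # exit: must be paired with an earlier entry on the same diagonal
            d = by_id[p.diagonal_id]
            b, par = NEG, None
            for e in entries_by_diag.get(p.diagonal_id, []):
                if (
                    e.col > p.col
                    or e.ref_coord > p.ref_coord
                    or e.contig_coord > p.contig_coord
                    or best[e] == NEG
                ):
                    continue
                s = best[e] + d.segment_score(e.col, p.col)
                if s > b:
                    b, par = s, e
            best[p] = b
            parent[p] = par
            insort(processed_exits, p, key=pred_key)

    # TERMINUS
    b = gap_score * contig_len  # ORIGIN -> TERMINUS, the empty traversal
    par: PathPoint | None = None
    for x in sorted(processed_exits, key=pred_key):
        if best[x] == NEG:
            continue
        s = best[x] + transition_score(x, terminus, gap_score)
        if s > b:
            b, par = s, x

    chain_pts: list[PathPoint] = [terminus]
    cur = par
    while cur is not None and cur.kind != ORIGIN:
        chain_pts.append(cur)
        cur = parent.get(cur)
    chain_pts.append(origin)
    chain_pts.reverse()
    return Traversal(points=chain_pts, score=int(b))


def validate_traversal(trav: Traversal, diagonals: list[Diagonal], ref_len: int, contig_len: int) -> None:
    """Assert conditions (i)-(vi) of a valid traversal; raises AssertionError."""
    pts = trav.points
    assert pts[0].kind == ORIGIN and pts[0].state == (0, 0)
    assert pts[-1].kind == TERMINUS and pts[-1].state == (ref_len, contig_len)
    for i, p in enumerate(pts):
        if i % 2 == 0:
            assert p.kind in (ORIGIN, EXIT_END, EXIT_WITHIN), f"point {i} not exit-class"
        else:
            assert p.kind in (TERMINUS, ENTRY_START, ENTRY_WITHIN), f"point {i} not entry-class"
    for a, b in zip(pts, pts[1:]):
        assert a.ref_coord <= b.ref_coord and a.contig_coord <= b.contig_coord, "monotonicity"
    for i in range(1, len(pts) - 1, 2):
        assert pts[i].diagonal_id == pts[i + 1].diagonal_id, "entry/exit diagonal pairing"
    assert len(set(pts)) == len(pts), "points not unique"


# ---------------------------------------------------------------------------
# rendering a traversal as an alignment
# ---------------------------------------------------------------------------

@dataclass
class GlobalAlignment:
    """Chained global alignment: the whole (oriented) contig against the
    reference slice ``[ref_start, ref_end)`` (0-based half-open)."""

    contig_id: str
    ref_id: str
    strand: str
    ref_start: int
    ref_end: int
    aligned_ref: str
    aligned_contig: str
    score: int

    def to_record(self) -> LocalAlignmentRecord:
        return LocalAlignmentRecord(
            contig_id=self.contig_id,
            ref_id=self.ref_id,
            strand=self.strand,
            ref_start=self.ref_start + 1,
            ref_end=self.ref_end,
            contig_start=1,
            contig_end=len(ungapped(self.aligned_contig)),
            aligned_ref=self.aligned_ref,
            aligned_contig=self.aligned_contig,
            score=self.score,
        )


def traversal_to_alignment(
    trav: Traversal,
    diagonals: list[Diagonal],
    reference: SequenceRecord,
    contig: SequenceRecord,
) -> GlobalAlignment | None:
    """Render a traversal as gapped rows.

    Inter-diagonal jumps become a block of contig-insertion columns followed
    by a block of reference-deletion columns; unaligned leading/trailing
    contig bases become insertion columns at the ends. Returns None for the
    empty traversal (no diagonal used)."""
    pts = trav.points
    if len(pts) <= 2:
        return None
    by_id = {d.id: d for d in diagonals}
    strand = by_id[pts[1].diagonal_id].strand
    oriented = contig.sequence if strand == "+" else revcomp(contig.sequence)
    parts_ref: list[str] = []
    parts_con: list[str] = []

    first_entry = pts[1]
    ref_start = first_entry.ref_coord
    # leading unaligned contig bases: insertions (ends-free on reference only)
    if first_entry.contig_coord > 0:
        parts_ref.append(GAP * first_entry.contig_coord)
        parts_con.append(oriented[: first_entry.contig_coord])
    prev_exit: PathPoint | None = None
    for i in range(1, len(pts) - 1, 2):
        entry, exit_ = pts[i], pts[i + 1]
        if prev_exit is not None:
            dcon = entry.contig_coord - prev_exit.contig_coord
            dref = entry.ref_coord - prev_exit.ref_coord
            if dcon:  # contig insertions first (deterministic rendering)
                parts_ref.append(GAP * dcon)
                parts_con.append(oriented[prev_exit.contig_coord : entry.contig_coord])
            if dref:
                parts_ref.append(reference.sequence[prev_exit.ref_coord : entry.ref_coord])
                parts_con.append(GAP * dref)
        d = by_id[entry.diagonal_id]
        parts_ref.append(d.aligned_ref[entry.col : exit_.col + 1])
        parts_con.append(d.aligned_contig[entry.col : exit_.col + 1])
        prev_exit = exit_
    ref_end = prev_exit.ref_coord
    trailing = len(oriented) - prev_exit.contig_coord
    if trailing:
        parts_ref.append(GAP * trailing)
        parts_con.append(oriented[prev_exit.contig_coord :])
    aligned_ref = "".join(parts_ref)
    aligned_contig = "".join(parts_con)
    assert ungapped(aligned_contig) == oriented, "contig characters not conserved"
    assert ungapped(aligned_ref) == reference.sequence[ref_start:ref_end]
    return GlobalAlignment(
        contig_id=contig.id,
        ref_id=reference.id,
        strand=strand,
        ref_start=ref_start,
        ref_end=ref_end,
        aligned_ref=aligned_ref,
        aligned_contig=aligned_contig,
        score=trav.score,
    )


# ---------------------------------------------------------------------------
# local alignment engines
# ---------------------------------------------------------------------------

def _match_forward(a: str, b: str, ai: int, bi: int, chunk: int = 256) -> int:
    """Length of the longest common prefix of a[ai:] and b[bi:]."""
    n = min(len(a) - ai, len(b) - bi)
    i = 0
    while i < n:
        j = min(i + chunk, n)
        if a[ai + i : ai + j] == b[bi + i : bi + j]:
            i = j
            continue
        for k in range(i, j):
            if a[ai + k] != b[bi + k]:
                return k
    return n


def _match_backward(a: str, b: str, ai: int, bi: int, chunk: int = 256) -> int:
    """Length of the longest common suffix of a[:ai] and b[:bi]."""
    n = min(ai, bi)
    i = 0
    while i < n:
        j = min(i + chunk, n)
        if a[ai - j : ai - i] == b[bi - j : bi - i]:
            i = j
            continue
        for k in range(i, j):
            if a[ai - 1 - k] != b[bi - 1 - k]:
                return k
    return n


def maximal_exact_matches(ref: str, query: str, k: int) -> list[tuple[int, int, int]]:
    """All maximal exact matches of length >= k as (ref_pos, query_pos, length),
    both 0-based. Deterministic; used by the internal seeding engine."""
    if len(query) < k or len(ref) < k:
        return []
    index: dict[str, list[int]] = {}
    for i in range(len(query) - k + 1):
        index.setdefault(query[i : i + k], []).append(i)
    mems: list[tuple[int, int, int]] = []
    ends: dict[int, int] = {}  # diagonal offset -> query end (exclusive) of last MEM
    for j in range(len(ref) - k + 1):
        hits = index.get(ref[j : j + k])
        if not hits:
            continue
        for i in hits:
            off = j - i
            if i < ends.get(off, 0):
                continue  # inside an already reported MEM on this diagonal
            left = _match_backward(ref, query, j, i)
            right = _match_forward(ref, query, j + k, i + k)
            length = k + left + right
            mems.append((j - left, i - left, length))
            ends[off] = i + k + right
    mems.sort()
    return mems


def _internal_seed(
    contig: SequenceRecord, reference: SequenceRecord, k: int
) -> list[LocalAlignmentRecord]:
    records = []
    for strand in "+-":
        seq = contig.sequence if strand == "+" else revcomp(contig.sequence)
        for rpos, qpos, length in maximal_exact_matches(reference.sequence, seq, k):
            block = reference.sequence[rpos : rpos + length]
            records.append(
                LocalAlignmentRecord(
                    contig_id=contig.id,
                    ref_id=reference.id,
                    strand=strand,
                    ref_start=rpos + 1,
                    ref_end=rpos + length,
                    contig_start=qpos + 1,
                    contig_end=qpos + length,
                    aligned_ref=block,
                    aligned_contig=block,
                    score=length,
                )
            )
    return records


def _external_seed(
    contig: SequenceRecord, references: list[SequenceRecord], engine: str
) -> list[LocalAlignmentRecord]:
    from .io import read_pairwise_sam, write_fasta

    exe = shutil.which(engine)
    if exe is None:
        raise ConfigurationError(f"external aligner {engine!r} not found on PATH")
    with tempfile.TemporaryDirectory(prefix="novograph_") as tmp:
        tmp = Path(tmp)
        ref_fa = tmp / "ref.fa"
        ctg_fa = tmp / "contig.fa"
        sam = tmp / "aln.sam"
        write_fasta(references, ref_fa)
        write_fasta([contig], ctg_fa)
        if engine == "bwa":
            subprocess.run([exe, "index", str(ref_fa)], check=True, capture_output=True)
            with open(sam, "wb") as out:
                subprocess.run(
                    [exe, "mem", "-a", str(ref_fa), str(ctg_fa)],
                    check=True, stdout=out, stderr=subprocess.DEVNULL,
                )
        elif engine == "minimap2":
            with open(sam, "wb") as out:
                subprocess.run(
                    [exe, "-a", "--secondary=yes", str(ref_fa), str(ctg_fa)],
                    check=True, stdout=out, stderr=subprocess.DEVNULL,
                )
        else:
            raise ConfigurationError(f"unknown engine {engine!r}")
        return read_pairwise_sam(sam, references, contigs={contig.id: contig})


def find_diagonals(
    contig: SequenceRecord,
    reference: SequenceRecord,
    engine: str = "internal",
    k: int = 15,
) -> list[LocalAlignmentRecord]:
    """High-scoring local alignments of ``contig`` against one reference
    contig. The internal engine reports all maximal exact matches of length
    >= ``k`` on both strands as gapless local alignments; ``bwa``/``minimap2``
    shell out to the external aligner."""
    if engine == "internal":
        return _internal_seed(contig, reference, k)
    if engine not in ("bwa", "minimap2"):
        raise ConfigurationError(f"unknown alignment engine {engine!r}")
    return [r for r in _external_seed(contig, [reference], engine) if r.ref_id == reference.id]


def global_align_contig(
    contig: SequenceRecord,
    references: list[SequenceRecord],
    engine: str = "internal",
    k: int = 15,
    gap_score: int = -1,
) -> GlobalAlignment | None:
    """Chain local alignments into the best global alignment over all
    (reference contig, orientation) pairs; None when no diagonals are found
    (the contig is then ignored downstream)."""
    if engine in ("bwa", "minimap2"):
        records = _external_seed(contig, references, engine)
    elif engine == "internal":
        records = []
        for ref in references:
            records.extend(_internal_seed(contig, ref, k))
    else:
        raise ConfigurationError(f"unknown alignment engine {engine!r}")
    if not records:
        logger.info("contig %s: no local alignments found; ignored", contig.id)
        return None
    ref_by_id = {r.id: r for r in references}
    partitions: dict[tuple[str, str], list[Diagonal]] = {}
    for idx, rec in enumerate(sorted(records, key=lambda r: (r.ref_id, r.strand, r.ref_start, r.contig_start))):
        partitions.setdefault((rec.ref_id, rec.strand), []).append(
            make_diagonal(rec, diag_id=f"d{idx:06d}")
        )
    best: tuple[int, str, str] | None = None
    best_result: tuple[Traversal, list[Diagonal], SequenceRecord] | None = None
    strand_rank = {"+": 0, "-": 1}
    for (ref_id, strand), diags in sorted(
        partitions.items(), key=lambda kv: (kv[0][0], strand_rank[kv[0][1]])
    ):
        ref = ref_by_id[ref_id]
        trav = chain(diags, len(ref.sequence), len(contig.sequence), gap_score)
        key = (-trav.score, ref_id, strand_rank[strand])
        if best is None or key < best:
            best = key
            best_result = (trav, diags, ref)
    trav, diags, ref = best_result
    aln = traversal_to_alignment(trav, diags, ref, contig)
    if aln is None:
        logger.info("contig %s: best traversal uses no diagonal; ignored", contig.id)
    return aln
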