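"""Step 2: windowed multiple sequence alignment.

The reference is tiled into non-overlapping windows of approximately
10,000 bases. Tentative boundaries sit at exact multiples of the window
size; each is then moved, independently, to the position within +/- 100 bp
whose pairwise-alignment columns carry the lowest proportion of gaps, so
windows avoid cutting through indels (final sizes 9,800-10,200 bases; the
terminal window absorbs the sub-window remainder). Contig sequence is
assigned to windows by the Step-1 alignment, each window is aligned as an
independent MSA (trivially parallelizable), and the per-window MSAs are
concatenated into one approximate global MSA per reference contig.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np

from .chaining import GlobalAlignment
from .io import GAP, FormatError, SequenceRecord, read_fasta, ungapped, write_fasta

logger = logging.getLogger("novograph")

_GAP_BYTE = ord(GAP)


@dataclass(frozen=True)
class Window:
    """A reference tile, 0-based half-open."""

    ref_id: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class WindowSequenceSet:
    """The sequences entering one window's MSA: the reference slice plus the
    contig bases assigned to the window by the Step-1 alignments.

    ``members`` holds (contig_id, slice, is_opening, is_closing); a slice may
    be empty when a deletion spans the whole window."""

    window: Window
    ref_slice: str
    members: list[tuple[str, str, bool, bool]] = field(default_factory=list)


@dataclass
class WindowMsa:
    """Gapped rows of one window, all equal length; the reference row is
    kept separate from the contig rows."""

    window: Window
    ref_row: str
    rows: dict[str, str]

    @property
    def width(self) -> int:
        return len(self.ref_row)


@dataclass
class ConcatenatedMsa:
    """Approximate global MSA of one reference contig and all contigs
    initially aligned to it."""

    ref_id: str
    ref_row: str
    rows: dict[str, str]

    @property
    def width(self) -> int:
        return len(self.ref_row)

    def aligned_span(self, contig_id: str) -> tuple[int, int]:
        """First and last (inclusive) non-gap column of a contig row."""
        row = self.rows[contig_id]
        first = next(i for i, c in enumerate(row) if c != GAP)
        last = len(row) - 1 - next(i for i, c in enumerate(reversed(row)) if c != GAP)
        return first, last


# ---------------------------------------------------------------------------
# window boundaries
# ---------------------------------------------------------------------------

def choose_window_boundaries(
    alignments: list[GlobalAlignment],
    ref: SequenceRecord,
    window_size: int = 10_000,
    boundary_scan: int = 100,
) -> list[Window]:
    """Tile ``ref`` into windows, nudging each tentative boundary (multiples
    of ``window_size``) to the surrounding position with the lowest gap
    proportion across the pairwise-alignment columns mapped to it.

    Ties are broken toward the smallest offset from the tentative boundary,
    then toward the left. Positions covered by no alignment count as
    proportion 0. The final window absorbs any sub-window remainder.
    """
    L = len(ref.sequence)
    covered = np.zeros(L, dtype=np.int32)
    gapped = np.zeros(L, dtype=np.int32)
    for aln in alignments:
        if aln.ref_id != ref.id:
            continue
        ar = np.frombuffer(aln.aligned_ref.encode(), np.uint8)
        ac = np.frombuffer(aln.aligned_contig.encode(), np.uint8)
        consumes = ar != _GAP_BYTE
        contig_gap = (ac == _GAP_BYTE)[consumes]
        covered[aln.ref_start : aln.ref_end] += 1
        gapped[aln.ref_start : aln.ref_end] += contig_gap
    boundaries = []
    for t in range(window_size, L, window_size):
        lo = max(1, t - boundary_scan)
        hi = min(L - 1, t + boundary_scan)
        best = None
        for p in range(lo, hi + 1):
            prop = gapped[p] / covered[p] if covered[p] else 0.0
            key = (prop, abs(p - t), p)
            if best is None or key < best:
                best = key
        boundaries.append(best[2])
    starts = [0] + boundaries
    ends = boundaries + [L]
    return [Window(ref.id, s, e) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# assigning contig sequence to windows
# ---------------------------------------------------------------------------

def partition_alignment(
    alignment: GlobalAlignment, windows: list[Window]
) -> list[tuple[int, str]]:
    """Assign the contig's bases to windows via the pairwise alignment.

    Each base goes to the window of the reference position of its column;
    insertion columns attach to the window of the nearest preceding
    reference-consuming column (leading insertions to the first overlapped
    window). Returns (window_index, slice) for every window the alignment
    touches, in order; slices concatenate to the full aligned contig."""
    if not windows or windows[0].ref_id != alignment.ref_id:
        raise ValueError("windows and alignment must share a reference contig")
    starts = np.array([w.start for w in windows])
    ar = np.frombuffer(alignment.aligned_ref.encode(), np.uint8)
    ac = np.frombuffer(alignment.aligned_contig.encode(), np.uint8)
    consumes = ar != _GAP_BYTE
    # reference base index of each column; insertions inherit the previous one
    refpos = np.cumsum(consumes) - 1 + alignment.ref_start
    refpos = np.maximum(refpos, alignment.ref_start)  # leading insertions
    widx = np.searchsorted(starts, refpos, side="right") - 1
    con_mask = ac != _GAP_BYTE
    base_windows = widx[con_mask]
    bases = ac[con_mask]
    w_first, w_last = int(widx.min()), int(widx.max())
    slices = {w: "" for w in range(w_first, w_last + 1)}
    if len(bases):
        cuts = np.flatnonzero(np.diff(base_windows)) + 1
        for chunk, w in zip(
            np.split(bases, cuts), [int(base_windows[0])] + [int(base_windows[c]) for c in cuts]
        ):
            slices[w] = slices.get(w, "") + chunk.tobytes().decode()
    return [(w, slices[w]) for w in sorted(slices)]


def build_window_sets(
    alignments: list[GlobalAlignment], windows: list[Window], ref: SequenceRecord
) -> list[WindowSequenceSet]:
    """One :class:`WindowSequenceSet` per window, members in input order."""
    sets = [
        WindowSequenceSet(window=w, ref_slice=ref.sequence[w.start : w.end])
        for w in windows
    ]
    for aln in alignments:
        if aln.ref_id != ref.id:
            continue
        parts = partition_alignment(aln, windows)
        for i, (w, piece) in enumerate(parts):
            sets[w].members.append(
                (aln.contig_id, piece, i == 0, i == len(parts) - 1)
            )
    return sets


# ---------------------------------------------------------------------------
# per-window MSA
# ---------------------------------------------------------------------------

class MsaEngineError(RuntimeError):
    def __init__(self, window: Window, message: str):
        super().__init__(f"MSA failed in window {window.ref_id}:{window.start}-{window.end}: {message}")
        self.window = window


def _pairwise_path(query: str, target: str) -> list[tuple[str, int]]:
    """Global alignment path of query against target as (op, length) runs
    over {'=', 'X', 'I', 'D'} (I consumes query, D consumes target)."""
    res = edlib.align(query, target, mode="NW", task="path")
    cigar = res["cigar"]
    if cigar is None:
        raise RuntimeError("edlib returned no path")
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    return out


def _chain_pairwise_rows(seq: str, ref_slice: str, k: int) -> tuple[str, str] | None:
    """Gapped (ref, member) rows from a seed-and-chain alignment scored
    +1 match / -1 mismatch / -1 gap, ends-free on the reference; None when
    no forward-strand seed of length >= k exists."""
    from .chaining import chain, find_diagonals, make_diagonal, traversal_to_alignment

    ref_rec = SequenceRecord("w", ref_slice)
    mem_rec = SequenceRecord("m", seq)
    records = [
        r for r in find_diagonals(mem_rec, ref_rec, engine="internal", k=k)
        if r.strand == "+"
    ]
    if not records:
        return None
    diags = [
        make_diagonal(r, diag_id=f"d{i:04d}")
        for i, r in enumerate(sorted(records, key=lambda r: (r.ref_start, r.contig_start)))
    ]
    trav = chain(diags, len(ref_slice), len(seq))
    aln = traversal_to_alignment(trav, diags, ref_rec, mem_rec)
    if aln is None:
        return None
    # pad the uncovered reference ends as deletions so rows span the window
    left, right = ref_slice[: aln.ref_start], ref_slice[aln.ref_end :]
    return (
        left + aln.aligned_ref + right,
        GAP * len(left) + aln.aligned_contig + GAP * len(right),
    )


def _edlib_pairwise_rows(seq: str, ref_slice: str) -> tuple[str, str]:
    """Gapped rows from a unit-cost global edit-distance path (fallback for
    pairs the seed-and-chain aligner cannot anchor)."""
    ar, ac = [], []
    qpos = rpos = 0
    for op, length in _pairwise_path(seq, ref_slice):
        if op in "=X":
            ar.append(ref_slice[rpos : rpos + length])
            ac.append(seq[qpos : qpos + length])
            rpos += length
            qpos += length
        elif op == "D":
            ar.append(ref_slice[rpos : rpos + length])
            ac.append(GAP * length)
            rpos += length
        else:  # I
            ar.append(GAP * length)
            ac.append(seq[qpos : qpos + length])
            qpos += length
    return "".join(ar), "".join(ac)


def _progressive_msa(
    ref_slice: str, members: list[tuple[str, str]], seed_k: int = 12
) -> tuple[str, dict[str, str]]:
    """Reference-anchored progressive MSA: align each member to the
    reference slice pairwise, then merge the paths with insertion blocks
    sized to the longest insertion at each reference position."""
    n = len(ref_slice)
    ins_at: list[dict[str, str]] = [dict() for _ in range(n + 1)]
    deleted: dict[str, np.ndarray] = {}
    aligned_chars: dict[str, list[str]] = {}
    for cid, seq in members:
        if not seq:
            continue
        rows = _chain_pairwise_rows(seq, ref_slice, seed_k)
        if rows is None:
            rows = _edlib_pairwise_rows(seq, ref_slice)
        dele = np.zeros(n, dtype=bool)
        chars = [""] * n
        qpos = rpos = 0
        for a, b in zip(*rows):
            if a != GAP and b != GAP:
                chars[rpos] = b
                rpos += 1
                qpos += 1
            elif a != GAP:
                dele[rpos] = True
                rpos += 1
            else:
                ins_at[rpos][cid] = ins_at[rpos].get(cid, "") + b
                qpos += 1
        deleted[cid] = dele
        aligned_chars[cid] = chars
    block = [max((len(s) for s in ins_at[p].values()), default=0) for p in range(n + 1)]

    def build_row(cid: str | None) -> str:
        parts = []
        for p in range(n + 1):
            if block[p]:
                if cid is None:
                    parts.append(GAP * block[p])
                else:
                    ins = ins_at[p].get(cid, "")
                    parts.append(ins + GAP * (block[p] - len(ins)))
            if p < n:
                if cid is None:
                    parts.append(ref_slice[p])
                elif deleted[cid][p]:
                    parts.append(GAP)
                else:
                    parts.append(aligned_chars[cid][p] or GAP)
        return "".join(parts)

    ref_row = build_row(None)
    rows = {}
    width = len(ref_row)
    for cid, seq in members:
        rows[cid] = build_row(cid) if seq else GAP * width
    return ref_row, rows


def _mafft_msa(
    window: Window, ref_slice: str, members: list[tuple[str, str]]
) -> tuple[str, dict[str, str]]:
    exe = shutil.which("mafft")
    if exe is None:
        raise MsaEngineError(window, "mafft not found on PATH")
    nonempty = [(cid, seq) for cid, seq in members if seq]
    if not nonempty:
        return ref_slice, {cid: GAP * len(ref_slice) for cid, _ in members}
    with tempfile.TemporaryDirectory(prefix="novograph_mafft_") as tmp:
        fa = Path(tmp) / "window.fa"
        out = Path(tmp) / "window.msa.fa"
        write_fasta(
            [SequenceRecord("ref", ref_slice)]
            + [SequenceRecord(cid, seq) for cid, seq in nonempty],
            fa,
        )
        with open(out, "wb") as oh:
            proc = subprocess.run(
                [exe, "--quiet", str(fa)], stdout=oh, stderr=subprocess.PIPE
            )
        if proc.returncode != 0:
            raise MsaEngineError(window, proc.stderr.decode(errors="replace"))
        import pysam

        with pysam.FastxFile(str(out)) as fh:  # gapped rows: keep '-' intact
            aligned = {entry.name: entry.sequence.upper() for entry in fh}
    ref_row = aligned.pop("ref")
    width = len(ref_row)
    rows = {cid: aligned.get(cid, GAP * width) for cid, _ in members}
    for cid, seq in members:
        if ungapped(rows[cid]) != seq.upper():
            raise MsaEngineError(window, f"mafft altered sequence of {cid}")
    return ref_row, rows


def align_window(ws: WindowSequenceSet, engine: str = "internal") -> WindowMsa:
    """MSA of one window. ``internal`` uses the reference-anchored
    progressive aligner; ``mafft`` shells out with default settings.
    A window with no members yields the bare reference row."""
    members = [(cid, seq) for cid, seq, _o, _c in ws.members]
    if len({cid for cid, _ in members}) != len(members):
        raise MsaEngineError(ws.window, "duplicate member ids in one window")
    if not members:
        return WindowMsa(ws.window, ws.ref_slice, {})
    if engine == "internal":
        ref_row, rows = _progressive_msa(ws.ref_slice, members)
    elif engine == "mafft":
        ref_row, rows = _mafft_msa(ws.window, ws.ref_slice, members)
    else:
        raise MsaEngineError(ws.window, f"unknown MSA engine {engine!r}")
    for cid, seq in members:
        assert ungapped(rows[cid]) == seq.upper(), f"window MSA lost characters of {cid}"
    assert ungapped(ref_row) == ws.ref_slice
    return WindowMsa(ws.window, ref_row, rows)


def concatenate_windows(msas: list[WindowMsa]) -> ConcatenatedMsa:
    """Join per-window MSAs (in window order, tiling one reference contig)
    into the approximate global MSA. Contig rows are padded with gaps
    outside their first/last window; a contig absent from a window strictly
    between occupied windows would be a bookkeeping error and raises."""
    if not msas:
        raise ValueError("no windows to concatenate")
    ref_id = msas[0].window.ref_id
    for a, b in zip(msas, msas[1:]):
        if b.window.ref_id != ref_id or b.window.start != a.window.end:
            raise FormatError("windows do not tile the reference contig in order")
    presence: dict[str, list[int]] = {}
    for i, m in enumerate(msas):
        for cid, row in m.rows.items():
            if len(row) != m.width:
                raise FormatError(f"row {cid!r} width mismatch in window {i}")
            presence.setdefault(cid, []).append(i)
    for cid, idxs in presence.items():
        if idxs != list(range(idxs[0], idxs[-1] + 1)):
            raise FormatError(f"contig {cid!r} absent from a window inside its span")
    ref_row = "".join(m.ref_row for m in msas)
    rows = {}
    for cid, idxs in presence.items():
        parts = []
        for i, m in enumerate(msas):
            parts.append(m.rows[cid] if i in set(idxs) else GAP * m.width)
        rows[cid] = "".join(parts)
    return ConcatenatedMsa(ref_id=ref_id, ref_row=ref_row, rows=rows)
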