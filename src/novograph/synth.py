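"""Synthetic references, contigs with planted variation, and independent
oracles.

Every stage of the pipeline is testable desk-scale: a random reference is
drawn base by base at a chosen GC content, contigs are slices of a mutated
haplotype (planted SNPs, small insertions/deletions, optional
reverse-complemented contigs and unalignable decoys), and the planted truth
is recorded in reference coordinates. Planted events are kept pairwise
non-overlapping with a configurable minimum spacing and avoid the ends of
each contig, so end-pruning cannot silently remove truth events.

The module also carries the scoring oracle for Step 1 — an exact
semi-global Needleman-Wunsch score (match +1, mismatch -1, gap -1,
reference end gaps free, contig end gaps penalized) — and applied-sequence
variant normalization used to compare called variants against the truth
independently of anchoring conventions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import SequenceRecord, VariantRecord, revcomp, write_fasta

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class VariantSpec:
    """A planted event in reference coordinates (0-based).

    SNP: ``payload`` is the substituted base (at ``pos``).
    INS: ``payload`` is the string inserted immediately after ``pos``.
    DEL: ``payload`` is the number of deleted bases starting at ``pos``.
    """

    kind: str
    pos: int
    payload: str | int

    @property
    def ref_span(self) -> tuple[int, int]:
        if self.kind == "DEL":
            return (self.pos, self.pos + int(self.payload))
        if self.kind == "SNP":
            return (self.pos, self.pos + 1)
        return (self.pos, self.pos + 1)  # INS occupies its anchor base


@dataclass
class Fixture:
    """A reference + contig set with known planted variation."""

    reference: list[SequenceRecord]
    contigs: list[SequenceRecord]
    truth: dict[str, list[VariantSpec]]
    seed: int
    config: dict = field(default_factory=dict)
    contig_map: dict[str, tuple[str, int, int, bool]] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.reference, outdir / "reference.fa")
        write_fasta(self.contigs, outdir / "contigs.fa")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("contig_id\tkind\tpos\tpayload\n")
            for cid, specs in sorted(self.truth.items()):
                for s in specs:
                    fh.write(f"{cid}\t{s.kind}\t{s.pos}\t{s.payload}\n")
        with open(outdir / "fixture.json", "w") as fh:
            json.dump({"seed": self.seed, "config": self.config}, fh, indent=2)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_reference(
    n_contigs: int, length: int, gc: float = 0.5, seed: int = 0
) -> list[SequenceRecord]:
    """i.i.d. random reference contigs at the stated GC content."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    at, gcp = (1.0 - gc) / 2.0, gc / 2.0
    p = [at, gcp, gcp, at]  # A C G T
    return [
        SequenceRecord(f"chr{i + 1}", "".join(rng.choice(BASES, size=length, p=p)))
        for i in range(n_contigs)
    ]


def mutate_slice(ref_seq: str, start: int, end: int, specs: list[VariantSpec]) -> str:
    """Apply non-overlapping planted events falling inside [start, end)."""
    specs = sorted(
        (s for s in specs if start <= s.pos and s.ref_span[1] <= end),
        key=lambda s: s.pos,
    )
    parts = []
    cur = start
    for s in specs:
        if s.pos < cur:
            raise ValueError("overlapping variant specs")
        parts.append(ref_seq[cur : s.pos])
        if s.kind == "SNP":
            parts.append(str(s.payload))
            cur = s.pos + 1
        elif s.kind == "INS":
            parts.append(ref_seq[s.pos] + str(s.payload))
            cur = s.pos + 1
        elif s.kind == "DEL":
            cur = s.pos + int(s.payload)
        else:
            raise ValueError(f"unknown variant kind {s.kind!r}")
    parts.append(ref_seq[cur:end])
    return "".join(parts)


def make_contig(
    reference: SequenceRecord,
    contig_id: str,
    start: int,
    end: int,
    specs: list[VariantSpec],
    reverse: bool = False,
) -> SequenceRecord:
    seq = mutate_slice(reference.sequence, start, end, specs)
    return SequenceRecord(contig_id, revcomp(seq) if reverse else seq)


def _sample_positions(
    rng: np.random.Generator,
    start: int,
    end: int,
    n: int,
    span_of: list[int],
    min_spacing: int,
    forbidden: list[tuple[int, int]],
) -> list[int]:
    """Rejection-sample event start positions with pairwise spacing and
    forbidden intervals; gives up (returning fewer) after many rejections."""
    placed: list[tuple[int, int]] = []
    out: list[int] = []
    attempts = 0
    for span in span_of:
        ok = False
        while attempts < 200 * max(n, 1) and not ok:
            attempts += 1
            pos = int(rng.integers(start, max(start + 1, end - span)))
            lo, hi = pos - min_spacing, pos + span + min_spacing
            if any(not (hi <= s or e <= lo) for s, e in placed):
                continue
            if any(not (pos + span <= s or e <= pos) for s, e in forbidden):
                continue
            placed.append((pos, pos + span))
            out.append(pos)
            ok = True
    return out


def derive_contigs(
    reference: list[SequenceRecord],
    n_contigs: int = 3,
    snp_rate: float = 1e-3,
    ins_rate: float = 2e-4,
    del_rate: float = 2e-4,
    ins_len: tuple[int, int] = (1, 10),
    del_len: tuple[int, int] = (1, 10),
    min_spacing: int = 10,
    end_buffer: int = 20,
    fragmentation: bool = True,
    revcomp_prob: float = 0.0,
    n_decoys: int = 0,
    decoy_length: int = 500,
    avoid: list[tuple[int, int]] | None = None,
    seed: int = 0,
) -> Fixture:
    """Contigs as slices of a mutated haplotype with recorded truth.

    With ``fragmentation`` the contigs tile each reference contig; without
    it every contig covers the whole reference contig (overlapping
    haplotypes). Events are sampled at the stated per-bp rates, pairwise
    non-overlapping with ``min_spacing``, at least ``end_buffer`` bases from
    contig ends, and outside ``avoid`` intervals.
    """
    rng = np.random.default_rng(seed)
    contigs: list[SequenceRecord] = []
    truth: dict[str, list[VariantSpec]] = {}
    contig_map: dict[str, tuple[str, int, int, bool]] = {}
    per_ref = max(1, n_contigs // max(1, len(reference)))
    idx = 0
    for ref in reference:
        L = len(ref.sequence)
        if fragmentation:
            cuts = np.linspace(0, L, per_ref + 1).astype(int)
            slices = list(zip(cuts[:-1], cuts[1:]))
        else:
            slices = [(0, L)] * per_ref
        for start, end in slices:
            cid = f"contig{idx}"
            idx += 1
            span = end - start
            inner = (start + end_buffer, end - end_buffer)
            specs: list[VariantSpec] = []
            if inner[1] > inner[0]:
                n_snp = rng.poisson(snp_rate * span)
                n_ins = rng.poisson(ins_rate * span)
                n_del = rng.poisson(del_rate * span)
                spans = (
                    [1] * n_snp
                    + [1] * n_ins
                    + [int(rng.integers(del_len[0], del_len[1] + 1)) for _ in range(n_del)]
                )
                kinds = ["SNP"] * n_snp + ["INS"] * n_ins + ["DEL"] * n_del
                positions = _sample_positions(
                    rng, inner[0], inner[1], len(spans), spans, min_spacing, avoid or []
                )
                for kind, pos, sp in zip(kinds, positions, spans):
                    if kind == "SNP":
                        base = ref.sequence[pos]
                        alt = str(rng.choice([b for b in "ACGT" if b != base]))
                        specs.append(VariantSpec("SNP", pos, alt))
                    elif kind == "INS":
                        n_bases = int(rng.integers(ins_len[0], ins_len[1] + 1))
                        payload = "".join(rng.choice(BASES, size=n_bases))
                        specs.append(VariantSpec("INS", pos, payload))
                    else:
                        specs.append(VariantSpec("DEL", pos, sp))
            reverse = bool(rng.random() < revcomp_prob)
            contigs.append(make_contig(ref, cid, start, end, specs, reverse=reverse))
            truth[cid] = sorted(specs, key=lambda s: s.pos)
            contig_map[cid] = (ref.id, start, end, reverse)
    for d in range(n_decoys):
        cid = f"decoy{d}"
        contigs.append(
            SequenceRecord(cid, "".join(rng.choice(BASES, size=decoy_length)))
        )
        truth[cid] = []
    config = dict(
        n_contigs=n_contigs, snp_rate=snp_rate, ins_rate=ins_rate, del_rate=del_rate,
        ins_len=ins_len, del_len=del_len, min_spacing=min_spacing,
        end_buffer=end_buffer, fragmentation=fragmentation,
        revcomp_prob=revcomp_prob, n_decoys=n_decoys,
    )
    return Fixture(
        reference=reference, contigs=contigs, truth=truth, seed=seed,
        config=config, contig_map=contig_map,
    )


# ---------------------------------------------------------------------------
# the semi-global Needleman-Wunsch oracle
# ---------------------------------------------------------------------------

def nw_semiglobal_oracle(
    ref_seq: str,
    contig_seq: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -1,
    max_cells: int = 10**7,
) -> int:
    """Exact optimal alignment score with free reference end gaps and
    penalized contig end gaps, over the full dynamic-programming matrix.

    The linear gap penalty lets the left-neighbour recurrence collapse into
    a running maximum, so each matrix row is computed vectorised.
    """
    n, m = len(ref_seq), len(contig_seq)
    if n * m > max_cells:
        raise ValueError(f"problem size {n}*{m} exceeds the {max_cells}-cell guard")
    ref = np.frombuffer(ref_seq.encode(), np.uint8)
    con = np.frombuffer(contig_seq.encode(), np.uint8)
    prev = np.zeros(n + 1, dtype=np.int64)  # S[0, :] = 0: ref prefix free
    offs = np.arange(n + 1, dtype=np.int64)
    for i in range(1, m + 1):
        sub = np.where(ref == con[i - 1], match, mismatch)
        cand = np.empty(n + 1, dtype=np.int64)
        cand[0] = i * gap  # contig prefix penalized
        cand[1:] = np.maximum(prev[:-1] + sub, prev[1:] + gap)
        # left moves: S[i, j] = max_{k <= j} (cand[k] + gap * (j - k))
        prev = np.maximum.accumulate(cand - gap * offs) + gap * offs
    return int(prev.max())  # ref suffix free


# ---------------------------------------------------------------------------
# truth scoring
# ---------------------------------------------------------------------------

def normalize_variant(
    pos: int, ref_allele: str, alt: str, ref_seq: str
) -> tuple[int, str, str]:
    """Parsimonious, left-aligned representation of (1-based pos, REF, ALT),
    so that anchor-shifted representations of the same event compare equal
    (applied-sequence equivalence)."""
    while True:
        if (
            ref_allele and alt
            and ref_allele[-1] == alt[-1]
            and (len(ref_allele) > 1 or len(alt) > 1)
        ):
            ref_allele, alt = ref_allele[:-1], alt[:-1]
            if not ref_allele or not alt:
                if pos == 1:
                    prev = ""
                else:
                    prev = ref_seq[pos - 2]
                    pos -= 1
                ref_allele, alt = prev + ref_allele, prev + alt
                if not prev:
                    break
        elif len(ref_allele) > 1 and len(alt) > 1 and ref_allele[0] == alt[0]:
            ref_allele, alt = ref_allele[1:], alt[1:]
            pos += 1
        else:
            break
    return pos, ref_allele, alt


def variant_kind(ref_allele: str, alt: str) -> str:
    if len(ref_allele) == len(alt):
        return "SNP" if len(ref_allele) == 1 else "MNP"
    return "INS" if len(alt) > len(ref_allele) else "DEL"


def truth_to_site(spec: VariantSpec, ref_seq: str) -> tuple[int, str, str]:
    """A planted event as a normalized (1-based pos, REF, ALT) site."""
    if spec.kind == "SNP":
        site = (spec.pos + 1, ref_seq[spec.pos], str(spec.payload))
    elif spec.kind == "INS":
        anchor = ref_seq[spec.pos]
        site = (spec.pos + 1, anchor, anchor + str(spec.payload))
    elif spec.kind == "DEL":
        length = int(spec.payload)
        if spec.pos == 0:
            site = (1, ref_seq[:length + 1], ref_seq[length])
        else:
            anchor = ref_seq[spec.pos - 1]
            site = (spec.pos, anchor + ref_seq[spec.pos : spec.pos + length], anchor)
    else:
        raise ValueError(f"unknown kind {spec.kind!r}")
    return normalize_variant(*site, ref_seq)


def score_truth_recovery(
    records: list[VariantRecord],
    truth: dict[str, list[VariantSpec]],
    reference: list[SequenceRecord],
    contig_ref: dict[str, str] | None = None,
) -> dict[str, dict[str, float]]:
    """Recall/precision per variant kind under normalized allele comparison.

    Truth positions are reference-global, so contigs sharing a planted event
    contribute one truth site. Returns {kind: {recall, precision, n_truth,
    n_called}} plus an 'ALL' summary.
    """
    ref_by_id = {r.id: r for r in reference}
    truth_sites: dict[str, set[tuple]] = {}
    for cid, specs in truth.items():
        if contig_ref is not None:
            ref = ref_by_id[contig_ref[cid]]
        elif len(reference) == 1:
            ref = reference[0]
        else:
            raise ValueError("contig_ref mapping required with multiple reference contigs")
        for spec in specs:
            site = truth_to_site(spec, ref.sequence)
            truth_sites.setdefault(spec.kind, set()).add((ref.id,) + site)
    called_sites: dict[str, set[tuple]] = {}
    for rec in records:
        ref_seq = ref_by_id[rec.chrom].sequence
        for alt in rec.alt_alleles:
            site = normalize_variant(rec.pos, rec.ref_allele, alt, ref_seq)
            kind = variant_kind(site[1], site[2])
            called_sites.setdefault(kind, set()).add((rec.chrom,) + site)
    out: dict[str, dict[str, float]] = {}
    all_truth = set().union(*truth_sites.values()) if truth_sites else set()
    all_called = set().union(*called_sites.values()) if called_sites else set()
    for kind in sorted(set(truth_sites) | set(called_sites) | {"ALL"}):
        t = all_truth if kind == "ALL" else truth_sites.get(kind, set())
        c = all_called if kind == "ALL" else called_sites.get(kind, set())
        out[kind] = {
            "recall": len(t & c) / len(t) if t else 1.0,
            "precision": len(t & c) / len(c) if c else 1.0,
            "n_truth": len(t),
            "n_called": len(c),
        }
    return out


def boundary_stress_fixture(
    seed: int,
    length: int = 1_000_000,
    n_contigs: int = 5,
    window_size: int = 10_000,
    indel_size: tuple[int, int] = (20, 80),
    scan: int = 100,
) -> Fixture:
    """Reference tiled by contigs that each carry one 20-80 bp indel within
    +/- ``scan`` bp of every tentative window boundary (multiple of
    ``window_size``) inside their slice — the stress input for the
    gap-avoiding boundary adjustment."""
    rng = np.random.default_rng(seed)
    reference = generate_reference(1, length, seed=seed)
    ref = reference[0]
    cuts = np.linspace(0, length, n_contigs + 1).astype(int)
    contigs: list[SequenceRecord] = []
    truth: dict[str, list[VariantSpec]] = {}
    contig_map: dict[str, tuple[str, int, int, bool]] = {}
    for ci, (start, end) in enumerate(zip(cuts[:-1], cuts[1:])):
        specs: list[VariantSpec] = []
        for t in range(window_size, length, window_size):
            if not (start + 2 * scan <= t < end - 2 * scan):
                continue
            size = int(rng.integers(indel_size[0], indel_size[1] + 1))
            if rng.random() < 0.5:
                pos = t + int(rng.integers(-scan, scan + 1 - size))
                specs.append(VariantSpec("DEL", pos, size))
            else:
                pos = t + int(rng.integers(-scan, scan + 1))
                payload = "".join(rng.choice(BASES, size=size))
                specs.append(VariantSpec("INS", pos, payload))
        cid = f"contig{ci}"
        contigs.append(make_contig(ref, cid, start, end, specs))
        truth[cid] = specs
        contig_map[cid] = (ref.id, int(start), int(end), False)
    return Fixture(
        reference=reference, contigs=contigs, truth=truth, seed=seed,
        config=dict(kind="boundary_stress", length=length, n_contigs=n_contigs,
                    window_size=window_size, indel_size=list(indel_size)),
        contig_map=contig_map,
    )
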