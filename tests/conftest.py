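from __future__ import annotations

import pytest

from novograph.io import GAP, LocalAlignmentRecord, SequenceRecord
from novograph.synth import derive_contigs, generate_reference


def gapless_record(ref_id, contig_id, ref_seq, ref_start0, contig_start0, length, strand="+"):
    """A gapless all-match LocalAlignmentRecord (1-based coords from 0-based)."""
    block = ref_seq[ref_start0 : ref_start0 + length]
    return LocalAlignmentRecord(
        contig_id=contig_id,
        ref_id=ref_id,
        strand=strand,
        ref_start=ref_start0 + 1,
        ref_end=ref_start0 + length,
        contig_start=contig_start0 + 1,
        contig_end=contig_start0 + length,
        aligned_ref=block,
        aligned_contig=block,
        score=length,
    )


@pytest.fixture
def small_fixture():
    """5 kb single-chromosome reference, 2 tiling contigs with a few planted
    events; deterministic."""
    reference = generate_reference(1, 5000, seed=11)
    return derive_contigs(
        reference, n_contigs=2, snp_rate=1e-3, ins_rate=3e-4, del_rate=3e-4, seed=12
    )


def make_msa(ref_row: str, **rows: str):
    """Convenience constructor for hand-written concatenated MSAs."""
    from novograph.windows import ConcatenatedMsa

    width = len(ref_row)
    assert all(len(r) == width for r in rows.values())
    return ConcatenatedMsa(ref_id="chr1", ref_row=ref_row, rows=dict(rows))


def ref_record_of(msa) -> SequenceRecord:
    return SequenceRecord(msa.ref_id, msa.ref_row.replace(GAP, ""))
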