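"""SAM interop so any external mapper can replace the built-in one.

Written records carry the mandatory fields plus NM (edit distance), AS
(score) and ZA (number of co-optimal placements); extra co-optimal
placements are emitted as secondary records.  Reading reconstructs
:class:`PairAlignment` objects, restoring the ambiguity flag from ZA or from
the presence of secondaries.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pysam

from .align import Alignment, PairAlignment
from .records import SequenceRecord, revcomp

_OP_TO_CODE = {"M": 0, "I": 1, "D": 2, "S": 4}
_CODE_TO_OP = {v: k for k, v in _OP_TO_CODE.items()}


def _flag(mate: str, aln: Alignment | None, other: Alignment | None, proper: bool, secondary: bool) -> int:
    f = 0x1  # paired
    if proper:
        f |= 0x2
    if aln is None:
        f |= 0x4
    elif aln.strand == "-":
        f |= 0x10
    if other is None:
        f |= 0x8
    elif other.strand == "-":
        f |= 0x20
    f |= 0x40 if mate == "R1" else 0x80
    if secondary:
        f |= 0x100
    return f


def write_sam(
    pairs: Sequence[PairAlignment],
    references: Sequence[SequenceRecord],
    path: str | Path,
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": r.id, "LN": len(r)} for r in references],
    }
    ref_ids = {r.id: i for i, r in enumerate(references)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for pair in pairs:
            mates = {"R1": (pair.r1, pair.seq1), "R2": (pair.r2, pair.seq2)}
            for mate, (alns, raw_seq) in mates.items():
                other_alns = pair.r2 if mate == "R1" else pair.r1
                other = other_alns[0] if other_alns else None
                if not alns:
                    a = pysam.AlignedSegment()
                    a.query_name = pair.read_id
                    a.flag = _flag(mate, None, other, False, False)
                    a.query_sequence = raw_seq or None
                    if other is not None:
                        a.next_reference_id = ref_ids[other.ref_id]
                        a.next_reference_start = other.pos
                    out.write(a)
                    continue
                for i, aln in enumerate(alns):
                    a = pysam.AlignedSegment()
                    a.query_name = pair.read_id
                    a.flag = _flag(mate, aln, other, pair.proper, i > 0)
                    a.reference_id = ref_ids[aln.ref_id]
                    a.reference_start = aln.pos
                    a.mapping_quality = 0 if aln.ambiguous else 60
                    a.cigartuples = [(_OP_TO_CODE[op], n) for op, n in aln.cigar]
                    a.query_sequence = aln.seq
                    if other is not None:
                        a.next_reference_id = ref_ids[other.ref_id]
                        a.next_reference_start = other.pos
                    a.set_tag("NM", int(aln.nm))
                    a.set_tag("AS", int(aln.score))
                    a.set_tag("ZA", len(alns))
                    out.write(a)


def read_sam(path: str | Path) -> list[PairAlignment]:
    """Group SAM records back into pairs; secondaries rebuild co-optimal
    lists."""
    by_read: dict[str, PairAlignment] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            rid = rec.query_name
            if rid not in by_read:
                by_read[rid] = PairAlignment(read_id=rid)
                order.append(rid)
            pair = by_read[rid]
            mate = "R1" if rec.is_read1 else "R2"
            seq = rec.query_sequence or ""
            raw = revcomp(seq) if rec.is_reverse else seq
            if not rec.is_secondary:
                if mate == "R1":
                    pair.seq1 = raw
                else:
                    pair.seq2 = raw
                if rec.is_proper_pair:
                    pair.proper = True
            if rec.is_unmapped:
                continue
            cigar = [(_CODE_TO_OP.get(code, "M"), n) for code, n in rec.cigartuples or []]
            aln = Alignment(
                read_id=rid,
                mate=mate,
                ref_id=rec.reference_name,
                pos=rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                cigar=cigar,
                nm=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                score=float(rec.get_tag("AS")) if rec.has_tag("AS") else 0.0,
                seq=seq,
            )
            target = pair.r1 if mate == "R1" else pair.r2
            if rec.is_secondary:
                target.append(aln)
            else:
                target.insert(0, aln)
    for pair in by_read.values():
        for alns in (pair.r1, pair.r2):
            if len(alns) > 1:
                for a in alns:
                    a.ambiguous = True
    return [by_read[r] for r in order]
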