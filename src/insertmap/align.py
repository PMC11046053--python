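"""Built-in read mapper and local aligner.

The mapper is seed-and-vote: sampled k-mers of the read are looked up in a
reference index, candidate diagonals are scored by a best-scoring-segment
scan (match/mismatch Kadane), and the unextendable read ends become soft
clips.  It is a substitution-only (gapless) placement model, which matches
the library's read simulator; SAM interop (:mod:`insertmap.samio`) lets any
external gapped mapper be substituted.  Co-optimal placements are all
reported and flagged ambiguous rather than broken arbitrarily, because the
downstream informative-read classes depend on detecting ambiguity.

`local_align` is a full Smith-Waterman local aligner (linear gap penalty)
used for clip re-alignment oracles and small sequence-vs-sequence problems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .records import SequenceRecord, revcomp

_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode A,C,G,T -> 0..3; anything else (N) -> 4."""
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _rc_encoded(enc: np.ndarray) -> np.ndarray:
    out = enc[::-1].copy()
    valid = out < 4
    out[valid] = 3 - out[valid]
    return out


@dataclass
class Alignment:
    """Gapless-or-gapped placement of one read (or fragment) on a reference.

    ``seq`` is stored in reference orientation (reverse-complemented for '-'
    strand placements) so CIGAR arithmetic and clip extraction are uniform.
    """

    read_id: str
    mate: str  # "R1", "R2" or ""
    ref_id: str
    pos: int  # 0-based leftmost reference coordinate of the aligned block
    strand: str  # "+" or "-"
    cigar: list[tuple[str, int]]
    nm: int
    score: float
    ambiguous: bool = False
    seq: str = ""

    def __post_init__(self) -> None:
        read_len = sum(n for op, n in self.cigar if op in "MIS")
        if self.seq and read_len != len(self.seq):
            raise ValueError("CIGAR M/I/S lengths do not sum to the read length")
        ops = [op for op, _ in self.cigar]
        for i, op in enumerate(ops):
            if op == "S" and i not in (0, len(ops) - 1):
                raise ValueError("soft clips are only allowed at CIGAR ends")

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def end(self) -> int:
        """One past the last aligned reference base."""
        return self.pos + self.ref_span

    @property
    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)

    @property
    def left_clip(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0

    @property
    def right_clip(self) -> int:
        return self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0


@dataclass
class PairAlignment:
    """Both mates of a pair aligned against the joint reference set."""

    read_id: str
    r1: list[Alignment] = field(default_factory=list)  # co-optimal placements
    r2: list[Alignment] = field(default_factory=list)
    proper: bool = False
    seq1: str = ""
    seq2: str = ""

    @property
    def primary1(self) -> Alignment | None:
        return self.r1[0] if self.r1 else None

    @property
    def primary2(self) -> Alignment | None:
        return self.r2[0] if self.r2 else None


class ReferenceIndex:
    """Exact k-mer position index over a reference set.

    References are concatenated with k invalid separator symbols so no k-mer
    spans two records; positions are stored globally and mapped back on use.
    """

    def __init__(self, references: Sequence[SequenceRecord], k: int = 21):
        if not references:
            raise ValueError("reference set must be nonempty")
        if k < 4:
            raise ValueError("k must be >= 4")
        self.k = k
        self.records = list(references)
        self.ids = [r.id for r in self.records]
        self.roles = {r.id: r.role for r in self.records}
        sep = np.full(k, 4, dtype=np.int8)
        chunks: list[np.ndarray] = []
        offsets: list[int] = []
        g = 0
        for rec in self.records:
            offsets.append(g)
            enc = encode(rec.sequence)
            chunks.append(enc)
            chunks.append(sep)
            g += len(enc) + k
        self.cat = np.concatenate(chunks)
        self.offsets = np.array(offsets, dtype=np.int64)
        self.lengths = np.array([len(r) for r in self.records], dtype=np.int64)
        self._pow = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        self._index = self._build()

    def _build(self) -> dict[int, np.ndarray]:
        k, enc = self.k, self.cat
        n = len(enc)
        encc = np.where(enc < 4, enc, 0).astype(np.int64)
        m = n - k + 1
        codes = np.zeros(m, dtype=np.int64)
        for j in range(k):
            codes = codes * 4 + encc[j : m + j]
        has_n = np.cumsum(np.concatenate([[0], (enc == 4).astype(np.int64)]))
        bad = (has_n[k:] - has_n[:-k]) > 0
        pos = np.nonzero(~bad)[0]
        cvals = codes[pos]
        order = np.argsort(cvals, kind="stable")
        cs, ps = cvals[order], pos[order]
        uniq, starts = np.unique(cs, return_index=True)
        ends = np.append(starts[1:], len(cs))
        return {
            int(u): ps[s:e]
            for u, s, e in zip(uniq.tolist(), starts.tolist(), ends.tolist())
        }

    def lookup(self, code: int) -> np.ndarray:
        return self._index.get(code, _EMPTY)

    def locate(self, gpos: int) -> tuple[int, int]:
        """Global concatenated coordinate -> (record index, local coordinate)."""
        ri = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
        return ri, int(gpos - self.offsets[ri])

    def n_kmers(self) -> int:
        return sum(len(v) for v in self._index.values())


_EMPTY = np.array([], dtype=np.int64)


def build_index(references: Sequence[SequenceRecord], k: int = 21) -> ReferenceIndex:
    return ReferenceIndex(references, k=k)


_EXACT_END = 10  # aligned blocks must end in this many exact matches


def _best_segment(matches: np.ndarray, match: int, mismatch: int) -> tuple[int, int, int]:
    """Best-scoring contiguous read segment; returns (start, end, score).

    Block ends are trimmed until their terminal ``_EXACT_END`` bases are
    mismatch-free: a block is allowed interior mismatches (sequencing error),
    but a boundary reached by scoring through a mismatch run would place a
    soft-clip breakpoint a few bases off, which junction calling cannot
    repair."""
    L = matches.size
    n_mis = L - int(matches.sum())
    if n_mis == 0:
        return 0, L, L * match
    v = np.where(matches, match, mismatch).astype(np.int64)
    prefix = np.concatenate([[0], np.cumsum(v)])
    min_acc = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - min_acc
    e = int(np.argmax(gains)) + 1
    s = int(np.argmin(prefix[:e]))
    mis_idx = np.flatnonzero(~matches)
    while e > s:
        inside = mis_idx[(mis_idx >= max(s, e - _EXACT_END)) & (mis_idx < e)]
        if inside.size == 0:
            break
        e = int(inside[0])
    while s < e:
        inside = mis_idx[(mis_idx >= s) & (mis_idx < min(e, s + _EXACT_END))]
        if inside.size == 0:
            break
        s = int(inside[-1]) + 1
    if e <= s:
        return 0, 0, 0
    score = int(prefix[e] - prefix[s])
    return s, e, score


def align_read(
    seq: str,
    index: ReferenceIndex,
    read_id: str = "",
    mate: str = "",
    n_offsets: int = 8,
    max_hits_per_seed: int = 256,
    max_candidates: int = 64,
    match: int = 1,
    mismatch: int = -3,
    min_score: int | None = None,
) -> list[Alignment]:
    """Map one read; returns all co-optimal placements (ambiguous-flagged).

    Unextendable read ends become soft clips, so a junction-spanning read
    yields e.g. ``60M90S`` anchored at its matching side.
    """
    k = index.k
    L = len(seq)
    if L < k:
        warnings.warn(f"read {read_id or '<anon>'} shorter than k={k}; unmapped")
        return []
    if min_score is None:
        min_score = k
    enc_f = encode(seq)
    if (enc_f < 4).sum() == 0:
        return []
    step = max(1, (L - k) // max(1, n_offsets - 1))
    offsets = sorted({min(o, L - k) for o in range(0, L - k + step, step)})

    results: dict[tuple, Alignment] = {}
    cat = index.cat
    ncat = len(cat)
    for strand, enc in (("+", enc_f), ("-", _rc_encoded(enc_f))):
        encc = np.where(enc < 4, enc, 0).astype(np.int64)
        votes: dict[int, int] = {}
        for o in offsets:
            window = enc[o : o + k]
            if (window == 4).any():
                continue
            code = int(np.dot(encc[o : o + k], index._pow))
            hits = index.lookup(code)
            if len(hits) == 0 or len(hits) > max_hits_per_seed:
                continue
            for g in hits.tolist():
                d = g - o
                votes[d] = votes.get(d, 0) + 1
        if not votes:
            continue
        diags = sorted(votes, key=lambda d: (-votes[d], d))[:max_candidates]
        for d in diags:
            lo, hi = max(d, 0), min(d + L, ncat)
            if hi <= lo:
                continue
            window = np.full(L, 5, dtype=np.int8)
            window[lo - d : hi - d] = cat[lo:hi]
            matches = (window == enc) & (window < 4)
            s, e, score = _best_segment(matches, match, mismatch)
            if score < min_score:
                continue
            ri1, local1 = index.locate(d + s)
            ri2, _ = index.locate(d + e - 1)
            if ri1 != ri2:
                continue  # segment crossed a record separator; spurious
            nm = (e - s) - int(matches[s:e].sum())
            cigar: list[tuple[str, int]] = []
            if s > 0:
                cigar.append(("S", s))
            cigar.append(("M", e - s))
            if e < L:
                cigar.append(("S", L - e))
            aln = Alignment(
                read_id=read_id,
                mate=mate,
                ref_id=index.ids[ri1],
                pos=local1,
                strand=strand,
                cigar=cigar,
                nm=nm,
                score=float(score),
                seq=seq if strand == "+" else revcomp(seq),
            )
            key = (aln.ref_id, aln.pos, aln.strand, aln.cigar_string)
            prev = results.get(key)
            if prev is None or aln.score > prev.score:
                results[key] = aln

    if not results:
        return []
    best = max(a.score for a in results.values())
    top = sorted(
        (a for a in results.values() if a.score == best),
        key=lambda a: (a.ref_id, a.pos, a.strand),
    )
    if len(top) > 1:
        for a in top:
            a.ambiguous = True
    return top


def align_pair(
    r1: str,
    r2: str,
    index: ReferenceIndex,
    read_id: str = "",
    insert_min: int = 100,
    insert_max: int = 1200,
    **kwargs,
) -> PairAlignment:
    """Align both mates independently and derive the properly-paired flag.

    Proper means: primaries on the same reference, opposite strands, in the
    forward-reverse (innie) layout, with an observed insert inside bounds.
    """
    a1 = align_read(r1, index, read_id=read_id, mate="R1", **kwargs)
    a2 = align_read(r2, index, read_id=read_id, mate="R2", **kwargs)
    pair = PairAlignment(read_id=read_id, r1=a1, r2=a2, seq1=r1, seq2=r2)
    p1, p2 = pair.primary1, pair.primary2
    if p1 and p2 and p1.ref_id == p2.ref_id and p1.strand != p2.strand:
        fwd, rev = (p1, p2) if p1.strand == "+" else (p2, p1)
        insert = rev.end - fwd.pos
        pair.proper = fwd.pos <= rev.end and insert_min <= insert <= insert_max
    return pair


# ---------------------------------------------------------------------------
# Smith-Waterman local alignment
# ---------------------------------------------------------------------------


def local_align(
    query: str,
    target: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> tuple[int, tuple[int, int], tuple[int, int], list[tuple[str, int]]]:
    """Optimal local alignment (Smith-Waterman, linear gap penalty).

    Returns ``(score, (query start, query end), (target start, target end),
    cigar)`` with half-open intervals; the empty alignment scores 0.
    """
    if match <= 0 or mismatch >= 0 or gap >= 0:
        raise ValueError("need match > 0, mismatch < 0, gap < 0")
    n, m = len(query), len(target)
    if n == 0 or m == 0:
        return 0, (0, 0), (0, 0), []
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 up(del q? ), 3 left
    best, bi, bj = 0, 0, 0
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        row_prev = H[i - 1]
        row = H[i]
        qi = q[i - 1]
        for j in range(1, m + 1):
            sub = match if qi == t[j - 1] else mismatch
            diag = row_prev[j - 1] + sub
            up = row_prev[j] + gap  # consume query base (insertion to target)
            left = row[j - 1] + gap  # consume target base (deletion from query)
            val = diag
            p = 1
            if up > val:
                val, p = up, 2
            if left > val:
                val, p = left, 3
            if val <= 0:
                val, p = 0, 0
            row[j] = val
            ptr[i, j] = p
            if val > best:
                best, bi, bj = val, i, j
    if best == 0:
        return 0, (0, 0), (0, 0), []
    i, j = bi, bj
    ops: list[str] = []
    while ptr[i, j] != 0:
        p = ptr[i, j]
        if p == 1:
            ops.append("M")
            i, j = i - 1, j - 1
        elif p == 2:
            ops.append("I")
            i -= 1
        else:
            ops.append("D")
            j -= 1
    ops.reverse()
    cigar: list[tuple[str, int]] = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return int(best), (i, bi), (j, bj), cigar
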