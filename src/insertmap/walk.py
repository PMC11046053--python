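"""Iterative de-novo-assembly genome walking.

Starting from a construct-anchored seed contig, each cycle (i) re-maps all
reads to the current contig, (ii) recruits the reads whose alignment overlaps
the terminal window on the growing end together with their mates — even when
the mate itself is unmapped, which is what reaches into uncharted sequence —
and (iii) assembles the recruits and splices the resulting contig onto the
growing end.  Twelve such cycles of serial assembly and re-mapping extend a
junction several kilobases into the flanking genome; the finished contig is
then placed back onto the reference set by chunked alignment.

The assembler is a greedy overlap-layout-consensus over exact suffix/prefix
overlaps.  It is intended for near-error-free, desk-scale read sets; the
contract is the reconstructed sequence, not assembler sophistication.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

from .align import Alignment, PairAlignment, ReferenceIndex, align_read
from .records import GenomeSet, SequenceRecord, revcomp


@dataclass
class WalkConfig:
    """Knobs of the walk.

    ``end_window`` is the recruitment window (bp) at the growing end of the
    current contig, applied every cycle; ``seed_window`` is the construct
    window used to build the initial seed contig.  ``min_overlap`` is the
    assembler's exact-overlap threshold.
    """

    direction: str = "upstream"
    n_cycles: int = 12
    end_window: int = 200
    seed_window: int = 1000
    min_overlap: int = 30
    min_reads: int = 2
    k: int = 21

    def __post_init__(self) -> None:
        if self.direction not in ("upstream", "downstream"):
            raise ValueError("direction must be 'upstream' or 'downstream'")
        if self.end_window < 50:
            raise ValueError("end_window must be >= 50 (mate rescue stalls below)")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")
        if self.min_overlap < 15:
            raise ValueError("min_overlap must be >= 15")


@dataclass
class WalkResult:
    cycle_contigs: list[SequenceRecord]
    extensions: list[int]
    final: SequenceRecord
    termination: str  # completed | stalled | circular
    cycle_log: list[dict] = field(default_factory=list)

    @property
    def total_extension(self) -> int:
        return sum(self.extensions)


# ---------------------------------------------------------------------------
# Greedy exact-overlap assembler
# ---------------------------------------------------------------------------


def _longest_overlap(left: str, right: str, min_overlap: int) -> int:
    """Longest l >= min_overlap with left[-l:] == right[:l] (0 if none)."""
    probe = right[:min_overlap]
    start = max(0, len(left) - len(right))
    p = left.find(probe, start)
    while p != -1:
        l = len(left) - p
        if right[:l] == left[p:]:
            return l
        p = left.find(probe, p + 1)
    return 0


def _drop_contained(seqs: list[str]) -> list[str]:
    seqs = sorted(set(seqs), key=lambda s: (-len(s), s))
    kept: list[str] = []
    for s in seqs:
        rc = revcomp(s)
        if any(s in t or rc in t for t in kept):
            continue
        kept.append(s)
    return kept


def assemble_reads(reads: list[str], min_overlap: int = 30) -> list[SequenceRecord]:
    """Greedy overlap-layout consensus over exact suffix-prefix overlaps.

    Both orientations are considered; reads contained in others (either
    strand) are absorbed; ties are broken by overlap length, then merge-pair
    identity, so the output is deterministic for a given input set.
    """
    if min_overlap < 15:
        raise ValueError("min_overlap must be >= 15")
    seqs = [s.upper() for s in reads if s and len(s) >= min_overlap]
    if not seqs:
        return []
    alive: dict[int, str] = {i: s for i, s in enumerate(_drop_contained(seqs))}
    next_id = len(alive)

    # combos: (left orientation, right orientation); (-,-) is the global
    # reverse complement of the transposed (+,+) pair and is skipped.
    combos = (("+", "+"), ("+", "-"), ("-", "+"))

    def oriented(seq: str, o: str) -> str:
        return seq if o == "+" else revcomp(seq)

    heap: list[tuple] = []

    def push_overlaps(i: int, j: int) -> None:
        a, b = alive[i], alive[j]
        for rank, (oa, ob) in enumerate(combos):
            ov = _longest_overlap(oriented(a, oa), oriented(b, ob), min_overlap)
            if ov >= min_overlap:
                heapq.heappush(heap, (-ov, i, j, rank))

    ids = sorted(alive)
    for i in ids:
        for j in ids:
            if i != j:
                push_overlaps(i, j)

    while heap:
        neg_ov, i, j, rank = heapq.heappop(heap)
        if i not in alive or j not in alive:
            continue
        oa, ob = combos[rank]
        left = oriented(alive[i], oa)
        right = oriented(alive[j], ob)
        ov = _longest_overlap(left, right, min_overlap)
        if ov != -neg_ov:  # stale entry
            if ov >= min_overlap:
                heapq.heappush(heap, (-ov, i, j, rank))
            continue
        merged = left if ov >= len(right) else left + right[ov:]
        del alive[i], alive[j]
        # absorb anything the merge now contains
        rc_merged = revcomp(merged)
        for key in [k for k, s in alive.items() if s in merged or s in rc_merged]:
            del alive[key]
        mid = next_id
        next_id += 1
        alive[mid] = merged
        for other in sorted(alive):
            if other != mid:
                push_overlaps(mid, other)
                push_overlaps(other, mid)

    contigs = sorted(alive.values(), key=lambda s: (-len(s), s))
    return [
        SequenceRecord(f"asm_{n}", s, role="assembled", copies=1)
        for n, s in enumerate(contigs)
    ]


# ---------------------------------------------------------------------------
# Recruitment and walking
# ---------------------------------------------------------------------------


def recruit_end_reads(
    contig: SequenceRecord,
    pairs: list[PairAlignment],
    window: int,
    direction: str = "upstream",
) -> list[str]:
    """Reads aligned into the terminal window on the growing side, plus their
    mates (mate rescue: unmapped mates are recruited by proxy)."""
    if window > len(contig):
        window = len(contig)
    if direction == "upstream":
        w_start, w_end = 0, window
    else:
        w_start, w_end = len(contig) - window, len(contig)

    def in_window(alns: list[Alignment]) -> bool:
        return bool(alns) and alns[0].pos < w_end and alns[0].end > w_start

    recruited: list[str] = []
    for pair in pairs:
        if in_window(pair.r1) or in_window(pair.r2):
            if pair.seq1:
                recruited.append(pair.seq1)
            if pair.seq2:
                recruited.append(pair.seq2)
    return recruited


def _align_pairs_to_contig(
    read_pairs: list[tuple[str, str, str]], contig: str, k: int
) -> list[PairAlignment]:
    ref = SequenceRecord("walk_contig", contig, role="assembled", copies=1)
    index = ReferenceIndex([ref], k=k)
    out = []
    for rid, s1, s2 in read_pairs:
        out.append(
            PairAlignment(
                read_id=rid,
                r1=align_read(s1, index, read_id=rid, mate="R1"),
                r2=align_read(s2, index, read_id=rid, mate="R2"),
                seq1=s1,
                seq2=s2,
            )
        )
    return out


_ANCHOR = 31


def _common_run(a: str, b: str, n: int) -> int:
    """Length of the common character run over the last/first ``n`` aligned
    positions (a scanned from its end, b up to index n)."""
    m = 0
    limit = min(len(a), n)
    while m < limit and a[len(a) - 1 - m] == b[n - 1 - m]:
        m += 1
    return m


def _splice_extension(
    contig: str, candidate: str, direction: str, min_overlap: int
) -> tuple[int, str] | None:
    """Extension bases gained by splicing ``candidate`` onto the growing end.

    The candidate is anchored on the contig's terminal k-mer and accepted on
    the longest exact terminal overlap; the candidate may start or end
    anywhere (assembled contigs routinely reach past the current contig into
    diverging repeat branches)."""
    if len(contig) < _ANCHOR:
        return None
    best: tuple[int, str] | None = None
    for variant in (candidate, revcomp(candidate)):
        if len(variant) < _ANCHOR:
            continue
        if direction == "downstream":
            anchor = contig[-_ANCHOR:]
            p = variant.find(anchor)
            while p != -1:
                end = p + _ANCHOR  # variant coordinate matching the contig end
                if _common_run(contig, variant, end) >= min_overlap and end < len(variant):
                    ext = len(variant) - end
                    if best is None or ext > best[0]:
                        best = (ext, variant[end:])
                p = variant.find(anchor, p + 1)
        else:
            anchor = contig[:_ANCHOR]
            p = variant.find(anchor)
            while p != -1:
                # longest common prefix of contig and variant[p:]
                m = 0
                limit = min(len(contig), len(variant) - p)
                while m < limit and contig[m] == variant[p + m]:
                    m += 1
                if m >= min_overlap and p > 0:
                    if best is None or p > best[0]:
                        best = (p, variant[:p])
                p = variant.find(anchor, p + 1)
    return best


def _fraction_known(newpart: str, contig: str, k: int = _ANCHOR) -> float:
    """Fraction of the extension's k-mers already present in the contig."""
    if len(newpart) < k:
        return 1.0 if newpart in contig or revcomp(newpart) in contig else 0.0
    total = len(newpart) - k + 1
    known = sum(
        1
        for i in range(total)
        if newpart[i : i + k] in contig or revcomp(newpart[i : i + k]) in contig
    )
    return known / total


def walk(
    seed: SequenceRecord,
    read_pairs: list[tuple[str, str, str]],
    config: WalkConfig,
) -> WalkResult:
    """Run the serial assembly/re-mapping walk from a seed contig.

    Stops after ``n_cycles``, or earlier as ``stalled`` (no extension) or
    ``circular`` (the new sequence re-enters already-assembled sequence,
    which happens when the walk runs into repeat structure such as tandem
    construct copies)."""
    if not seed.sequence:
        raise ValueError("seed must be nonempty")
    contig = seed.sequence
    cycle_contigs: list[SequenceRecord] = []
    extensions: list[int] = []
    log: list[dict] = []
    termination = "completed"

    for cycle in range(1, config.n_cycles + 1):
        pairs = _align_pairs_to_contig(read_pairs, contig, config.k)
        recruits = recruit_end_reads(
            SequenceRecord("walk_contig", contig, role="assembled", copies=1),
            pairs,
            config.end_window,
            config.direction,
        )
        if len(recruits) < config.min_reads:
            termination = "stalled"
            break
        assembled = assemble_reads(recruits, config.min_overlap)
        best = None
        for cand in assembled:
            res = _splice_extension(contig, cand.sequence, config.direction, config.min_overlap)
            if res and (best is None or res[0] > best[0]):
                best = res
        if best is None:
            termination = "stalled"
            break
        ext, newpart = best
        if _fraction_known(newpart, contig) > 0.9:
            termination = "circular"
            break
        contig = newpart + contig if config.direction == "upstream" else contig + newpart
        extensions.append(ext)
        cycle_contigs.append(
            SequenceRecord(f"{seed.id}_cycle{cycle}", contig, role="assembled", copies=1)
        )
        log.append({"cycle": cycle, "reads_recruited": len(recruits), "extension_bp": ext})

    final = SequenceRecord(f"{seed.id}_walked", contig, role="assembled", copies=1)
    return WalkResult(cycle_contigs, extensions, final, termination, log)


def make_seed(
    read_pairs: list[tuple[str, str, str]],
    construct: SequenceRecord,
    config: WalkConfig,
) -> SequenceRecord:
    """Assemble the initial seed contig from reads mapping to the construct
    window facing the walk direction (start for upstream, end for downstream),
    oriented to match the construct's forward strand."""
    pairs = _align_pairs_to_contig(read_pairs, construct.sequence, config.k)
    recruits = recruit_end_reads(construct, pairs, config.seed_window, config.direction)
    contigs = assemble_reads(recruits, config.min_overlap)
    if not contigs:
        raise ValueError("no seed contig could be assembled from the construct window")
    probe = (
        construct.sequence[:_ANCHOR]
        if config.direction == "upstream"
        else construct.sequence[-_ANCHOR:]
    )
    for cand in contigs:
        if probe in cand.sequence:
            return SequenceRecord("seed", cand.sequence, role="assembled", copies=1)
        if probe in revcomp(cand.sequence):
            return SequenceRecord("seed", revcomp(cand.sequence), role="assembled", copies=1)
    return SequenceRecord("seed", contigs[0].sequence, role="assembled", copies=1)


# ---------------------------------------------------------------------------
# Final placement of the assembled contig
# ---------------------------------------------------------------------------


@dataclass
class Placement:
    """A locally aligned block of the assembled contig on one reference."""

    contig_start: int
    contig_end: int
    ref_id: str
    ref_start: int
    ref_end: int
    strand: str
    identity: float

    @property
    def length(self) -> int:
        return self.contig_end - self.contig_start


def place_contig(
    contig: SequenceRecord,
    genome: GenomeSet,
    chunk: int = 250,
    min_len: int = 100,
    min_identity: float = 0.9,
    k: int = 21,
) -> list[Placement]:
    """Genome-wide placement of an assembled contig by chunked alignment.

    The contig is mapped in ``chunk``-bp pieces which are chained along
    consistent diagonals; boundaries between adjacent placements on different
    references are refined to base precision by extending each placement
    along its diagonal until the first mismatch, so a contig spanning a
    fusion yields two placements whose boundary is the fusion junction."""
    index = ReferenceIndex(genome.records, k=k)
    seqs = {r.id: r.sequence for r in genome.records}
    L = len(contig)
    starts = list(range(0, max(L - chunk, 0) + 1, chunk))
    if starts and starts[-1] + chunk < L:
        starts.append(L - chunk)
    if not starts:
        starts = [0]

    raw: list[tuple[int, int, str, int, int, str, int]] = []
    # (contig_start, contig_end, ref, ref_start, ref_end, strand, nm)
    for cs in starts:
        piece = contig.sequence[cs : cs + chunk]
        alns = align_read(piece, index)
        if not alns:
            continue
        a = alns[0]
        n = len(piece)
        s, e = a.left_clip, n - a.right_clip
        if a.strand == "+":
            ci, cj = cs + s, cs + e
        else:
            ci, cj = cs + n - e, cs + n - s
        raw.append((ci, cj, a.ref_id, a.pos, a.end, a.strand, a.nm))

    raw.sort()
    placements: list[Placement] = []
    cur: list | None = None
    for ci, cj, ref, rs, re_, strand, nm in raw:
        diag = rs - ci if strand == "+" else rs + cj
        if cur is not None and cur[2] == ref and cur[5] == strand and abs(diag - cur[7]) <= 30:
            cur[1] = max(cur[1], cj)
            cur[3] = min(cur[3], rs)
            cur[4] = max(cur[4], re_)
            cur[6] += nm
        else:
            if cur is not None:
                placements.append(_to_placement(cur))
            cur = [ci, cj, ref, rs, re_, strand, nm, diag]
    if cur is not None:
        placements.append(_to_placement(cur))

    refined = [_refine(p, contig.sequence, seqs[p.ref_id]) for p in placements]
    return [p for p in refined if p.length >= min_len and p.identity >= min_identity]


def _to_placement(cur: list) -> Placement:
    ci, cj, ref, rs, re_, strand, nm, _ = cur
    alen = max(cj - ci, 1)
    return Placement(ci, cj, ref, rs, re_, strand, 1.0 - nm / alen)


def _refine(p: Placement, contig: str, ref: str) -> Placement:
    """Extend a placement base-by-base along its diagonal to its exact ends."""
    if p.strand == "+":
        d = p.ref_start - p.contig_start
        ci, cj = p.contig_start, p.contig_end
        while ci > 0 and 0 <= ci - 1 + d < len(ref) and contig[ci - 1] == ref[ci - 1 + d]:
            ci -= 1
        while cj < len(contig) and 0 <= cj + d < len(ref) and contig[cj] == ref[cj + d]:
            cj += 1
        return Placement(ci, cj, p.ref_id, ci + d, cj + d, "+", p.identity)
    # '-' strand: contig position c pairs with ref position A - c
    A = p.ref_end - 1 + p.contig_start
    comp = str.maketrans("ACGTN", "TGCAN")
    ci, cj = p.contig_start, p.contig_end
    while ci > 0 and 0 <= A - (ci - 1) < len(ref) and contig[ci - 1] == ref[A - ci + 1].translate(comp):
        ci -= 1
    while cj < len(contig) and 0 <= A - cj < len(ref) and contig[cj] == ref[A - cj].translate(comp):
        cj += 1
    return Placement(ci, cj, p.ref_id, A - cj + 1, A - ci + 1, "-", p.identity)
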