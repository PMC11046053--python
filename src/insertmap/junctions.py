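"""Single-base fusion-junction calling from soft-clipped alignments.

A junction is represented as a canonical unordered pair of breakends.  Each
breakend is ``(reference, position, retained side)``: side ``L`` means the
fused sequence retains the reference bases to the left of ``pos`` (so ``pos``
is the last aligned base of that segment), side ``R`` means it retains the
bases to the right (``pos`` is the first aligned base).  A junction whose two
sides differ (one L, one R) joins two same-orientation segments; equal sides
mean the downstream segment is inverted.  This representation stays exact for
inverted-repeat junctions, where a naive "last base of the left segment,
first base of the right segment" convention becomes ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .align import Alignment, ReferenceIndex, align_read
from .records import SequenceRecord


@dataclass(frozen=True, order=True)
class JunctionEnd:
    ref_id: str
    pos: int
    side: str  # "L" or "R", the side of `pos` retained in the fused sequence

    def __post_init__(self) -> None:
        if self.side not in ("L", "R"):
            raise ValueError("side must be 'L' or 'R'")


@dataclass(frozen=True, order=True)
class Junction:
    """Canonical unordered pair of breakends (a <= b)."""

    a: JunctionEnd
    b: JunctionEnd

    @classmethod
    def canonical(cls, e1: JunctionEnd, e2: JunctionEnd) -> "Junction":
        return cls(*sorted((e1, e2)))

    @property
    def orientation(self) -> str:
        return "same" if self.a.side != self.b.side else "inverted"


@dataclass
class ClipFragment:
    """A terminal soft-clipped piece of a read, with its anchor breakpoint.

    ``side`` is the side of the *matched block* the clip hangs off ("left"
    clips precede the block, "right" clips follow it); ``anchor`` is the
    reference coordinate of the matched base adjacent to the clip.
    """

    read_id: str
    ref_id: str
    anchor: int
    side: str
    seq: str


@dataclass
class Candidate:
    junction: Junction
    read_id: str
    fragment: ClipFragment


@dataclass
class JunctionCall:
    junction: Junction
    support: int
    fragments: list[ClipFragment] = field(default_factory=list)

    @property
    def orientation(self) -> str:
        return self.junction.orientation


_COMP = str.maketrans("ACGTN", "TGCAN")


def _shift_once(
    left: JunctionEnd, right: JunctionEnd, seqs: dict[str, str]
) -> Junction | None:
    """Move one base from the junction's left flank to its right flank.

    Under micro-homology a fused sequence admits several equivalent breakpoint
    representations; this is the elementary equivalence move."""
    sl, sr = seqs[left.ref_id], seqs[right.ref_id]
    if left.side == "L":
        if left.pos - 1 < 0:
            return None
        x0 = sl[left.pos]
        new_left = JunctionEnd(left.ref_id, left.pos - 1, "L")
    else:  # left flank is reverse-complemented reference suffix
        if left.pos + 1 >= len(sl):
            return None
        x0 = sl[left.pos].translate(_COMP)
        new_left = JunctionEnd(left.ref_id, left.pos + 1, "R")
    if right.side == "R":
        if right.pos - 1 < 0 or sr[right.pos - 1] != x0:
            return None
        new_right = JunctionEnd(right.ref_id, right.pos - 1, "R")
    else:  # right flank is reverse-complemented
        if right.pos + 1 >= len(sr) or sr[right.pos + 1].translate(_COMP) != x0:
            return None
        new_right = JunctionEnd(right.ref_id, right.pos + 1, "L")
    return Junction.canonical(new_left, new_right)


def canonicalize_junction(
    junction: Junction, seqs: dict[str, str], max_shift: int = 200
) -> Junction:
    """Canonical representative of a junction's micro-homology orbit.

    All breakpoint representations describing the same fused sequence are
    enumerated (bounded by ``max_shift`` elementary moves) and the smallest
    is returned, so truth junctions and clip-derived calls agree exactly no
    matter where within the homology run the aligner split the read."""
    seen = {junction}
    frontier = [junction]
    steps = 0
    while frontier and steps < max_shift:
        steps += 1
        nxt = []
        for j in frontier:
            for left, right in ((j.a, j.b), (j.b, j.a)):
                moved = _shift_once(left, right, seqs)
                if moved is not None and moved not in seen:
                    seen.add(moved)
                    nxt.append(moved)
        frontier = nxt
    return min(seen)


def extract_softclips(
    alignments: Iterable[Alignment],
    min_clip: int = 20,
    skip_ambiguous: bool = True,
) -> list[ClipFragment]:
    """One fragment per terminal soft-clip block of length >= ``min_clip``.

    Ambiguously placed anchors are skipped by default: a clip hanging off an
    anchor that could sit at several loci carries no reliable breakpoint.
    """
    frags: list[ClipFragment] = []
    for aln in alignments:
        if skip_ambiguous and aln.ambiguous:
            continue
        if not any(op == "M" for op, _ in aln.cigar):
            warnings.warn(f"alignment of {aln.read_id!r} has no aligned block; skipped")
            continue
        lc, rc = aln.left_clip, aln.right_clip
        if lc >= min_clip:
            frags.append(
                ClipFragment(aln.read_id, aln.ref_id, aln.pos, "left", aln.seq[:lc])
            )
        if rc >= min_clip:
            frags.append(
                ClipFragment(
                    aln.read_id, aln.ref_id, aln.end - 1, "right", aln.seq[len(aln.seq) - rc :]
                )
            )
    return frags


def _clip_breakend(frag: ClipFragment, aln: Alignment, ref_len: int) -> JunctionEnd:
    """Breakend of the re-aligned clip, extrapolated to the junction-proximal
    clip base when the re-alignment trimmed a few bases."""
    L = len(frag.seq)
    s = aln.left_clip  # block start within the (possibly reverse-complemented) clip
    if aln.strand == "+":
        if frag.side == "right":  # proximal clip base is index 0
            pos, side = aln.pos - s, "R"
        else:  # proximal base is the last clip base
            pos, side = aln.pos + (L - 1 - s), "L"
    else:
        # alignment coordinates refer to revcomp(clip): clip index c maps to
        # rc index L-1-c, which maps to ref pos aln.pos + (L-1-c-s)
        if frag.side == "right":
            pos, side = aln.pos + (L - 1 - s), "L"
        else:
            pos, side = aln.pos - s, "R"
    return JunctionEnd(aln.ref_id, min(max(pos, 0), ref_len - 1), side)


def _anchor_breakend(frag: ClipFragment) -> JunctionEnd:
    side = "L" if frag.side == "right" else "R"
    return JunctionEnd(frag.ref_id, frag.anchor, side)


def realign_clips(
    clips: Sequence[ClipFragment],
    references: Sequence[SequenceRecord],
    min_clip: int = 20,
    min_identity: float = 0.95,
    k: int = 13,
    index: ReferenceIndex | None = None,
) -> list[Candidate]:
    """Re-align clipped fragments to the references and emit junction
    candidates.

    A candidate requires a unique placement covering >= ``min_clip`` bases at
    >= ``min_identity``; clips with co-optimal placements on several loci are
    discarded (ambiguity-safe, mirroring the exclusion of homologous
    evidence).
    """
    if not clips:
        return []
    if index is None:
        index = ReferenceIndex(references, k=k)
    ref_len = {r.id: len(r) for r in index.records}
    ref_seq = {r.id: r.sequence for r in index.records}
    out: list[Candidate] = []
    for frag in clips:
        alns = align_read(frag.seq, index, read_id=frag.read_id, n_offsets=8)
        if not alns or alns[0].ambiguous:
            continue
        aln = alns[0]
        block = sum(n for op, n in aln.cigar if op == "M")
        if block < min(min_clip, len(frag.seq)):
            continue
        if block == 0 or 1.0 - aln.nm / block < min_identity:
            continue
        end_a = _anchor_breakend(frag)
        end_b = _clip_breakend(frag, aln, ref_len[aln.ref_id])
        junction = canonicalize_junction(Junction.canonical(end_a, end_b), ref_seq)
        out.append(Candidate(junction, frag.read_id, frag))
    return out


def call_junctions(
    candidates: Sequence[Candidate],
    min_support: int = 3,
    position_tolerance: int = 2,
    min_self_distance: int = 150,
) -> list[JunctionCall]:
    """Cluster junction candidates and call breakpoints at the modal position.

    Same-reference, same-orientation pairs closer than ``min_self_distance``
    are internal soft-clip noise and dropped; inverted self-junctions are kept
    at any distance because inverted repeats legitimately fold back on
    themselves.  Support counts distinct read ids.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    groups: dict[tuple, dict[tuple[int, int], list[Candidate]]] = {}
    for cand in candidates:
        j = cand.junction
        key = (j.a.ref_id, j.a.side, j.b.ref_id, j.b.side)
        groups.setdefault(key, {}).setdefault((j.a.pos, j.b.pos), []).append(cand)

    calls: list[JunctionCall] = []
    for key, exact in groups.items():
        ref_a, side_a, ref_b, side_b = key
        order = sorted(
            exact, key=lambda p: (-len({c.read_id for c in exact[p]}), p)
        )
        assigned: set[tuple[int, int]] = set()
        for center in order:
            if center in assigned:
                continue
            members = []
            for p in order:
                if p in assigned:
                    continue
                if abs(p[0] - center[0]) <= position_tolerance and abs(
                    p[1] - center[1]
                ) <= position_tolerance:
                    assigned.add(p)
                    members.extend(exact[p])
            junction = Junction(
                JunctionEnd(ref_a, center[0], side_a), JunctionEnd(ref_b, center[1], side_b)
            )
            reads = {c.read_id for c in members}
            if len(reads) < min_support:
                continue
            if (
                ref_a == ref_b
                and junction.orientation == "same"
                and abs(junction.b.pos - junction.a.pos) < min_self_distance
            ):
                continue
            calls.append(
                JunctionCall(junction, len(reads), [c.fragment for c in members])
            )
    calls.sort(key=lambda c: (-c.support, c.junction))
    return calls


def match_junctions(
    calls: Sequence[JunctionCall],
    truth: Sequence[Junction],
    tolerance: int = 0,
) -> dict:
    """Precision/recall of called junctions against a truth list."""

    def matches(call: Junction, true: Junction) -> bool:
        for x, y in ((call.a, true.a), (call.b, true.b)):
            if x.ref_id != y.ref_id or x.side != y.side or abs(x.pos - y.pos) > tolerance:
                return False
        return True

    matched_truth: set[int] = set()
    tp = 0
    for call in calls:
        hit = next(
            (i for i, t in enumerate(truth) if i not in matched_truth and matches(call.junction, t)),
            None,
        )
        if hit is not None:
            matched_truth.add(hit)
            tp += 1
    fp = len(calls) - tp
    fn = len(truth) - len(matched_truth)
    precision = tp / (tp + fp) if calls else 0.0
    recall = tp / (tp + fn) if truth else 0.0
    return {"tp": tp, "fp": fp, "fn": fn, "precision": precision, "recall": recall}


def junctions_to_frame(calls: Sequence[JunctionCall]) -> pd.DataFrame:
    rows = [
        (
            c.junction.a.ref_id,
            c.junction.a.pos,
            c.junction.a.side,
            c.junction.b.ref_id,
            c.junction.b.pos,
            c.junction.b.side,
            c.orientation,
            c.support,
        )
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["ref_a", "pos_a", "side_a", "ref_b", "pos_b", "side_b", "orientation", "support"],
    )
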