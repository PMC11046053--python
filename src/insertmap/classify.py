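"""Informative-read classification of aligned pairs.

Pairs mapped jointly against host + construct references fall into five
mutually exclusive classes:

* ``ISOLATERAL`` — both mates land on the construct only (deep inside the
  insert, no junction information beyond presence);
* ``FLANKING`` — one mate uniquely on the construct, the other uniquely on a
  host contig (the pair straddles a junction);
* ``CHIMERIC`` — a single read is split across two references: its soft clip
  re-aligns to a different reference than its matched block (base-resolution
  junction evidence);
* ``HOMOLOGOUS`` — a mate is ambiguous between construct and host because the
  two share sequence (e.g. the selection-marker gene);
* ``NON_INFORMATIVE`` — everything else (host-only pairs, unmapped).

Precedence when several criteria fire: CHIMERIC > FLANKING > HOMOLOGOUS >
ISOLATERAL > NON_INFORMATIVE; split-read evidence must not be absorbed by the
coarser pair-level classes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .align import Alignment, PairAlignment, ReferenceIndex, align_read
from .junctions import ClipFragment, extract_softclips


class InformativeClass(str, Enum):
    ISOLATERAL = "ISOLATERAL"
    FLANKING = "FLANKING"
    CHIMERIC = "CHIMERIC"
    HOMOLOGOUS = "HOMOLOGOUS"
    NON_INFORMATIVE = "NON_INFORMATIVE"


@dataclass
class ClassCounts:
    """Tallies of classified pairs, overall and per reference."""

    pair_counts: Counter = field(default_factory=Counter)
    # (class, reference id) -> number of pairs with a primary mate on that ref
    ref_pair_counts: Counter = field(default_factory=Counter)
    # (class, mate) -> mapped-mate tallies, for the R1/R2 symmetry check
    mate_counts: Counter = field(default_factory=Counter)
    roles: dict[str, str] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.pair_counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (cls.value, self.pair_counts.get(cls, 0),
             self.mate_counts.get((cls, "R1"), 0), self.mate_counts.get((cls, "R2"), 0))
            for cls in InformativeClass
        ]
        return pd.DataFrame(rows, columns=["class", "pairs", "r1_mapped", "r2_mapped"])

    def support_frame(self) -> pd.DataFrame:
        rows = [
            (cls, ref, n) for (cls, ref), n in sorted(self.ref_pair_counts.items())
        ]
        return pd.DataFrame(rows, columns=["class", "reference", "pairs"])


class PairClassifier:
    """Classifies pairs against a joint reference index.

    ``min_clip`` is the minimum soft-clip length considered as chimeric
    evidence; shorter clips re-align spuriously.  A small-k secondary index is
    built lazily for clip re-alignment.
    """

    def __init__(self, index: ReferenceIndex, min_clip: int = 20, clip_k: int = 13):
        self.index = index
        self.min_clip = min_clip
        self._clip_index = (
            index if index.k <= clip_k else ReferenceIndex(index.records, k=clip_k)
        )

    def _role(self, ref_id: str) -> str:
        return self.index.roles.get(ref_id, "host")

    def _mate_refs(self, alns: Sequence[Alignment]) -> set[str]:
        return {self._role(a.ref_id) for a in alns}

    def _is_chimeric_mate(self, alns: Sequence[Alignment]) -> bool:
        if not alns:
            return False
        primary = alns[0]
        if primary.ambiguous:
            return False
        for frag in extract_softclips([primary], min_clip=self.min_clip):
            hits = align_read(frag.seq, self._clip_index, n_offsets=8)
            if not hits or hits[0].ambiguous:
                continue
            if hits[0].ref_id != primary.ref_id:
                return True
        return False

    def classify_pair(self, pair: PairAlignment) -> InformativeClass:
        if pair.r1 is None and pair.r2 is None:
            raise ValueError("pair was never aligned")
        mates = [pair.r1, pair.r2]
        if self._is_chimeric_mate(pair.r1) or self._is_chimeric_mate(pair.r2):
            return InformativeClass.CHIMERIC

        def unique_role(alns: Sequence[Alignment]) -> str | None:
            if alns and not alns[0].ambiguous:
                return self._role(alns[0].ref_id)
            return None

        u1, u2 = unique_role(pair.r1), unique_role(pair.r2)
        if {u1, u2} == {"construct", "host"}:
            return InformativeClass.FLANKING
        for alns in mates:
            if alns and alns[0].ambiguous and self._mate_refs(alns) >= {"construct", "host"}:
                return InformativeClass.HOMOLOGOUS
        if (
            pair.r1
            and pair.r2
            and self._mate_refs(pair.r1) == {"construct"}
            and self._mate_refs(pair.r2) == {"construct"}
        ):
            return InformativeClass.ISOLATERAL
        return InformativeClass.NON_INFORMATIVE


def classify_pair(
    pair: PairAlignment, index: ReferenceIndex, min_clip: int = 20
) -> InformativeClass:
    """Convenience wrapper; build a :class:`PairClassifier` for bulk use."""
    return PairClassifier(index, min_clip=min_clip).classify_pair(pair)


def count_classes(
    classified: Iterable[tuple[PairAlignment, InformativeClass]],
    index: ReferenceIndex | None = None,
) -> ClassCounts:
    """Exhaustive, mutually exclusive tally with per-mate and per-reference
    breakdowns."""
    counts = ClassCounts()
    if index is not None:
        counts.roles = dict(index.roles)
    for pair, cls in classified:
        counts.pair_counts[cls] += 1
        refs = set()
        for mate_name, alns in (("R1", pair.r1), ("R2", pair.r2)):
            if alns:
                counts.mate_counts[(cls, mate_name)] += 1
                refs.add(alns[0].ref_id)
        for ref in refs:
            counts.ref_pair_counts[(cls, ref)] += 1
    return counts


def nominate_integration_contigs(
    counts: ClassCounts, min_support: int = 3
) -> list[str]:
    """Host contigs ranked by flanking + chimeric pair support.

    These are the putative construct-integrated contigs; contigs below
    ``min_support`` pairs are excluded.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    support: Counter = Counter()
    for (cls, ref), n in counts.ref_pair_counts.items():
        if cls in (InformativeClass.FLANKING, InformativeClass.CHIMERIC):
            if counts.roles.get(ref, "host") == "host":
                support[ref] += n
    ranked = sorted(support.items(), key=lambda kv: (-kv[1], kv[0]))
    return [ref for ref, n in ranked if n >= min_support]
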