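"""Core containers: named sequences, genome sets, features, and assay tables.

Coordinates are 0-based, half-open throughout the library; SAM output is the
only place where 1-based coordinates appear (handled by pysam).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

ALPHABET = frozenset("ACGTN")
ROLES = ("host", "construct", "assembled")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named nucleotide sequence with a pipeline role.

    ``copies`` is the background copy count used by the read simulator: host
    contigs default to 2 (diploid-like), engineered alleles are created at 1.
    """

    id: str
    sequence: str
    role: str = "host"
    copies: int = 2

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be nonempty")
        if self.role not in ROLES:
            raise ValueError(f"record {self.id!r}: unknown role {self.role!r}")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(f"record {self.id!r}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Feature:
    """A labelled half-open interval on a record.

    ``copies`` carries the planned copy count where one is meaningful (cassette
    annotations on the reference set; copy-altered regions for the simulator).
    """

    record_id: str
    start: int
    end: int
    label: str
    copies: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"feature {self.label!r}: bad interval [{self.start}, {self.end})")


@dataclass
class GenomeSet:
    """A set of sequence records plus interval annotations."""

    records: list[SequenceRecord]
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in genome set")
        by_id = {r.id: r for r in self.records}
        for f in self.features:
            rec = by_id.get(f.record_id)
            if rec is None:
                raise ValueError(f"feature {f.label!r} references unknown record {f.record_id!r}")
            if f.end > len(rec):
                raise ValueError(f"feature {f.label!r} exceeds record {f.record_id!r} bounds")

    def __iter__(self):
        return iter(self.records)

    def get(self, record_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(record_id)

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.records)

    def features_of(self, label: str) -> list[Feature]:
        return [f for f in self.features if f.label == label]

    def write_fasta(self, path: str | Path) -> None:
        recs = [
            _BioSeqRecord(Seq(r.sequence), id=r.id, description=f"role={r.role} copies={r.copies}")
            for r in self.records
        ]
        SeqIO.write(recs, str(path), "fasta")

    @classmethod
    def read_fasta(cls, path: str | Path, role: str = "host", copies: int = 2) -> "GenomeSet":
        """Read a FASTA; ``role=...`` / ``copies=...`` tokens written by
        :meth:`write_fasta` are honoured when present."""
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            rec_role, rec_copies = role, copies
            for token in (rec.description or "").split():
                if token.startswith("role=") and token[5:] in ROLES:
                    rec_role = token[5:]
                elif token.startswith("copies=") and token[7:].isdigit():
                    rec_copies = int(token[7:])
            records.append(
                SequenceRecord(rec.id, str(rec.seq).upper(), role=rec_role, copies=rec_copies)
            )
        return cls(records)

    def write_features_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in self.features:
                copies = "." if f.copies is None else str(f.copies)
                fh.write(f"{f.record_id}\t{f.start}\t{f.end}\t{f.label}\t{copies}\n")


@dataclass
class CultureTimeSeries:
    """Batch-culture observables: day, viable cell density, viability, titer.

    Units: day (d), VCD (cells/mL), viability (percent), titer (ug/mL).
    """

    day: np.ndarray
    vcd: np.ndarray
    viability: np.ndarray
    titer: np.ndarray

    def __post_init__(self) -> None:
        self.day = np.asarray(self.day, dtype=float)
        self.vcd = np.asarray(self.vcd, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        self.titer = np.asarray(self.titer, dtype=float)
        n = len(self.day)
        if not (len(self.vcd) == len(self.viability) == len(self.titer) == n):
            raise ValueError("culture series columns must have equal length")
        if n and np.any(np.diff(self.day) <= 0):
            raise ValueError("day must be strictly increasing")
        if np.any(self.vcd < 0) or np.any(self.titer < 0):
            raise ValueError("VCD and titer must be nonnegative")
        if np.any((self.viability < 0) | (self.viability > 100)):
            raise ValueError("viability must lie in [0, 100]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": self.day, "vcd": self.vcd, "viability": self.viability, "titer": self.titer}
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CultureTimeSeries":
        df = pd.read_csv(path, sep="\t")
        return cls(df["day"].values, df["vcd"].values, df["viability"].values, df["titer"].values)


class CtTable:
    """qPCR quantification-cycle table: one row per (sample, gene, replicate).

    Genes are conventionally ``target`` (the assayed locus) and ``reference``
    (the normalizer, e.g. vinculin).
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"sample", "gene", "ct"}
        if not required <= set(frame.columns):
            raise ValueError(f"Ct table needs columns {sorted(required)}")
        if (frame["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        for sample, sub in frame.groupby("sample"):
            if set(sub["gene"]) != {"target", "reference"}:
                raise ValueError(f"sample {sample!r} must have both target and reference rows")
        self.frame = frame.reset_index(drop=True)

    def mean_ct(self, sample: str, gene: str) -> float:
        sel = self.frame[(self.frame["sample"] == sample) & (self.frame["gene"] == gene)]
        if sel.empty:
            raise KeyError(f"no Ct rows for sample={sample!r} gene={gene!r}")
        return float(sel["ct"].mean())

    def samples(self) -> list[str]:
        return sorted(self.frame["sample"].unique())

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CtTable":
        return cls(pd.read_csv(path, sep="\t"))


def write_fastq_pairs(
    pairs: Sequence[tuple[str, str, str]], path_r1: str | Path, path_r2: str | Path
) -> None:
    """Write (read id, seq1, seq2) triples as a /1,/2-suffixed FASTQ pair."""
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for rid, s1, s2 in pairs:
            f1.write(f"@{rid}/1\n{s1}\n+\n{'I' * len(s1)}\n")
            f2.write(f"@{rid}/2\n{s2}\n+\n{'I' * len(s2)}\n")


def read_fastq_pairs(path_r1: str | Path, path_r2: str | Path) -> list[tuple[str, str, str]]:
    r1 = list(SeqIO.parse(str(path_r1), "fastq"))
    r2 = list(SeqIO.parse(str(path_r2), "fastq"))
    if len(r1) != len(r2):
        raise ValueError("R1 and R2 FASTQ files have different read counts")
    out = []
    for a, b in zip(r1, r2):
        rid = a.id.removesuffix("/1")
        if b.id.removesuffix("/2") != rid:
            raise ValueError(f"unpaired reads: {a.id} vs {b.id}")
        out.append((rid, str(a.seq).upper(), str(b.seq).upper()))
    return out
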