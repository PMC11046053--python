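"""Synthetic integrant genomes with known truth, plus read/assay simulators.

The generators emulate the data a transgene-integration analysis consumes: a
multi-contig, mostly two-copy host genome; an engineered allele carrying an
expression construct in rearranged form (an intact copy, a truncated copy
lacking the selection-marker and heavy-chain cassettes, extra light-chain
copies with one inversion, a short fragment borrowed from an unrelated host
contig, and a tandemly amplified upstream region); error-prone paired-end
reads; batch-culture growth/titer curves; and qPCR quantification-cycle
tables.  Every generator is deterministic under a fixed seed and each
engineered genome ships with a :class:`TruthSet` for closed-loop testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .records import (
    CtTable,
    CultureTimeSeries,
    Feature,
    GenomeSet,
    SequenceRecord,
    revcomp,
)
from .junctions import Junction, JunctionEnd, canonicalize_junction

import pandas as pd

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def simulate_host_genome(
    n_contigs: int,
    lengths: Sequence[int],
    seed: int,
    ids: Sequence[str] | None = None,
) -> GenomeSet:
    """Random host contigs with a diploid-like two-copy background.

    Bases are drawn uniformly, so expected GC content is 0.50.
    """
    if len(lengths) != n_contigs:
        raise ValueError("lengths must have n_contigs entries")
    if any(l <= 0 for l in lengths):
        raise ValueError("contig lengths must be positive")
    if ids is None:
        ids = [f"chr_{i + 1}" for i in range(n_contigs)]
    rng = np.random.default_rng(seed)
    records = [
        SequenceRecord(cid, _random_sequence(rng, length), role="host", copies=2)
        for cid, length in zip(ids, lengths)
    ]
    return GenomeSet(records)


# ---------------------------------------------------------------------------
# Integration plans
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    """One inserted piece: a source interval taken forward or reverse-complement."""

    ref_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"segment on {self.ref_id}: bad interval")
        if self.strand not in "+-":
            raise ValueError("segment strand must be '+' or '-'")


@dataclass
class IntegrationPlan:
    """Where and how the construct material enters the host genome.

    ``position`` is 0-based: inserted material goes before that base of the
    host contig.  ``amplified_region`` is a host interval ending at or before
    the insertion point; with ``amplification_factor`` f the modified allele
    carries 2f-1 tandem copies so that against the unmodified homolog the
    total copy count is 2f (an f-fold gain over the diploid baseline).
    """

    host_id: str
    position: int
    segments: list[Segment] = field(default_factory=list)
    amplified_region: tuple[int, int] | None = None
    amplification_factor: int = 1

    def __post_init__(self) -> None:
        if self.amplification_factor < 1:
            raise ValueError("amplification factor must be >= 1")
        if self.amplification_factor > 1 and self.amplified_region is None:
            raise ValueError("amplification factor > 1 requires an amplified region")


@dataclass
class TruthSet:
    """Ground truth derived from an :class:`IntegrationPlan`."""

    junctions: list[Junction]
    cassette_copies: dict[str, int]
    amplified_fold: float


def _layout_elements(
    genome: GenomeSet, construct: SequenceRecord, plan: IntegrationPlan
) -> list[tuple[str, int, int, str]]:
    """Expand a plan into the ordered (ref, start, end, strand) pieces of the
    modified allele."""
    host = genome.get(plan.host_id)
    if not (0 <= plan.position <= len(host)):
        raise ValueError("insertion position outside host contig")
    elements: list[tuple[str, int, int, str]] = []
    if plan.position > 0:
        elements.append((host.id, 0, plan.position, "+"))
    if plan.amplified_region is not None and plan.amplification_factor > 1:
        a, b = plan.amplified_region
        if not (0 <= a < b <= plan.position):
            raise ValueError("amplified region must lie upstream of the insertion point")
        for _ in range(2 * plan.amplification_factor - 2):
            elements.append((host.id, a, b, "+"))
    sources = {construct.id: construct.sequence}
    for rec in genome:
        sources[rec.id] = rec.sequence
    for seg in plan.segments:
        if seg.ref_id not in sources:
            raise ValueError(f"segment references unknown record {seg.ref_id!r}")
        if seg.end > len(sources[seg.ref_id]):
            raise ValueError(f"segment on {seg.ref_id} out of bounds")
        elements.append((seg.ref_id, seg.start, seg.end, seg.strand))
    if plan.position < len(host):
        elements.append((host.id, plan.position, len(host), "+"))
    return elements


def _element_ends(el: tuple[str, int, int, str]) -> tuple[JunctionEnd, JunctionEnd]:
    """(left end, right end) of an element in the fused reading direction."""
    ref, start, end, strand = el
    if strand == "+":
        return JunctionEnd(ref, start, "R"), JunctionEnd(ref, end - 1, "L")
    return JunctionEnd(ref, end - 1, "L"), JunctionEnd(ref, start, "R")


def _contiguous(prev: tuple[str, int, int, str], nxt: tuple[str, int, int, str]) -> bool:
    if prev[0] != nxt[0] or prev[3] != nxt[3]:
        return False
    if prev[3] == "+":
        return prev[2] == nxt[1]
    return prev[1] == nxt[2]


def count_occurrences(genome: GenomeSet, motif: str) -> int:
    """Copy-weighted occurrences of a motif (either strand) in a genome set."""
    rc = revcomp(motif)
    total = 0
    for rec in genome:
        for probe in {motif, rc}:
            n, idx = 0, rec.sequence.find(probe)
            while idx >= 0:
                n += 1
                idx = rec.sequence.find(probe, idx + 1)
            total += n * rec.copies
    return total


def apply_integration(
    genome: GenomeSet,
    construct: SequenceRecord,
    plan: IntegrationPlan,
    cassette_features: Sequence[Feature] | None = None,
) -> tuple[GenomeSet, TruthSet]:
    """Build the engineered genome and its truth set.

    The modified allele becomes a new record at copy count 1; the unmodified
    homolog of the insertion contig is kept at copy count 1 so the locus stays
    diploid overall.  Other host contigs are untouched (copy count 2).
    """
    elements = _layout_elements(genome, construct, plan)
    sources = {construct.id: construct.sequence}
    for rec in genome:
        sources[rec.id] = rec.sequence
    parts = []
    for ref, start, end, strand in elements:
        piece = sources[ref][start:end]
        parts.append(piece if strand == "+" else revcomp(piece))
    modified = SequenceRecord(
        f"{plan.host_id}__integrant", "".join(parts), role="host", copies=1
    )

    junctions: set[Junction] = set()
    for prev, nxt in zip(elements, elements[1:]):
        if _contiguous(prev, nxt):
            continue
        left = _element_ends(prev)[1]
        right = _element_ends(nxt)[0]
        # canonicalize under micro-homology so truth and clip-derived calls
        # use the same representative of each breakpoint orbit
        junctions.add(
            canonicalize_junction(Junction.canonical(left, right), sources)
        )

    records = [modified]
    for rec in genome:
        copies = 1 if rec.id == plan.host_id else rec.copies
        records.append(SequenceRecord(rec.id, rec.sequence, role=rec.role, copies=copies))
    integrant = GenomeSet(records)

    cassette_copies: dict[str, int] = {}
    if cassette_features:
        src = {construct.id: construct.sequence, **{r.id: r.sequence for r in genome}}
        for feat in cassette_features:
            motif = src[feat.record_id][feat.start : feat.end]
            cassette_copies[feat.label] = count_occurrences(integrant, motif)

    fold = float(plan.amplification_factor)
    truth = TruthSet(sorted(junctions), cassette_copies, fold)
    return integrant, truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _copy_pieces(genome: GenomeSet) -> list[tuple[int, int, int, int]]:
    """Per-record piecewise copy profile: (record index, start, end, copies).

    Features carrying an explicit copy count override the record background.
    """
    pieces = []
    for ri, rec in enumerate(genome):
        cuts = {0, len(rec)}
        overrides = [
            f for f in genome.features if f.record_id == rec.id and f.copies is not None
        ]
        for f in overrides:
            cuts.update((f.start, f.end))
        bounds = sorted(cuts)
        for s, e in zip(bounds, bounds[1:]):
            copies = rec.copies
            for f in overrides:
                if f.start <= s and e <= f.end:
                    copies = f.copies
            pieces.append((ri, s, e, copies))
    return pieces


def simulate_reads(
    genome: GenomeSet,
    coverage: float,
    read_len: int = 150,
    insert_mean: float = 500.0,
    insert_sd: float = 50.0,
    error_rate: float = 0.001,
    seed: int = 0,
    with_truth: bool = False,
):
    """Paired-end substitution-error reads, fragments weighted by copy count.

    The pair count is ``round(coverage * total_length / (2 * read_len))``;
    with an all-two-copy genome this yields mean per-base depth ~= coverage.
    Returns a list of ``(read id, R1 seq, R2 seq)``; with ``with_truth`` also
    a DataFrame of fragment origins.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if read_len > insert_mean:
        raise ValueError("read length must not exceed the mean insert size")
    rng = np.random.default_rng(seed)
    pieces = _copy_pieces(genome)
    weights = np.array([(e - s) * c for _, s, e, c in pieces], dtype=float)
    if weights.sum() == 0:
        raise ValueError("genome has zero total copy weight")
    probs = weights / weights.sum()
    n_pairs = int(round(coverage * genome.total_length / (2 * read_len)))

    piece_idx = rng.choice(len(pieces), size=n_pairs, p=probs)
    inserts = rng.normal(insert_mean, insert_sd, size=n_pairs)
    swap = rng.random(n_pairs) < 0.5
    records = genome.records

    pairs: list[tuple[str, str, str]] = []
    truth_rows = []
    for i in range(n_pairs):
        ri, ps, pe, _ = pieces[piece_idx[i]]
        rec = records[ri]
        ins = int(round(inserts[i]))
        for _ in range(10):
            if ins >= read_len:
                break
            ins = int(round(rng.normal(insert_mean, insert_sd)))
        ins = max(ins, read_len)
        ins = min(ins, len(rec))
        start = int(rng.integers(ps, pe))
        if start + ins > len(rec):
            start = len(rec) - ins
        frag = rec.sequence[start : start + ins]
        fwd = frag[:read_len]
        rev = revcomp(frag[-read_len:])
        r1, r2 = (rev, fwd) if swap[i] else (fwd, rev)
        rid = f"pair{i:06d}"
        pairs.append((rid, r1, r2))
        if with_truth:
            truth_rows.append((rid, rec.id, start, start + ins, not swap[i]))

    if error_rate > 0:
        pairs = _add_substitutions(pairs, error_rate, rng)
    if with_truth:
        truth = pd.DataFrame(
            truth_rows, columns=["read_id", "record_id", "frag_start", "frag_end", "r1_forward"]
        )
        return pairs, truth
    return pairs


def _add_substitutions(pairs, error_rate: float, rng: np.random.Generator):
    out = []
    for rid, r1, r2 in pairs:
        out.append((rid, _mutate(r1, error_rate, rng), _mutate(r2, error_rate, rng)))
    return out


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


# ---------------------------------------------------------------------------
# Culture / qPCR simulators
# ---------------------------------------------------------------------------


def simulate_culture(
    growth_rate: float,
    capacity: float,
    qp_true: float,
    days: int,
    seed: int = 0,
    v0: float = 0.3e6,
    titer_noise_sd: float = 0.0,
) -> CultureTimeSeries:
    """Logistic batch culture sampled daily from day 0 to ``days``.

    VCD follows the closed-form logistic curve; the titer increment of each
    step is ``qp_true`` (pg/cell/day) times the trapezoidal viable-cell
    integral of the step, converted to ug/mL.  With zero noise the specific
    productivity estimator recovers ``qp_true`` exactly by construction.
    """
    if capacity <= 0 or qp_true < 0 or days <= 0 or v0 <= 0 or growth_rate < 0:
        raise ValueError("culture parameters must be positive (qp, growth rate >= 0)")
    rng = np.random.default_rng(seed)
    day = np.arange(days + 1, dtype=float)
    expo = np.exp(growth_rate * day)
    vcd = capacity * v0 * expo / (capacity + v0 * (expo - 1.0))
    viability = np.clip(98.0 - 10.0 * (vcd / capacity) ** 4, 0.0, 100.0)
    steps = 0.5 * (vcd[1:] + vcd[:-1]) * np.diff(day)  # cell*day/mL
    titer = np.concatenate([[0.0], np.cumsum(qp_true * steps) * 1e-6])  # ug/mL
    if titer_noise_sd > 0:
        titer = np.clip(titer + rng.normal(0, titer_noise_sd, size=titer.size), 0, None)
        titer[0] = 0.0
    return CultureTimeSeries(day, vcd, viability, titer)


def simulate_qpcr(
    copy_target_sample: float,
    copy_target_control: float,
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    base_ct: float = 26.0,
    reference_ct: float = 20.0,
) -> CtTable:
    """Quantification-cycle table for a target locus vs a stable reference gene.

    Assumes 100% amplification efficiency (one Ct per doubling), so the
    noiseless target Ct difference between samples is -log2 of the copy ratio
    while the reference gene is constant.
    """
    if copy_target_sample <= 0 or copy_target_control <= 0:
        raise ValueError("copy numbers must be positive")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    rows = []
    for sample, copies in (("sample", copy_target_sample), ("control", copy_target_control)):
        for gene, ct0 in (("target", base_ct - np.log2(copies)), ("reference", reference_ct)):
            for r in range(replicates):
                ct = ct0 + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append((sample, gene, r + 1, float(ct)))
    return CtTable(pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"]))


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


@dataclass
class ScenarioConfig:
    """Sizes and layout of the default engineered-genome scenario.

    The construct carries promoter/heavy-chain (HC), promoter/light-chain
    (LC), and promoter/selection-marker (GS) cassettes.  The engineered allele
    is: host upstream with the region just upstream of the insertion point
    tandemly amplified, a short fragment of an unrelated host contig, one
    intact construct copy, a truncated copy lacking the GS and HC cassettes,
    one extra forward LC copy and one inverted LC copy, then the host
    downstream.  Net cassette copy numbers: HC 1, LC 4, GS 3 (one vector copy
    plus the diploid host homolog of the marker).
    """

    host_lengths: tuple[int, ...] = (40_000, 12_000, 10_000)
    construct_length: int = 8_000
    # construct cassette coordinates (0-based, half-open)
    hc: tuple[int, int] = (600, 2_400)
    lc: tuple[int, int] = (2_600, 4_000)
    gs: tuple[int, int] = (4_200, 5_600)
    promoter: tuple[int, int] = (400, 600)
    truncated_copy: tuple[int, int] = (2_400, 4_200)  # lacks HC and GS
    # extra LC copies are carried with 200 bp of flanking construct context so
    # every LC copy sits in identical sequence and depth stays flat across it
    extra_copy: tuple[int, int] = (2_400, 4_200)
    insertion_position: int = 20_000
    amplified_region: tuple[int, int] = (16_000, 20_000)
    amplification_factor: int = 4
    fragment_source: tuple[int, int] = (6_000, 6_240)  # on the second host contig
    gs_homolog_position: int = 4_000  # on the third host contig

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs = {}
        for key, value in raw.items():
            kwargs[key] = tuple(value) if isinstance(value, list) else value
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(self).items()},
                fh,
                sort_keys=False,
            )


@dataclass
class Scenario:
    """A fully built synthetic study: references, engineered genome, truth."""

    host: GenomeSet
    construct: SequenceRecord
    reference: GenomeSet  # host contigs + construct: the mapping reference set
    integrant: GenomeSet  # what reads are simulated from
    truth: TruthSet
    plan: IntegrationPlan
    config: ScenarioConfig


def build_scenario(config: ScenarioConfig, seed: int) -> Scenario:
    rng = np.random.default_rng(seed)
    host = simulate_host_genome(
        len(config.host_lengths), list(config.host_lengths), seed=int(rng.integers(2**31))
    )
    construct_seq = _random_sequence(rng, config.construct_length)
    construct = SequenceRecord("construct", construct_seq, role="construct", copies=1)

    # plant the selection-marker homolog in the host genome (shared sequence
    # makes read origins ambiguous, the homologous informative class)
    gs_seq = construct_seq[config.gs[0] : config.gs[1]]
    carrier = host.records[2]
    p = config.gs_homolog_position
    carrier.sequence = carrier.sequence[:p] + gs_seq + carrier.sequence[p + len(gs_seq) :]

    cassette_features = [
        Feature("construct", *config.hc, "HC", 1),
        Feature("construct", *config.lc, "LC", 4),
        Feature("construct", *config.gs, "GS", 3),
        Feature("construct", *config.promoter, "promoter", 1),
        Feature(
            host.records[0].id,
            *config.amplified_region,
            "amplified-region",
            2 * config.amplification_factor,
        ),
    ]
    frag_src = host.records[1].id
    plan = IntegrationPlan(
        host_id=host.records[0].id,
        position=config.insertion_position,
        segments=[
            Segment(frag_src, *config.fragment_source, "+"),
            Segment("construct", 0, config.construct_length, "+"),
            Segment("construct", *config.truncated_copy, "+"),
            Segment("construct", *config.extra_copy, "+"),
            Segment("construct", *config.extra_copy, "-"),
        ],
        amplified_region=config.amplified_region,
        amplification_factor=config.amplification_factor,
    )
    integrant, truth = apply_integration(host, construct, plan, cassette_features)

    reference = GenomeSet(
        [SequenceRecord(r.id, r.sequence, role="host", copies=r.copies) for r in host]
        + [SequenceRecord(construct.id, construct.sequence, role="construct", copies=1)],
        features=cassette_features,
    )
    return Scenario(host, construct, reference, integrant, truth, plan, config)


def default_scenario(seed: int) -> Scenario:
    """The repo's shared engineered-genome fixture (see :class:`ScenarioConfig`)."""
    cfg_path = Path(__file__).parent / "data" / "default_scenario.yaml"
    config = ScenarioConfig.from_yaml(cfg_path) if cfg_path.exists() else ScenarioConfig()
    return build_scenario(config, seed)


def random_scenario(
    seed: int,
    host_lengths: tuple[int, int] = (10_000, 5_000),
    construct_length: int = 2_500,
) -> Scenario:
    """A randomized small integrant scenario for seeded sweeps.

    Each draw varies the insertion point, a borrowed host fragment (either
    strand), an optional extra construct sub-segment (either strand) and an
    optional tandem amplification, while keeping all junction pairs far
    enough apart to be individually resolvable."""
    rng = np.random.default_rng(seed)
    host = simulate_host_genome(2, list(host_lengths), seed=int(rng.integers(2**31)))
    construct = SequenceRecord(
        "construct", _random_sequence(rng, construct_length), role="construct", copies=1
    )
    position = int(rng.integers(3_000, host_lengths[0] - 3_000))
    frag_len = int(rng.integers(240, 600))
    frag_start = int(rng.integers(500, host_lengths[1] - 1_000))
    segments = [
        Segment(host.records[1].id, frag_start, frag_start + frag_len, rng.choice(["+", "-"])),
        Segment("construct", 0, construct_length, "+"),
    ]
    if rng.random() < 0.5:
        sub_start = int(rng.integers(400, 1_000))
        sub_len = int(rng.integers(400, 800))
        segments.append(
            Segment("construct", sub_start, sub_start + sub_len, rng.choice(["+", "-"]))
        )
    amplified = None
    factor = 1
    if rng.random() < 0.5:
        reg_len = int(rng.integers(1_000, 1_500))
        amplified = (position - reg_len, position)
        factor = int(rng.integers(2, 4))
    plan = IntegrationPlan(
        host_id=host.records[0].id,
        position=position,
        segments=segments,
        amplified_region=amplified,
        amplification_factor=factor,
    )
    integrant, truth = apply_integration(host, construct, plan)
    reference = GenomeSet(
        [SequenceRecord(r.id, r.sequence, role="host", copies=2) for r in host]
        + [SequenceRecord(construct.id, construct.sequence, role="construct", copies=1)]
    )
    return Scenario(host, construct, reference, integrant, truth, plan, ScenarioConfig())


def simulate_hemizygous_genome(
    lengths: Sequence[int],
    one_copy_regions: Sequence[tuple[int, int, int]],
    seed: int,
) -> tuple[GenomeSet, GenomeSet]:
    """A diploid genome carrying hemizygous (one-copy) regions, as explicit
    haplotypes.

    ``one_copy_regions`` are (contig index, start, end) intervals deleted from
    one allele.  Returns ``(reference, read_source)``: the reference holds the
    full contigs annotated with the one-copy intervals; the read source holds
    both alleles at copy 1 each, so reads simulated from it show flat one-copy
    depth inside the regions and reads spanning a deletion junction soft-clip
    at it — the physical signal of a hemizygous loss.
    """
    host = simulate_host_genome(len(lengths), list(lengths), seed=seed)
    features = [
        Feature(host.records[ci].id, s, e, "one-copy", 1) for ci, s, e in one_copy_regions
    ]
    reference = GenomeSet(
        [SequenceRecord(r.id, r.sequence, role="host", copies=2) for r in host], features
    )
    source_records = []
    for i, rec in enumerate(host):
        keep = rec.sequence
        dels = sorted((s, e) for ci, s, e in one_copy_regions if ci == i)
        deleted = []
        prev = 0
        for s, e in dels:
            deleted.append(keep[prev:s])
            prev = e
        deleted.append(keep[prev:])
        source_records.append(SequenceRecord(rec.id + "_a", keep, role="host", copies=1))
        source_records.append(
            SequenceRecord(rec.id + "_b", "".join(deleted), role="host", copies=1)
        )
    return reference, GenomeSet(source_records)


def walk_scenario(
    seed: int,
    host_length: int = 20_000,
    construct_length: int = 4_000,
    position: int = 12_000,
) -> Scenario:
    """A minimal single-junction scenario used for genome-walking studies:
    one host contig with one intact construct copy and ample unique upstream
    sequence."""
    rng = np.random.default_rng(seed)
    host = simulate_host_genome(1, [host_length], seed=int(rng.integers(2**31)))
    construct = SequenceRecord(
        "construct", _random_sequence(rng, construct_length), role="construct", copies=1
    )
    plan = IntegrationPlan(
        host_id=host.records[0].id,
        position=position,
        segments=[Segment("construct", 0, construct_length, "+")],
    )
    integrant, truth = apply_integration(host, construct, plan)
    reference = GenomeSet(
        [SequenceRecord(r.id, r.sequence, role="host", copies=2) for r in host]
        + [SequenceRecord(construct.id, construct.sequence, role="construct", copies=1)]
    )
    return Scenario(host, construct, reference, integrant, truth, plan, ScenarioConfig())
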