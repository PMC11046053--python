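import numpy as np
import pytest

import insertmap as im
from insertmap.synth import _random_sequence
from insertmap.walk import (
    WalkConfig,
    assemble_reads,
    make_seed,
    place_contig,
    recruit_end_reads,
    walk,
)


def test_assembler_reconstructs_tiled_sequence():
    rng = np.random.default_rng(5)
    truth = _random_sequence(rng, 1000)
    reads = [truth[i : i + 150] for i in range(0, 851, 50)]
    contigs = assemble_reads(reads, min_overlap=30)
    assert len(contigs) == 1
    assert contigs[0].sequence in (truth, im.revcomp(truth))


def test_assembler_mixed_orientations_still_reconstruct():
    rng = np.random.default_rng(6)
    truth = _random_sequence(rng, 800)
    reads = []
    for i in range(0, 651, 50):
        piece = truth[i : i + 150]
        reads.append(piece if i % 100 == 0 else im.revcomp(piece))
    contigs = assemble_reads(reads, min_overlap=30)
    assert len(contigs) == 1
    assert contigs[0].sequence in (truth, im.revcomp(truth))


def test_assembler_disjoint_reads_stay_separate():
    rng = np.random.default_rng(7)
    a, b = _random_sequence(rng, 120), _random_sequence(rng, 120)
    contigs = assemble_reads([a, b], min_overlap=30)
    assert len(contigs) == 2


def test_assembler_read_and_its_reverse_complement_collapse():
    rng = np.random.default_rng(8)
    a = _random_sequence(rng, 150)
    contigs = assemble_reads([a, im.revcomp(a)], min_overlap=30)
    assert len(contigs) == 1


def test_assembler_empty_and_validation():
    assert assemble_reads([], min_overlap=30) == []
    with pytest.raises(ValueError):
        assemble_reads(["ACGT" * 50], min_overlap=10)


def test_assembler_deterministic():
    rng = np.random.default_rng(9)
    truth = _random_sequence(rng, 600)
    reads = [truth[i : i + 150] for i in range(0, 451, 30)]
    rng.shuffle(reads)
    a = assemble_reads(list(reads), min_overlap=30)
    b = assemble_reads(list(reads), min_overlap=30)
    assert [c.sequence for c in a] == [c.sequence for c in b]


def _pairs_for(contig_seq, alns):
    return alns


def test_recruit_end_reads_window_and_mate_rescue():
    rng = np.random.default_rng(10)
    contig_seq = _random_sequence(rng, 2000)
    contig = im.SequenceRecord("c", contig_seq, role="assembled", copies=1)
    idx = im.ReferenceIndex([contig], k=21)
    inside = im.align_pair(contig_seq[50:200], "N" * 150, idx, read_id="edge")
    outside = im.align_pair(contig_seq[500:650], im.revcomp(contig_seq[900:1050]), idx, read_id="far")
    recruits = recruit_end_reads(contig, [inside, outside], window=200, direction="upstream")
    # the edge read is recruited together with its unmapped mate
    assert contig_seq[50:200] in recruits
    assert "N" * 150 in recruits
    assert contig_seq[500:650] not in recruits
    assert recruit_end_reads(contig, [], 200, "upstream") == []


def test_walk_zero_cycles_returns_seed():
    seed = im.SequenceRecord("s", "ACGT" * 100, role="assembled", copies=1)
    res = walk(seed, [], WalkConfig(n_cycles=0))
    assert res.final.sequence == seed.sequence
    assert res.total_extension == 0
    assert res.termination == "completed"


def test_walk_config_validation():
    with pytest.raises(ValueError):
        WalkConfig(direction="sideways")
    with pytest.raises(ValueError):
        WalkConfig(end_window=10)
    with pytest.raises(ValueError):
        WalkConfig(n_cycles=-1)


@pytest.fixture(scope="module")
def walk_setup():
    sc = im.walk_scenario(7)
    reads = im.simulate_reads(
        sc.integrant, coverage=40, read_len=150, insert_mean=500, insert_sd=50,
        error_rate=0.0, seed=7,
    )
    return sc, reads


def test_walk_extends_upstream_with_exact_sequence(walk_setup):
    sc, reads = walk_setup
    cfg = WalkConfig(direction="upstream", n_cycles=3)
    seed = make_seed(reads, sc.construct, cfg)
    res = walk(seed, reads, cfg)
    assert res.termination == "completed"
    assert len(res.extensions) == 3
    assert all(e > 0 for e in res.extensions)
    # never shrinks; cumulative extension = final - seed
    assert len(res.final) - len(seed) == res.total_extension
    # the upstream overhang matches the true host flank exactly
    t = res.final.sequence.find(sc.construct.sequence[:31])
    assert t > 0
    host = sc.host.records[0].sequence
    P = sc.plan.position
    overhang = res.final.sequence[:t]
    assert overhang == host[P - len(overhang) : P]


def test_walk_deterministic(walk_setup):
    sc, reads = walk_setup
    cfg = WalkConfig(direction="upstream", n_cycles=2)
    seed = make_seed(reads, sc.construct, cfg)
    r1 = walk(seed, reads, cfg)
    r2 = walk(seed, reads, cfg)
    assert r1.final.sequence == r2.final.sequence
    assert r1.extensions == r2.extensions


def test_place_contig_exact_substring():
    g = im.simulate_host_genome(1, [20_000], seed=12)
    piece = im.SequenceRecord("q", g.records[0].sequence[4_000:7_000], role="assembled", copies=1)
    placements = place_contig(piece, g)
    assert len(placements) == 1
    p = placements[0]
    assert (p.ref_id, p.contig_start, p.contig_end, p.ref_start, p.ref_end, p.strand) == (
        "chr_1", 0, 3_000, 4_000, 7_000, "+",
    )
    assert p.identity == 1.0


def test_place_contig_fusion_boundary_at_base_precision():
    g = im.simulate_host_genome(2, [20_000, 15_000], seed=13)
    s1, s2 = g.records[0].sequence, g.records[1].sequence
    fused = im.SequenceRecord("f", s1[2_000:4_000] + s2[9_000:11_000], role="assembled", copies=1)
    placements = sorted(place_contig(fused, g), key=lambda p: p.contig_start)
    assert len(placements) == 2
    a, b = placements
    assert a.ref_id == "chr_1" and b.ref_id == "chr_2"
    assert abs(a.contig_end - 2_000) <= 2
    assert abs(b.contig_start - 2_000) <= 2
    assert abs(a.ref_end - 4_000) <= 2
    assert abs(b.ref_start - 9_000) <= 2


def test_downstream_walk_stays_in_construct_repeats():
    sc = im.default_scenario(5)
    reads = im.simulate_reads(sc.integrant, coverage=30, error_rate=0.0, seed=5)
    cfg = WalkConfig(direction="downstream", n_cycles=6)
    res = walk(make_seed(reads, sc.construct, cfg), reads, cfg)
    assert res.termination in ("stalled", "circular")
    assert res.total_extension > 0
    placements = place_contig(res.final, sc.reference)
    roles = {sc.reference.get(p.ref_id).role for p in placements}
    assert roles == {"construct"}  # partial construct copies, never host flank
    # the walk left the construct 3' end and re-entered interior construct
    # sequence (the truncated/extra cassette copies)
    assert len(placements) >= 2
    interior = [p for p in placements if p.ref_start < 5_000]
    assert interior, "walk should re-enter construct-interior repeat copies"
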