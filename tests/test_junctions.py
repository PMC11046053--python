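import numpy as np
import pytest

import insertmap as im
from insertmap.align import Alignment
from insertmap.junctions import (
    Candidate,
    Junction,
    JunctionEnd,
    call_junctions,
    canonicalize_junction,
    extract_softclips,
    match_junctions,
    realign_clips,
)


def _aln(pos, cigar, seq, ref="r", rid="x"):
    return Alignment(rid, "R1", ref, pos, "+", cigar, 0, 100.0, seq=seq)


def test_extract_right_clip_anchor_coordinates():
    aln = _aln(100, [("M", 60), ("S", 90)], "A" * 150)
    frags = extract_softclips([aln], min_clip=20)
    assert len(frags) == 1
    f = frags[0]
    assert (f.side, f.anchor, len(f.seq)) == ("right", 159, 90)  # p + 59, last matched base


def test_extract_left_clip_anchor_coordinates():
    aln = _aln(100, [("S", 90), ("M", 60)], "A" * 150)
    frags = extract_softclips([aln], min_clip=20)
    assert (frags[0].side, frags[0].anchor, len(frags[0].seq)) == ("left", 100, 90)


def test_extract_respects_min_clip_threshold():
    aln = _aln(0, [("M", 140), ("S", 10)], "A" * 150)
    assert extract_softclips([aln], min_clip=20) == []


def test_extract_skips_ambiguous_anchors():
    aln = _aln(0, [("M", 100), ("S", 50)], "A" * 150)
    aln.ambiguous = True
    assert extract_softclips([aln], min_clip=20) == []


def test_realign_exact_and_reverse_complement_clips(toy_references):
    h2 = toy_references.get("h2").sequence
    c = toy_references.get("construct").sequence
    # clip copied exactly from construct start, anchored on h2
    frag_fwd = im.ClipFragment("r1", "h2", 499, "right", c[0:40])
    frag_rev = im.ClipFragment("r2", "h2", 499, "right", im.revcomp(c[200:240]))
    cands = realign_clips([frag_fwd, frag_rev], toy_references.records)
    assert len(cands) == 2
    same = cands[0].junction
    assert same.orientation == "same"
    assert {same.a.ref_id, same.b.ref_id} == {"h2", "construct"}
    inverted = cands[1].junction
    assert inverted.orientation == "inverted"


def test_realign_random_clips_produce_no_spurious_candidates(toy_references):
    rng = np.random.default_rng(77)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    clips = [
        im.ClipFragment(f"r{i}", "h1", 100, "right", bases[rng.integers(0, 4, 30)].tobytes().decode())
        for i in range(1000)
    ]
    cands = realign_clips(clips, toy_references.records)
    assert cands == []


def test_call_junctions_support_threshold_and_clustering():
    j = Junction(JunctionEnd("a", 100, "L"), JunctionEnd("b", 200, "R"))
    near = Junction(JunctionEnd("a", 101, "L"), JunctionEnd("b", 201, "R"))
    frag = im.ClipFragment("r", "a", 100, "right", "A" * 30)
    cands = [Candidate(j, f"r{i}", frag) for i in range(3)] + [Candidate(near, "r9", frag)]
    calls = call_junctions(cands, min_support=3, position_tolerance=2)
    assert len(calls) == 1
    assert calls[0].support == 4  # near candidate absorbed into the modal cluster
    assert calls[0].junction == j
    assert call_junctions(cands[:2], min_support=3) == []


def test_call_junctions_support_counts_distinct_reads():
    j = Junction(JunctionEnd("a", 100, "L"), JunctionEnd("b", 200, "R"))
    frag = im.ClipFragment("r", "a", 100, "right", "A" * 30)
    cands = [Candidate(j, "same_read", frag) for _ in range(5)]
    assert call_junctions(cands, min_support=3) == []


def test_call_junctions_drops_close_same_orientation_self_pairs():
    j = Junction(JunctionEnd("a", 100, "L"), JunctionEnd("a", 140, "R"))
    frag = im.ClipFragment("r", "a", 100, "right", "A" * 30)
    cands = [Candidate(j, f"r{i}", frag) for i in range(5)]
    assert call_junctions(cands, min_support=3, min_self_distance=150) == []
    # inverted self-junctions are real (fold-backs) and must survive
    inv = Junction(JunctionEnd("a", 100, "L"), JunctionEnd("a", 100, "L"))
    cands = [Candidate(inv, f"r{i}", frag) for i in range(5)]
    assert len(call_junctions(cands, min_support=3, min_self_distance=150)) == 1


def test_canonicalization_collapses_microhomology_shifts():
    # x[..5]+y[1..] and x[..4]+y[0..] spell the same fused sequence because
    # y[0] == x[5] (a 1-base micro-homology)
    seqs = {"x": "AAAACGTTTT", "y": "GTCCCCCCCC"}
    a = Junction.canonical(JunctionEnd("x", 5, "L"), JunctionEnd("y", 1, "R"))
    shifted = Junction.canonical(JunctionEnd("x", 4, "L"), JunctionEnd("y", 0, "R"))
    ca = canonicalize_junction(a, seqs)
    cb = canonicalize_junction(shifted, seqs)
    assert ca == cb


def test_default_scenario_junctions_exact(default_run):
    sc = default_run["scenario"]
    metrics = match_junctions(default_run["calls"], sc.truth.junctions, tolerance=0)
    assert metrics["precision"] == 1.0
    assert metrics["recall"] == 1.0
    # includes the host-host fusion and the inverted-cassette fold-back
    orientations = {c.orientation for c in default_run["calls"]}
    assert "inverted" in orientations
    host_host = [
        c
        for c in default_run["calls"]
        if {c.junction.a.ref_id, c.junction.b.ref_id} == {"chr_1", "chr_2"}
    ]
    assert host_host, "host-host fusion junction must be called"


def test_match_junctions_counting():
    j1 = Junction(JunctionEnd("a", 10, "L"), JunctionEnd("b", 5, "R"))
    j2 = Junction(JunctionEnd("a", 99, "L"), JunctionEnd("b", 7, "R"))
    calls = [im.JunctionCall(j1, 5), im.JunctionCall(j2, 4)]
    m = match_junctions(calls, [j1], tolerance=0)
    assert (m["tp"], m["fp"], m["fn"]) == (1, 1, 0)
    assert m["precision"] == 0.5 and m["recall"] == 1.0
    assert match_junctions([], [j1])["recall"] == 0.0
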