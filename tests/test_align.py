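import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import insertmap as im
from insertmap.align import ReferenceIndex, local_align
from insertmap.pipeline import align_all
from insertmap.samio import read_sam, write_sam


def test_build_index_counts_and_lookup():
    ref = im.SequenceRecord("r", "ACGTACGT", role="host", copies=1)
    idx = ReferenceIndex([ref], k=4)
    assert idx.n_kmers() == 5  # L - k + 1
    # duplicated 4-mer ACGT occurs at 0 and 4
    code = int(np.dot(im.align.encode("ACGT").astype(np.int64), idx._pow))
    hits = idx.lookup(code)
    assert sorted(idx.locate(int(g))[1] for g in hits) == [0, 4]
    absent = int(np.dot(im.align.encode("TTTT").astype(np.int64), idx._pow))
    assert len(idx.lookup(absent)) == 0


def test_build_index_validation():
    with pytest.raises(ValueError):
        ReferenceIndex([], k=21)
    with pytest.raises(ValueError):
        ReferenceIndex([im.SequenceRecord("r", "ACGT" * 10)], k=2)


def test_align_exact_read_and_reverse_complement(toy_references, toy_index):
    h1 = toy_references.get("h1").sequence
    alns = im.align_read(h1[500:650], toy_index)
    assert len(alns) == 1
    a = alns[0]
    assert (a.ref_id, a.pos, a.strand, a.cigar_string, a.nm) == ("h1", 500, "+", "150M", 0)
    alns = im.align_read(im.revcomp(h1[700:850]), toy_index)
    assert (alns[0].ref_id, alns[0].pos, alns[0].strand) == ("h1", 700, "-")


def test_align_junction_read_soft_clips(toy_references, toy_index):
    h1 = toy_references.get("h1").sequence
    c = toy_references.get("construct").sequence
    read = h1[1000:1060] + c[0:90]  # 60 bp host prefix, 90 bp construct suffix
    alns = im.align_read(read, toy_index)
    by_ref = {a.ref_id: a for a in alns} if len(alns) > 1 else {alns[0].ref_id: alns[0]}
    best = alns[0]
    assert best.cigar_string in ("60S90M", "60M90S")
    if best.ref_id == "construct":
        assert (best.pos, best.cigar_string) == (0, "60S90M")
    else:
        assert (best.pos, best.cigar_string) == (1000, "60M90S")
    # clip length complements the matched prefix
    assert best.left_clip + best.right_clip == 150 - sum(
        n for op, n in best.cigar if op == "M"
    )


def test_align_shared_cassette_is_ambiguous(toy_references, toy_index):
    c = toy_references.get("construct").sequence
    read = c[1600:1750]  # inside the cassette shared with h1
    alns = im.align_read(read, toy_index)
    assert len(alns) >= 2
    assert all(a.ambiguous for a in alns)
    assert {a.ref_id for a in alns} == {"h1", "construct"}


def test_align_short_read_warns_and_unmapped(toy_index):
    with pytest.warns(UserWarning):
        assert im.align_read("ACGT", toy_index) == []


def test_align_pure_n_mate_keeps_pair(toy_references, toy_index):
    h1 = toy_references.get("h1").sequence
    pair = im.align_pair(h1[100:250], "N" * 150, toy_index)
    assert pair.r1 and not pair.r2
    assert not pair.proper


def test_align_pair_proper_flag(toy_references, toy_index):
    h1 = toy_references.get("h1").sequence
    r1 = h1[600:750]
    r2 = im.revcomp(h1[950:1100])  # insert 500
    pair = im.align_pair(r1, r2, toy_index, insert_min=100, insert_max=800)
    assert pair.proper
    # mates on different references are never proper
    c = toy_references.get("construct").sequence
    pair2 = im.align_pair(h1[600:750], im.revcomp(c[100:250]), toy_index)
    assert not pair2.proper


def test_recovery_of_error_free_reads_at_truth_positions():
    g = im.simulate_host_genome(1, [100_000], seed=21)
    reads, truth = im.simulate_reads(g, coverage=20, error_rate=0.0, seed=21, with_truth=True)
    idx = ReferenceIndex(g.records, k=21)
    by_id = truth.set_index("read_id")
    ok = total = 0
    for rid, r1, r2 in reads:
        row = by_id.loc[rid]
        expected = {int(row.frag_start), int(row.frag_end) - 150}
        for seq in (r1, r2):
            alns = im.align_read(seq, idx)
            total += 1
            if alns and alns[0].cigar_string == "150M" and alns[0].pos in expected:
                ok += 1
    assert ok / total >= 0.999


def test_cigar_bookkeeping_on_sam_roundtrip(tmp_path, toy_references, toy_index):
    h1 = toy_references.get("h1").sequence
    c = toy_references.get("construct").sequence
    pairs = [
        im.align_pair(h1[100:250], im.revcomp(h1[450:600]), toy_index, read_id="a"),
        im.align_pair(h1[1000:1060] + c[0:90], im.revcomp(c[300:450]), toy_index, read_id="b"),
        im.align_pair(c[1600:1750], "N" * 150, toy_index, read_id="c"),
    ]
    path = tmp_path / "out.sam"
    write_sam(pairs, toy_references.records, path)
    back = read_sam(path)
    assert [p.read_id for p in back] == ["a", "b", "c"]
    for orig, rec in zip(pairs, back):
        for o, r in zip([orig.primary1, orig.primary2], [rec.primary1, rec.primary2]):
            if o is None:
                assert r is None
                continue
            assert (r.ref_id, r.pos, r.strand, r.cigar_string, r.seq) == (
                o.ref_id,
                o.pos,
                o.strand,
                o.cigar_string,
                o.seq,
            )
            # M/I/S lengths must sum to the read length (asserted on build)
            assert sum(n for op, n in r.cigar if op in "MIS") == len(r.seq)
    # ambiguity restored from secondary records
    assert back[2].primary1.ambiguous


# ---------------------------------------------------------------------------
# Smith-Waterman
# ---------------------------------------------------------------------------


from oracles import nw_global as _nw_global, sw_bruteforce as _sw_bruteforce


def test_local_align_examples():
    score, qi, ti, cigar = local_align("ACGTACGT", "ACGTACGT", 1, -1, -2)
    assert (score, qi, ti, cigar) == (8, (0, 8), (0, 8), [("M", 8)])
    score, *_ = local_align("ACGTACGT", "ACGAACGT", 1, -1, -2)
    assert score == 6
    assert local_align("", "ACGT", 1, -1, -2)[0] == 0
    with pytest.raises(ValueError):
        local_align("A", "A", 0, -1, -2)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    st.text(alphabet="ACGT", min_size=0, max_size=12),
    st.text(alphabet="ACGT", min_size=0, max_size=12),
)
def test_local_align_matches_bruteforce_oracle(q, t):
    score, (qs, qe), (ts, te), cigar = local_align(q, t, 2, -3, -4)
    assert score == _sw_bruteforce(q, t, 2, -3, -4)
    # reported intervals must rescore to the reported value
    if score > 0:
        qq, tt = q[qs:qe], t[ts:te]
        assert _nw_global(qq, tt, 2, -3, -4) >= score
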