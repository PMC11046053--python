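import numpy as np
import pytest

import insertmap as im
from insertmap.junctions import Junction, JunctionEnd
from insertmap.synth import ScenarioConfig, Segment, _random_sequence


def test_host_genome_lengths_and_determinism():
    g1 = im.simulate_host_genome(2, [100_000, 50_000], seed=7)
    g2 = im.simulate_host_genome(2, [100_000, 50_000], seed=7)
    assert [len(r) for r in g1] == [100_000, 50_000]
    assert all(a.sequence == b.sequence for a, b in zip(g1, g2))
    assert all(r.copies == 2 for r in g1)


def test_host_genome_gc_near_half():
    s = im.simulate_host_genome(1, [100_000], seed=11).records[0].sequence
    gc = (s.count("G") + s.count("C")) / len(s)
    # binomial: p=0.5, n=1e5 -> 0.5 +- ~0.005 at 3 sigma
    assert abs(gc - 0.5) < 0.01


def test_host_genome_input_errors():
    with pytest.raises(ValueError):
        im.simulate_host_genome(1, [0], seed=1)
    with pytest.raises(ValueError):
        im.simulate_host_genome(2, [100], seed=1)


def test_apply_integration_full_construct_arithmetic():
    host = im.simulate_host_genome(1, [10_000], seed=3)
    construct = im.SequenceRecord("construct", _random_sequence(np.random.default_rng(4), 2_000), role="construct", copies=1)
    plan = im.IntegrationPlan(host_id="chr_1", position=4_000, segments=[Segment("construct", 0, 2_000, "+")])
    integrant, truth = im.apply_integration(host, construct, plan)
    mod = integrant.records[0]
    assert len(mod) == 12_000
    assert mod.sequence == host.records[0].sequence[:4_000] + construct.sequence + host.records[0].sequence[4_000:]
    ends = {(j.a.ref_id, j.a.pos, j.a.side, j.b.ref_id, j.b.pos, j.b.side) for j in truth.junctions}
    # host|construct at P-1|0 and construct|host at C-1|P (up to homology canonicalization)
    assert len(truth.junctions) == 2
    for j in truth.junctions:
        refs = {j.a.ref_id, j.b.ref_id}
        assert refs == {"chr_1", "construct"}
        assert j.orientation == "same"


def test_apply_integration_reverse_complement_segment_verbatim():
    host = im.simulate_host_genome(1, [5_000], seed=5)
    construct = im.SequenceRecord("construct", _random_sequence(np.random.default_rng(6), 1_000), role="construct", copies=1)
    plan = im.IntegrationPlan(
        host_id="chr_1", position=2_000, segments=[Segment("construct", 200, 700, "-")]
    )
    integrant, _ = im.apply_integration(host, construct, plan)
    assert im.revcomp(construct.sequence[200:700]) in integrant.records[0].sequence


def test_apply_integration_out_of_bounds_segment():
    host = im.simulate_host_genome(1, [5_000], seed=5)
    construct = im.SequenceRecord("construct", "ACGT" * 100, role="construct", copies=1)
    plan = im.IntegrationPlan(
        host_id="chr_1", position=100, segments=[Segment("construct", 0, 4_000, "+")]
    )
    with pytest.raises(ValueError):
        im.apply_integration(host, construct, plan)


def _flank(seqs, end):
    """20 bp of fused sequence approaching a junction end from its retained side."""
    s = seqs[end.ref_id]
    if end.side == "L":
        return s[end.pos - 19 : end.pos + 1]
    return im.revcomp(s[end.pos : end.pos + 20])


def test_truth_junctions_rederivable_from_output_sequence():
    """Oracle: each truth junction's two 20 bp flanks, glued, must occur
    verbatim in the engineered genome (one strand or the other)."""
    sc = im.default_scenario(9)
    seqs = {r.id: r.sequence for r in sc.host}
    seqs["construct"] = sc.construct.sequence
    genome_seqs = [r.sequence for r in sc.integrant]
    for j in sc.truth.junctions:
        a, b = _flank(seqs, j.a), _flank(seqs, j.b)
        # one end enters the junction, the other leaves: try both gluings
        probes = {a + im.revcomp(b), b + im.revcomp(a), im.revcomp(a) + b, im.revcomp(b) + a}
        found = any(
            p in g or im.revcomp(p) in g for p in probes for g in genome_seqs
        )
        assert found, f"junction {j} not present in the engineered genome"


def test_default_scenario_truth_counts():
    sc = im.default_scenario(1)
    assert sc.truth.cassette_copies["HC"] == 1
    assert sc.truth.cassette_copies["LC"] == 4
    assert sc.truth.cassette_copies["GS"] == 3  # vector copy + diploid host homolog
    assert sc.truth.amplified_fold == 4.0
    assert len(sc.truth.junctions) == 7


def test_simulate_reads_pair_count_formula():
    g = im.simulate_host_genome(2, [100_000, 50_000], seed=2)
    reads = im.simulate_reads(g, coverage=30, read_len=150, error_rate=0.0, seed=2)
    assert len(reads) == 15_000


def test_simulate_reads_error_free_reads_are_genome_substrings():
    g = im.simulate_host_genome(1, [20_000], seed=8)
    s = g.records[0].sequence
    reads = im.simulate_reads(g, coverage=3, error_rate=0.0, seed=8)
    for _, r1, r2 in reads[:200]:
        assert r1 in s or im.revcomp(r1) in s
        assert r2 in s or im.revcomp(r2) in s


def test_simulate_reads_insert_size_clt():
    g = im.simulate_host_genome(1, [30_000], seed=9)
    _, truth = im.simulate_reads(
        g, coverage=100, insert_mean=500, insert_sd=50, error_rate=0.0, seed=9, with_truth=True
    )
    inserts = (truth.frag_end - truth.frag_start).values
    assert len(inserts) == 10_000
    assert abs(inserts.mean() - 500) < 3 * 50 / np.sqrt(len(inserts))


def test_simulate_reads_respects_feature_copy_overrides():
    g = im.simulate_host_genome(1, [50_000], seed=10)
    g = im.GenomeSet(g.records, [im.Feature("chr_1", 10_000, 20_000, "one-copy", 1)])
    _, truth = im.simulate_reads(g, coverage=40, error_rate=0.0, seed=10, with_truth=True)
    starts = truth.frag_start.values
    inside = ((starts >= 10_000) & (starts < 20_000)).sum()
    outside = len(starts) - inside
    # one-copy region should collect ~half the per-bp start density
    ratio = (inside / 10_000) / (outside / 40_000)
    assert 0.4 < ratio < 0.62


def test_simulate_reads_reproducible_and_validated():
    g = im.simulate_host_genome(1, [10_000], seed=1)
    a = im.simulate_reads(g, coverage=5, seed=3)
    b = im.simulate_reads(g, coverage=5, seed=3)
    assert a == b
    with pytest.raises(ValueError):
        im.simulate_reads(g, coverage=0, seed=1)
    with pytest.raises(ValueError):
        im.simulate_reads(g, coverage=5, read_len=600, insert_mean=500, seed=1)


def test_simulate_culture_roundtrip_and_degenerate_cases():
    s = im.simulate_culture(growth_rate=0.9, capacity=1.2e7, qp_true=20, days=8, seed=0)
    assert im.specific_productivity(s, 0, 8) == pytest.approx(20, abs=1e-6)
    flat = im.simulate_culture(growth_rate=0.0, capacity=1e7, qp_true=5, days=4, seed=0)
    assert np.allclose(flat.vcd, flat.vcd[0])
    zero = im.simulate_culture(growth_rate=0.7, capacity=1e7, qp_true=0, days=4, seed=0)
    assert np.all(zero.titer == 0)


def test_simulate_qpcr_delta_ct():
    t4 = im.simulate_qpcr(8, 2, replicates=3, noise_sd=0.0, seed=1)
    dct = t4.mean_ct("sample", "target") - t4.mean_ct("control", "target")
    assert dct == pytest.approx(-2.0)  # log2(4) cycles earlier
    t1 = im.simulate_qpcr(5, 5, replicates=2, noise_sd=0.0, seed=1)
    assert t1.mean_ct("sample", "target") == pytest.approx(t1.mean_ct("control", "target"))
    assert t1.mean_ct("sample", "reference") == pytest.approx(t1.mean_ct("control", "reference"))


def test_simulate_qpcr_replicate_noise_scale():
    sds = []
    for seed in range(40):
        t = im.simulate_qpcr(4, 2, replicates=3, noise_sd=0.1, seed=seed)
        sub = t.frame[(t.frame["sample"] == "sample") & (t.frame["gene"] == "target")]
        sds.append(sub["ct"].std(ddof=1))
    assert np.mean(sds) == pytest.approx(0.1, rel=0.35)


def test_hemizygous_genome_structure():
    ref, source = im.simulate_hemizygous_genome([30_000], [(0, 10_000, 12_000)], seed=4)
    assert ref.total_length == 30_000
    assert source.total_length == 30_000 + 28_000
    full, deleted = source.records
    assert ref.records[0].sequence == full.sequence
    assert deleted.sequence == full.sequence[:10_000] + full.sequence[12_000:]


def test_scenario_config_yaml_roundtrip(tmp_path):
    cfg = ScenarioConfig()
    path = tmp_path / "scenario.yaml"
    cfg.to_yaml(path)
    assert ScenarioConfig.from_yaml(path) == cfg


def test_build_scenario_deterministic():
    a = im.default_scenario(5)
    b = im.default_scenario(5)
    assert a.integrant.records[0].sequence == b.integrant.records[0].sequence
    assert a.truth.junctions == b.truth.junctions
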