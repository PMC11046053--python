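import numpy as np
import pytest

import insertmap as im
from insertmap.pipeline import DEFAULT_CONFIG, discover


@pytest.fixture(scope="session")
def default_run():
    """One full discovery run on the default engineered-genome scenario,
    shared across test modules (the chain is deterministic for a seed)."""
    sc = im.default_scenario(3)
    reads = im.simulate_reads(sc.integrant, coverage=30, error_rate=0.0, seed=3)
    counts, noms, calls, profiles, aligned = discover(sc.reference, reads, dict(DEFAULT_CONFIG))
    return {
        "scenario": sc,
        "reads": reads,
        "counts": counts,
        "nominations": noms,
        "calls": calls,
        "profiles": profiles,
        "aligned": aligned,
    }


@pytest.fixture(scope="session")
def toy_references():
    """Small handmade reference set: two host contigs and a construct that
    shares a 500 bp cassette with the first host contig (the homologous
    trap)."""
    rng = np.random.default_rng(1234)
    bases = np.frombuffer(b"ACGT", dtype="S1")

    def seq(n):
        return bases[rng.integers(0, 4, n)].tobytes().decode()

    host1 = seq(3000)
    host2 = seq(2000)
    construct = seq(2000)
    # plant the shared cassette: host1[2000:2500] == construct[1500:2000]
    host1 = host1[:2000] + construct[1500:2000] + host1[2500:]
    records = [
        im.SequenceRecord("h1", host1, role="host", copies=2),
        im.SequenceRecord("h2", host2, role="host", copies=2),
        im.SequenceRecord("construct", construct, role="construct", copies=1),
    ]
    return im.GenomeSet(records)


@pytest.fixture(scope="session")
def toy_index(toy_references):
    return im.ReferenceIndex(toy_references.records, k=21)
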