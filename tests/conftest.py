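import numpy as np
import pytest

from venomtx import readmerge, simulate


@pytest.fixture(scope="session")
def tiny_sim():
    """Tiny simulated transcriptome + reads, shared across tests."""
    cfg = simulate.benchmark_scenario("tiny")
    records, annotations, truth = simulate.simulate_transcriptome(cfg)
    reads1, reads2, read_truth = simulate.simulate_reads(
        records, truth.weights, cfg, truth.alleles)
    return {"config": cfg, "records": records, "annotations": annotations,
            "truth": truth, "reads1": reads1, "reads2": reads2,
            "read_truth": read_truth}


@pytest.fixture(scope="session")
def tiny_merged(tiny_sim):
    merged = []
    for r1, r2 in zip(tiny_sim["reads1"], tiny_sim["reads2"]):
        m = readmerge.merge_pair(r1, r2)
        if m is not None:
            merged.append((m.id, m.sequence))
    return merged


@pytest.fixture()
def rng():
    return np.random.default_rng(20130802)
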