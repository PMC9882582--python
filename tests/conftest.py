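import numpy as np
import pytest

import quantalign as qa


@pytest.fixture(scope="session")
def model6():
    return qa.synthetic_qmer_model(Q=6, seed=1)


@pytest.fixture(scope="session")
def qcfg3(model6):
    return qa.compute_thresholds(model6, 3)


@pytest.fixture(scope="session")
def model2():
    return qa.synthetic_qmer_model(Q=2, seed=5)


@pytest.fixture(scope="session")
def qcfg2(model2):
    return qa.compute_thresholds(model2, 3)


@pytest.fixture(scope="session")
def genome50k():
    return qa.simulate_genome(qa.SimConfig(genome_length=50_000, seed=3))


@pytest.fixture(scope="session")
def hybrid50k(genome50k, model6, qcfg3):
    return qa.HybridAligner(genome50k, model6, qcfg3)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))
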