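import numpy as np
import pytest

from phagewatch.model import GenomeRecord, PipelineConfig
from phagewatch.synthetic import (
    build_cassette,
    implant_prophage,
    make_host_genome,
    random_dna,
)


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def implant_fixture():
    """Host A+phage+B with reference A+B and exact implant truth."""
    host = make_host_genome(120_000, 0.63, seed=7, genome_id="synth_host")
    reference = GenomeRecord("reference", host.sequence)
    cassette = build_cassette(seed=7, phage_id="phageA")
    infected, truth = implant_prophage(host, cassette, position=60_000,
                                       att_len=15, seed=7)
    return {"host": infected, "reference": reference, "cassette": cassette,
            "truth": truth}


def make_random_seq(n, seed, gc=0.5):
    return random_dna(n, np.random.default_rng(seed), gc)
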