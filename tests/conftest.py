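import numpy as np
import pandas as pd
import pytest

from tndiva.formats_io import GeneModel, InsertionProfile, SampleSheet
from tndiva.simulator import SimConfig, simulate_experiment


@pytest.fixture
def five_genes():
    """Five genes on two replicons, mixed strands and COG annotations."""
    return [
        GeneModel("g1", "chr1", 101, 200, "+", frozenset("I"), "lipase"),
        GeneModel("g2", "chr1", 301, 600, "-", frozenset("IQ"), "synthase"),
        GeneModel("g3", "chr1", 550, 800, "+", frozenset(), "hypothetical protein"),
        GeneModel("g4", "plasmid", 1, 1000, "+", frozenset("R"), "regulator"),
        GeneModel("g5", "plasmid", 2000, 2199, "-", frozenset("S"), "unknown"),
    ]


@pytest.fixture
def two_condition_sheet():
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["A1", "A2", "A3", "B1", "B2", "B3"],
                "condition": ["ref"] * 3 + ["trt"] * 3,
                "mapped_fraction": [0.95] * 6,
                "include": [True] * 6,
            }
        )
    )


def random_profile(rng, sample_id, replicons=("chr1", "plasmid"), n_sites=200,
                   span=3000, max_count=50):
    counts = {}
    for rep in replicons:
        pos = rng.choice(span, size=n_sites // len(replicons), replace=False) + 1
        for p in pos:
            counts[(rep, int(p))] = float(rng.integers(1, max_count))
    return InsertionProfile(sample_id=sample_id, counts=counts)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_sim():
    """A small but realistic simulated experiment shared across tests."""
    config = SimConfig(
        seed=11,
        n_genes=80,
        reads_per_replicate=40_000,
        n_depleted=8,
    )
    return simulate_experiment(config)
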