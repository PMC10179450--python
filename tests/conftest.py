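from __future__ import annotations

import numpy as np
import pytest

import mitorecomb as mr


@pytest.fixture(scope="session")
def tiny_sim():
    """A small error-free study system shared by structural tests.

    20 kb circle with 1000/800 bp direct repeats, exact reads from all
    four isomers.
    """
    cfg = mr.SimulationConfig(
        genome_length=20_000,
        repeat_lengths=(1000, 800),
        read_mean_length=5_000,
        read_length_sd=1_000,
        n_reads=150,
        error_rate=0.0,
        isomer_weights=(0.4, 0.2, 0.2, 0.2),
        truth_flank=200,
        seed=7,
    )
    genome, repeats, graph, isomers, reads = mr.simulate(cfg)
    return cfg, genome, repeats, graph, isomers, reads


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))
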