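"""Shared fixtures: small simulated populations reused across test modules."""

import pytest

from polytill import genomes


@pytest.fixture(scope="session")
def tiny_population():
    """Six homoeologous families, three M5 lines, fixed seed."""
    cfg = genomes.SimConfig(identity=0.97, ems_rate_per_mb=300.0, generation=4)
    sets, lines = genomes.simulate_population(6, 3, rng_seed=7, config=cfg)
    return sets, lines


@pytest.fixture(scope="session")
def one_gene():
    """A single simulated plus-strand gene with its contig sequence."""
    models, contigs = genomes.simulate_gene_model(
        1, rng_seed=11, config=genomes.SimConfig(strands="+"))
    m = models[0]
    return m, contigs[m.contig_id]
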