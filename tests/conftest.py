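import numpy as np
import pytest

from rfmnet import (
    ExperimentConfig,
    generate_codon_table,
    generate_genome,
    generate_reporter,
    make_desk_genome,
    normalize_decoding_times,
    rates_from_orf,
)


@pytest.fixture(scope="session")
def toy_table():
    return generate_codon_table(seed=11, spread=0.5)


@pytest.fixture(scope="session")
def uniform_table():
    return generate_codon_table(seed=0, spread=0.0)


@pytest.fixture(scope="session")
def small_world():
    """A 20-gene desk-scale cell: genome, normalized table, chain specs."""
    cfg = ExperimentConfig(n_genes=20, seed=3, length_range=(25, 400))
    genome, table = make_desk_genome(cfg)
    specs = [rates_from_orf(g, table) for g in genome]
    return cfg, genome, table, specs


@pytest.fixture(scope="session")
def reporter():
    return generate_reporter(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
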