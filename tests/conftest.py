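import numpy as np
import pandas as pd
import pytest

from te_storm.simulate import (
    SimulationConfig,
    generate_counts,
    generate_te_reference,
    generate_transcripts,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        n_loci=120, n_subjects_conv=6, n_controls=8, de_fraction=0.1,
        seed=101,
    )


@pytest.fixture(scope="session")
def small_reference(small_cfg):
    return generate_te_reference(small_cfg)


@pytest.fixture(scope="session")
def small_transcripts(small_cfg, small_reference):
    loci, seqs = small_reference
    return generate_transcripts(loci, seqs, small_cfg)


@pytest.fixture(scope="session")
def small_dataset(small_cfg, small_reference):
    loci, _ = small_reference
    em, truth = generate_counts(loci, small_cfg)
    return em, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def nb_matrix(rng):
    """A 200 x 4 NB count matrix with mild library-size differences."""
    depths = np.array([1.0, 1.4, 0.8, 1.1])
    base = rng.gamma(2.0, 50.0, size=200)
    counts = np.column_stack([
        rng.negative_binomial(10, 10 / (10 + base * d)) for d in depths
    ])
    return pd.DataFrame(counts, columns=["s1", "s2", "s3", "s4"],
                        index=[f"L{i:03d}" for i in range(200)])
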