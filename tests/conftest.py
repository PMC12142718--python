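import numpy as np
import pytest

from finlife import SimulationConfig, simulate_study, train_bagged

STUDY_SEED = 11


@pytest.fixture(scope="session")
def trained_study():
    """The standard synthetic study, trained once and shared.

    Conditions: 200 species x 100 promoters, 20 causal, planted population
    R^2 = 0.7, 5% sequence divergence, fixed seed.
    """
    config = SimulationConfig(seed=STUDY_SEED)
    study = simulate_study(config)
    table = study.feature_table()
    model, report = train_bagged(table, seed=STUDY_SEED)
    return study, table, model, report


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def write_fasta(path, entries):
    """entries: iterable of (header, sequence)."""
    with open(path, "w") as fh:
        for header, seq in entries:
            fh.write(f">{header}\n{seq}\n")
    return path
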