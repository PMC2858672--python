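import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from l1asp import SimulationConfig, simulate_dataset, synthetic_promoter_locus
from l1asp.methylation_analysis import qc_clones

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def locus():
    """The default synthetic bidirectional L1 promoter locus."""
    return synthetic_promoter_locus()


@pytest.fixture(scope="session")
def clean_dataset(locus):
    """A noise-free dataset: enzyme efficiency 1, conversion rate 1."""
    cfg = SimulationConfig(
        n_molecules=120, enzyme_efficiency=1.0, conversion_rate=1.0, seed=42
    )
    return simulate_dataset(locus, cfg)


@pytest.fixture(scope="session")
def noisy_dataset(locus):
    """A dataset at the default wet-lab noise levels (0.85 / 0.99)."""
    cfg = SimulationConfig(n_molecules=300, seed=7)
    return simulate_dataset(locus, cfg)


@pytest.fixture(scope="session")
def noisy_matrix(locus, noisy_dataset):
    matrix, _report = qc_clones(
        list(zip(noisy_dataset.clone_ids, noisy_dataset.reads)), locus
    )
    return matrix


@pytest.fixture(scope="session")
def clean_matrix(locus, clean_dataset):
    matrix, _report = qc_clones(
        list(zip(clean_dataset.clone_ids, clean_dataset.reads)), locus
    )
    return matrix
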