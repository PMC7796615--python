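import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plastidflow.synthetic_data import SimConfig, simulate_species

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_sim():
    """One small fully simulated species with injected edits (shared, read-only)."""
    cfg = SimConfig(
        n_genes=8, n_operons=3, n_read_pairs=5000, seed=2, base_error_rate=0.001
    )
    return simulate_species(cfg, n_edit_sites=6, min_edit_coverage=100)


@pytest.fixture(scope="session")
def clean_sim():
    """A small error-free species without edits (exact-truth comparisons)."""
    cfg = SimConfig(
        n_genes=6, n_operons=2, n_read_pairs=2000, seed=11, base_error_rate=0.0
    )
    return simulate_species(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
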