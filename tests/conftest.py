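import pytest
from hypothesis import HealthCheck, settings

import chromcycle as cc

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic world (2 scaffolds x 1 Mb, 1000 genes, seed 1)."""
    return cc.generate_dataset(seed=1)


@pytest.fixture(scope="session")
def default_pairs(default_dataset):
    return cc.classify_adjacent_pairs(default_dataset.annotation)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small world for file-based round trips (1 x 120 kb, 50 genes)."""
    cfg = cc.SyntheticConfig(n_scaffolds=1, scaffold_length=120_000, n_genes=50)
    return cc.generate_dataset(cfg, seed=9)
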