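import pytest

from kat3id import SimConfig, generate_truth
from kat3id.pipeline import inputs_from_world, run_analysis


def small_config(**overrides) -> SimConfig:
    """A reduced world for tests that rerun the pipeline many times."""
    base = dict(
        n_genes=60,
        chrom_length=2_000_000,
        n_elements_per_class=60,
        n_se_genes=4,
        n_lowexpr_cluster_genes=3,
        seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def world(default_config):
    return generate_truth(default_config)


@pytest.fixture(scope="session")
def analysis(world, default_config):
    """Full default-scale analysis, shared across tests (read-only)."""
    inputs = inputs_from_world(world, default_config)
    return run_analysis(inputs)
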