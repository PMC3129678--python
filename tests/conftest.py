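import numpy as np
import pytest

from snpsieve.pipeline import PipelineConfig, run_pipeline
from snpsieve.simulate import (
    SimulationConfig,
    generate_reference,
    simulate_mutant_line,
)

#: one fixed seed used for every session-scoped simulation fixture
SESSION_SEED = 11


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def genome(default_config):
    return generate_reference(default_config)


@pytest.fixture(scope="session")
def truth(genome, default_config):
    return simulate_mutant_line(genome, default_config)


@pytest.fixture(scope="session")
def small_config():
    """A 3 x 100 kb genome for tests that run the simulator repeatedly."""
    return SimulationConfig(seed=SESSION_SEED, chrom_lengths=(100_000,) * 3,
                            causal_chrom_index=2)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default-configuration pipeline run shared across tests."""
    outdir = tmp_path_factory.mktemp("pipeline")
    report = run_pipeline(PipelineConfig(), seed=SESSION_SEED, outdir=outdir)
    return report, outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(SESSION_SEED)
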