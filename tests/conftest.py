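import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from dimorphseq.pipeline import PipelineConfig, run_simulate
from dimorphseq.synthetic import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def bundle(sim_config):
    """In-memory default synthetic bundle (seed 1), shared across tests."""
    return simulate_bundle(sim_config)


@pytest.fixture(scope="session")
def fixture_dir(sim_config, tmp_path_factory) -> Path:
    """The same bundle written to disk as a fixture directory."""
    out = tmp_path_factory.mktemp("fixture")
    run_simulate(sim_config, out)
    return out


@pytest.fixture()
def pipeline_config(fixture_dir, tmp_path) -> PipelineConfig:
    return PipelineConfig.from_fixture_dir(fixture_dir, tmp_path / "results")
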