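import numpy as np
import pytest

from retrofunc.pipeline import RunConfig, run_pipeline
from retrofunc.synth import (
    GroundTruth,
    SimConfig,
    generate_genome_and_catalog,
    write_fixtures,
)


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def sim_world(sim_config):
    """(genome, annotation, catalog, truth) for the default config."""
    return generate_genome_and_catalog(sim_config)


@pytest.fixture(scope="session")
def fixture_dir(sim_config, tmp_path_factory):
    return write_fixtures(sim_config, tmp_path_factory.mktemp("fixtures"))


@pytest.fixture(scope="session")
def ground_truth(fixture_dir) -> GroundTruth:
    return GroundTruth.from_tsv(fixture_dir / "ground_truth.tsv")


@pytest.fixture(scope="session")
def pipeline_result(fixture_dir, tmp_path_factory):
    config = RunConfig(
        input_dir=str(fixture_dir),
        output_dir=str(tmp_path_factory.mktemp("pipeline_out")),
    )
    return run_pipeline(config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
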