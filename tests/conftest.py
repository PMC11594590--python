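import numpy as np
import pytest

from pestrisk import (
    EcoclimaticIndexEngine,
    default_global_scenario,
    generate_climate_grid,
    sweetgum_parameters,
)
from pestrisk.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def coarse_spec():
    """The bundled globe at 4-degree resolution: fast but fully featured."""
    return default_global_scenario(resolution_arcmin=240.0, seed=7)


@pytest.fixture(scope="session")
def coarse_grid(coarse_spec):
    return generate_climate_grid(coarse_spec)


@pytest.fixture(scope="session")
def coarse_ei(coarse_grid):
    return EcoclimaticIndexEngine(sweetgum_parameters()).run_grid(coarse_grid)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full pipeline run on the coarse globe, shared across tests."""
    out = tmp_path_factory.mktemp("demo_run")
    config = PipelineConfig(
        output_dir=str(out), seed=11, resolution_arcmin=240.0,
        n_occurrences=100, n_pseudo_absences=80, n_estimators=200,
    )
    manifest = run_pipeline(config)
    return config, manifest
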