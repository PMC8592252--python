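from pathlib import Path

import numpy as np
import pytest

from sirnakit.pipeline import run_pipeline
from sirnakit.simulate import SimulationConfig, read_truth_tsv, simulate_experiment
from sirnakit.utils import LIBRARIES


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        library_depth=20_000, n_up=10, n_down=10, n_flat=10, seed=11,
        qpcr_ct_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim_small")
    paths = simulate_experiment(small_config, outdir)
    return paths


@pytest.fixture(scope="session")
def small_truth(small_experiment):
    return read_truth_tsv(small_experiment["truth"])


@pytest.fixture(scope="session")
def small_pipeline(small_config, small_experiment, tmp_path_factory):
    fastqs = {lib: small_experiment[f"fastq_{lib}"] for lib in LIBRARIES}
    outdir = tmp_path_factory.mktemp("pipe_small")
    return run_pipeline(
        Path(small_experiment["genome"]),
        Path(small_experiment["annotation"]),
        fastqs,
        small_config.adapter,
        outdir=outdir,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
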