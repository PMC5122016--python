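import numpy as np
import pandas as pd
import pytest

from scamp.synthetic_data import (
    SimulationConfig,
    generate_experiment,
    simulate_detection_dataset,
)
from scamp import detection_model as dm


@pytest.fixture(scope="session")
def small_experiment(tmp_path_factory):
    """A small but complete synthetic dilution experiment on disk."""
    outdir = tmp_path_factory.mktemp("exp")
    config = SimulationConfig(n_genes=1200, n_replicates=10, depth=300_000, seed=42)
    data = generate_experiment(config, outdir)
    data["config"] = config
    data["outdir"] = outdir
    return data


@pytest.fixture(scope="session")
def logistic_fit():
    """A detection-model fit on data drawn directly from the logistic
    surface with known coefficients."""
    config = SimulationConfig(
        n_genes=2000, n_replicates=12, depth=5_000_000, seed=7
    )
    obs, truth = simulate_detection_dataset(config)
    obs, bounds = dm.trim_covariates(obs)
    fit = dm.fit_detection_glm(obs, split_seed=1)
    return fit, obs, np.asarray(truth["capture_beta"])
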