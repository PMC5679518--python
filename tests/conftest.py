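"""Shared fixtures: the desk-scale training set is built once per session."""

import numpy as np
import pytest

from lakemwat.cli_io import PipelineConfig, fit_surrogate, training_table


@pytest.fixture(scope="session")
def desk_config():
    """The shipped desk-scale configuration (3 x 3 x 27 design, 10 years)."""
    return PipelineConfig()


@pytest.fixture(scope="session")
def desk_training(desk_config):
    """(table, X, y, feature_names) of the desk-scale training experiment."""
    return training_table(desk_config)


@pytest.fixture(scope="session")
def desk_gp(desk_config, desk_training):
    """Sum-kernel (SE + RQ) surrogate fitted to the desk-scale set."""
    _, X, y, _ = desk_training
    gp, _ = fit_surrogate(X, y, desk_config)
    return gp


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
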