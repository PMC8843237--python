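"""Shared fixtures: one trained six-action model reused across the suite.

Heavy computations (training, sweeps, the riff demo) are session-scoped and
lazy, so unit-test runs stay fast while the acceptance tests share work.
"""

import numpy as np
import pytest

from acdc import (ModelParams, fixture_sequence, run_learning_experiment,
                  run_rescale_experiment, sweep_overlap)

SEED = 1


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def sim1_spec():
    return fixture_sequence("sim1")


@pytest.fixture(scope="session")
def trained_sim1(sim1_spec, params):
    result, record = run_learning_experiment(sim1_spec, params, seed=SEED)
    return result, record


@pytest.fixture(scope="session")
def rescale_results(trained_sim1):
    trained, _ = trained_sim1
    return run_rescale_experiment(trained)


@pytest.fixture(scope="session")
def overlap_scan(params):
    return sweep_overlap(params=params, seed=SEED)
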