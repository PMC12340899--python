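import numpy as np
import pytest

from repflow.cfr import CFRHyperparams, inputs_from_cohort
from repflow.flows import FlowHyperparams, RepFlowCFR
from repflow.synthdata import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Unconfounded cohort with heterogeneous effect, small enough for
    per-test training."""
    cfg = SynthConfig(n_encounters=600, n_features=8, gamma_treat=0.0,
                      gamma_outcome=0.0, tau_scale=0.8, seed=7)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def small_inputs(small_cohort):
    cohort, _ = small_cohort
    return inputs_from_cohort(cohort)


@pytest.fixture(scope="session")
def fast_hp():
    return (CFRHyperparams(seed=0, max_epochs=40, patience=8),
            FlowHyperparams(seed=0, max_epochs=40, patience=8))


@pytest.fixture(scope="session")
def trained_model(small_inputs, fast_hp):
    """A fully fitted three-stage model shared across tests."""
    hp_cfr, hp_flow = fast_hp
    return RepFlowCFR(hp_cfr, hp_flow).fit(small_inputs)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
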