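import warnings

import numpy as np
import pytest

import fluxmaint as fm

# cobra warns on every infeasible optimize(); the grid search triggers
# that routinely and on purpose
warnings.filterwarnings("ignore", message="Solver status is 'infeasible'")


@pytest.fixture(scope="session")
def toy_model():
    return fm.build_toy_model()


@pytest.fixture(scope="session")
def noiseless_dataset(toy_model):
    truth = fm.SyntheticTruth(true_matp=6.0, noise_cv=0.0, seed=1)
    exchange, c13, table = fm.simulate_c13_dataset(toy_model, truth, "ds_clean")
    return truth, exchange, c13, table


@pytest.fixture(scope="session")
def noiseless_chemostat(toy_model):
    truth = fm.SyntheticTruth(true_matp=6.0, noise_cv=0.0, seed=3)
    dilution_rates = list(np.linspace(0.016, 0.035, 6))
    records = fm.simulate_chemostat(toy_model, truth, dilution_rates)
    return truth, records


@pytest.fixture()
def model(toy_model):
    """A fresh mutable copy of the toy model."""
    return toy_model.copy()
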