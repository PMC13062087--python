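import numpy as np
import pandas as pd
import pytest

from respsense.synth import DesignSpec, ObserverModel, gen_design, simulate_session


@pytest.fixture(scope="session")
def full_design():
    """The standard 6-run, 30-per-condition-per-run schedule (720 trials)."""
    return gen_design(DesignSpec(seed=11))


@pytest.fixture(scope="session")
def quest_session(full_design):
    """A stationary (unmodulated) observer run through the full staircase."""
    rng = np.random.default_rng(21)
    phases = rng.uniform(-np.pi, np.pi, len(full_design))
    observer = ObserverModel(mod_amplitude=0.0)
    trials, truth = simulate_session(full_design, phases, observer, seed=22)
    return trials, observer


@pytest.fixture(scope="session")
def modulated_session(full_design):
    """Observer with phase-modulated threshold (sensitivity peak -pi/3)."""
    rng = np.random.default_rng(31)
    phases = rng.uniform(-np.pi, np.pi, len(full_design))
    observer = ObserverModel()  # defaults: A=0.1, phi0=-pi/3
    trials, truth = simulate_session(full_design, phases, observer, seed=32)
    return trials, observer


@pytest.fixture()
def small_trials():
    rng = np.random.default_rng(5)
    n = 40
    return pd.DataFrame({
        "run": np.repeat([0, 1], n // 2),
        "trial": np.arange(n),
        "contrast": rng.uniform(0.2, 0.8, n),
        "hit": rng.integers(0, 2, n),
        "phase_rad": rng.uniform(-np.pi, np.pi, n),
    })
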