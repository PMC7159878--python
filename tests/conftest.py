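import numpy as np
import pytest

from stopcascade import synth


@pytest.fixture(scope="session")
def default_config():
    return synth.SimConfig(n_trials=2000, seed=42)


@pytest.fixture(scope="session")
def session_data(default_config):
    """One simulated session shared across read-only tests."""
    trials, truth = synth.simulate_task(default_config)
    return trials, truth


@pytest.fixture(scope="session")
def stop_emg(default_config, session_data):
    """Rendered EMG for the successful-stop trials of the shared session."""
    trials, truth = session_data
    succ = trials[(trials["type"] == "stop")
                  & trials["outcome"].str.startswith("SuccStop")]
    return synth.synthesize_emg(trials, truth, default_config,
                                subset=succ["trial"].to_numpy())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
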