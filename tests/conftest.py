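import numpy as np
import pytest

from viscmap import SimConfig, default_protocol
from viscmap.pipeline import process_experiment
from viscmap.synth import generate_experiment


@pytest.fixture(scope="session")
def default_experiment():
    """The default synthetic study: 2,000 neurons, default SNR, seed 0,
    graded multi-organ stimulus series — processed through the full
    dF/F -> detrend -> response-calling path."""
    config = SimConfig(n_neurons=2000, seed=0)
    protocol = default_protocol()
    neurons, truth, fluor = generate_experiment(config, protocol)
    dff, table = process_experiment(fluor, protocol, seed=0)
    return {
        "config": config,
        "protocol": protocol,
        "neurons": neurons,
        "truth": truth,
        "fluor": fluor,
        "dff": dff,
        "table": table,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
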