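import numpy as np
import pytest

from prestim.simulate import CohortConfig, simulate_eeg_epochs

#: Posterior subset: enough spatial structure for the occipital analyses
#: at a fraction of the 64-channel cost.
POSTERIOR_CHANNELS = ["P3", "Pz", "P4", "PO3", "POz", "PO4", "O1", "Oz", "O2"]


@pytest.fixture(scope="session")
def posterior_config():
    return CohortConfig(channel_labels=list(POSTERIOR_CHANNELS))


@pytest.fixture(scope="session")
def small_epochs(posterior_config):
    """30 clean NE trials on the posterior channel subset."""
    epochs, _ = simulate_eeg_epochs(
        posterior_config, "ne", np.random.default_rng(2024), n_trials=30
    )
    return epochs


@pytest.fixture(scope="session")
def theta_epochs(posterior_config):
    """40 theta-entrained trials on the posterior channel subset."""
    epochs, _ = simulate_eeg_epochs(
        posterior_config, "theta", np.random.default_rng(77), n_trials=40
    )
    return epochs
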