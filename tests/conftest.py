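import numpy as np
import pytest

from seegbench import (EpochSet, SimConfig, apply_scheme, baseline_zscore,
                       extract_features, preprocess_subject, simulate_subject)


@pytest.fixture(scope="session")
def sim_subject():
    """One small but complete simulated subject (60 trials, 12 contacts)."""
    cfg = SimConfig(n_shafts=2, contacts_per_shaft=6, seed=42)
    recording, events, truth = simulate_subject(cfg)
    return cfg, recording, events, truth


@pytest.fixture(scope="session")
def preprocessed(sim_subject):
    _, recording, events, _ = sim_subject
    epochs, events2, bad_ids = preprocess_subject(recording, events)
    return epochs, events2, bad_ids


@pytest.fixture(scope="session")
def lap_features(preprocessed):
    """Normalized band-power features under the Laplacian reference."""
    epochs, _, _ = preprocessed
    ep = apply_scheme(epochs, "laplacian")
    return ep, baseline_zscore(extract_features(ep))


@pytest.fixture(scope="session")
def white_epochs():
    """White-noise epochs (no structure at all) for null checks."""
    rng = np.random.default_rng(7)
    fs = 500.0
    data = rng.standard_normal((30, 3, int(8 * fs)))
    from seegbench.io_montage import ChannelInfo

    montage = [ChannelInfo(f"S0C{i+1}", "S0", i + 1) for i in range(3)]
    labels = np.array((["a", "b", "c"] * 10))
    return EpochSet(data=data, fs=fs, montage=montage, labels=labels)
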