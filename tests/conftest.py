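import numpy as np
import pytest
from hypothesis import settings

import frostgrip as fg

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_config():
    return fg.SimulationConfig(n_per_class=6, seed=3)


@pytest.fixture(scope="session")
def small_dataset(sim_config):
    """A dozen simulated trials shared across the fast tests."""
    trials, manifest = fg.generate_dataset(sim_config)
    return trials, manifest


@pytest.fixture(scope="session")
def pre_config():
    return fg.PreprocessConfig()


@pytest.fixture(scope="session")
def small_inputs(small_dataset, pre_config):
    trials, _ = small_dataset
    return fg.build_model_inputs(trials, pre_config)


@pytest.fixture(scope="session")
def noiseless_trial():
    """One deterministic, noise-free grasp for closed-form checks."""
    cfg = fg.SimulationConfig(n_per_class=1, seed=5, pressure_sd_counts=0.0,
                              vibration_sd_counts=0.0)
    rng = np.random.default_rng(5)
    profile = fg.sample_fruit_profile(cfg, fg.NORMAL, rng)
    profile.micro_event_rate_hz = 0.0
    trial = fg.simulate_trial(profile, cfg, rng)
    return trial, cfg


def make_toy_inputs(n_per_class=20, seed=0, T=50):
    """Two perfectly separable constant-signal classes.

    The class signal is a spatial/temporal *pattern* (not a uniform
    offset, which layer normalization would remove): the two classes
    load opposite halves of the pressure grid and carry opposite-sign
    vibration half-sequences.
    """
    rng = np.random.default_rng(seed)
    inputs = []
    for c, label in enumerate([fg.NORMAL, fg.FROST]):
        pattern = np.full(36, 0.2)
        pattern[:18 if c == 0 else None] = 0.8
        if c == 1:
            pattern[:18] = 0.2
        vib = np.where(np.arange(T) < T // 2, 2.0, -2.0) * (1 if c == 0 else -1)
        for i in range(n_per_class):
            p = np.tile(pattern, (T, 1)) + rng.normal(0, 0.01, (T, 36))
            v = vib[:, None] + rng.normal(0, 0.1, (T, 1))
            onehot = np.array([1.0, 0.0]) if label == fg.NORMAL \
                else np.array([0.0, 1.0])
            inputs.append(fg.ModelInput(trial_id=f"toy_{label}_{i}",
                                        pressure_seq=np.clip(p, 0, 1),
                                        vibration_seq=v,
                                        label_onehot=onehot))
    return inputs
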