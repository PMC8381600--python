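"""Shared fixtures: tiny configs and small seeded cohorts.

Everything is generated programmatically; nothing is read from disk.
"""

import numpy as np
import pytest

from p3msda.network import ModelConfig
from p3msda.synthetic import (SubjectProfile, SynthConfig,
                              default_components, simulate_subject)
from p3msda.trainer import TrainConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_model_config():
    """Smallest valid architecture: 4 channels, 20 samples at 20 Hz
    (kernels 11 and 5), dropout off for deterministic forward passes."""
    return ModelConfig(F1=2, F2=3, p_dropout=0.0, ch=4, T=20, fs=20.0)


@pytest.fixture
def tiny_train_config():
    return TrainConfig(K=8, epochs=3, seed=0)


def make_subject(subject_id="s0", p3_gain=3.0, noise_sd=5.0, channels=4,
                 n_trials=60, trial_len=20, fs=20.0, seed=0,
                 imbalance_ratio=4.0, **profile_kwargs):
    """One small simulated subject with sensible test-scale defaults."""
    cfg = SynthConfig(n_subjects_per_group=1, channels=channels, fs=fs,
                      trial_len=trial_len, n_trials=n_trials,
                      imbalance_ratio=imbalance_ratio, seed=seed)
    comps = [c for c in default_components(channels)
             if c.latency_mean < trial_len / fs * 1000.0]
    # rescale component timing into the short trial window
    scale = (trial_len / fs) / 1.0
    for c in comps:
        c.latency_mean *= scale
        c.latency_jitter_sd *= scale
        c.width *= scale
    profile = SubjectProfile(subject_id=subject_id, group="strong",
                             p3_gain=p3_gain, noise_sd=noise_sd,
                             **profile_kwargs)
    return simulate_subject(profile, cfg, np.random.default_rng(seed), comps)


@pytest.fixture
def small_subject():
    return make_subject()
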