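"""Shared fixtures: one noiseless phantom realization per session."""

from __future__ import annotations

import pytest

from qmuscle.phantom import PhantomConfig, default_config, realize_phantom


@pytest.fixture(scope="session")
def clean_config() -> PhantomConfig:
    return default_config(seed=11, noise_sigma=0.0)


@pytest.fixture(scope="session")
def clean_truth(clean_config):
    return realize_phantom(clean_config)
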