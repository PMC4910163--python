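"""Shared fixtures: small synthetic datasets and a cheaply trained model."""

import pytest

from lipidsites import synth, training


@pytest.fixture(scope="session")
def myr_data():
    """A small, strongly planted myristoylation dataset."""
    spec = synth.SynthSpec(mod_type="MYR", n_positive=30, signal_strength=0.9, seed=2)
    return synth.generate(spec)


@pytest.fixture(scope="session")
def myr_model(myr_data):
    """A model trained with a reduced optimizer budget (fast, deterministic)."""
    proteins, sites = myr_data
    cfg = training.TrainConfig(seed=3, pso_iterations=30)
    return training.train(proteins, sites, "MYR", cfg)


@pytest.fixture(scope="session")
def myr_training_set(myr_data):
    proteins, sites = myr_data
    return training.build_training_set(proteins, sites, "MYR")
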