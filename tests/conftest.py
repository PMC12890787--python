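"""Shared fixtures; the expensive trained-model fixture is session-scoped."""

import warnings

import numpy as np
import pytest

from bsbt.phantom import BundleSpec, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def single_tube_phantom():
    """Noiseless 64-cube phantom with one bilateral thalamus-medulla tube."""
    tube = BundleSpec(
        "MLc", ("medulla", "thalamus"), 0.38, 0.45, 0.33, 0.05, 0.75, 0.65
    )
    return generate_phantom(
        PhantomSpec(bundles=(tube,), noise_sigma=0.0, rng_seed=2)
    )


@pytest.fixture(scope="session")
def default_phantom():
    """Standard eight-bundle 64-cube phantom with default noise."""
    return generate_phantom(PhantomSpec(rng_seed=11))


@pytest.fixture(scope="session")
def trained_models():
    """Tiny full-input and zero-PFM models trained on a fresh 32-cube suite.

    Session-scoped because training dominates the suite's runtime; the
    same weights back the end-to-end accuracy, ablation-direction and
    test-retest checks.
    """
    from bsbt.workflows import train_tiny_models

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train_tiny_models(seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
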