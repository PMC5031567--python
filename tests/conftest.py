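"""Shared fixtures: the default study phantom and cached pipeline runs."""

import numpy as np
import pytest

import marrowdose as md


@pytest.fixture(scope="session")
def spec():
    return md.default_spec(seed=1)


@pytest.fixture(scope="session")
def study_noise_free(spec):
    """(images, truth) for the default phantom without counting noise."""
    return md.generate_study(spec, noise=False)


@pytest.fixture(scope="session")
def result_noise_free(spec):
    """Full-chain run on the noise-free default phantom."""
    return md.run_phantom_study(spec, noise=False)


@pytest.fixture(scope="session")
def result_noisy(spec):
    """Full-chain run on the Poisson-noised default phantom."""
    return md.run_phantom_study(spec, noise=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * float((a & b).sum()) / float(a.sum() + b.sum())


@pytest.fixture()
def dice_fn():
    return dice
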