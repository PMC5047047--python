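"""Shared fixtures: one default phantom, its preprocessing, one resolution.

Session scope keeps the expensive objects (60 x 208 cube, MCR model) shared
across test modules without any cross-test mutation (all consumers treat
them as read-only).
"""

import numpy as np
import pytest

from discspect.mcr import resolve
from discspect.phantom import PhantomConfig, generate_phantom
from discspect.spectra import WavenumberAxis, compute_mask, second_derivative


@pytest.fixture(scope="session")
def phantom_default():
    """Default-condition phantom (mild degeneration) with ground truth."""
    config = PhantomConfig(seed=11)
    image, truth, covariates = generate_phantom(config)
    return config, image, truth, covariates


@pytest.fixture(scope="session")
def preprocessed(phantom_default):
    _, image, _, _ = phantom_default
    deriv = second_derivative(image)
    mask = compute_mask(deriv)
    return deriv, mask


@pytest.fixture(scope="session")
def model5(preprocessed):
    deriv, mask = preprocessed
    return resolve(deriv, mask, 5)


@pytest.fixture(scope="session")
def clean_phantom():
    """Distortion-free phantom: cube is exactly C* S*^T."""
    config = PhantomConfig(noise_sigma=0.0, baseline_order=-1, seed=11)
    image, truth, covariates = generate_phantom(config)
    return config, image, truth, covariates


@pytest.fixture
def small_axis():
    return WavenumberAxis.regular(900.0, 1800.0, 2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
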