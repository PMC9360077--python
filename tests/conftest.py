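import numpy as np
import pytest

import nanopbpk as npk


@pytest.fixture(scope="session")
def phys():
    return npk.default_physiology()


@pytest.fixture(scope="session")
def fixed():
    return npk.default_fixed_kinetics()


@pytest.fixture(scope="session")
def designs():
    return npk.builtin_designs()


@pytest.fixture(scope="session")
def theta_paca_low():
    return npk.published_median_theta("paca_low")


@pytest.fixture(scope="session")
def bounds_paca():
    return npk.published_bounds("PACA-Cbz")


@pytest.fixture(scope="session")
def noisefree_paca(phys, fixed, designs, theta_paca_low):
    """Noise-free synthetic PACA low-dose dataset (values = model predictions)."""
    return npk.generate_synthetic(
        theta_paca_low, designs["paca_low"], phys, fixed, noise_sigma=0.0, seed=0
    )


@pytest.fixture(scope="session")
def noisy_paca(phys, fixed, designs, theta_paca_low):
    """Synthetic PACA low-dose dataset with sigma=0.2 multiplicative noise."""
    return npk.generate_synthetic(
        theta_paca_low, designs["paca_low"], phys, fixed, noise_sigma=0.2, seed=7
    )


def make_samples(draws: np.ndarray, param_names=None) -> npk.PosteriorSamples:
    """Wrap a draw matrix as PosteriorSamples for summary-level tests."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 1:
        draws = draws[:, None]
    names = param_names or tuple(f"p{i}" for i in range(draws.shape[1]))
    return npk.PosteriorSamples(
        draws=draws,
        log_posteriors=np.zeros(draws.shape[0]),
        acceptance_rate=0.25,
        settings=npk.SamplerSettings(n_iterations=draws.shape[0], seed=0),
        param_names=tuple(names),
    )
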