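"""Shared fixtures: reproducible random decay problems on resolvable grids."""

import numpy as np
import pytest

from multiexp import DecompositionModel, SampledSignal


def draw_separated_model(rng, n_components, k_lo=0.5, k_hi=80.0,
                         separation=4.0, min_weight_frac=0.05):
    """Random positive-component model with pairwise decrement ratio >= separation
    and every weight at least ``min_weight_frac`` of the total."""
    while True:
        ks = np.sort(np.exp(rng.uniform(np.log(k_lo), np.log(k_hi), n_components)))
        if n_components == 1 or np.all(ks[1:] / ks[:-1] >= separation):
            break
    while True:
        w = rng.uniform(0.1, 1.0, n_components)
        w /= w.sum()
        if np.min(w) >= min_weight_frac:
            break
    return DecompositionModel(w, ks)


def make_signal(model, times, noise_sd=0.0, rng=None):
    x = model.predict(times)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, times.size)
    return SampledSignal(times, x)


@pytest.fixture
def grid_401():
    """Time grid resolving decrements roughly in [0.02, 160] 1/s."""
    return np.linspace(0.0, 5.0, 401)


@pytest.fixture
def grid_1001():
    return np.linspace(0.0, 5.0, 1001)
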