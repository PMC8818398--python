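"""Shared fixtures: random histograms, small images, phantom configs."""

from __future__ import annotations

import numpy as np
import pytest

from metathresh import Histogram, HistogramSpec, sample_histogram


def random_gmm_histogram(seed: int, levels: int = 16, n_samples: int = 512) -> Histogram:
    """Random 2-3 mode Gaussian-mixture histogram at small L, per-seed deterministic."""
    rng = np.random.default_rng(seed)
    n_modes = int(rng.integers(2, 4))
    centers = rng.uniform(0, levels - 1, n_modes)
    weights = rng.dirichlet(np.ones(n_modes))
    spreads = rng.uniform(0.5, 3.0, n_modes)
    modes = tuple(
        (float(c), float(w), float(s)) for c, w, s in zip(centers, weights, spreads)
    )
    return sample_histogram(
        HistogramSpec(modes=modes, levels=levels, n_samples=n_samples, seed=seed)
    )


@pytest.fixture
def gmm_histogram():
    """Factory fixture for random small-L mixture histograms."""
    return random_gmm_histogram


@pytest.fixture
def uniform16() -> Histogram:
    return Histogram(np.ones(16, dtype=np.int64), levels=16)


@pytest.fixture
def uniform256() -> Histogram:
    return Histogram(np.ones(256, dtype=np.int64), levels=256)
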