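"""Shared fixtures: a session-scoped cache of grown tumours so expensive
simulations are reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from spatialith import SimulationConfig, grow_tumour


@pytest.fixture(scope="session")
def tumour_cache():
    cache: dict[SimulationConfig, object] = {}

    def factory(**kwargs):
        cfg = SimulationConfig(**kwargs)
        if cfg not in cache:
            cache[cfg] = grow_tumour(cfg)
        return cache[cfg]

    return factory


@pytest.fixture(scope="session")
def tum_p1_small(tumour_cache):
    """Exponential growth, 2**10 cells, lambda=10."""
    return tumour_cache(push_rate=1.0, mutation_rate=10.0, target_size=2**10, seed=42)


@pytest.fixture(scope="session")
def tum_p0_small(tumour_cache):
    """Surface growth, 2**12 cells, lambda=0 (growth geometry only)."""
    return tumour_cache(push_rate=0.0, mutation_rate=0.0, target_size=2**12, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
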