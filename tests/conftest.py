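import numpy as np
import pytest

from lifmass import NetworkConfig, SpikeRaster


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    """Small, fast network: ~1 s of activity, 100 units."""
    return NetworkConfig(
        n_units=100,
        m_external=1000,
        p_internal=0.2,
        p_external=1.0,
        lambda_exc=0.8,
        t_total=1000.0,
        t_transient=200.0,
        seed=7,
    )


@pytest.fixture
def poisson_raster(rng):
    """100 independent 5 Hz Poisson units over 10 s."""
    n_units, t_total, rate = 100, 10_000.0, 5.0
    units, times = [], []
    for i in range(n_units):
        n = rng.poisson(rate * t_total / 1e3)
        units.extend([i] * n)
        times.extend(rng.uniform(0, t_total, n))
    return SpikeRaster(
        units=np.asarray(units),
        times=np.asarray(times),
        unit_type=np.ones(n_units, dtype=bool),
        t_total=t_total,
    )


def periodic_raster(n_units, period, t_total, offset=None):
    """Identical periodic trains on every unit."""
    offset = period / 2 if offset is None else offset
    times = np.arange(offset, t_total, period)
    return SpikeRaster(
        units=np.repeat(np.arange(n_units), times.size),
        times=np.tile(times, n_units),
        unit_type=np.ones(n_units, dtype=bool),
        t_total=t_total,
    )
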