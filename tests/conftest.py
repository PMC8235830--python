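import numpy as np
import pytest

from itscompare import SeriesParams, build_design, simulate_series


@pytest.fixture
def exact_dataset():
    """Noise-free series on the two-segment line 1 + 2t (+5 level, +1 slope)."""
    return simulate_series(SeriesParams(n_pre=3, n_post=3, beta=(1, 2, 5, 1),
                                        rho=0.0, sigma=0.0, seed=0,
                                        series_id="exact"))


@pytest.fixture
def noisy_dataset():
    return simulate_series(SeriesParams(n_pre=15, n_post=15,
                                        beta=(10, 0.5, 2, 0.1),
                                        rho=0.4, sigma=1.0, seed=7,
                                        series_id="noisy"))


@pytest.fixture
def noisy_design(noisy_dataset):
    return build_design(noisy_dataset)


def random_instance(rng, n_min=8, n_max=12):
    """A small random dataset + design for brute-force oracle checks."""
    n = int(rng.integers(n_min, n_max + 1))
    n_pre = int(rng.integers(3, n - 2))
    ds = simulate_series(SeriesParams(
        n_pre=n_pre, n_post=n - n_pre,
        beta=tuple(rng.normal(0, 2, size=4)),
        rho=float(rng.uniform(-0.7, 0.7)),
        sigma=float(rng.uniform(0.3, 2.0)),
        seed=int(rng.integers(0, 2**31)),
    ))
    return ds, build_design(ds)
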