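import numpy as np
import pytest

from ftl_chiasma.sim import MarkerInterval, MeiosisModel, StudyDesign


@pytest.fixture
def interval():
    return MarkerInterval("TEST1", 1, 1_000_000, 5_710_000)  # 4.71 Mb


@pytest.fixture
def long_interval():
    return MarkerInterval("TEST2", 1, 10_000_000, 20_500_000)  # 10.5 Mb


@pytest.fixture
def no_interference_model():
    return MeiosisModel(lambda_m=0.25, lambda_f=0.25)


@pytest.fixture
def small_design():
    return StudyDesign(ages=(40, 45, 50, 55), n_replicates=3, seeds_per_cell=300)


def stationary_renewal_counts_oracle(mean_count: float, nu: int, n: int, seed: int) -> np.ndarray:
    """Independent Monte-Carlo oracle for the stationary gamma-renewal count.

    Simulates the process directly from its definition: inter-event gaps are
    Gamma(nu, mean 1) on the scale where the interval has genetic length
    ``mean_count``; the first gap follows the equilibrium (stationary excess)
    distribution, which for integer shape is an equal mixture of
    Gamma(j, same rate) for j = 1..nu.  Construction is deliberately
    different from the package's Poisson-skip implementation.
    """
    rng = np.random.default_rng(seed)
    counts = np.zeros(n, dtype=int)
    scale = 1.0 / nu  # gap mean 1 in crossover units
    j = rng.integers(1, nu + 1, size=n)
    t = rng.gamma(j, scale)
    active = t <= mean_count
    while active.any():
        counts[active] += 1
        t[active] += rng.gamma(nu, scale, size=int(active.sum()))
        active = t <= mean_count
    return counts
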