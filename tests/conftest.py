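import numpy as np
import pytest

from paleomort import (
    FitOptions,
    GompertzMakehamParams,
    Individual,
)
from paleomort.synthetic import sample_ages


@pytest.fixture
def gm_reference():
    """The GM parameter set used in the worked hand calculations."""
    return GompertzMakehamParams(a1=0.01, a2=0.005, beta=0.1)


@pytest.fixture
def fast_options():
    return FitOptions(n_starts=3)


def simulate_individuals(baseline, rho, n, seed, sex_ratio=0.5, period="all"):
    """Direct GM-PH draws as Individual records (no assemblage overhead)."""
    rng = np.random.default_rng(seed)
    x = (rng.uniform(size=n) < sex_ratio).astype(float)
    ages, _ = sample_ages(baseline, x, rho, rng)
    return [
        Individual(id=str(i), t=a - 15.0, x=int(xi), period=period)
        for i, (a, xi) in enumerate(zip(ages, x))
    ]


@pytest.fixture
def simulate():
    return simulate_individuals
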