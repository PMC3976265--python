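import numpy as np
import pytest

from spskit import GeneratorSpec, generate_series


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def noiseless_step_problem():
    """A constant-trend/line-shape problem: level shift from 15 down to 10."""
    return generate_series(
        GeneratorSpec(
            n=1000, bias_fraction=0.25, trend="constant", shape="line",
            steady_mean=10.0, bias_amplitude=5.0, noise_low=0.0, noise_high=0.0,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def random_series_batch():
    """100 seeded random series (lengths <= 200) for oracle-equivalence checks."""
    gen = np.random.default_rng(991)
    out = []
    for _ in range(100):
        n = int(gen.integers(20, 201))
        kind = gen.integers(0, 3)
        if kind == 0:
            x = gen.normal(10, 1, n)
        elif kind == 1:  # biased head
            L = int(gen.integers(1, n // 2 + 1))
            x = np.concatenate([gen.normal(15, 1, L), gen.normal(10, 1, n - L)])
        else:  # ramp into noise
            x = 10 + np.linspace(5, 0, n) + gen.normal(0, 0.5, n)
        out.append(x)
    return out
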