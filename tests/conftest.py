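import numpy as np
import pytest


def make_three_segment(seed: int, n: int = 1000, left: int = 100, right: int = 100):
    """Synthetic S-curve with known geometry: steep exponential left tail,
    exactly linear middle, steep exponential right tail.

    Returns (values, first_middle_rank, last_middle_rank) with 1-based ranks;
    the values are non-decreasing by construction.
    """
    rng = np.random.default_rng(seed)
    mid = n - left - right
    slope = rng.uniform(0.005, 0.02)
    base = rng.uniform(20, 60)
    v_mid = base + slope * np.arange(mid)
    alpha = rng.uniform(0.05, 0.12)
    c = rng.uniform(0.5, 2.0)
    lt = v_mid[0] - c * (np.exp(alpha * np.arange(left, 0, -1)) - 1)
    rt = v_mid[-1] + c * (np.exp(alpha * np.arange(1, right + 1)) - 1)
    values = np.concatenate([lt, v_mid, rt])
    assert np.all(np.diff(values) >= 0)
    return values, left + 1, left + mid


@pytest.fixture
def three_segment():
    return make_three_segment


@pytest.fixture
def mixture_sample():
    """One default-mixture draw shared across tests."""
    from enorms.synthetic import default_spec, generate

    return generate(default_spec(n=5000, seed=20240416))
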