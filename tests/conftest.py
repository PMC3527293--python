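import numpy as np
import pytest


def oracle_g_factor(signal, times, period=24.0):
    """Independent O(n^2) direct-summation DFT g-factor for cross-checking.

    Returns (g, complex coefficient at the target frequency).
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    dt = times[1] - times[0]
    k_target = int(round(n * dt / period))
    xc = x - x.mean()
    powers = []
    coef_target = None
    for k in range(1, n // 2 + 1):
        c = sum(xc[j] * np.exp(-2j * np.pi * k * j / n) for j in range(n))
        powers.append(abs(c) ** 2)
        if k == k_target:
            coef_target = c
    total = sum(powers)
    g = powers[k_target - 1] / total if total > 0 else 0.0
    return g, coef_target


@pytest.fixture
def oracle_g():
    return oracle_g_factor


@pytest.fixture
def ct_grid_48h():
    """The two-day sampling design: 12 points, 4-h spacing, starting CT14."""
    return 14.0 + 4.0 * np.arange(12)


def cosine_profile(times, baseline=5.0, amplitude=1.5, phase=6.0, period=24.0):
    return baseline + amplitude * np.cos(2 * np.pi * (np.asarray(times) - phase) / period)
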