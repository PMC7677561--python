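import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20201106)


def brute_force_window_counts(times, duration, window, stride):
    """O(n*m) reference tally of half-open windows [t, t+w)."""
    counts = []
    t = 0.0
    while t + window <= duration + 1e-9:
        counts.append(sum(1 for x in times if t <= x < t + window))
        t += stride
    return counts


def brute_force_ks_d(a, b):
    """sup |ECDF_a - ECDF_b| by sweeping every sample point."""
    d = 0.0
    for x in list(a) + list(b):
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        d = max(d, abs(fa - fb))
    return d
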