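import numpy as np
import pytest

from striamark.scan_io import HeightMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_mark(rng):
    """A small noisy striated mark: identical rows plus mild noise."""
    profile = np.cumsum(rng.standard_normal(200))
    z = np.tile(profile, (20, 1)) + 0.05 * rng.standard_normal((20, 200))
    return HeightMap(z, dx=3.0, dy=3.0, kind="cast", label="small")


def brute_force_best_lag(v1, v2, max_lag, min_overlap=3):
    """Independent double-loop oracle for the exhaustive lag search.

    Pure-python sums over the overlap region; ties resolved by visiting
    candidate lags ordered by (|lag|, lag) and keeping strict improvements.
    """
    import math

    p = len(v1)
    best = None
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), l)):
        num = s1sq = s2sq = 0.0
        count = 0
        for i in range(p):
            j = i + lag
            if 0 <= j < p and math.isfinite(v1[i]) and math.isfinite(v2[j]):
                num += v1[i] * v2[j]
                s1sq += v1[i] ** 2
                s2sq += v2[j] ** 2
                count += 1
        if count < min_overlap:
            continue
        den = math.sqrt(s1sq * s2sq)
        if den == 0.0:
            continue
        c = num / den
        if best is None or c > best[0]:
            best = (c, lag)
    return best
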