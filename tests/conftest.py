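"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


def brute_force_otsu(gray: np.ndarray) -> tuple[int, np.ndarray]:
    """Exhaustive-scan Otsu oracle: for every threshold t in [0, 255] compute
    the within-class sum of squared deviations of {pixel < t} and
    {pixel >= t} directly from the pixel masks; return the lowest minimizing
    threshold and the per-threshold criterion array."""
    g = np.asarray(gray).ravel().astype(np.float64)
    ss = np.empty(256)
    for t in range(256):
        lo = g[g < t]
        hi = g[g >= t]
        s = 0.0
        if lo.size:
            s += float(((lo - lo.mean()) ** 2).sum())
        if hi.size:
            s += float(((hi - hi.mean()) ** 2).sum())
        ss[t] = s
    best = int(np.argmin(ss))
    return best, ss


@pytest.fixture
def otsu_oracle():
    return brute_force_otsu


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
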