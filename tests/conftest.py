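import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_semicont(rng, n, p, K=2, zero_prob=0.3, shift=0.0, ensure_filtered=True):
    """Random small semicontinuous dataset; optionally resample until the
    pairwise-support filter would keep every column (so closed forms apply
    directly)."""
    from scmanova import SemicontDataset

    while True:
        Z = rng.standard_normal((n, p)) + shift * (np.arange(n) >= n // 2)[:, None]
        present = rng.random((n, p)) >= zero_prob
        X = np.exp(Z) * present
        groups = np.repeat(np.arange(K), [n // K] * (K - 1) + [n - (n // K) * (K - 1)])
        co = present.T.astype(int) @ present.astype(int)
        if not ensure_filtered or (co > 0).all():
            return SemicontDataset(X, groups)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
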