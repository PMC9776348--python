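import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_ssm(rng):
    """A valid random 40x40 cosine SSM (Gram matrix of unit-norm columns)."""
    from ssmseg.features import WindowingConfig
    from ssmseg.ssm import SelfSimilarityMatrix

    X = rng.normal(size=(12, 40))
    X /= np.linalg.norm(X, axis=0, keepdims=True)
    values = X.T @ X
    values = 0.5 * (values + values.T)
    np.clip(values, -1.0, 1.0, out=values)
    config = WindowingConfig(8, 0.5)
    starts = np.arange(40) * config.hop
    return SelfSimilarityMatrix(values, starts, config, fs=100.0)
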