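import numpy as np
import pytest

from ldpool import LDMatrix, PValueSet


def exchangeable(k: int, rho: float) -> LDMatrix:
    return LDMatrix(rho * np.ones((k, k)) + (1.0 - rho) * np.eye(k))


@pytest.fixture
def pset5() -> PValueSet:
    return PValueSet("demo", [0.1, 0.2, 0.3, 0.4, 0.5])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


def random_correlation(k: int, rng: np.random.Generator, n_factors: int = None) -> LDMatrix:
    """A random full-rank correlation matrix from a Gaussian factor model."""
    A = rng.standard_normal((k, max(k, n_factors or k)))
    S = A @ A.T + 1e-3 * np.eye(k)
    d = np.sqrt(np.diag(S))
    return LDMatrix(S / np.outer(d, d))
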