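import numpy as np
import pytest

import homeodyn as hd


@pytest.fixture(scope="session")
def wt_matrix() -> hd.GainMatrix:
    return hd.generate_wt_matrix(hd.SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def als_matrix() -> hd.GainMatrix:
    return hd.generate_als_matrix(hd.SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_stable_matrix(rng: np.random.Generator, n: int, margin: float = 0.05) -> np.ndarray:
    """Random matrix with spectral abscissa shifted to -margin."""
    A = rng.normal(0, 0.1, (n, n))
    shift = np.max(np.linalg.eigvals(A).real) + margin
    return A - shift * np.eye(n)
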