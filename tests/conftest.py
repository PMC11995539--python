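import numpy as np
import pandas as pd
import pytest

from coda24.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A modest two-stratum synthetic cohort shared across tests."""
    return generate_cohort(GeneratorConfig(n_urban=400, n_rural=250, seed=7))


def random_compositions(rng: np.random.Generator, n: int, d: int = 4,
                        kappa: float = 1440.0) -> np.ndarray:
    """Strictly positive rows closed to kappa (log-normal parts)."""
    X = np.exp(rng.normal(size=(n, d)))
    return X * (kappa / X.sum(axis=1, keepdims=True))
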