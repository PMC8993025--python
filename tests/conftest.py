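import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", message=".*ArviZ is undergoing a major refactor.*")

from grmkit.grm import ItemBank, ItemParameters, ResponseMatrix
from grmkit.simulate import BankSpec, simulate_bank, simulate_responses


@pytest.fixture
def item_2pl() -> ItemParameters:
    """Dichotomous item: lambda=1, single threshold at 0."""
    return ItemParameters("bin", 2, 1.0, (0.0,))


@pytest.fixture
def item_3cat() -> ItemParameters:
    """The worked three-category example: lambda=2, thresholds (-1, 1)."""
    return ItemParameters("tri", 3, 2.0, (-1.0, 1.0))


@pytest.fixture
def symmetric_bank() -> ItemBank:
    """Two mirrored dichotomous items: (high, low) responses score to 0."""
    return ItemBank(
        "sym",
        (
            ItemParameters("plus", 2, 1.3, (0.7,)),
            ItemParameters("minus", 2, 1.3, (-0.7,)),
        ),
    )


@pytest.fixture
def small_bank() -> ItemBank:
    return simulate_bank(BankSpec(n_items=5, n_categories=4, seed=42))


@pytest.fixture(scope="session")
def medium_study():
    """P=400, I=8, J=4 simulated responses with known truth (session cache)."""
    bank = simulate_bank(BankSpec(n_items=8, n_categories=4, seed=7))
    rng = np.random.default_rng(8)
    theta = rng.normal(size=400)
    responses = simulate_responses(bank, theta, missing_rate=0.1, seed=9)
    return bank, theta, responses


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
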