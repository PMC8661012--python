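import numpy as np
import pandas as pd
import pytest

from bidirmr.mr import HarmonizedInstruments


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_harmonized(
    rng,
    n_instruments: int = 6,
    theta: float = 0.3,
    noise: float = 0.02,
    outcome_binary: bool = False,
) -> HarmonizedInstruments:
    """Random summary-statistic fixture with a known generative slope."""
    bx = rng.uniform(0.2, 1.0, n_instruments) * rng.choice([-1, 1], n_instruments)
    sx = rng.uniform(0.01, 0.05, n_instruments)
    sy = rng.uniform(0.01, 0.08, n_instruments)
    by = theta * bx + rng.normal(0.0, noise, n_instruments)
    return HarmonizedInstruments(
        pd.DataFrame(
            {
                "snp_id": [f"s{j}" for j in range(n_instruments)],
                "beta_exposure": bx,
                "se_exposure": sx,
                "beta_outcome": by,
                "se_outcome": sy,
            }
        ),
        outcome_binary=outcome_binary,
    )


@pytest.fixture
def harmonized_factory():
    return make_harmonized
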