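import numpy as np
import pytest

from protonex import ExchangePair


def random_pairs(n: int, seed: int = 0):
    """Random exchange parameterizations spanning slow to fast exchange.

    Rates 0.1-5 s^-1, concentrations 1e2-1e5 mol/m^3, k_ex 1e-6-1e-1
    s^-1 mol^-1 m^3, so k_A/k_B range from far below to far above the
    relaxation rates.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        pairs.append(
            ExchangePair(
                R1_A=float(np.exp(rng.uniform(np.log(0.1), np.log(5)))),
                R1_B=float(np.exp(rng.uniform(np.log(0.1), np.log(5)))),
                R2_A=float(np.exp(rng.uniform(np.log(0.5), np.log(20)))),
                R2_B=float(np.exp(rng.uniform(np.log(0.5), np.log(20)))),
                k_ex=float(10 ** rng.uniform(-6, -1)),
                A_tot=float(10 ** rng.uniform(2, 5)),
                B_tot=float(10 ** rng.uniform(2, 5)),
            )
        )
    return pairs


@pytest.fixture(scope="session")
def pair_ensemble():
    return random_pairs(24, seed=20260930)
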