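import numpy as np
import pytest

import fmtpk as F


@pytest.fixture(scope="session")
def known():
    return F.KnownRates()


@pytest.fixture(scope="session")
def mix():
    """Default mixing matrix: published IDV, default rBV, blend mode."""
    return F.assemble_mixing()


@pytest.fixture(scope="session")
def scheme7():
    return F.make_scheme("7")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_params(rng, n=1, lo=0.001, hi=0.02):
    draws = [F.KineticParameters(rng.uniform(lo, hi, 8)) for _ in range(n)]
    return draws[0] if n == 1 else draws
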