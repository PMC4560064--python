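import numpy as np
import pytest

from rmnet.nro_core import model_surface


@pytest.fixture
def rng():
    return np.random.default_rng(20150904)


def make_planted_srp(rng, n_extra: int = 0, k: int = 13):
    """SRP matrix whose row 2 is the exact surface response of rows 0 and 1.

    Rows 0 and 1 span [0, 1]; the target row is the pointwise surface value,
    min-max rescaled is not applied (surface outputs already lie in [0, 1]).
    Extra random rows are appended if requested.
    """
    m = rng.uniform(0, 1, k)
    c = rng.uniform(0, 1, k)
    m = (m - m.min()) / np.ptp(m)
    c = (c - c.min()) / np.ptp(c)
    t = model_surface(m, c)
    rows = [m, c, t]
    for _ in range(n_extra):
        x = rng.uniform(0, 1, k)
        rows.append((x - x.min()) / np.ptp(x))
    return np.array(rows)


@pytest.fixture
def planted_srp(rng):
    return make_planted_srp(rng, n_extra=2)
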