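import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helpers

from ecoevo import lotka_volterra as lv
from ecoevo import public_goods as pg


@pytest.fixture
def pg_params():
    """Public goods setup of the worked example: alpha=beta=K=1, mu=0.2,
    kappa=0.1, initial (u, s) = (0.5, 0.01)."""
    return pg.PublicGoodsParams()


@pytest.fixture
def lv_params():
    """Predator-competition setup of the worked example: alpha=0.2, beta=1,
    delta=0.5, gamma=1, epsilon=0.05, initial (x, y1, y2) = (1, 1, 0.01)."""
    return lv.LVParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20220319)
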