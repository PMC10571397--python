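import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_factor_frame():
    """Balanced 2 x 3 crossed design, 5 replicates per cell (n = 30)."""
    a = np.repeat(["a1", "a2"], 15)
    b = np.tile(np.repeat(["b1", "b2", "b3"], 5), 2)
    return pd.DataFrame({"A": a, "B": b})
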