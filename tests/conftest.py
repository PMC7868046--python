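import numpy as np
import pytest
from hypothesis import settings

from patternsub import DataTable

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture
def two_pattern_table():
    """n=8, p=2: four complete rows, four rows missing x1."""
    rng = np.random.default_rng(42)
    X = rng.normal(3.0, 1.0, (8, 2))
    y = 1.0 + 3.0 * X[:, 0] + X[:, 1] + rng.normal(size=8)
    Xobs = X.copy()
    Xobs[4:, 0] = np.nan
    return DataTable(y=y, X=Xobs), X


@pytest.fixture
def three_pattern_table():
    """n=30, p=2 with patterns (0,0), (1,0) and (1,1)."""
    rng = np.random.default_rng(7)
    X = rng.normal(3.0, 1.0, (30, 2))
    y = 1.0 + 3.0 * X[:, 0] + X[:, 1] + rng.normal(size=30)
    Xobs = X.copy()
    Xobs[10:20, 0] = np.nan
    Xobs[20:30, :] = np.nan
    return DataTable(y=y, X=Xobs), X
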