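import numpy as np
import pandas as pd
import pytest

from demap import ScorePanel


def make_panel(tables, control="UT"):
    """Build a ScorePanel from {(cond, screen): 2-D array-like} with generated
    gene names."""
    first = next(iter(tables.values()))
    nq, na = np.asarray(first, dtype=float).shape
    queries = [f"Q{i+1:03d}" for i in range(nq)]
    arrays = [f"A{j+1:04d}" for j in range(na)]
    dfs = {
        key: pd.DataFrame(np.asarray(val, dtype=float), index=queries, columns=arrays)
        for key, val in tables.items()
    }
    return ScorePanel(queries, arrays, dfs, control=control)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def small_panel():
    """2 queries x 3 arrays, control + one stress, one missing stress cell."""
    return make_panel(
        {
            ("UT", "S1"): [[0.0, 1.0, -2.0], [3.0, -1.0, 0.5]],
            ("SO", "S1"): [[0.5, 4.0, -2.0], [np.nan, -1.5, 0.0]],
        }
    )
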