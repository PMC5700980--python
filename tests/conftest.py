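import numpy as np
import pandas as pd
import pytest

from chromostoch.storm import LocalizationTable


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_table(xy, bounds, channel=1, precision=15.0):
    xy = np.asarray(xy, dtype=float)
    rows = pd.DataFrame(
        {
            "x_nm": xy[:, 0],
            "y_nm": xy[:, 1],
            "frame": np.arange(len(xy)),
            "channel": channel,
            "precision_nm": precision,
        }
    )
    return LocalizationTable(rows, bounds)


def uniform_table(n, fx, fy, seed):
    r = np.random.default_rng(seed)
    return make_table(
        np.column_stack([r.uniform(0, fx, n), r.uniform(0, fy, n)]), (0.0, fx, 0.0, fy)
    )
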