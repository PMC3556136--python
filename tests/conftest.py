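import numpy as np
import pandas as pd
import pytest

from condde import Dag, ExpressionDataset


def make_dataset(columns: dict, treatment) -> ExpressionDataset:
    """Build a small ExpressionDataset from literal column vectors."""
    n = len(next(iter(columns.values())))
    idx = [f"s{i}" for i in range(n)]
    values = pd.DataFrame({k: np.asarray(v, float) for k, v in columns.items()},
                          index=idx)
    return ExpressionDataset(values, pd.Series(list(treatment), index=idx))


@pytest.fixture
def chain_dag():
    return Dag(["a", "b", "c"], [("a", "b"), ("b", "c")])


@pytest.fixture
def binary_fixture():
    """Fixed N=8 dataset: one parent, binary treatment, 4 samples/group.

    Frozen oracle values (explicit normal-equations / RSS computation):
    RSS_reduced = 2.286289752650177, RSS_full = 0.6513669064748203,
    F = 12.54993790691266 on (1, 5) df, p = 0.016517044477817804.
    """
    return make_dataset(
        {
            "parent": [0.8, -0.3, 1.2, 0.1, -1.0, 0.5, 2.0, -0.7],
            "child": [1.5, 0.2, 2.1, 0.9, -0.4, 2.6, 4.0, 0.8],
        },
        ["ctl", "ctl", "ctl", "ctl", "trt", "trt", "trt", "trt"],
    )


@pytest.fixture
def threelevel_fixture():
    """Fixed N=9 dataset with a 3-level treatment and one parent.

    Frozen oracle values: F = 14.306388810714928 on (2, 5) df,
    p = 0.008534223360956463.
    """
    return make_dataset(
        {
            "parent": [0.3, -0.2, 1.1, 0.7, -0.9, 0.4, 1.6, -0.5, 0.0],
            "child": [1.0, 0.1, 2.2, 1.9, -0.3, 1.4, 3.5, 0.2, 0.9],
        },
        ["a", "a", "a", "b", "b", "b", "c", "c", "c"],
    )
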