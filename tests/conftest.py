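import networkx as nx
import numpy as np
import pandas as pd
import pytest

from duxent import ExpressionMatrix


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples, two conditions."""
    data = pd.DataFrame(
        {
            "c1": [5.0, 3.0, 1.0],
            "c2": [5.2, 3.1, 2.0],
            "d1": [7.0, 2.9, 3.0],
            "d2": [7.1, 3.0, 2.5],
        },
        index=["gA", "gB", "gC"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def tiny_metadata():
    return pd.DataFrame(
        {
            "sample_id": ["c1", "c2", "d1", "d2"],
            "condition": ["control", "control", "DUX4", "DUX4"],
            "replicate": [1, 2, 1, 2],
        }
    )


@pytest.fixture
def triangle():
    return nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def triangle_expression():
    return pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})


def make_de_table(genes, t, p, condition="X"):
    """Hand-built DE table with the columns the signature filters read."""
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    table = pd.DataFrame(
        {"effect": t, "s2": 1.0, "df": 4.0, "t_mod": t, "p": p, "p_bh": np.minimum(1.0, p)},
        index=list(genes),
    )
    table.attrs["condition"] = condition
    return table
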