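"""Shared fixtures: tiny hand-enumerable graphs and expression tables."""

import numpy as np
import pandas as pd
import pytest

from sexnet import ExpressionMatrix, InteractionNetwork


@pytest.fixture
def toy_network() -> InteractionNetwork:
    """Five-node graph whose subnetworks are enumerable by hand:

    u1—m1, m1—f1, f1—u1, m1—m2 (a triangle u1-m1-f1 plus a pendant m2).
    """
    return InteractionNetwork(
        [("u1", "m1"), ("m1", "f1"), ("f1", "u1"), ("m1", "m2")])


@pytest.fixture
def toy_labels() -> dict:
    return {"u1": "U", "m1": "M", "m2": "M", "f1": "F"}


@pytest.fixture
def toy_bias() -> pd.Series:
    """Bias values consistent with the toy labels under t_b=2."""
    return pd.Series({"u1": 0.0, "m1": 6.0, "m2": 6.5, "f1": -6.0},
                     name="bias")


@pytest.fixture
def small_expression() -> ExpressionMatrix:
    """2 genes x 4 samples with unequal per-sample totals."""
    counts = pd.DataFrame(
        {"m1": [10, 90], "m2": [60, 240], "f1": [5, 195], "f2": [5, 195]},
        index=["g1", "g2"])
    sexes = {"m1": "male", "m2": "male", "f1": "female", "f2": "female"}
    return ExpressionMatrix(counts, sexes)


def random_expression(rng: np.random.Generator, n_genes: int, n_m: int,
                      n_f: int, max_count: int = 1000) -> ExpressionMatrix:
    """Random integer count matrix (integers keep the oracle exact)."""
    cols = [f"m{i}" for i in range(n_m)] + [f"f{i}" for i in range(n_f)]
    sexes = {c: ("male" if c.startswith("m") else "female") for c in cols}
    counts = pd.DataFrame(
        rng.integers(0, max_count, size=(n_genes, n_m + n_f)),
        index=[f"g{i}" for i in range(n_genes)], columns=cols)
    # guarantee nonzero totals per sex
    counts.iloc[0] = counts.iloc[0].clip(lower=1)
    return ExpressionMatrix(counts, sexes)
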