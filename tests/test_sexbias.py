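"""Bias statistic: worked examples, caps, classification, invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sexnet import (
    BIAS_CAP,
    ClassificationScheme,
    ExpressionMatrix,
    classify,
    classify_table,
    compute_bias_table,
    global_read_bias,
)
from sexnet.sexbias import UndefinedBiasError

from .conftest import random_expression
from .oracles import eq1_bias_oracle


def _expr(male_cols: dict, female_cols: dict, genes) -> ExpressionMatrix:
    counts = pd.DataFrame({**male_cols, **female_cols}, index=genes)
    sexes = {c: "male" for c in male_cols} | {c: "female" for c in female_cols}
    return ExpressionMatrix(counts, sexes)


class TestGlobalReadBias:
    def test_symmetric_totals_give_zero(self):
        e = _expr({"m1": [200], "m2": [200]}, {"f1": [200], "f2": [200]},
                  ["g"])
        assert global_read_bias(e) == 0.0

    def test_fourfold_depth_imbalance(self):
        e = _expr({"m1": [800]}, {"f1": [200]}, ["g"])
        assert global_read_bias(e) == pytest.approx(2.0, abs=1e-15)

    def test_unequal_samples_same_average(self):
        # N̂ is the per-sample average total, so {100,300} matches {200,200}
        e = _expr({"m1": [100], "m2": [300]}, {"f1": [200], "f2": [200]},
                  ["g"])
        assert global_read_bias(e) == pytest.approx(0.0, abs=1e-15)

    def test_zero_depth_sex_raises(self):
        counts = pd.DataFrame({"m1": [0], "f1": [5]}, index=["g"])
        e = ExpressionMatrix(counts, {"m1": "male", "f1": "female"})
        with pytest.raises(UndefinedBiasError):
            global_read_bias(e)


class TestComputeBiasTable:
    def test_worked_example(self, small_expression):
        """Depth-proportional weights: w^m = (0.25, 0.75), N̄^m = 47.5."""
        table, inter = compute_bias_table(small_expression)
        assert inter.weights["male"].tolist() == [0.25, 0.75]
        assert inter.gene_means["male"]["g1"] == pytest.approx(47.5)
        assert inter.gene_means["female"]["g1"] == pytest.approx(5.0)
        assert inter.global_bias == pytest.approx(0.0)
        assert table["g1"] == pytest.approx(np.log2(9.5), abs=1e-12)

    def test_symmetric_gene_is_unbiased(self):
        e = _expr({"m1": [7, 93]}, {"f1": [7, 93]}, ["g1", "g2"])
        table, _ = compute_bias_table(e)
        assert table["g1"] == 0.0

    def test_one_sex_zero_hits_cap_with_expressed_sign(self):
        e = _expr({"m1": [50, 100, 0]}, {"f1": [0, 100, 40]},
                  ["male_only", "both", "female_only"])
        table, _ = compute_bias_table(e)
        assert table["male_only"] == BIAS_CAP
        assert table["female_only"] == -BIAS_CAP

    def test_all_zero_gene_dropped(self):
        e = _expr({"m1": [10, 0]}, {"f1": [10, 0]}, ["kept", "dropped"])
        table, _ = compute_bias_table(e)
        assert list(table.index) == ["kept"]

    def test_table_size_counts_expressed_genes(self):
        rng = np.random.default_rng(11)
        e = random_expression(rng, 40, 3, 3, max_count=4)
        table, _ = compute_bias_table(e)
        expressed = (e.counts.sum(axis=1) > 0).sum()
        assert len(table) == expressed

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exact_rational_oracle(self, seed):
        rng = np.random.default_rng(seed)
        e = random_expression(rng, 50, 4, 4)
        table, _ = compute_bias_table(e)
        oracle = eq1_bias_oracle(e.counts, e.sample_sex)
        assert set(table.index) == set(oracle)
        for g, expect in oracle.items():
            assert table[g] == pytest.approx(expect, abs=1e-12)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_global_rescaling_is_absorbed(self, scale, seed):
        """B soaks up any common depth scale; every b_g is unchanged."""
        rng = np.random.default_rng(seed)
        e = random_expression(rng, 12, 2, 2)
        t1, _ = compute_bias_table(e)
        t2, _ = compute_bias_table(
            ExpressionMatrix(e.counts * scale, e.sample_sex))
        assert np.allclose(t1.to_numpy(), t2.to_numpy(), atol=1e-9)

    @given(seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_sex_swap_negates_bias(self, seed):
        rng = np.random.default_rng(seed)
        e = random_expression(rng, 12, 2, 3)
        swapped = {s: ("male" if x == "female" else "female")
                   for s, x in e.sample_sex.items()}
        t1, _ = compute_bias_table(e)
        t2, _ = compute_bias_table(ExpressionMatrix(e.counts, swapped))
        assert np.allclose(t1.to_numpy(), -t2.to_numpy(), atol=1e-9)


class TestValidation:
    def test_negative_counts_rejected(self):
        counts = pd.DataFrame({"m1": [-1], "f1": [2]}, index=["g"])
        with pytest.raises(ValueError, match="non-negative"):
            ExpressionMatrix(counts, {"m1": "male", "f1": "female"})

    def test_missing_sex_group_rejected(self):
        counts = pd.DataFrame({"m1": [1], "m2": [2]}, index=["g"])
        with pytest.raises(ValueError, match="no female samples"):
            ExpressionMatrix(counts, {"m1": "male", "m2": "male"})

    def test_duplicate_gene_ids_rejected(self):
        counts = pd.DataFrame({"m1": [1, 2], "f1": [3, 4]},
                              index=["g", "g"])
        with pytest.raises(ValueError, match="duplicate gene"):
            ExpressionMatrix(counts, {"m1": "male", "f1": "female"})


class TestClassify:
    @pytest.mark.parametrize("b,t_b,t_u,label", [
        (2.5, 2, 2, "male"),
        (2.0, 2, 2, "unbiased"),   # closed unbiased band at the boundary
        (-2.5, 2, 2, "female"),
        (0.0, 2, 2, "unbiased"),
        (3.0, 5, 1, "unclassified"),  # between the two-fold and 32-fold cuts
        (6.0, 5, 1, "male"),
        (-1.0, 5, 1, "unbiased"),
    ])
    def test_threshold_rules(self, b, t_b, t_u, label):
        assert classify(b, ClassificationScheme(t_b, t_u)) == label

    def test_vectorised_agrees_with_scalar(self):
        scheme = ClassificationScheme(5, 1)
        bias = pd.Series([-10, -5.0, -3, -1, 0, 1, 3, 5.0, 10],
                         index=[f"g{i}" for i in range(9)], dtype=float)
        vec = classify_table(bias, scheme)
        for g, b in bias.items():
            assert vec[g] == classify(b, scheme)

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError):
            ClassificationScheme(biased_cutoff=-1)
        with pytest.raises(ValueError):
            ClassificationScheme(biased_cutoff=1, unbiased_cutoff=2)
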