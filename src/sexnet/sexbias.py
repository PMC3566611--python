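"""Depth-weighted log2 sex-bias statistic and gene classification.

The statistic compares male and female whole-body RNA-seq read depth per
gene.  Within each sex, samples are weighted by their share of the sex's
total read depth (``w_i = N_i / N``), giving a weighted per-gene mean
``N̄_g = Σ_i w_i N_ig``.  The per-gene bias is

    b_g = log2(N̄_g^m / N̄_g^f) − B,       B = log2(N̂^m / N̂^f),

where ``N̂ = N / k`` is the average total depth per sample of that sex and
``B`` removes the global depth imbalance between the sexes.  Values are
capped at ±10 (over a thousand-fold difference) so that genes expressed in
only one sex stay finite; genes with zero depth in every sample carry no
information and are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "BiasIntermediates",
    "ClassificationScheme",
    "UndefinedBiasError",
    "BIAS_CAP",
    "global_read_bias",
    "compute_bias_table",
    "classify",
    "classify_table",
]

#: Cap on |b_g|, in log2 units (2**10 ≈ a thousand-fold difference).
BIAS_CAP = 10.0

MALE = "male"
FEMALE = "female"
UNBIASED = "unbiased"
UNCLASSIFIED = "unclassified"


class UndefinedBiasError(ValueError):
    """Raised when a sex group has zero total read depth."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Per-gene, per-sample read depths with sample sex labels.

    Parameters
    ----------
    counts
        DataFrame of non-negative read depths, genes in rows, samples in
        columns.  Fractional values are allowed (coverage estimators need
        not be integral).
    sample_sex
        Mapping from sample id to ``"male"`` or ``"female"``; must cover
        every column of ``counts`` and include at least one sample of each
        sex.
    """

    counts: pd.DataFrame
    sample_sex: Mapping[str, str]

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in count table")
        if c.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers in count table")
        vals = c.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("counts must be finite")
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in c.columns if s not in self.sample_sex]
        if missing:
            raise ValueError(f"samples without a sex label: {missing}")
        bad = {s: self.sample_sex[s] for s in c.columns
               if self.sample_sex[s] not in (MALE, FEMALE)}
        if bad:
            raise ValueError(f"sex labels must be 'male' or 'female': {bad}")
        for sex in (MALE, FEMALE):
            if not any(self.sample_sex[s] == sex for s in c.columns):
                raise ValueError(f"no {sex} samples present")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, sex: str) -> list[str]:
        return [s for s in self.counts.columns if self.sample_sex[s] == sex]


@dataclass(frozen=True)
class BiasIntermediates:
    """Per-sex quantities entering the bias statistic.

    ``weights[sex]`` maps sample id to ``w_i`` (summing to 1 within the
    sex); ``gene_means[sex]`` is the weighted per-gene mean depth N̄_g;
    ``avg_total[sex]`` is N̂ = N/k; ``global_bias`` is B in log2 units.
    """

    weights: dict[str, pd.Series]
    gene_means: dict[str, pd.Series]
    avg_total: dict[str, float]
    global_bias: float


@dataclass(frozen=True)
class ClassificationScheme:
    """Log2 thresholds turning a bias value into a class label.

    ``b > biased_cutoff`` is male-biased, ``b < -biased_cutoff`` is
    female-biased, ``|b| <= unbiased_cutoff`` is unbiased, and anything in
    between is unclassified.  With the two cutoffs equal (the default) the
    unclassified band is empty and the three classes partition the line.
    """

    biased_cutoff: float = 2.0
    unbiased_cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.unbiased_cutoff is None:
            object.__setattr__(self, "unbiased_cutoff", self.biased_cutoff)
        if self.biased_cutoff <= 0:
            raise ValueError("biased_cutoff must be positive")
        if self.unbiased_cutoff > self.biased_cutoff:
            raise ValueError("unbiased_cutoff must not exceed biased_cutoff")


#: §-style defaults: four-fold window for network classification.
NETWORK_SCHEME = ClassificationScheme(biased_cutoff=2.0)
#: Stringent scheme for conflict detection: 32-fold biased, <2-fold unbiased.
CONFLICT_SCHEME = ClassificationScheme(biased_cutoff=5.0, unbiased_cutoff=1.0)


def _sex_group(expr: ExpressionMatrix, sex: str):
    """Column block, per-sample totals, weights, N̂ for one sex."""
    cols = expr.samples_of(sex)
    block = expr.counts[cols]
    totals = block.sum(axis=0)  # N_i over all genes in the table
    grand = float(totals.sum())  # N
    if grand <= 0:
        raise UndefinedBiasError(f"total read depth of {sex} samples is zero")
    weights = totals / grand
    avg_total = grand / len(cols)  # N̂ = N / k
    return block, weights, avg_total


def global_read_bias(expr: ExpressionMatrix) -> float:
    """Global average read bias B = log2(N̂^m / N̂^f)."""
    _, _, nhat_m = _sex_group(expr, MALE)
    _, _, nhat_f = _sex_group(expr, FEMALE)
    return float(np.log2(nhat_m / nhat_f))


def compute_bias_table(
    expr: ExpressionMatrix, cap: float = BIAS_CAP
) -> tuple[pd.Series, BiasIntermediates]:
    """Capped per-gene sex bias b_g and the intermediates behind it.

    Genes with zero depth in every sample are dropped.  Genes expressed in
    exactly one sex hit the cap with the sign of the expressed sex.  The
    cap is applied to the final value, after subtracting B.
    """
    weights: dict[str, pd.Series] = {}
    means: dict[str, pd.Series] = {}
    avg_tot: dict[str, float] = {}
    for sex in (MALE, FEMALE):
        block, w, nhat = _sex_group(expr, sex)
        weights[sex] = w
        means[sex] = block.mul(w, axis=1).sum(axis=1)
        avg_tot[sex] = nhat
    B = float(np.log2(avg_tot[MALE] / avg_tot[FEMALE]))

    expressed = (expr.counts.sum(axis=1) > 0)
    m = means[MALE][expressed].to_numpy(dtype=float)
    f = means[FEMALE][expressed].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        raw = np.log2(m) - np.log2(f) - B  # ±inf for one-sex-zero genes
    b = np.clip(raw, -cap, cap)
    table = pd.Series(b, index=expr.counts.index[expressed], name="bias")
    inter = BiasIntermediates(
        weights=weights, gene_means=means, avg_total=avg_tot, global_bias=B
    )
    return table, inter


def classify(b: float, scheme: ClassificationScheme = NETWORK_SCHEME) -> str:
    """Label one bias value: male / female / unbiased / unclassified.

    Biased labels require strict inequality; the unbiased band is closed,
    so |b| exactly at the cutoff is unbiased when the cutoffs coincide.
    """
    if not np.isfinite(b):
        raise ValueError("bias value must be finite (cap upstream)")
    if b > scheme.biased_cutoff:
        return MALE
    if b < -scheme.biased_cutoff:
        return FEMALE
    if abs(b) <= scheme.unbiased_cutoff:
        return UNBIASED
    return UNCLASSIFIED


def classify_table(
    bias: pd.Series, scheme: ClassificationScheme = NETWORK_SCHEME
) -> pd.Series:
    """Vectorised :func:`classify` over a bias table."""
    b = bias.to_numpy(dtype=float)
    out = np.full(b.shape, UNCLASSIFIED, dtype=object)
    out[b > scheme.biased_cutoff] = MALE
    out[b < -scheme.biased_cutoff] = FEMALE
    out[np.abs(b) <= scheme.unbiased_cutoff] = UNBIASED
    return pd.Series(out, index=bias.index, name="class")
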