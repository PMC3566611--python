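"""Gene-set overlap tests and rank concordance between bias tables.

Overlap between two gene sets drawn from a finite universe is tested
against the hypergeometric null (sampling without replacement): the
enrichment p-value is the upper tail P[X >= k], the depletion p-value the
lower tail P[X <= k], and the two-tailed p-value doubles the smaller tail
(capped at 1).  Concordance between two per-gene bias tables is measured
by Kendall's tau-b on the shared genes, which corrects for ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Iterable

import pandas as pd
from scipy import stats

__all__ = ["OverlapTestResult", "hypergeom_pmf", "overlap_test", "kendall_tau"]


@dataclass(frozen=True)
class OverlapTestResult:
    universe_size: int
    size_a: int
    size_b: int
    overlap: int
    p_enrich: float   # P[X >= k]
    p_deplete: float  # P[X <= k]
    p_two_tailed: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def hypergeom_pmf(N: int, K: int, n: int, k: int) -> float:
    """P[X = k] drawing ``n`` from a universe of ``N`` with ``K`` marked.

    Out-of-support ``k`` returns 0; invalid parameters raise.
    """
    _validate_params(N, K, n)
    if k < max(0, n + K - N) or k > min(n, K):
        return 0.0
    if N == 0:  # empty universe: the only draw is empty
        return 1.0
    return float(stats.hypergeom.pmf(k, N, K, n))


def overlap_test(
    set_a: Collection[str],
    set_b: Collection[str],
    universe: Collection[str],
) -> OverlapTestResult:
    """Hypergeometric overlap test of two gene sets within a universe."""
    universe = set(universe)
    a, b = set(set_a), set(set_b)
    stray = (a | b) - universe
    if stray:
        raise ValueError(f"genes outside the universe: {sorted(stray)[:10]}")
    N, K, n = len(universe), len(a), len(b)
    k = len(a & b)
    _validate_params(N, K, n)
    if N == 0:
        p_enrich = p_deplete = 1.0
    else:
        p_enrich = float(stats.hypergeom.sf(k - 1, N, K, n))
        p_deplete = float(stats.hypergeom.cdf(k, N, K, n))
    p_two = min(1.0, 2.0 * min(p_enrich, p_deplete))
    return OverlapTestResult(N, K, n, k, p_enrich, p_deplete, p_two)


def kendall_tau(bias1: pd.Series, bias2: pd.Series) -> float:
    """Kendall tau-b between two bias tables over their shared genes."""
    shared = bias1.index.intersection(bias2.index)
    if len(shared) < 2:
        raise ValueError(
            f"need at least 2 shared genes, have {len(shared)}")
    tau, _ = stats.kendalltau(bias1.loc[shared], bias2.loc[shared],
                              variant="b")
    return float(tau)


def _validate_params(N: int, K: int, n: int) -> None:
    if N < 0 or not (0 <= K <= N) or not (0 <= n <= N):
        raise ValueError(
            f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
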