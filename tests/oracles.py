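"""Independent brute-force oracles used across the test suite.

These deliberately avoid the code paths they check: exact rational
arithmetic for the bias statistic and the hypergeometric distribution,
and O(n²) pair counting for Kendall's tau.
"""

import math
from fractions import Fraction
from itertools import combinations

import pandas as pd


def eq1_bias_oracle(counts: pd.DataFrame, sample_sex: dict,
                    cap: float = 10.0) -> dict:
    """Exact-rational evaluation of the depth-weighted bias statistic.

    Returns gene -> bias for genes with any nonzero count.  All weights,
    means and the male/female ratio are Fractions; only the final log2 is
    floating point.
    """
    out = {}
    groups = {"male": [c for c in counts.columns if sample_sex[c] == "male"],
              "female": [c for c in counts.columns if sample_sex[c] == "female"]}
    mean = {}
    nhat = {}
    for sex, cols in groups.items():
        totals = {c: Fraction(int(counts[c].sum())) for c in cols}
        grand = sum(totals.values())
        weights = {c: totals[c] / grand for c in cols}
        nhat[sex] = grand / len(cols)
        mean[sex] = {
            g: sum(weights[c] * Fraction(int(counts.at[g, c])) for c in cols)
            for g in counts.index}
    for g in counts.index:
        if all(counts.at[g, c] == 0 for c in counts.columns):
            continue
        m, f = mean["male"][g], mean["female"][g]
        if f == 0:
            out[g] = cap
        elif m == 0:
            out[g] = -cap
        else:
            ratio = (m / f) / (nhat["male"] / nhat["female"])
            b = math.log2(ratio.numerator) - math.log2(ratio.denominator)
            out[g] = max(-cap, min(cap, b))
    return out


def hypergeom_pmf_oracle(N: int, K: int, n: int, k: int) -> Fraction:
    """Exact C(K,k)·C(N−K,n−k)/C(N,n)."""
    if k < 0 or k > n or k > K or n - k > N - K:
        return Fraction(0)
    return Fraction(math.comb(K, k) * math.comb(N - K, n - k),
                    math.comb(N, n))


def hypergeom_pmf_by_enumeration(N: int, K: int, n: int, k: int) -> Fraction:
    """P[|draw ∩ marked| = k] by enumerating every n-subset of the universe."""
    marked = set(range(K))
    hits = total = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) == k:
            hits += 1
    return Fraction(hits, total)


def kendall_tau_b_oracle(x, y) -> float:
    """Tie-corrected Kendall tau by O(n²) concordant/discordant counting."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = int(x[i] > x[j]) - int(x[i] < x[j])
            dy = int(y[i] > y[j]) - int(y[i] < y[j])
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx == dy:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) // 2
    return (conc - disc) / math.sqrt((n0 - tx) * (n0 - ty))
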