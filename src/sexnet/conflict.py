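"""Indirect and direct nodes of interlocus sexual conflict.

A sex-unbiased gene whose interaction partners include at least one
strongly male-biased and one strongly female-biased gene is a candidate
for *indirect* conflict: the shared partner couples two loci pulled in
opposite directions by the sexes.  An edge joining a strongly male-biased
gene to a strongly female-biased gene is a candidate for *direct*
conflict.  The default thresholds are deliberately stringent — a 32-fold
expression difference (|b| > 5 in log2 units) to call a gene sex-biased
here, and under two-fold (|b| <= 1) to call it unbiased — so candidate
sets are conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .network import InteractionNetwork
from .sexbias import CONFLICT_SCHEME, ClassificationScheme

__all__ = ["ConflictReport", "find_indirect", "find_direct", "conflict_report"]


@dataclass(frozen=True)
class ConflictReport:
    """Conflict candidates under one classification scheme.

    ``indirect`` is sorted; ``direct_pairs`` holds (male gene, female
    gene) tuples sorted lexicographically; ``direct_male``/``direct_female``
    are the endpoint projections of the pairs.
    """

    scheme: ClassificationScheme
    indirect: tuple[str, ...]
    direct_pairs: tuple[tuple[str, str], ...]

    @property
    def direct_male(self) -> tuple[str, ...]:
        return tuple(sorted({m for m, _ in self.direct_pairs}))

    @property
    def direct_female(self) -> tuple[str, ...]:
        return tuple(sorted({f for _, f in self.direct_pairs}))


def find_indirect(
    net: InteractionNetwork,
    bias: pd.Series,
    scheme: ClassificationScheme = CONFLICT_SCHEME,
) -> set[str]:
    """Unbiased genes with both a very-male and a very-female neighbour.

    The network must already be restricted to genes carrying a bias value.
    """
    _require_bias(net, bias)
    t_b, t_u = scheme.biased_cutoff, scheme.unbiased_cutoff
    out = set()
    for gene in net.graph.nodes:
        if abs(bias[gene]) > t_u:
            continue
        has_m = has_f = False
        for nb in net.graph.neighbors(gene):
            b = bias[nb]
            if b > t_b:
                has_m = True
            elif b < -t_b:
                has_f = True
            if has_m and has_f:
                out.add(gene)
                break
    return out


def find_direct(
    net: InteractionNetwork,
    bias: pd.Series,
    scheme: ClassificationScheme = CONFLICT_SCHEME,
) -> set[tuple[str, str]]:
    """Edges joining a very-male to a very-female gene, as (male, female)."""
    _require_bias(net, bias)
    t_b = scheme.biased_cutoff
    pairs = set()
    for u, v in net.graph.edges:
        bu, bv = bias[u], bias[v]
        if bu > t_b and bv < -t_b:
            pairs.add((u, v))
        elif bv > t_b and bu < -t_b:
            pairs.add((v, u))
    return pairs


def conflict_report(
    net: InteractionNetwork,
    bias: pd.Series,
    scheme: ClassificationScheme = CONFLICT_SCHEME,
) -> ConflictReport:
    """Run both detectors and package sorted, reproducible outputs."""
    return ConflictReport(
        scheme=scheme,
        indirect=tuple(sorted(find_indirect(net, bias, scheme))),
        direct_pairs=tuple(sorted(find_direct(net, bias, scheme))),
    )


def write_gene_list(genes, path) -> None:
    """One gene id per line, sorted (byte-stable)."""
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def write_pair_list(pairs, path) -> None:
    """Two-column TSV of (male gene, female gene) pairs, sorted."""
    with open(path, "w") as fh:
        for m, f in sorted(pairs):
            fh.write(f"{m}\t{f}\n")


def _require_bias(net: InteractionNetwork, bias: pd.Series) -> None:
    missing = sorted(n for n in net.graph.nodes if n not in bias.index)
    if missing:
        raise ValueError(
            "network nodes without a bias value (restrict first): "
            f"{missing[:10]}" + ("..." if len(missing) > 10 else ""))
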