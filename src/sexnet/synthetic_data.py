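"""Synthetic expression matrices and interactomes with known ground truth.

The generator emulates the shape of the real inputs — a small-replicate
whole-body RNA-seq count table (two males, two females by default) and a
heavy-tailed undirected interactome — while planting a known truth:

* genes are assigned to male-biased / female-biased / unbiased /
  zero-expression classes in configured proportions;
* counts are negative binomial around ``baseline × sex-effect × library
  factor``, with the sex effect split symmetrically (``×2^(e/2)`` in one
  sex, ``÷2^(e/2)`` in the other) so the planted log2 bias is ≈ e
  regardless of baseline;
* the interactome is a configuration-model graph with a power-law degree
  sequence, on top of which conflict motifs are wired explicitly: for each
  indirect motif an unbiased gene gains edges to a planted male and a
  planted female gene, and each direct motif is a male–female edge.

With ``forbid_accidental_motifs`` the background wiring is rewired so that
*only* the planted motifs qualify, making exact-recovery tests
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import networkx as nx
import pandas as pd

from .conflict import ConflictReport
from .network import InteractionNetwork
from .sexbias import CONFLICT_SCHEME, ExpressionMatrix

__all__ = ["SyntheticConfig", "generate_expression", "generate_network",
           "truth_bias_table"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth generator settings.

    Proportions must sum to 1.  ``effect_size`` is the planted log2
    male/female difference for biased genes (default 6 = 64-fold, safely
    above the stringent 32-fold conflict threshold).  ``dispersion`` is
    the negative-binomial shape parameter θ (variance = μ + μ²/θ); 10 is
    moderate bulk-RNA-seq overdispersion.  Library-size factors are drawn
    uniformly from ``lib_factor_range`` per sample.
    """

    n_genes: int = 1000
    prop_male: float = 0.10
    prop_female: float = 0.10
    prop_unbiased: float = 0.75
    prop_zero: float = 0.05
    effect_size: float = 6.0
    baseline_mean: float = 200.0
    baseline_sigma: float = 1.0  # lognormal sd of per-gene baselines
    dispersion: float = 10.0
    samples_per_sex: int = 2
    lib_factor_range: tuple[float, float] = (0.7, 1.3)
    # interactome
    degree_exponent: float = 2.5
    min_degree: int = 1
    max_degree: int = 100
    n_indirect_motifs: int = 20
    n_direct_motifs: int = 30
    forbid_accidental_motifs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        total = (self.prop_male + self.prop_female
                 + self.prop_unbiased + self.prop_zero)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.samples_per_sex < 1:
            raise ValueError("need at least one sample per sex")


def _assign_classes(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_genes
    n_m = int(round(cfg.prop_male * n))
    n_f = int(round(cfg.prop_female * n))
    n_z = int(round(cfg.prop_zero * n))
    n_u = n - n_m - n_f - n_z
    if n_u < 0:
        raise ValueError("class proportions leave no room for unbiased genes")
    classes = (["male"] * n_m + ["female"] * n_f
               + ["zero"] * n_z + ["unbiased"] * n_u)
    rng.shuffle(classes)
    width = len(str(n))
    genes = [f"G{i:0{width}d}" for i in range(1, n + 1)]
    effect = {"male": cfg.effect_size, "female": -cfg.effect_size,
              "unbiased": 0.0, "zero": 0.0}
    return pd.DataFrame(
        {"gene": genes, "class": classes,
         "effect": [effect[c] for c in classes]}
    ).set_index("gene")


def generate_expression(
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a count table; returns the matrix and per-gene truth.

    The truth frame has columns ``class`` (male / female / unbiased /
    zero) and ``effect`` (signed planted log2 difference).  Runs are
    byte-deterministic for a fixed config (the seed lives in the config).
    """
    rng = np.random.default_rng(cfg.seed)
    truth = _assign_classes(cfg, rng)
    n = cfg.n_genes
    k = cfg.samples_per_sex

    baseline = rng.lognormal(np.log(cfg.baseline_mean), cfg.baseline_sigma, n)
    lib = rng.uniform(*cfg.lib_factor_range, size=2 * k)
    sample_ids = [f"male_{i+1}" for i in range(k)] + \
                 [f"female_{i+1}" for i in range(k)]
    sample_sex = {s: ("male" if s.startswith("male") else "female")
                  for s in sample_ids}

    half = truth["effect"].to_numpy() / 2.0
    mult = {"male": 2.0 ** half, "female": 2.0 ** (-half)}
    zero_mask = (truth["class"] == "zero").to_numpy()

    counts = np.zeros((n, 2 * k), dtype=np.int64)
    theta = cfg.dispersion
    for j, s in enumerate(sample_ids):
        mu = baseline * mult[sample_sex[s]] * lib[j]
        mu[zero_mask] = 0.0
        pos = mu > 0
        draw = np.zeros(n, dtype=np.int64)
        # NB(θ, p) with p = θ/(θ+μ) has mean μ and variance μ + μ²/θ
        draw[pos] = rng.negative_binomial(theta, theta / (theta + mu[pos]))
        counts[:, j] = draw
    frame = pd.DataFrame(counts, index=truth.index, columns=sample_ids)
    return ExpressionMatrix(frame, sample_sex), truth


def truth_bias_table(truth: pd.DataFrame) -> pd.Series:
    """Noise-free bias table from the planted effects (zero class absent)."""
    keep = truth["class"] != "zero"
    return truth.loc[keep, "effect"].rename("bias")


def _power_law_degrees(cfg: SyntheticConfig, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Sample n degrees from p(k) ∝ k^(−γ) on [min_degree, max_degree]."""
    ks = np.arange(cfg.min_degree, cfg.max_degree + 1)
    p = ks.astype(float) ** (-cfg.degree_exponent)
    p /= p.sum()
    degs = rng.choice(ks, size=n, p=p)
    if degs.sum() % 2:  # configuration model needs an even stub count
        degs[rng.integers(n)] += 1
    return degs


def generate_network(
    cfg: SyntheticConfig, truth: pd.DataFrame
) -> tuple[InteractionNetwork, ConflictReport]:
    """Background interactome plus explicitly wired conflict motifs.

    Nodes are the non-zero-class genes.  Returns the network and the
    planted truth as a :class:`ConflictReport` under the stringent
    conflict scheme.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    genes = truth.index[truth["class"] != "zero"]
    males = list(truth.index[truth["class"] == "male"])
    females = list(truth.index[truth["class"] == "female"])
    unbiased = list(truth.index[truth["class"] == "unbiased"])
    if cfg.n_indirect_motifs > len(unbiased):
        raise ValueError("not enough unbiased genes for indirect motifs")
    if cfg.n_indirect_motifs and not (males and females):
        raise ValueError("indirect motifs need male and female genes")
    if cfg.n_direct_motifs > len(males) * len(females):
        raise ValueError("not enough male-female pairs for direct motifs")

    # background: configuration model on a heavy-tailed degree sequence
    degs = _power_law_degrees(cfg, len(genes), rng)
    g_multi = nx.configuration_model(degs, seed=int(rng.integers(2**31)))
    g = nx.Graph(g_multi)
    g.remove_edges_from(nx.selfloop_edges(g))
    g = nx.relabel_nodes(g, dict(enumerate(genes)))
    g.add_nodes_from(genes)

    # plant indirect motifs: unbiased hub wired to one male + one female
    planted_indirect = sorted(
        str(u) for u in
        rng.choice(unbiased, size=cfg.n_indirect_motifs, replace=False))
    for u in planted_indirect:
        g.add_edge(u, males[rng.integers(len(males))])
        g.add_edge(u, females[rng.integers(len(females))])

    # plant direct motifs: distinct male-female edges
    planted_direct: set[tuple[str, str]] = set()
    while len(planted_direct) < cfg.n_direct_motifs:
        m = males[rng.integers(len(males))]
        f = females[rng.integers(len(females))]
        planted_direct.add((m, f))
    g.add_edges_from(planted_direct)

    if cfg.forbid_accidental_motifs:
        _rewire_accidental(g, truth, planted_indirect, planted_direct)

    report = ConflictReport(
        scheme=CONFLICT_SCHEME,
        indirect=tuple(planted_indirect),
        direct_pairs=tuple(sorted(planted_direct)),
    )
    return InteractionNetwork.from_graph(g), report


def _rewire_accidental(g: nx.Graph, truth: pd.DataFrame,
                       planted_indirect, planted_direct) -> None:
    """Delete background edges that would create unplanted motifs."""
    cls = truth["class"]
    planted_direct = set(planted_direct)
    indirect = set(planted_indirect)
    # accidental direct: any male-female edge not planted
    drop = []
    for u, v in g.edges:
        cu, cv = cls[u], cls[v]
        if {cu, cv} == {"male", "female"}:
            pair = (u, v) if cu == "male" else (v, u)
            if pair not in planted_direct:
                drop.append((u, v))
    g.remove_edges_from(drop)
    # accidental indirect: an unplanted unbiased node with both-sex
    # neighbours loses its edges to female genes
    for node in list(g.nodes):
        if cls[node] != "unbiased" or node in indirect:
            continue
        nbr_cls = {n: cls[n] for n in g.neighbors(node)}
        if "male" in nbr_cls.values() and "female" in nbr_cls.values():
            g.remove_edges_from(
                (node, n) for n, c in nbr_cls.items() if c == "female")
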