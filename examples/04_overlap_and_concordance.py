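"""Hypergeometric gene-set overlap and Kendall concordance of bias tables.

Compares the detected indirect-conflict genes against a random gene set
of the same size (expected: no significant overlap), and measures rank
concordance between the estimated bias table and the planted truth.
"""

import numpy as np

from sexnet import (CONFLICT_SCHEME, SyntheticConfig, compute_bias_table,
                    find_indirect, generate_expression, generate_network,
                    kendall_tau, overlap_test, restrict_nodes,
                    truth_bias_table)

cfg = SyntheticConfig(n_genes=1000, seed=19)
expr, truth = generate_expression(cfg)
net, planted = generate_network(cfg, truth)
bias, _ = compute_bias_table(expr)
net = restrict_nodes(net, set(bias.index))

indirect = find_indirect(net, bias, CONFLICT_SCHEME)
universe = sorted(net.nodes)
rng = np.random.default_rng(19)
random_set = list(rng.choice(universe, size=max(len(indirect), 1),
                             replace=False))

res = overlap_test(indirect, random_set, universe)
print(f"universe {res.universe_size}, |A| = {res.size_a} indirect genes, "
      f"|B| = {res.size_b} random genes, overlap k = {res.overlap}")
print(f"P[enrichment] = {res.p_enrich:.3f}, P[depletion] = "
      f"{res.p_deplete:.3f}, two-tailed = {res.p_two_tailed:.3f}")
print("A random set should show no significant enrichment or depletion.")

tau = kendall_tau(bias, truth_bias_table(truth))
print(f"\nKendall tau-b, estimated vs planted bias: {tau:.3f}")
print("Concordance is well below 1 because most genes are truly unbiased")
print("(planted value 0, a massive tie block) while their estimates scatter.")
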