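"""Recover planted nodes of sexual conflict from a synthetic network.

Plants indirect motifs (an unbiased gene bridging a very-male and a
very-female gene) and direct motifs (male–female edges) in a background
interactome, then detects them from the noise-free truth biases and from
biases re-estimated from simulated counts.
"""

from sexnet import (CONFLICT_SCHEME, SyntheticConfig, compute_bias_table,
                    find_direct, find_indirect, generate_expression,
                    generate_network, restrict_nodes, truth_bias_table)

cfg = SyntheticConfig(n_genes=1000, seed=11, n_indirect_motifs=20,
                      n_direct_motifs=30, forbid_accidental_motifs=True)
expr, truth = generate_expression(cfg)
net, planted = generate_network(cfg, truth)

truth_bias = truth_bias_table(truth)
ind = find_indirect(net, truth_bias, CONFLICT_SCHEME)
dirp = find_direct(net, truth_bias, CONFLICT_SCHEME)
print(f"noise-free biases: {len(ind)} indirect genes "
      f"(planted {len(planted.indirect)}), {len(dirp)} direct pairs "
      f"(planted {len(planted.direct_pairs)})")
print("  exact recovery:",
      sorted(ind) == list(planted.indirect)
      and sorted(dirp) == list(planted.direct_pairs))

est_bias, _ = compute_bias_table(expr)
est_net = restrict_nodes(net, set(est_bias.index))
ind_est = find_indirect(est_net, est_bias, CONFLICT_SCHEME)
dirp_est = find_direct(est_net, est_bias, CONFLICT_SCHEME)
print(f"estimated biases:  {len(ind_est)} indirect genes, "
      f"{len(dirp_est)} direct pairs")
print(f"  planted indirect recovered: "
      f"{len(ind_est & set(planted.indirect))}/{len(planted.indirect)}")
print(f"  planted direct recovered:   "
      f"{len(dirp_est & set(planted.direct_pairs))}/"
      f"{len(planted.direct_pairs)}")
print("With noise-free biases recovery is exact by construction; with")
print("count noise a planted pair is missed when an endpoint's estimated")
print("bias slips below the stringent 32-fold threshold.")
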