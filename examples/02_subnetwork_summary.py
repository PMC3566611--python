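"""Summarise sex-classed subnetworks of a synthetic interactome.

Generates a seeded expression matrix and interactome, classifies genes
under the four-fold scheme, and prints node/edge counts plus a power-law
tail fit for a few X–Y subnetworks (X nodes with at least one Y
neighbour).
"""

from sexnet import (ClassificationScheme, SyntheticConfig, bin_degrees,
                    classify_table, compute_bias_table, fit_power_law,
                    generate_expression, generate_network, restrict_nodes)
from sexnet.degree_stats import InsufficientDataError
from sexnet.network import subnetwork_degrees, summarize_subnetwork

cfg = SyntheticConfig(n_genes=2000, seed=7)
expr, truth = generate_expression(cfg)
net, _ = generate_network(cfg, truth)

bias, _ = compute_bias_table(expr)
net = restrict_nodes(net, set(bias.index))
labels = classify_table(bias, ClassificationScheme(2.0))
code = {"male": "M", "female": "F", "unbiased": "U", "unclassified": "X"}
node_labels = {g: code[labels[g]] for g in net.graph.nodes}

print(f"analysis network: {net.n_nodes} nodes, {net.n_edges} edges")
print(f"{'net':5s} {'nodes':>6s} {'edges':>6s} {'E/N':>6s} "
      f"{'mean k':>7s} {'tail exp':>9s}")
for x, y in [("A", "A"), ("U", "U"), ("M", "M"), ("F", "F"), ("M", "F")]:
    s = summarize_subnetwork(net, node_labels, x, y, degree_mode="full")
    degs = subnetwork_degrees(net, node_labels, x, y, degree_mode="within")
    try:
        exp = f"{fit_power_law(bin_degrees(degs, 5), cutoff=1).exponent:9.2f}"
    except (InsufficientDataError, ValueError):
        exp = "       NA"
    ratio = "NA" if s.n_nodes == 0 else f"{s.edges_per_node:6.2f}"
    print(f"{x}-{y:3s} {s.n_nodes:6d} {s.n_edges:6d} {ratio} "
          f"{s.mean_degree:7.2f} {exp}")
print("X-Y counts class-X nodes touching class Y; 'mean k' is the full-")
print("network degree of those nodes; the exponent is the log-log slope of")
print("the binned within-subnetwork degree distribution (NA: too few bins).")
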