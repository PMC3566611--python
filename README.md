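# sexnet

Sex-biased expression networks and candidate nodes of interlocus sexual
conflict.

Males and females of one species share nearly the same genome yet express
it differently; when a gene's optimal expression differs between the
sexes, selection can pull interacting loci in opposite directions.
`sexnet` couples per-gene male/female expression bias, estimated from
small-replicate whole-body RNA-seq, with an undirected gene-interaction
network to (1) characterise male-, female- and unbiased subnetworks and
their heavy-tailed degree distributions and (2) flag two kinds of
candidate conflict nodes:

* **indirect** — a sex-unbiased gene with at least one strongly
  male-biased *and* one strongly female-biased interaction partner;
* **direct** — an edge joining a strongly male-biased gene to a strongly
  female-biased gene.

It is aimed at evolutionary genomicists who have a count table with sex
labels and one or more edge-list interactomes (e.g. a DroID-style
download) and want reproducible subnetwork statistics and conservative
conflict candidate lists.

## The statistic

For samples *i* = 1…*k* of one sex, let *N<sub>ig</sub>* be the read
depth of gene *g* in sample *i*, *N<sub>i</sub>* = Σ<sub>g</sub>
*N<sub>ig</sub>*, and *N* = Σ<sub>i</sub> *N<sub>i</sub>*. Each sample
gets weight *w<sub>i</sub>* = *N<sub>i</sub>*/*N*, the weighted gene mean
is N̄<sub>g</sub> = Σ<sub>i</sub> *w<sub>i</sub>N<sub>ig</sub>*, and
N̂ = *N*/*k* is the average total depth per sample. The per-gene sex bias
is

> b<sub>g</sub> = log₂(N̄<sub>g</sub><sup>m</sup> / N̄<sub>g</sub><sup>f</sup>) − B,  B = log₂(N̂<sup>m</sup> / N̂<sup>f</sup>)

clamped to [−10, 10] so genes expressed in only one sex stay finite;
genes silent in every sample are dropped. Classification uses |b| > 2
(four-fold) for the sex-biased network classes, and the deliberately
stringent |b| > 5 (32-fold) biased / |b| ≤ 1 (under two-fold) unbiased
windows for conflict detection. Subnetwork **X**–Y collects class-X nodes
with at least one class-Y neighbour plus the unique X–Y edges; degree
distributions are binned (width 5) and a power-law exponent is fit by
least squares to the log–log tail above a per-subnetwork degree cutoff.
Gene-set overlaps are tested against the hypergeometric null, and bias
tables are compared by Kendall's tau-b.

## Worked example

```python
import pandas as pd
from sexnet import ExpressionMatrix, compute_bias_table, classify

counts = pd.DataFrame(
    {"male_1": [10, 90], "male_2": [60, 240],
     "female_1": [5, 195], "female_2": [5, 195]},
    index=["gene_a", "gene_b"])
expr = ExpressionMatrix(counts, {"male_1": "male", "male_2": "male",
                                 "female_1": "female", "female_2": "female"})
bias, inter = compute_bias_table(expr)
print(round(inter.global_bias, 4), round(bias["gene_a"], 4),
      classify(bias["gene_a"]))
```

prints `0.0 3.2479 male`: the male samples carry weights 0.25/0.75, so
gene_a's weighted male mean is 47.5 against a female mean of 5, a 9.5-fold
ratio (log₂ 9.5 ≈ 3.25) that clears the four-fold threshold, while the
equal sex totals make the global correction B zero.

The `examples/` scripts walk through each capability end to end; e.g.
`python examples/03_conflict_detection.py` plants 20 indirect and 30
direct motifs in a 1,000-gene synthetic interactome and reports

```
noise-free biases: 20 indirect genes (planted 20), 30 direct pairs (planted 30)
  exact recovery: True
estimated biases:  17 indirect genes, 28 direct pairs
```

— detection is exact given the true biases, and loses a few planted
motifs when biases are re-estimated from noisy counts because an endpoint
slips below the 32-fold cutoff.

There is also a thin CLI (`sexnet simulate|bias|summarize|fit-tail|
conflict|overlap|all`) for shell use; `sexnet all --config run.yaml` runs
the whole pipeline and writes the 13-row subnetwork summary, degree
distributions, conflict lists and a run manifest.

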