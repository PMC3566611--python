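# Methods

## Sex-bias statistic

Within each sex, samples are combined by depth-proportional weights
w_i = N_i/N (a deeper library contributes more to the weighted gene mean
N̄_g = Σ_i w_i N_ig), and the per-gene bias is
b_g = log₂(N̄_g^m/N̄_g^f) − B with B = log₂(N̂^m/N̂^f), N̂ = N/k. B removes
the global depth imbalance between the sexes, so rescaling all counts by
a common factor leaves every b_g unchanged, and swapping the sex labels
negates the table exactly (both are property-tested).

Choices worth stating:

* **Depth-proportional weighting is implemented verbatim.** It is the
  opposite of the more conventional inverse-depth (CPM-style)
  normalisation; we keep it because it is the definition of the
  statistic this package computes. Users wanting per-sample
  normalisation can pre-scale the count table.
* **Capping order.** b_g is clamped to ±10 *after* subtracting B, so a
  gene expressed in only one sex lands exactly on the cap with the sign
  of the expressed sex. Capping the ratio before the correction would
  shift one-sex genes off ±10 by B; with whole-genome tables B is small
  (the two capping orders differ only there), and the chosen order keeps
  the "capped" set byte-stable.
* **Degenerate inputs.** Genes with zero depth in all samples are
  dropped (their ratio is 0/0); a sex whose total depth is zero is a
  hard error, since w_i and B are undefined.
* **Classification.** Two threshold schemes coexist: |b| > 2 (four-fold)
  for the network classes, and the stringent conflict scheme, biased
  |b| > 5 (32-fold) with unbiased |b| ≤ 1 (under two-fold). In the
  stringent scheme genes with 1 < |b| ≤ 5 belong to neither side and are
  labelled `unclassified`; they can anchor neither a conflict bridge nor
  a biased endpoint. Biased calls use strict inequality, the unbiased
  band is closed, so a boundary value is never biased.

## Networks and subnetworks

All interaction evidence is flattened to unique undirected edges on a
simple graph (self-loops dropped with a logged count, duplicate and
reversed pairs collapsed); "strict" versus "permissive" is purely a
configuration grouping of edge-list files. Before any statistic the
network is restricted to genes carrying a bias value, and nodes left
without a surviving edge are removed — the analysis network is the
largest bias-scored subgraph with positive degree.

Subnetwork **X**–Y = class-X nodes with ≥ 1 class-Y neighbour, plus the
unique X–Y edges. Because edges are unordered, |edges(X,Y)| =
|edges(Y,X)|, and the six unordered class pairs partition the full edge
set — both identities are tested. Two degree definitions are exposed and
every report states which was used: `full` (degree in the whole analysis
network; the default for the summary table's mean/SD/quartiles, which
makes mean(A–A) = 2E/N exactly) and `within` (only subnetwork edges; the
default for degree-distribution fits, and the definition under which
every subnetwork node has degree ≥ 1).

## Degree distributions and tail fits

Degrees are binned with fixed width 5 starting at [1, 5]; counts are
unnormalised and trailing empty bins trimmed. The tail exponent is the
OLS slope through (log₁₀ midpoint, log₁₀ count) over non-empty bins whose
lower edge is at or above a per-subnetwork cutoff; at least three usable
bins are required. The bin representative is the arithmetic midpoint
(e.g. 3 for [1–5]); lower-edge or geometric-mean representatives shift
the intercept and, on non-ideal data, the slope slightly, and were
rejected for simplicity. Base-10 logs on both axes make the slope
base-invariant. Cutoffs are supplied by the user (defaults bundled per
subnetwork code); automated cutoff selection and maximum-likelihood
(Clauset-style) estimation are deliberately out of scope — the OLS slope
on binned counts is the quantity this package reports, and it is known
to be a biased estimator of the generating exponent when far-tail bins
hold single nodes (the sampled-degree checks therefore use a stochastic
±0.3 tolerance rather than asserting unbiasedness).

## Conflict detection

Indirect candidates: genes with |b| ≤ t_u whose neighbourhood contains
at least one b > t_b and one b < −t_b partner. Direct candidates: edges
with endpoints on opposite sides of ±t_b, reported as (male, female)
pairs plus both endpoint projections — a pair count and the two per-side
gene counts answer different questions and both are emitted. Defaults
t_b = 5, t_u = 1. All outputs are sorted lexicographically so reruns are
byte-identical.

## Synthetic data generator

The generator emulates the real inputs' *shape*: a count table with two
replicates per sex, and a heavy-tailed interactome.

* **Counts** are negative binomial with mean baseline_g × 2^(±e/2) ×
  lib_i and shape θ (variance μ + μ²/θ). Defaults: 1,000 genes; 10%
  planted male-biased and 10% female-biased at e = 6 (64-fold), 75%
  unbiased, 5% silent; per-gene baselines lognormal(log 200, 1); library
  factors uniform on [0.7, 1.3]; θ = 10 — moderate bulk-RNA-seq
  overdispersion (per-observation CV ≈ 0.33 at high expression). The sex
  effect is split symmetrically (×2^(e/2) in one sex, ÷2^(e/2) in the
  other) so the planted |b| ≈ e independent of baseline. Under these
  conditions the estimator recalls ≈ 97% of 64-fold planted genes at the
  32-fold threshold; a single 100-gene replicate estimates that rate
  with ≈ 1.7% Monte-Carlo error, so recovery checks pool five seeded
  replicates.
* **Interactome**: a configuration-model graph over the non-silent genes
  with degrees drawn from p(k) ∝ k^−γ on [1, 100] (γ = 2.5 by default),
  reduced to a simple graph. Conflict motifs are wired explicitly on
  top; with `forbid_accidental_motifs` background edges that would
  create unplanted motifs are deleted (background male–female edges, and
  the female-side edges of unplanted unbiased bridges), making recovered
  sets equal planted truth exactly rather than being supersets.
* **What it does not model**: tissue- and stage-specific expression,
  correlated genes, isoform structure, mapping artefacts, and any
  relationship between a gene's expression class and its network degree.
  Passing recovery tests therefore demonstrates the pipeline's
  correctness and noise behaviour, not biological validity on real data.

## Set statistics

The hypergeometric overlap test reports the upper tail P[X ≥ k]
(enrichment), the lower tail P[X ≤ k] (depletion) and a two-tailed
p-value as the doubled smaller tail capped at 1 (the minimum-likelihood
two-tailed construction is a documented alternative, not the default).
Both tails include P[X = k], hence p_enrich + p_deplete ≥ 1. The
empty-universe case is defined explicitly (all mass at k = 0). The
default universe for conflict-overlap comparisons is the analysis
network's gene set, configurable. Bias-table concordance uses Kendall's
tau-b, the tie-corrected variant — ties are unavoidable when many genes
sit at the caps or at planted value 0.

## Problem sizes and numerics

Test and validation runs use 300–2,000-gene simulations (10,000 nodes
for the degree-tail check and 20,000 sampled degrees for the fit check),
sizes at which every stochastic tolerance has comfortable margin while
the whole suite stays fast. Exactness claims are backed by independent
oracles: exact rational (Fraction) re-evaluation of the bias statistic
(agreement to 1e-12), exhaustive combinatorial enumeration of the
hypergeometric distribution for all universes ≤ 12, and O(n²) pair
counting for tau-b. All randomness flows through numpy Generators seeded
from explicit config fields; pipeline outputs are sorted before writing
so a rerun with the same config and inputs is byte-identical.

## Known limitations

* The depth-proportional weighting amplifies, rather than removes,
  library-size effects within a sex; that is intrinsic to the statistic.
* OLS-on-binned-counts tail exponents are estimator-dependent; compare
  only like with like.
* With two samples per sex the bias estimate for low-expression genes is
  noisy, and near-threshold genes flip classes between seeds; the
  stringent conflict scheme is conservative by design, trading recall
  for precision.
* Edge direction and interaction type are discarded; regulatory
  asymmetry cannot be recovered downstream.
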