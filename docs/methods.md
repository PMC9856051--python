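# Methods

`txscape` computes network-based transcriptional landscapes for
multi-group RNA-seq count studies: it ranks genes by shrunken fold
change, tests gene sets by preranked enrichment, assembles the
significant sets into an overlap network, clusters that network by
simulated stochastic flow, projects further group comparisons onto the
fixed scaffold, and overlays gene-level results on a curated
ligand/receptor interactome. This note records the model, the defaults
and why they are what they are, the numerical conventions, and what the
synthetic benchmark does and does not establish.

## Differential expression and ranking

Counts are normalized by median-of-ratios size factors: the reference
profile is the gene-wise geometric mean over samples restricted to genes
positive everywhere; each sample's factor is the median of its
count/reference ratios. When no gene is positive in all samples
(pathological for bulk data) the total-count fallback is used with a
warning. CPM is available separately for inspection and is not used for
testing.

For a contrast (A, B) the effect size is
`lfc = log2((mean_A + c) / (mean_B + c))` on normalized counts with
pseudocount `c = 0.5` (configurable). Inference defaults to Welch's
unequal-variance test on `log2(normalized + c)` — robust, assumption-light
and, as the null-study calibration shows, close to nominal at the sample
sizes this package targets (n >= 8 per group). An optional
negative-binomial Wald mode fits per-group log-link intercepts by Newton
iteration with a per-gene method-of-moments dispersion and uses the
Fisher standard error of the log2 difference; it is provided for users
who want a count-model test, and the two modes agree in sign on
essentially all strongly significant genes.

Fold changes are shrunk with a normal-prior ridge:
`slfc = lfc * tau^2 / (tau^2 + se^2)`, with
`tau^2 = max(0, var(lfc) - mean(se^2))` estimated by moment matching
across genes. This keeps the two properties that matter for ranking —
`|slfc| <= |lfc|` and sign preservation — and empirically dominates the
raw estimate in mean squared error when true effects exist. Two limits
are intentional: `se = 0` leaves the estimate untouched, and pure-noise
studies give `tau^2 = 0`, shrinking every gene to exactly zero (see the
degenerate-ranking rule below). With fewer than 10 genes the prior
variance is not estimable and shrinkage is skipped with a warning.

Genes with zero counts in every sample of both contrast groups are
dropped before ranking. The ranking is strictly total: descending slfc,
ties by test statistic (descending), then gene id — so every downstream
stage is deterministic.

Gene-level significance for volcano classes and the interactome overlay
uses `padj < 0.05` plus a fold-change gate on slfc. "Fold change > 2" is
read as linear two-fold by default (`|slfc| >= 1` in log2 units); a
config switch (`fc_scale="log2"`) selects the literal `|slfc| > 2`
reading. The linear reading is the default because the symmetric "< -2
for downregulation" phrasing most naturally describes two-fold down.

## Preranked enrichment

The enrichment score is the classic weighted Kolmogorov–Smirnov running
sum with exponent `weight_p = 1` (configurable): hits add
`|score|^p / sum_set |score|^p`, misses subtract `1/(N - N_hit)`; the ES
is the signed maximal deviation and the leading edge is the member genes
at or before the peak (at or after the trough for depletion). The
leading-edge fraction is leading-edge size over set size in the ranked
universe.

Numerical conventions, all deterministic:

* extremum ties within one sign resolve to the earliest ranking index;
* positive/negative extrema whose magnitudes agree within 1e-12 are
  treated as exact ties and resolved to the earlier walk index — running
  sums that tie in real arithmetic (e.g. ±1/3) otherwise resolve by
  floating-point accident, differently in the serial and vectorized
  paths;
* the p-value tail comparison carries the same 1e-12 tolerance, so null
  draws reproducing the observed subset always count as at least as
  extreme;
* an identically zero ranking metric (the `tau^2 = 0` limit of a
  global-null study) falls back to the unweighted statistic (every hit
  adds `1/k`), which keeps permutation p-values calibrated instead of
  making the whole run undefined; a set whose members all score zero
  while other genes do not is skipped with a warning.

Significance uses a gene-sampling null: ES values of uniform random
member subsets of the same size. One pool of random subsets serves all
sizes (the k smallest of N iid uniform keys are a uniform k-subset, and
prefixes nest), so the null costs one pass over the pool per distinct set
size. The null is sign-partitioned, the standard GSEA convention:
`NES = ES / mean(|null of matching sign|)` and
`p = (1 + #{matching sign, |ES_null| >= |ES_obs|}) / (1 + #matching sign)`.
Benjamini–Hochberg (implemented as the closed-form step-up) adjusts
across the sets of one comparison.

**Permutation resolution rule.** Sign-partitioning halves the effective
null, so the smallest attainable p is about `2/nperm`, and with `m` sets
tested and `d` discoveries tied at the floor the best attainable adjusted
p is about `2m/(d * nperm)`. A padj gate of 0.001 with m ~ 200 and
d ~ 5–10 therefore needs `nperm > 40,000`; the default is
`nperm = 50,000`. Users applying stricter gates or larger collections
should scale nperm by the same formula. (Adaptive p-refinement schemes
avoid this cost; plain sampling was chosen because it is directly
verifiable against exhaustive enumeration.)

## Landscape construction

Nodes: sets with anchor-comparison `padj < 0.001` and leading-edge
fraction `>= 33.34%` (strict p, inclusive LE). Enriched and depleted sets
coexist; direction is an attribute, not a filter.

Edges: for an unordered pair, the gate is leading-edge overlap relative
to the smaller member set, `|LE_A ∩ LE_B| / min(|M_A|, |M_B|) >= 0.05`;
the weight is the member overlap coefficient
`|M_A ∩ M_B| / min(|M_A|, |M_B|)` with member sets taken in the ranked
universe. Gating on leading edges but weighting on full membership
follows the description that weights reflect member-gene overlap while
the gate references leading edges; both denominators are recorded in the
export metadata since a Jaccard variant would also be defensible.
Enriched–depleted pairs may be linked when the gate passes.

MCL: self-loops at each node's maximum incident weight (1 for isolates),
column normalization, then alternating expansion (matrix power 2) and
inflation (entrywise power, default 2.0, renormalized) with pruning of
entries below 1e-5, until the matrix changes by less than 1e-8 or 200
iterations (non-convergence returns the current partition with a warning
flag). Clusters come from the limit's attractor structure: rows with
positive diagonal mass are attractors, attractors flowing into each other
form one system, and every node joins the attractor system it flows to —
a node supported by several systems is assigned to the lowest cluster
index, so the output is always a partition. Inflation 2.0 and expansion 2
are the canonical MCL defaults; the 2.5 value some graph tools default to
is available via configuration.

Projection annotates scaffold nodes with another comparison's padj,
direction and significance tier (<0.001, <0.01, <0.05, ns; absent sets:
not-tested) and never alters topology — maps for different contrasts stay
superimposable. Theme summaries emit one tidy row per (cluster,
comparison, member set) with `sign(direction) * -log10(padj)`, padj
floored at 1e-16 and the transform capped at ±16. Cluster label
suggestions are frequency-ranked name tokens (stop-words removed,
trailing numbers re-attached, lexicographic tie-break); naming the
biological theme remains a human decision.

Exports are GraphML plus flat node/edge TSV twins; attribute round trips
are exercised by the tests. Layout is deliberately left to the viewer.

## Interactome overlay

A directed ligand→receptor graph is built from a TSV pair table
(deduplicated; self-pairs warned but kept) and annotated per comparison
with each endpoint's slfc, padj and volcano class — classes are copied
from the differential-expression stage, never recomputed, so there is one
source of truth. Pairs are flagged `receptor-only-activation` (receptor
up, ligand not), `autocrine-candidate` (both up), `no-data` (neither
endpoint tested) or `other`. A curated human interleukin/interferon pair
table compiled from HGNC gene families and published pairing reviews
ships with the package; tests and examples use synthetic pair tables so
nothing requires network access.

## Synthetic studies and what they show

The generator emulates a three-group bulk study (two disease-like groups
A, B versus control C). Baseline means are log-normal (natural-log mean
5.0, sd 1.2 — moderately deep sequencing of expressed genes), dispersion
follows `phi = phi0 + a/mu` with `phi0 = 0.05`, `a = 1.0` (the usual
decreasing mean–dispersion trend), library factors are log-uniform in
[0.6, 1.6], and counts are negative binomial with `Var = mu + phi mu^2`.
Defaults: 5,000 genes, 8 samples per group, 200 sets of 15–100 genes.

Planted signals shift responder genes (a configured fraction of a set's
members) by `2^lfc` in the first group of each affected comparison.
Because signals act through group means, a signal planted for both
A-vs-C and B-vs-C is exactly null in A-vs-B, while an A-vs-C-specific
signal also separates A from B — the projection dichotomy the landscape
stage is designed to expose, available as ground truth. Signals sharing a
`family` label draw members from one common pool (disjoint across
families), producing the redundant, overlapping sets that enrichment-map
edges and MCL clusters summarize; per-set responder counts are then exact
only for singleton families. An optional known batch covariate can be
planted as an additive log-scale offset to exercise covariate adjustment;
there is no hidden batch structure by default, and surrogate-variable
estimation is out of scope.

Every generator stream is derived from one seed via separate child
streams (members, counts, collection, interactome, library sizes), so the
collection is identical whether or not counts were drawn first and
regeneration is byte-identical.

What passing the benchmark does show: calibrated type-I behaviour of the
gene- and set-level statistics under the generator's null; recovery of
planted coordinated shifts at the production gates; correct
shared-versus-specific logic under projection; exact agreement of the
enrichment machinery with brute-force enumeration; reproducibility. What
it does not show: robustness to FFPE degradation, hidden batch structure,
correlated genes within real pathways, composition effects beyond what
median-of-ratios absorbs, or annotation noise in real gene-set
collections — real-data behaviour on those axes is untested here.

## Problem sizes and runtime choices

Desk-scale defaults keep a full fixture run (2,000 genes, 3x8 samples,
100 sets, three comparisons, nperm = 50,000) around half a minute on one
CPU, and the repeated-seed benchmarks (10 seeds of the recovery and
dichotomy studies at 5,000 and 2,000 genes) in a few minutes each. The
enrichment null is the dominant cost and scales as
`O(nperm * (N + sum_k k log k))` over distinct set sizes.

## Known limitations

* The Welch-on-log default is not a count model; at very small n or very
  low counts its calibration degrades (the NB Wald mode helps, at the
  cost of asymptotic p-values).
* Ridge shrinkage with a single global `tau^2` is cruder than mixture
  priors; it can under-shrink when effects are sparse and heavy-tailed.
* The permutation floor bounds attainable adjusted p-values (see the
  resolution rule); sets tied at the floor share identical p.
* MCL on graphs with near-tied attractor structure can be sensitive to
  the pruning threshold; the defaults are the canonical ones and both
  thresholds are recorded in run manifests.
* Gene identifiers are opaque strings; no alias resolution is attempted.
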