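# Methods

## Model and assumptions

The package treats a disease (or a drug-induced side effect) as a *network
module*: the subgraph its associated genes induce in a genome-scale
protein–protein interaction network. Two assumptions follow. First, the
interactome is taken as an undirected, unweighted graph; interaction
direction, sign and confidence are ignored. Second, identifiers are opaque
strings assumed pre-mapped to one namespace — no UniProt/Entrez/symbol
translation is attempted, and genes absent from the interactome are dropped
(with counts reported) before any statistic is computed.

### Module significance

A gene set qualifies as a module when three metrics of its induced
subgraph — largest-connected-component (LCC) size, LCC interaction count,
and total interaction count — exceed degree-matched chance. The null
replaces each gene by a uniform draw from its degree bin (without
replacement within one replicate; a gene may draw itself), repeated
`n_reps` times (default 1000). Each metric is z-scored against its null
and the one-sided upper-tail normal p is reported; the empirical rank p,
`(1 + #{null ≥ obs}) / (n_reps + 1)`, is emitted alongside because the
normal tail is an approximation on what is a discrete statistic.

Degree bins are logarithmic (base 2) and merged upward until each holds at
least `min_bin_size` nodes (default 20). On toy graphs a dense planted set
can monopolize its own degree class, in which case the null can only
resample the planted set itself and the z-score collapses to zero; widening
`min_bin_size` restores a meaningful null. Real interactomes have thousands
of nodes per degree class, so the default is safe there.

### Proximity and its null

Closest-distance proximity `p(T, S)` averages, over drug targets, the BFS
hop distance to the nearest module gene; `p = 0` exactly when every target
is itself a module gene. Distances are computed on the full interactome,
not its LCC. Targets unreachable from the module are excluded from the
average and counted (`n_targets_unreachable`); a pair whose targets are all
unreachable is *unscored* (NaN, flagged) rather than given an arbitrary
large proximity, because the average is undefined at infinite distance and
any finite stand-in would distort cross-drug comparisons.

The randomization null redraws degree-matched stand-ins for **both** the
target set and the module per replicate (target-only randomization is a
switch). Null replicates that are themselves unscorable are dropped. The
significance rule `z ≤ −1.65` is inclusive; a −∞ sentinel (degenerate null
with sd 0) passes, NaN never does.

Determinism: replicate *r* of any null uses RNG substream
`default_rng([seed, r])`, so results are bit-reproducible and growing
`n_reps` never reshuffles earlier replicates.

### Adjusted similarity and the network

Accepted pairs (z ≤ cutoff) form a bipartite graph weighted provisionally
by `(m − p)/m` with `m = max(p)` over the **retained** pairs (a
`pre_filter` switch uses all scored pairs; post-filter is the default as
the conservative reading — only retained pairs are scored). If every
retained proximity is 0, `m` falls back to the maximum over all scored
pairs so the rescaling stays defined. Clusters come from greedy
(Clauset–Newman–Moore) modularity maximization on the weighted graph, with
nodes and edges inserted in sorted order so the partition is reproducible;
standard unipartite modularity is used on the bipartite graph. Zero-weight
edges are floored at 1e-12 for the clustering step only.

The quality-cluster bonus is defined here as: for a cluster, the total
intra-cluster edge weight divided by the total weight incident to the
cluster's nodes (1 when no edge leaves the cluster); a drug–disease pair
receives its cluster's score when co-clustered, else 0. This concrete
definition is isolated behind one function so alternates can be swapped.

The sigmoid `AS(p) = 1/(1 + exp(−c[(1+QC)(m−p)/m − d]))` uses steepness
`c = 10` and midpoint `d = 0.5` by default; both are mandatory run-config
values echoed into all outputs. Midpoint 0.5 makes AS = 0.5 the natural
proximal/distal boundary used by the filtering rules. AS is strictly inside
(0, 1) mathematically, though the float evaluation saturates to exactly 1.0
for |c·bracket| ≳ 37.

### Screening and modes of action

Criterion 1 removes drugs not significantly proximal to the disease
(`z > −1.65`). Criterion 2 removes survivors significantly proximal to the
side effect with `AS ≥ 0.5` (both thresholds inclusive and configurable).
A drug that is *not* significantly proximal to the side effect is retained
regardless of any AS value; with several side effects the union of
removals applies, which is order-independent.

Mode of action is a quadrant over (AS to side effect, AS to disease), named
side-effect first. On **either** axis, a drug with no significant
association is classified distal: significance is what licenses reading AS
as closeness, and treating only the side-effect axis this way (while
letting a raw AS value drive the disease axis) proved inconsistent on
planted data — mid-distance random drugs were called disease-proximal. Raw
(no-cluster-bonus) AS values are still recorded for non-significant pairs
and drive the drug-action-map coordinates, where such drugs are marked in a
separate `not_significant` stratum rather than being given invented scores.

The mechanism-of-action subnetwork around a drug collects its mapped
targets, the disease and side-effect genes adjacent to them, and *bridge*
nodes: first neighbors of targets, members of neither gene set, that touch
at least one disease-module gene. Roles (target / disease / side_effect /
bridge) are combinable flags.

### Validation statistics

Hypergeometric enrichment is the inclusive upper tail
`Σ_{i≥X} C(K,i)C(U−K,S−i)/C(U,S)`, evaluated through the hypergeometric
survival function (log-space, stable for large universes); all four counts
are restricted to the label catalog's drug universe. ROC curves sweep
decreasing similarity with ties entering together; AUC is the trapezoid
area, identical to the tie-corrected Mann–Whitney statistic. The t
comparison is pooled-variance Student by default (Welch by flag), with
zero-variance inputs flagged degenerate instead of returning NaN.
Disease dendrograms use complete linkage on Euclidean distances between
rows of the (1 − AS) matrix, absent pairs imputed at distance 1; the
comparison helper reports partition identity at a cut plus cophenetic
correlation.

## The synthetic scenario generator

`make_scenario` emulates the real inputs at desk scale: a 400-node
configuration-model background with truncated power-law degrees (exponent
2.5, degrees 2–20; interactome degree distributions are heavy-tailed — an
Erdős–Rényi background is available for simple tests), two disjoint
20-gene modules (one disease, one side effect) wired internally to density
0.35 via a random spanning tree plus uniform extra edges (so each planted
module is connected by construction), and 32 three-target drugs: 8 with
targets inside the disease module, 8 inside the side-effect module, 16
placed at random outside all modules. A `ring` placement (targets at exact
hop distance k from a module) exists for targeted tests but is not part of
the default conditions: a drug at distance 1 sits exactly on the AS = 0.5
boundary, where its quadrant depends on the run-level `m` rather than on
its own placement, so it has no well-defined planted class.

Adverse labels are Bernoulli draws with probability 0.85 / 0.35 / 0.05 at
planted side-effect distance 0 / 1 / ≥2 — label noise in both directions,
emulating incomplete and partly erroneous pharmacovigilance catalogs. Each
drug also receives 2–5 other side-effect terms, with labelled drugs drawing
from a shared half of the vocabulary so that vocabulary-overlap statistics
have signal. Ground truth records each drug's realized mean distance to
each module.

What the generator does **not** emulate: biological annotation content,
interactome motif structure and clustering coefficients, correlated
drug-target profiles (polypharmacology), and module overlap between disease
and side effect. Passing tests therefore demonstrate statistical
correctness and recovery of planted structure, not performance on real
pharmacological data.

## Problem sizes and numerical choices

Multi-seed studies in the test suite run 20 scenario seeds with 300 null
replicates per proximity/module call — enough for stable z-scores at the
planted effect sizes while keeping the full suite under a few minutes. The
null-calibration study draws 1000 test sets against one shared
2000-replicate null on a 500-node graph; sharing is exact because every
test set has the same per-bin demand profile as the base set, hence the
same null distribution. The calibration uses the total-edge-count metric
with 40-gene sets: the most nearly continuous of the three module metrics,
where the normal-tail p is a fair approximation (LCC size on small sparse
subgraphs is too discrete to calibrate at the 5% tail).

Tie-breaking and degenerate inputs: sd = 0 nulls yield z = 0 (observation
at the mean) or ±∞ sentinels with p reported as 1/n_reps; empty networks
are returned with an explanatory status, never raised mid-pipeline; an
entity that maps to nothing on the interactome is flagged unusable rather
than silently kept or dropped.
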