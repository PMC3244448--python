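# Methods

`spanet` reconstructs a process-specific protein–protein interaction (PPI)
network from a seed set of curated proteins, statistically filters it
against a degree-preserving null model, and dissects the filtered network
into fixed-length signaling routes and their step-specific key proteins.
This note records the model, the parameters that matter, the numerical
choices, and what the synthetic test bed does and does not demonstrate.

## Selective-permissibility expansion

The core set C is the list of proteins curated to the biological process
under study. Their Gene Ontology annotations are pooled aspect-wise
(biological process, molecular function, cellular component) into the
*annotation collection*, which always also contains the three root
"unknown" sentinels (`biological_process`, `molecular_function`,
`cellular_component`). Expansion iterates: every interactor of the current
member set is admitted if its own annotation falls within the collection;
the loop stops at the fixed point, and the result is the induced subgraph
of the source interactome on the member set.

Because admission depends only on the candidate's annotation, the fixed
point is independent of examination order and of the ordering of the core
list; membership is monotone over iterations, and every member is
reachable from the core inside the result.

Two permissibility readings are offered for multiply-annotated proteins.
The default, `any`, requires at least one collection term per aspect; it is
the reading consistent with the expansion's stated purpose of not excluding
poorly annotated proteins (the sentinels always match, so a protein is
never dropped for missing curation). The stricter `all` mode requires every
term of every aspect to be in the collection. Both modes are first-class
and covered by the planted-truth tests.

Literal term matching is used throughout — no ancestor closure over the GO
graph. This mirrors how annotation collections are built in this style of
reconstruction and keeps the admission criterion transparent; it also means
a protein annotated only with a child of a collection term is not admitted.

## Network tuning by betweenness centrality

Automated reconstruction admits false positives. Tuning asks, node by node,
whether the node's unnormalized shortest-path betweenness centrality (BC)
in the reconstructed network differs from its BC in R = 100 degree-
preserving rewirings (double-edge swaps, 10 accepted swaps per edge, which
is a standard mixing heuristic). A node that fails the test is discarded
with its incident edges; significant nodes are kept even if isolated
(`prune_isolates` is available, off by default), and the core can be made
immune with `protect` (off by default).

The per-node test is a dependent two-tailed t-test on the paired
differences d_i = BC_obs − BC_null,i:

    t = mean(d) / (sd(d)/√R),  df = R−1,  keep iff p < α   (α = 0.001)

Degenerate cases are resolved by the test's own logic: all d_i = 0 means
the node's flow role is identical in every rewiring (p = 1, discard);
zero spread with nonzero mean is an unambiguous difference (p = 0, keep).

**Calibration caveat (important).** Pairing a *single* observed value
against R null draws makes this statistic strongly anti-conservative as a
test of "the observation is a typical null draw": mean(d) has variance
σ²(1+1/R) while sd(d)/√R estimates σ/√R, so under that reading t is
inflated by ≈√(R+1) and the realized rejection rate at nominal α = 0.1 is
about 0.86 (measured by Monte-Carlo in the test suite). What the paired
statistic actually tests is whether the observation equals the *mean* of
the null ensemble — an ensemble-average reading under which most
genuinely structured nodes are significant and only flow-indifferent nodes
are removed; with it, roughly a quarter to a third of a reconstructed
network's nodes are typically discarded at α = 0.001. The calibrated
alternative (`statistic="ensemble"`, the prediction-form statistic
t = mean(d)/(sd(d)·√(1+1/R))) is provided and its nominal type-I error is
verified by simulation; it is far more aggressive in removal and is not
the default. No multiple-testing correction is applied across nodes — the
protocol is per-node α by design.

The discard sets nest with α: since p-values are fixed by the seed,
keep ⟺ p < α implies the discard set at α = 0.001 contains the one at
0.01, which contains the one at 0.1.

**Null-ensemble quality control.** Each rewiring's BC distribution is
summarized by its bias-corrected sample skewness — the monitored trait,
chosen because real PPI networks have strongly right-skewed BC
distributions. The ensemble is charted with a Shewhart individuals chart:
center line = ensemble mean of the skewness values, control limits at
±3σ (σ = ensemble standard deviation); flagged rewirings are regenerated
with fresh seeds (bounded rounds), and exhaustion raises an explicit
error. A variant that pins the center line to the *reference network's*
skewness is available (`chart_center="reference"`), but it diverges
whenever rewiring shifts the skewness systematically — on small synthetic
networks the real network's skewness routinely sits outside the rewired
ensemble's ±3σ band, in which case no amount of regeneration can clear
the flags; this is why the convergent ensemble-centered chart is the
default.

## Topology

Summary statistics follow the conventions of PPI-network topology tables:
average degree 2|E|/|V|; critical path length = mean shortest-path length
over connected ordered pairs (within components, when disconnected);
diameter on the largest component; mean local clustering with degree-<2
nodes contributing 0. The degree distribution P(k) and the degree-
conditional clustering spectrum C(k) are fitted by ordinary least squares
on log10–log10 axes over the *raw* (non-binned, non-cumulative) empirical
points, reporting the regression R²; the fitted exponents γ (scale-free)
and w (hierarchical) are the negated slopes. Raw OLS fitting is the
classical style these exponents are reported in; maximum-likelihood
power-law estimation is deliberately out of scope, so the exponents should
be read as descriptive regime indicators, not calibrated estimates. Fits
require at least three distinct positive abscissae; a regular graph or a
triangle-free graph is reported as unfittable rather than silently
skipped.

Hub listings are top-N by degree with ties broken by identifier;
robustness probes report the connected-component count after deleting one
node, and its fold change against the intact count.

## Linear paths

A linear path of node-length L (default 6: input, four intermediates,
output; five steps) is a simple path in the tuned network. Enumeration is
an exhaustive depth-first search with visited-set pruning plus an exact
feasibility bound (a node whose hop distance to the output exceeds the
remaining edge budget cannot complete a path). The bound only removes
provably dead branches, so the enumeration remains exact and complete;
paths are emitted in lexicographic order, making every downstream artifact
deterministic. Enumeration is streaming and aborts with an explicit
explosion error (carrying the partial count) the moment the cap (default
2×10⁶) is exceeded. Only exact-length paths are enumerated; shorter routes
between the same endpoints are a different spectrum, not a subset of this
one.

Spectrum metrics follow the standard activity table: path count, protein
union size (endpoints included), unique proteins (present in exactly one
input's union, computed per output), core protein coverage
CPC = 100·|union ∩ core∩V|/|core∩V| and overall coverage
OPC = 100·|union|/|V|, both against the analyzed network.

## Step-specific key proteins

For one input/output pair, the participation percentage of a protein at
position p is the percentage of the spectrum's paths carrying it exactly
there. The decomposition of a position's participation values into a key
set works on a frequency histogram: k = round-half-up(√n) equal-width bins
(minimum 2) over (0, f_max], left-open right-closed; cumulative
percentages M_i (M_0 = 0, M_k = 100); increments D_i; fold changes
F_i = D_i/D_{i+1} for i = 1..k−1, undefined when D_{i+1} = 0 and then
excluded from ranking. Bins are ranked by fold change (descending, ties to
the smaller index) and the first bin whose strict tail — the proteins in
bins above it — holds at most 10% of the n proteins (inclusive) becomes
the threshold; the tail is the key set. The forward fold change peaks
where the cumulative curve flattens, which is exactly the boundary between
the low-participation bulk and the high-participation tail. The reciprocal
reading D_{i+1}/D_i is available as `fold="reciprocal"` for comparison.
When no bin qualifies (single-occupied-bin and similar pathological
histograms), the fallback takes the top ⌊0.10·n⌋ proteins by participation
(ties by participation, then identifier) and flags the decomposition; the
audit trail records every candidate bin and verdict.

Bait-and-hit iteration: step 1 decomposes position 2 of the full spectrum;
paths whose position-2 member is a key are kept; step 2 decomposes
position 3 of the subset; and so on through position L−1. A step whose key
set is empty (flagged fallback on a degenerate subset) leaves the subset
unfiltered rather than emptying it — the audit trail preserves the
degeneracy. Subset sizes are non-increasing by construction.

The heart network pools every pair's step key sets with the inputs and
outputs and takes the induced subgraph of the analyzed network; per-pair
coverage is the percentage of that pair's full spectrum whose four
intermediates all lie inside the heart.

## Synthetic test bed

The generator produces what the pipeline needs to be falsifiable without
external downloads:

* **Interactome** — preferential attachment (n nodes, `attachment` edges
  per arrival), giving a connected graph with a heavy-tailed degree
  distribution, the regime real interactomes occupy. Node labels are a
  seeded permutation so identifiers carry no degree information. Exact
  degree-exponent matching is not a goal; fits on these graphs are regime
  checks.
* **Planted admissible region** — stochastic breadth-first growth from the
  core (each frontier neighbor admitted with probability `admit_prob`,
  default 0.65 in the packaged fixture). Annotations are then assigned so
  a protein passes the permissibility check *iff* it is in the region:
  admissible proteins draw only core-pooled terms (with `unknown_prob`
  = 0.1 per aspect of being the sentinel), every other protein receives a
  fresh out-of-vocabulary term as the only term of one randomly chosen
  aspect — the minimal violation, which defeats both permissibility modes
  at once. The expansion-equals-truth property is the generator's defining
  contract and is tested across seeds and modes.
* **Planted corridors** — a backbone chain between an input and an output,
  `corridor_width` decoys per intermediate position attached to the
  backbone at adjacent positions (and to the next position's decoys,
  stopping before the last intermediate position so the backbone dominates
  everywhere), plus a chaff tier: per position, ~10·(width+1) proteins
  attached to the previous backbone protein with dedicated one-path tail
  chains to the output. The three tiers make positional participation
  histograms realistic (a dominant backbone, mid-tier decoys, a
  low-participation bulk). The chaff count is not cosmetic: the 10% rule
  can only accept a threshold bin when the corridor tier is ≤10% of the
  participants, so a corridor without a bulk tier is unrecoverable by
  construction — an instructive miniature of why the decomposition needs
  path-rich networks.
* **Packaged study fixture** — a 300-node interactome (attachment 3), a
  high-degree core, two input→output corridors between core proteins
  (width 3, no chaff — the organic paths of the admissible region supply
  the bulk tier), annotations with the corridor forced admissible. This is
  the fixture the end-to-end determinism check and the acceptance script
  run on.

What the fixture does **not** emulate: curated-annotation sparsity
patterns, interaction false-positive structure, assortativity, and —
importantly — the path-richness of a full-size interactome. At 300-node
scale the tuned network yields hundreds (not tens of thousands) of paths
per pair and ~10–30 participants per position, so later bait-and-hit steps
often hit the flagged fallback with zero or one key and the heart network
is small with near-zero path coverage. Passing tests therefore demonstrate
the correctness and determinism of the machinery, not that a 300-node
surrogate reproduces full-scale biological coverage figures.

## Numerical choices and tie-breaks

* Bin assignment uses ceil(f/width) with a 10⁻¹² relative guard; the tail
  of a threshold bin is defined by bin index (strictly above), never by
  float comparison against the edge.
* "Did not exceed 10%" is inclusive (≤).
* All rankings break ties deterministically: bins by smaller index, hubs
  and fallback keys by identifier.
* Betweenness is left unnormalized; only within-run consistency matters
  for the paired test.
* Skewness of a zero-variance BC sample is defined as 0.
* Every stage's randomness flows through explicit integer seeds
  (sub-seeds drawn below 2³¹); two runs with the same configuration
  produce byte-identical output files.
* Rewiring that finds no valid swap (e.g. a triangle) returns the graph
  unchanged with a warning; a partially met swap budget also warns.

## Known limitations

* Exponents from raw log-log OLS are biased estimators; they are reported
  for regime comparison only.
* The paired test's anti-conservatism (above) is inherited by design from
  the tuning protocol; use `statistic="ensemble"` for a calibrated
  outlier test.
* Path enumeration is exponential in L; the cap guards memory, not time.
  Practical lengths are L ≤ 7 on networks of a few thousand nodes.
* The expansion treats GO terms as opaque strings; curation differences
  between annotation releases change results.
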