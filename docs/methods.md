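# Methods

## Model and procedure

The pipeline treats a pathway as a directed graph over gene symbols whose
edges carry a sign: +1 for activation/expression relations, −1 for
inhibition/repression. All other KGML relation subtypes (binding,
association, indirect effects, …) carry no directional expression
semantics for this statistic and are dropped on load, with a warning.
KGML entries listing several gene symbols are split into one node per
symbol, each inheriting the entry's relations; map and compound entries
and self-loops are discarded. Gene symbols are upper-cased everywhere and
matching between pathways, datasets and annotations is by exact symbol.

A **subpathway** is a simple (repeat-free) directed path inside one
pathway; enumeration never crosses pathway boundaries. "All possible
paths" is implemented as all simple directed paths with a configurable
node-count window, default 2–10 nodes: uncapped enumeration is exponential
and 10 nodes covers the longest chain the method is normally asked to
report. Enumeration additionally enforces a path-count budget (default
10⁶) and fails loudly rather than degrade silently. Output order is
deterministic — lexicographic by pathway id, then by the node chain — so
downstream tie-breaking is reproducible.

**Consistency statistic.** Direction of a fold-change ratio *r* (case
over control, strictly positive): up if *r* > 1, down if *r* < 1, neutral
at exactly 1. An activation edge is consistent when its endpoints share a
direction, an inhibition edge when they oppose; any neutral endpoint
breaks consistency. The chain statistic is the count of consistent edges.
Magnitudes deliberately do not enter: the statistic is invariant to the
dynamic range of the platform, which is what makes chains comparable
across datasets. The boundary at exactly 1.0 gets its own neutral state
because a ratio of 1 carries no direction; with continuous data it occurs
with probability zero, but degenerate inputs (imputed or rounded tables)
should not silently count as agreement.

**Null models.** Two are shipped, selected by flag:

* *Binomial* (default): each edge agrees by chance with probability ½, so
  P = P(X ≥ k) with X ~ Bin(e, ½) for k consistent of e edges. For a chain
  (a path graph), edge agreements under independent random directions are
  genuinely independent, so this null is exact, deterministic and fast.
* *Permutation*: observed fold-changes are reassigned to genes uniformly
  at random over the dataset's whole gene universe (equivalently, an
  ordered sample of k distinct values is drawn per replicate); the
  consistent-edge count is recomputed and P is the add-one estimator
  (1 + #{perm ≥ obs}) / (n_perm + 1), which can never return 0. This null
  preserves the dataset's empirical up/down imbalance, which the binomial
  null idealises away. An exhaustive mode enumerates every ordered
  assignment and returns the exact fraction; it is intended for small
  universes and for validating the Monte-Carlo mode.

Chains containing genes absent from a dataset are skipped (and counted in
the log), not imputed: no imputation rule is defensible at the
fold-change level, and a partial chain is a different hypothesis.

**Significance and networks.** Chains with P strictly below α (default
0.05) are retained; no multiple-testing correction is applied by default,
matching the method's published filtering convention, but a
Benjamini–Hochberg helper is available for stricter use. The per-dataset
disease network is the union graph of surviving chains: one node per
gene, one edge per distinct (source, target, sign), annotated with the
contributing pathway ids and a support count. Top-k summaries (default
k = 100) sort by ascending P with ties broken lexicographically by
(pathway id, formatted chain string) — the ranking is a total order, so
reports are bit-identical across runs.

**Cross-disease comparison.** The direction-opposed common genes are
those measured in *every* dataset that are up in the cancer-like dataset
and down in every AD-like dataset, or the mirror; the two sets are
disjoint by construction. The default up/down cutoffs are exactly 1.0
(any deviation counts) and are exposed as flags, since any other Venn
cutoff is a modelling choice the user should make explicitly. Category
assignment lays those genes out against user-supplied GMT gene sets; the
repository bundles a five-category inflammation-term GMT (16 genes) as a
worked reference input, with genes allowed to sit in several categories
and the distinct-gene union reported deduplicated. Gene→pathway usage
cross-tabulates each opposed gene against the pathway ids of the network
chains containing it, per network, alongside its direction per dataset.

**Over-representation.** The enrichment stage is a plain one-sided
hypergeometric (Fisher exact, greater) test of query/category overlap
against an explicit universe, with categories intersected with the
universe before testing and results ordered by (P, category name). It is
an open, deterministic stand-in for proprietary enrichment engines, not a
re-implementation of any of them.

## Synthetic benchmark

The generator emulates the three-dataset study design the comparison
stage expects: one cancer-like and two AD-like case/control datasets over
a shared universe (default 600 genes), plus random signed pathway graphs
(default 4 pathways of 25–40 genes, edge density 0.05, inhibition
fraction 0.25). Expression is generated per sample and arm on the log2
scale — cases at N(planted effect, noise_sd), controls at N(0, noise_sd),
default 10 samples per arm — and the fold-change is the ratio of
geometric means, so the sampling noise of real ratio tables is
reproduced. Defaults: planted |log2 FC| = 1.0, noise_sd = 0.25.

Planted structure, recorded in a truth object: (a) chains embedded
verbatim in the pathway graphs whose genes receive coherent directions
(head direction propagated through the edge signs) in their designated
datasets, making the chains fully sign-consistent there; (b) 16 genes
split between up-in-cancer/down-in-both-AD and the mirror. Planted chains
default to 6–8 genes because the sign null makes shorter chains
undetectable: a fully consistent chain of e edges has P = 2⁻ᵉ, so 5 edges
is the minimum that clears α = 0.05. Unplanted genes have median
fold-change 1 by construction.

What the benchmark does *not* emulate: probe-level microarray structure,
batch effects, correlated co-expression beyond the planted chains, and
realistic pathway topology (random digraphs are denser in long paths than
curated maps). Passing recovery tests therefore demonstrates that the
machinery detects the signal it defines, under its own noise model — not
that any particular biological claim reproduces on real GEO data.

## Calibration and discreteness

The permutation test's statistic is integer-valued, so attainable
significance levels are coarse: for a chain of e edges the smallest tail
is ≈ 2⁻ᵉ. At α = 0.05 a 6-node (5-edge) chain is the shortest with a
non-empty rejection region, and there the attainable level is
2⁻⁵ ≈ 0.031. The calibration benchmark
(`null_chain_type1_rate`) therefore uses 6-node null chains over a
500-gene i.i.d. log-normal universe; the measured type-I rate on 1,000
chains sits near 0.03, and for 4-node chains the rate is exactly 0 — the
test is conservative, never anti-conservative. Equivalent behaviour holds
for the binomial null by the same arithmetic.

## Numerical and design choices

* Fold-change round-tripping uses Python's shortest-repr float
  formatting, so parsed report chains reformat bit-identically.
* The printed "∣" (U+2223) arrow glyph is accepted on input and
  normalised to ASCII "|" on output.
* Permutation sampling is vectorised (random-key argsort) and seeded via
  `numpy.random.SeedSequence`; batch scoring spawns one child seed per
  chain, so results are reproducible and independent of chain order
  evaluation details.
* The significance filter is strictly `p < alpha`, so a chain at exactly
  0.05 is excluded.
* KGML parse failures report the byte offset of the malformed construct;
  conflicting activation/inhibition annotations on the same ordered gene
  pair are an input error, never silently resolved.
* Exit codes of the CLI: 0 success, 2 usage error, 3 data validation
  error.

## Problem sizes used by the test and acceptance runs

The shipped test suite and the acceptance script run the full machinery
at deliberately moderate sizes chosen as representative rather than
exhaustive: enumeration cross-checks on 100 random digraphs of ≤ 8 nodes;
calibration on 1,000 null chains × 999 permutations over a 500-gene
universe; benchmark recovery on the default 600-gene, 4-pathway
configuration with paths capped at 8 nodes (~23k subpathways). These
sizes exercise every code path; scaling any of them up is a matter of the
corresponding flags.

## Known limitations

* The published per-chain P-values of the method this package
  re-implements are not reproducible from sign information alone (they
  imply a statistic in which magnitudes enter); this package documents
  and ships its own two nulls instead.
* Ranking among equally significant chains is dominated by chain length
  under the binomial null (longer fully consistent chains always rank
  higher); planted shorter chains can be displaced from a top-k summary
  by chance long chains in dense graphs, even when correctly detected as
  significant.
* No probe-to-gene mapping, no KEGG REST access: inputs are fold-change
  tables and KGML files the user supplies.
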