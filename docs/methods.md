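# Methods

This note records the statistical model behind each analysis, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical and design choices made where the design
was genuinely open.

## Data model

An omics layer is a feature × condition matrix plus a set of significant
("relevant") features supplied by the user's upstream statistics; the
package performs no differential testing of its own. Missing values are
kept missing (NaN) and excluded pairwise from correlations and from
metagene standardization — silent zero-imputation would bias every
downstream test. Pathways are node/edge sets whose nodes (gene or
compound) carry member feature identifiers; features are mapped to the
lowest pathway level by identifier match against node members. No
identifier translation is attempted: cross-database reconciliation
(KEGG compound vs ChEBI, probe vs gene symbol) is the caller's
responsibility. The metabolic graph is the union of pathway connectivity
over the selected databases, merged on node id, undirected and
unweighted; reaction directionality is discarded because neighborhoods
are defined by step counts, not flux direction.

The KGML reader covers entries, relations and reactions only. Gene and
ortholog entries become gene nodes, compound entries compound nodes, map
entries are dropped; each reaction links its catalyzing gene entries to
its substrate and product compounds, and every relation contributes one
edge. How gene–compound edges should be derived from other databases'
internal formats is not standardized; the reaction-based rule is this
package's convention.

## Pathway enrichment

Per layer and pathway, the one-sided hypergeometric over-representation
tail P(X ≥ k), X ~ Hypergeom(N, K, n). The per-layer statistic is a
convention (the classical Fisher exact over-representation test); the
background N defaults to the layer's features mapped to ≥ 1 pathway of
the selected databases ("annotated"), the standard guard against
annotation bias, with `background="measured"` as the alternative. Layer
P-values are combined with Fisher's method, −2 Σ ln pᵢ against χ² with
2m degrees of freedom, where m counts only layers with ≥ 1 mapped
measured feature in the pathway — imputing P = 1 for absent layers would
dilute real signal, so degrees of freedom vary per pathway. BH correction
is applied within each source database rather than pooled, because
pathway definitions overlap heavily across databases. P-values are never
reported as exactly zero; they are floored at the smallest positive
normal double with a warning.

## Metabolite hub analysis

The step-s neighborhood (s = 1..4) of a compound is every gene node
within shortest-path distance ≤ s over the heterogeneous graph, with
intermediate nodes of any kind — cumulative shells, not exact-distance
rings. Two tests:

* **Binomial.** With p₀ the global DEG proportion of the expression
  layer, the neighborhood DEG count is referred to the upper tail of
  Binomial(n_measured, p₀). Only measured genes enter n — DEG status is
  undefined for unmeasured neighbors, which are reported but untested.
* **Percentile.** The neighborhood DEG proportion of every compound in
  the graph (measured or not, but with ≥ 1 measured neighboring gene)
  forms the reference distribution; the queried metabolite's midrank
  percentile — (count strictly below + half the tied count)/total × 100 —
  is reported, so a full tie yields 50.

The default scope tests significant metabolites (DEMs) only, with
`scope="all"` for every measured metabolite; BH correction runs across
the tested set. The reference distribution could alternatively be
restricted to measured metabolites; using the whole network is this
package's reading of "overall", and is documented rather than claimed
equivalent to any other tool. There is no privileged default step; the
CLI requires `--step` explicitly.

## Metabolite class activity

Upper-tail exact binomial on each class's significant-compound count at a
user threshold. When no threshold is given, the overall significant
fraction among all measured metabolites is used (not the mean of
per-class fractions — the two readings differ when class sizes vary;
the overall fraction is the less noisy estimator and treats unclassified
metabolites consistently, since they still inform the null). Classes may
overlap and are tested independently; BH runs across classes. A fully
significant (or fully non-significant) metabolite panel leaves the
default null undefined, and the run demands an explicit threshold.

## Trans-regulatory analysis

Regulator→target pairs come from a user mapping. Correlation is computed
across shared condition labels, pairwise-complete over missing values,
requiring ≥ 3 complete pairs; the default coefficient is Pearson (no
coefficient is canonical for this filter; Spearman is available).
Retention: r ≥ t (positive mode, e.g. activating TFs), r ≤ −t (negative
mode, e.g. miRNA repression), |r| ≥ t (both). Unretained pairs keep a
recorded reason (unmeasured member, too few complete pairs, zero
variance, below threshold).

Pathway-level scoring counts either regulators (with ≥ 1 retained target
in the pathway) or regulated targets (with ≥ 1 retained regulator,
reached through gene nodes only), each against its universe with the
shared hypergeometric kernel and BH across pathways. In targets mode a
target counts as significant when at least one of its retained
regulators is significant. Realizing the "enrichment score" as a
hypergeometric test is this package's convention.

## Metagenes

Pathway nodes with **more than four** matched measured features of one
layer are compressed. Profiles are standardized per feature (zero mean,
unit variance over conditions, missing excluded then mean-imputed),
clustered by correlation distance (1 − Pearson) with average linkage;
k ∈ 2..min(5, n − 1) is chosen by maximum mean silhouette, collapsing to
k = 1 when the best silhouette is below 0.25 (an undistinguished profile
cloud is one trend, not many). Each cluster's metagene is the first
right singular vector of its standardized profile matrix (the dominant
condition pattern), sign-oriented to correlate positively with the
cluster mean, re-standardized, and reported with PC1's variance share.
The k cap of 5 reflects how many trends a map node can visually carry
and is configurable. Every step is deterministic; no seed is involved.
The clustering + PC1 realization is this package's design — "one
metagene per profile type" admits several constructions, and no
equivalence with any server implementation is claimed.

## Synthetic fixtures

The generator emulates the *structure* the analyses consume, not
biochemistry: each pathway is a gene–compound bipartite chain with random
chord edges, and compounds are re-drawn from the global pool with
probability 0.25, so pathways merge into a connected graph with hub
structure. Defaults: 20 pathways, 6–12 genes and 4–8 compounds each, 6
conditions, background DEG rate 0.1 (matching the regime in which the
hub test is meant to operate), DEM rate 0.3, 10 regulators × 6 targets,
5 classes, plus 15 measured genes mapped to no pathway. Significance is
i.i.d. Bernoulli at those rates; significant features receive a scaled
linear-trend profile so that correlation-based analyses see signal, and
all profiles carry unit-variance Gaussian noise.

Planted effects override locally: **hub** raises the DEG rate among one
compound's step-1 genes (auto-pick: the highest-degree compound, topped
up with extra gene edges to ≥ 15 measured neighbors — a planted hub is,
by construction, a hub) and flags that compound significant so the
default scope tests it; **pathway** raises the DEG rate of one pathway's
genes to 0.7 by default (auto-pick: the largest pathway — a weak effect
in a six-gene pathway is statistically invisible and would make recovery
checks meaningless); **class** raises one class's DEM rate; **metagene**
injects three +u and three −u profiles (u a standardized half-sine,
noise σ = 1 − strength) into one dense node; **regulatory** redirects
significant regulators' targets into one pathway and copies the
regulator profile onto them with σ = 0.1 noise (correlation ≈ 0.995).
Every file derives from its own random stream spawned from the master
seed, so outputs are byte-stable per seed and adding a new output never
perturbs existing ones. `truth.json` records planted locations and
realized counts.

What the generator does **not** emulate: realistic pathway size and
degree distributions, stoichiometry, correlated significance between
layers, batch effects, or organism identifier spaces. Passing recovery
tests therefore demonstrates the statistical machinery under its own
assumptions, not performance on any real dataset.

## Calibration checks and problem sizes

The type-I checks run each test family on 200 null fixtures and compare
the 0.05-level rejection fraction with exact binomial 99% bounds. All
three tests are discrete and exact, hence conservative: the achievable
level just below 0.05 falls short of 0.05 by about half the local
p-value grid spacing, which shrinks as the counting sizes grow. The null
fixtures are therefore sized for near-nominal achievable levels —
pathways of 700–800 genes (single layer, so the combined P inherits one
fine grid rather than the product of a fine and a coarse one),
step-3 neighborhoods of ~280 measured genes with p₀ estimated from a
6000-gene unannotated pool (decoupling the estimate from the
neighborhoods), classes of ~150 compounds — at significance rate 0.5,
which maximizes the binomial variance and hence grid resolution. Pooled
test counts per family (≈ 400–600) keep the exact bounds wide relative
to the residual discreteness deflation. Recovery checks use 100 fixtures
per planted effect at the default study conditions above.

## Known limitations

* Per-layer enrichment assumes feature-level independence within a layer;
  co-expression inflates significance as in any over-representation test.
* Fisher's combination assumes independence across layers; layers
  measuring the same biology are positively dependent, making the
  combined P anti-conservative in that direction.
* The percentile test is descriptive (a rank, not a P-value) and is not
  multiplicity-corrected.
* Hub neighborhoods treat all edges equally; a step through a promiscuous
  currency metabolite counts like any other.
* The metagene cluster count is bounded by the silhouette heuristic;
  patterns subtler than the 0.25 cutoff merge into one trend.
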