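# Methods

## The levelled knowledge graph

Nodes are stratified into five levels — compound, reaction, enzyme, module,
pathway — with the fixed ordering compound < reaction < enzyme < module <
pathway.  The working schema allows edges between adjacent levels plus
enzyme–pathway shortcuts; the loader accepts any cross-level edge but warns
on non-schema pairs, and rejects same-level edges and self-loops outright
(same-level edges would leave the directed view undefined).  The undirected
view drives heat diffusion; the directed view, with every edge oriented
toward the strictly higher level, drives PageRank and the reachability rule
for pathway membership: a compound belongs to a pathway iff the pathway is
reachable from it.  The enzyme–pathway shortcut matters here because it lets
a pathway or module be reported with no compound members at all, purely
through enzyme-level relationships.

Loading restricts to the largest connected component by default, matching a
curated single-component working graph.  Identifiers are opaque strings; no
database-prefix validation is done, so synthetic identifiers behave exactly
like real ones.

## Heat diffusion

The conductance matrix is `KI = L + B` with `L` the unnormalised Laplacian
and `B` the diagonal pathway-boundary indicator.  Temperatures solve
`KI·T = G`.  We use the positive-temperature convention `T = (L+B)⁻¹G`: the
literal composition of a positive-semidefinite `L` plus positive diagonal
`B` with a leading minus sign would make all temperatures negative, so the
minus sign occasionally seen in front of `KI⁻¹` is treated as a
sign-convention artefact.  This convention reproduces every property the
method relies on: temperatures are nonnegative (maximum principle), warm
near the sources, and conserve flow — `Σ_i B_ii·T_i = n_in` exactly, every
unit of injected flow leaving through the pathway boundary.  `KI` is
nonsingular iff every connected component holds a pathway node; the system
constructor enforces this with an explicit error.

Solves go through a cached sparse LU factorisation; the response matrix
`R = KI⁻¹` restricted to compound columns is obtained by multi-RHS solves
against unit vectors.  Column `j` is the temperature field of the unit input
`{j}`, and linearity (`T(S) = Σ_{j∈S} R·e_j`) is what makes the analytic
null tractable.

## PageRank

Personalised PageRank on the directed view with damping `d = 0.85` (the
value of the original web-ranking formulation), restart distribution uniform
over the input compounds.  Pathways have no out-edges in the upward
orientation, so dangling mass must go somewhere: we redistribute it to the
restart vector, keeping the process a restart walk anchored on the input.
A useful consequence: the stationary distribution is algebraically the
L1-normalisation of `v·(I − dP)⁻¹`, so the package offers both power
iteration (L1 tolerance 1e−12, at most 1000 iterations) and an exact sparse
linear solve; they agree to solver tolerance and the solver is chosen
automatically by graph size.  All edges are unweighted; each out-edge is
equally likely.

For the analytic null, the PageRank statistic is taken on the
pre-normalisation linear scale, `u = R_pr·X` with response columns
`(1−d)(I − dPᵀ)⁻¹e_j`, which is exactly linear in the input indicator.  The
final sum-to-one normalisation is a per-input scalar; z-scores are invariant
to per-node affine scalings but not to that input-dependent scalar, so norm
mode works on the linear scale while the displayed score vector remains the
normalised distribution.  In sim mode observed and null scores are both
sum-to-one PageRank vectors, so no such distinction arises.

## The null model and normalisation

The null input is `n_in` compounds drawn uniformly at random without
replacement.  The indicator vector has dependent Bernoulli entries with
mean `p = n_in/N`, variance `p(1−p)` and pairwise covariance
`−p(1−p)/(N−1)`; each covariance row sums to zero because the draw size is
fixed.  Null moments of the scores follow row-wise from the response matrix
(`s1 = Σ_j R_ij`, `s2 = Σ_j R_ij²`):

```
μ_i = p·s1_i,   σ_i² = p(1−p)·s2_i − p(1−p)/(N−1)·(s1_i² − s2_i)
```

without materialising the full covariance.  Nodes with `σ_i = 0` (for
example when `n_in = N`, or a node whose response row is constant) are
flagged and excluded from ranking rather than mapped to infinite z-scores.

Monte-Carlo normalisation uses the corrected empirical tail
`p_i = (r_i + 1)/(n_perm + 1)` with `r_i` the number of permutations whose
null score is ≥ the observed one.  Tail counting uses a 1e−9 slack so exact
score ties — e.g. integer hit counts reproduced by a float linear solve —
are counted as ties instead of being split by 1e−15 solver noise.  Each
permutation draws from its own counter-derived RNG stream
(`default_rng((seed, t))`), so results are reproducible and increasing
`n_perm` never reshuffles earlier draws.  An exhaustive variant enumerates
every possible draw when `C(N, n_in)` is small; on bipartite
compound→pathway toys it recovers the hypergeometric tail exactly, which is
the precise sense in which classical ORA is a special case of the pipeline.

Consensus over `n_vote` independent Monte-Carlo runs keeps a node iff it
appears in at least `⌈(n_vote+1)/2⌉` of the per-run top-k sets — a strict
majority, tie-free for the default odd `n_vote = 9`.  The consensus size may
therefore differ from `k`.

Defaults: `k = 250`, `n_perm = 10,000`, `n_vote = 9`.

## Ranking and the reported subgraph

Top-k selection is deterministic: z-statistic descending (or p ascending),
ties broken by descending raw score, then lexicographic node id.  Input
compounds are eligible for the subgraph; no special exclusion.  The induced
undirected subgraph is summarised by its number of weak connected components
and largest-component size — spurious selections resemble random node picks
in a sparse graph (many small components), real perturbations concentrate
into large ones.  The pathway table reports, per selected pathway, its
statistic, raw score, reachable-compound count and hit count.  Solutions are
compared by the overlap coefficient `|G1∩G2| / min(|G1|,|G2|)`.

## Synthetic graph generator

The generator emulates the shape of a curated KEGG-style graph: five levels
(default sizes 288/178/1149/4699/3869), connectedness, and a heavy-tailed
degree distribution.  Within each level pair, source nodes draw
`1 + Poisson(rate−1)` targets by preferential attachment
(probability ∝ `(degree+1)^α`, default `α = 1`) with targets activated on an
evenly spaced schedule over the edge sequence — a Yule-type growth that
yields approximately power-law target degrees.  Default edge rates per
source node are reaction→compound 2.5, enzyme→reaction 3.0, module→enzyme
3.0, pathway→module 1.5 and pathway→enzyme 1.0.  These rates were chosen so
that the full-scale graph shows a maximum-likelihood degree-tail exponent
near 2.1 (within the scale-free range 2–3 reported for real curated
metabolic knowledge graphs) and so that each pathway reaches a specific
minority of compounds (roughly 5–15% at benchmark scale) rather than most of
the graph — pathway specificity is what makes recovery benchmarks
meaningful.  Remaining disconnected components are merged by adding single
schema-respecting edges to the main component, preferring high-degree
partners.  Generation is bit-reproducible given a seed.

What the generator does *not* emulate: real annotation semantics (reaction
stoichiometry, enzyme promiscuity patterns, module curation), correlated
pathway overlap beyond what shared hubs induce, and identifier systems.
Passing benchmarks on these graphs therefore demonstrates properties of the
*method* under realistic topology, not database-specific results.

## Signal benchmark

Every signal is a list of `n_in = 35` compounds drawn without replacement
(successive weighted draws with renormalisation).  Three schemes: `uniform`
(noise; every compound equal), `proportional` (compounds reachable from the
target pathway are `k_i = 10` times more likely — the generative assumption
of Fisher's exact test), and `network` (probability ∝ the target pathway's
heat-response row over compounds, so nearby-but-outside compounds carry
signal too).  The metric is the target pathway's normalised rank `r/n_p`
(1/n_p best, 1 worst).  Ties are broken uniformly at random under a seeded
RNG — mid-ranks would hide the rank asymmetry caused by blocks of pathways
tied at zero hits, random ranks reproduce it.  Fisher's exact test is the
one-tailed hypergeometric tail on reachability membership, identical to the
one-sided 2×2 test.  Monte-Carlo variants are excluded from the benchmark;
the parametric z-score route represents each scorer.

The bias study draws noise signals and averages each pathway's rank across
them; since ranks within a signal are a permutation, the grand mean over
pathways equals `(n_p+1)/(2n_p)` exactly, and per-pathway deviations from
0.5 expose topology-driven favouritism.  The benchmark default graph scales
the KEGG level sizes down about tenfold (29/18/115/470/387) so a full sweep
over all pathways runs in seconds; sizes are configurable.

## Resistance-distance validation

Reported reactions are validated against an independent compound set on the
reaction–compound graph: the largest connected subgraph induced on reaction
and compound nodes.  The metric is the effective resistance
`Ω(i,j) = L⁺_ii + L⁺_jj − 2L⁺_ij` (unit resistors; `L⁺` the pseudoinverse of
the subgraph Laplacian), a metric that accounts for all parallel paths and
is therefore robust to hub-mediated shortcuts that dominate shortest-path
distances in metabolic networks.  A grounded-Laplacian solve (fix one node,
inject unit current) is kept as an independent computation route; both agree
to 1e−8.  Queries on nodes outside the largest component are dropped with a
warning.

The comparison reports, per target compound, mean ± SD of distances from
(a) all reactions, (b) the first neighbours — all reactions adjacent to any
input compound — and (c) each reported solution, plus a one-sided
Mann–Whitney rank-sum test that reported distances are smaller than
first-neighbour distances, Benjamini–Hochberg-adjusted across all
(solution × target) comparisons.  SDs are taken over the reactions of each
(set, target) cell.  Comparisons with fewer than two reactions on either
side are flagged and skipped.

## Numerical choices and limitations

* Sparse LU for all linear systems; dense response matrices only over
  compound columns (fine up to a few thousand nodes — beyond that, memory
  for `R` becomes the limit and Monte-Carlo moment estimation is the
  fallback).
* Degenerate-null detection at `σ ≤ 1e−12`; z-scores there are NaN and the
  nodes are excluded from ranking with a warning.
* The power-law exponent estimator is the continuous MLE with the discrete
  half-shift, over degrees ≥ kmin (default 2); it is a tail summary, not a
  goodness-of-fit claim.
* Weighted graphs, finite-time heat kernels and normalised-Laplacian
  variants are out of scope.
* The consensus rule is a strict majority; other vote thresholds would
  change the reported size for even `n_vote`.
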