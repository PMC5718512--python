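# heatpath

Null-diffusion pathway enrichment for summary metabolomics data.

Given a list of affected metabolites, `heatpath` scores **every** node of a
levelled metabolic knowledge graph — compounds, reactions, enzymes, modules
and pathways, in the KEGG style — by a diffusive process, normalises the
scores against a random-input null model, and reports the relevant part of
the graph as a connected, multi-level subgraph.  The output is richer than a
pathway p-value list: it shows *through which* reactions and enzymes the
perturbation reaches the reported pathways, which is useful for generating
mechanistic hypotheses and spotting pathway crosstalk.

## The model

The graph is treated as a meshed object.  Affected compounds inject unit
heat flow, pathway nodes act as boundary sinks, and each node's score is its
stationary temperature, the solution of

```
(L + B) T = G
```

where `L` is the unnormalised graph Laplacian of the undirected view, `B` is
diagonal with `B_ii = 1` on pathway nodes, and `G` is the 0/1 generation
vector of the input compounds (`KI = L + B` is the conductance matrix).
Warm nodes are close to many input compounds.  Alternatively the directed
view (edges oriented compound → reaction → enzyme → module → pathway)
supports a personalised PageRank with damping `d = 0.85`, restarting on the
input compounds.

Raw scores are biased by topology — large pathways are warm regardless of the
input — so they are normalised against the null model of `n_in` compounds
drawn uniformly at random without replacement.  Because the scores are linear
in the input indicator `X` (`T = R·X` with `R = KI⁻¹`), the null moments are
closed-form:

```
μ = R·E(X),   σ_i² = (R·Σ(X)·Rᵀ)_ii,   z_i = (T_i − μ_i) / σ_i
```

or estimated by Monte-Carlo permutations, `p_i = (r_i + 1)/(n_perm + 1)`,
with a majority-vote consensus over independent permutation runs.  The top-k
nodes by the normalised statistic form the reported subgraph.  Classical
over-representation analysis is the special case of this machinery on a
bipartite compound→pathway graph, where a pathway's temperature equals its
hit count and its null is exactly hypergeometric.

The package also ships the surrounding apparatus: a synthetic generator for
connected 5-level graphs with heavy-tailed (scale-free-like) degrees, a
hypergeometric ORA baseline, a signal-recovery benchmark with three signal
schemes (uniform noise, in-pathway proportional, network-based), and
resistance-distance validation of reported reactions against an independent
compound set.

## Worked example

Ten compounds, each belonging to exactly one of three pathways; pathway A
holds three compounds; the input holds four compounds, two of them in A:

```python
import heatpath as hp

graph = hp.bipartite_ora_graph((3, 3, 4))          # 10 compounds, A holds 3
input_set = hp.map_input(graph, ["cpd_01", "cpd_02", "cpd_04", "cpd_07"])

system = hp.conductance_system(graph)
temperatures = hp.heat_diffusion_scores(system, input_set)
response = hp.heat_response_matrix(system)
null = hp.analytic_null_moments(response, hp.null_input_moments(10, input_set.n_in))
z = hp.zscore_normalise(temperatures, null)

i = graph.index["pw_A"]
print(f"temperature(A) = {temperatures['pw_A']:.3f}")
print(f"null mean      = {null.mu[i]:.3f}")
print(f"null variance  = {null.sigma[i]**2:.3f}")
print(f"z-score(A)     = {z.z[i]:.3f}")
print(f"ORA p-value    = {hp.ora_pathway_test(graph, input_set, 'pw_A'):.4f}")
```

prints

```
temperature(A) = 2.000
null mean      = 1.200
null variance  = 0.560
z-score(A)     = 1.069
ORA p-value    = 0.3333
```

The pathway's temperature equals its hit count (2 of the 4 inputs are
members).  Its null moments are those of Hypergeometric(N=10, K=3, n=4) —
mean 1.2, variance 0.56 — and the one-tailed p-value 1/3 equals the exact
hypergeometric tail P(X ≥ 2): on this family, diffusion plus the null model
*is* over-representation analysis.

## Command line

```
heatpath generate-graph --levels 288,178,1149,4699,3869 --seed 1 --out graph.graphml
heatpath enrich --graph graph.graphml --input compounds.txt \
    --method hd --approx norm --k 250 --out-prefix run1
heatpath benchmark --graph graph.graphml --scheme network --methods hd,pr,fisher \
    --signals-per-target 5 --seed 1 --out ranks.tsv
heatpath resistance --graph graph.graphml --reactions reported.txt \
    --input ms_compounds.txt --targets nmr_compounds.txt --out table.tsv
```

`enrich` writes per-node scores (`.scores.tsv`), the induced subgraph
(`.subgraph.graphml`), the pathways in the solution (`.pathways.tsv`) and a
JSON summary with the connected-component counts.

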