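# orclust — Ollivier-Ricci curvature community identification

`orclust` finds community structure in undirected networks by exploiting the
geometry of the graph rather than a quality function such as modularity.  It
is aimed at network scientists working with social, biological and
drug-interaction networks who want a divisive method that exposes fine
("communities within communities") structure, together with a reproducible
benchmark harness for planted-partition experiments.

## The method

For a weighted graph with edge weights ρ, every vertex *i* carries a
probability measure over its neighbors,

    μ_i(k) = ρ_ik / Σ_{k∈N(i)} ρ_ik ,

and every edge (i, j) a coarse Ricci curvature

    κ(i, j) = 1 − W₁(μ_i, μ_j) / d(i, j) ,

where d is the shortest-path metric induced by ρ and W₁ the Wasserstein-1
(earth mover's) distance, computed as an exact transportation linear program

    W₁(μ_i, μ_j) = min_ξ Σ_{k,ℓ} d(k, ℓ) ξ(k, ℓ)
    s.t.  Σ_ℓ ξ(k, ℓ) = μ_i(k),  Σ_k ξ(k, ℓ) = μ_j(ℓ),  ξ ≥ 0 .

Edges inside densely interconnected neighborhoods have κ > 0, edges hanging
off degree-1 vertices have κ = 0, and bridges between communities have
κ < 0.  The detector removes the single most negative edge, updates the
curvatures the removal can have changed, and repeats until every remaining
edge satisfies κ ≥ −ε; the connected components of the residual graph are
the communities.  Small residual components can optionally be re-attached to
the large communities by preferential attachment, scored by the mean
curvature (at removal time) of the edges that used to connect them.

## Worked example

```python
>>> import networkx as nx
>>> from orclust import OllivierRicciCommunities, compute_all_curvatures

>>> g = nx.barbell_graph(5, 0)          # two K5 cliques + one bridge
>>> table = compute_all_curvatures(g)
>>> table[(4, 5)]                        # the bridge
-1.2
>>> table[(0, 1)]                        # inside a clique
0.75

>>> res = OllivierRicciCommunities(g).fit()
>>> print(res.summary())
Ollivier-Ricci community identification
===============================================
vertices:            10
edges:               21
mode:                local
epsilon:             1e-09
edges removed:       1
communities (pre):   2
merge policy:        none
communities (final): 2
community sizes:     [5, 5]
removed-edge kappa:  min -1.2000  mean -1.2000  max -1.2000
```

The bridge is the only negatively curved edge (κ = −1.2); removing it
separates the two cliques — pure clique edges sit at the K₅ value
κ = 3/4 — and the loop stops.  `res.partition` maps each vertex to its community,
`res.removal_log` is a DataFrame of the removal sequence, and
`res.curvatures` holds the final per-edge values.

The same pipeline is available from the shell:

```bash
orclust curvature --input graph.edgelist --out-dir out/
orclust detect    --input graph.edgelist --target-count 2 --out-dir out/
orclust benchmark --k 40 --l 10 --p-in 0.7 --p-out 0.05 --reps 5 --seed 1
```

## Benchmarks

`orclust.sbm` generates planted-partition (stochastic block model) graphs —
`l` communities of `k` vertices, intra-community edge probability `p_in`,
inter-community probability `p_out` — and scores recovered partitions with
two metrics: exact-match accuracy (percent of planted communities reproduced
exactly as vertex sets) and per-node misclassification under a
maximum-overlap one-to-one matching.  `orclust.datasets.karate_club()`
bundles the classic 34-member karate-club benchmark; the larger real-world
networks (college football 2000, the 2005 political blogosphere, DrugBank
4.1 drug-drug interactions) are not redistributed — place them under
`data/` (`football.gml`, `polblogs.gml`, `drugbank_ddi.edgelist`) to enable
the corresponding integration tests.

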