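# bacon — transition-matrix inference with a topological prior

Many network analyses — PageRank rankings, InfoMap community detection,
random-walk embeddings — start from a row-stochastic **transition matrix**
`T` describing how a random walker moves between nodes. When the edge
weights come from a *finite sample* of observed interactions (passenger
trips, clickstreams, message events), building `T` is an inference problem:
with few observations, relative frequencies badly overfit, and unobserved
but perfectly possible transitions get probability zero.

`bacon` infers `T` by combining two data sources that practitioners usually
have to choose between:

1. the observed interaction counts `n_ij`, and
2. a **topological constraint** `G = (V, E)` saying which directed
   interactions are possible at all (a transport network's physical links,
   a hyperlink graph, a social structure).

## The model

Each row of `T` is a categorical distribution over the possible successors
`S(i) = {j : (i,j) ∈ E}`. Pairs outside `E` carry a Dirac delta at zero;
on `S(i)` the prior is a symmetric Dirichlet with shape `α`:

    π_i ~ Dir(α·1_{|S(i)|})

With multinomial observations the posterior is again Dirichlet with
concentrations `α_i = α·1 + n_i`, so inference is exact counting, and the
estimate used downstream is the posterior mean

    E[T_ij] = α_ij / Σ_k α_ik .

`α > 1` favours equiprobable rows, `α < 1` favours peaked rows; `α` can be
chosen by maximising the (analytic) log marginal likelihood over a candidate
grid. Two standard baselines are included behind the same API: the
frequentist MLE `T_ij = n_ij / n_i` and the noninformative Bayes estimate
(the same Dirichlet machinery on the complete graph, i.e. no topological
knowledge). The zero-data limit of the constrained model is the *topology
baseline*: uniform rows over `S(i)`.

The package also ships the synthetic study systems used to validate the
method — Erdős–Rényi `G(N, M)` topologies and soft random geometric graphs
(Euclidean square and hyperbolic disk, edge probability `exp(-d/σ)`) with
Dirichlet-drawn ground-truth rows — plus the evaluation toolkit: Frobenius
recovery error, PageRank/Kendall-τ ranking agreement, InfoMap/AMI cluster
agreement, and data-requirement ratios between methods.

## Worked example

```python
from bacon import (BayesTransitionModel, FrequentistTransitionModel,
                   GeneratorConfig, generate_system, sample_interactions,
                   frobenius_distance, topology_baseline, pagerank, kendall_tau)

system = generate_system(GeneratorConfig("hyperbolic_rgg"), seed=42)
counts = sample_interactions(system, 20_000, seed=7)

model = BayesTransitionModel(counts, system.constraint)
res = model.fit(alpha=1.0)
print(res.summary())
```

```
Transition matrix estimation
============================================
Method:            BaCon (topological prior)
Nodes:             500
Defined rows:      500
Observations (m):  20000
alpha:             1
log evidence:      -7426.94
```

Comparing estimates against the generating ground truth:

```python
mle = FrequentistTransitionModel(counts, system.constraint.nodes).fit()
frobenius_distance(res.transition_matrix, system.t_gt)   # 3.784
frobenius_distance(mle.transition_matrix, system.t_gt)   # 5.630
frobenius_distance(topology_baseline(system.constraint), system.t_gt)  # 7.215

kendall_tau(pagerank(res.transition_matrix), pagerank(system.t_gt))  # 0.734
model.fit(alpha="select").alpha   # 0.91  (evidence-selected shape)
```

With 20 000 sampled interactions on a 500-node hyperbolic constraint
(~4 000 directed edges), the constrained posterior mean recovers the truth
substantially better (error 3.78) than both the pure-counts MLE (5.63) and
the pure-topology baseline (7.22), and the evidence selects a shape near 1 —
consistent with the flat Dirichlet the rows were actually drawn from.

A `bacon` CLI wraps the library: `bacon generate`, `bacon infer`,
`bacon evaluate`, `bacon sweep`, `bacon report` (see `--help`).

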