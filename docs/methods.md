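# Methods

## Inference model

A random walk on nodes `V` (`N = |V|`) is parameterised by row distributions
`π_i` over the successors `S(i)` allowed by a directed constraint graph
`G = (V, E)`. Observations are an aggregated multiset of directed
interactions with counts `n_ij` and total `m`. Three estimators share this
setting:

* **Frequentist (MLE).** `T_ij = n_ij / n_i`. Rows of nodes never observed
  as a source are *undefined*; they are stored as zero rows and materialised
  as uniform-over-V only where a consumer needs a stochastic matrix
  (PageRank). For matrix-recovery scoring they enter as zeros, so an
  unobserved row contributes the full mass of the reference row to the
  error — which is what makes the MLE's small-sample behaviour visible.
* **Constrained Bayes (BaCon).** Prior `π_i ~ Dir(α·1_{|S(i)|})` on `S(i)`;
  a Dirac delta at zero outside `E`, enforced strictly: an observation on a
  forbidden pair raises an error rather than being silently clipped.
  Posterior concentrations are `α + n_ij`; the point estimate is the
  posterior mean `α_ij / Σ_k α_ik`.
* **Noninformative Bayes.** Identical machinery on the complete graph.
  By default the complete graph excludes self-loops so that all three
  methods share the synthetic generators' successor spaces; `self_loops=True`
  puts prior mass on them instead (the choice is exposed because the
  baseline's classical definition does not resolve it).

The shape `α` may be a scalar, the per-node preset `1/|S(i)|`
(Schurmann–Grassberger-style; exposed without any optimality claim), or
selected by maximum a posteriori under a flat hyperprior over a candidate
grid — the evidence

`log p(E|α,G) = Σ_i [ log Z_i + log B(α·1 + n_i) − log B(α·1) ]`

is analytic (`B` the multivariate beta, `Z_i` the per-node multinomial
coefficient) and is evaluated entirely through log-gamma; no factorials are
formed, so totals far above 10^6 are safe. Including `Z_i` does not affect
the argmax over `α` but makes the evidence a proper probability, which the
tests exploit: summing it over all count configurations of a small row
equals 1 to 1e-10. Ties in the selection break toward the smallest
candidate — the conservative choice when the constraint may contain
spurious edges. The default grid is 50 log-spaced points on [1e-2, 1e2].

Numerical note: for symmetric concentration vectors the posterior mean is
emitted as exactly `1/|S(i)|` rather than `α/(α·|S(i)|)`, because the shape
cancels analytically; this keeps the identity "zero-data constrained mean ==
topology baseline" bitwise for every `α`, which downstream zero-data
equalities rely on.

## Synthetic study systems

The generators emulate the study conditions end to end; all defaults are
the study values.

* **Topologies** (undirected, then made connected, then doubled to
  directed): Erdős–Rényi `G(N=500, M=5000)`; Euclidean soft RGG with nodes
  uniform in the unit square; hyperbolic soft RGG with nodes uniform with
  respect to hyperbolic area (radial CDF `(cosh(ζr)−1)/(cosh(ζR)−1)`,
  inverted per draw) in a disk of radius `R=1` with curvature `−ζ²`, `ζ=1`.
  Geometric edges appear with probability `exp(−d/σ)`, `σ=0.1`, under the
  respective metric (the hyperbolic distance via
  `cosh ζd = cosh ζr_i cosh ζr_j − sinh ζr_i sinh ζr_j cos Δθ`). The same
  `σ` is applied to both metrics. Connectivity is enforced by one
  undirected bridge from a uniformly random node of each non-largest
  component to a uniformly random node of the largest, *before* doubling.
  The result always has one component and no sinks. Calibration at the
  defaults: ≈10 000 (ER), ≈12 000 (Euclidean), ≈4 000 (hyperbolic)
  directed edges.
* **Ground-truth rows** `π_i ~ Dir(ᾱ_i)`: flat (`1` per successor, or a
  configurable common concentration for the model-selection experiments)
  for matrix/ranking studies; community-biased for clustering studies
  (concentration 10 toward same-community successors, 1 otherwise).
  Communities: uniform three groups (ER); quadrants from one random
  vertical and one random horizontal cut (Euclidean); the 2-bit side
  pattern with respect to two random geodesics (hyperbolic). A geodesic is
  realised as the perpendicular bisector — in the hyperbolic metric — of a
  chord between two independent uniform boundary angles; the construction
  is one admissible reading of "cut with two geodesics" and is isolated
  behind the operation boundary so alternatives can be swapped in.
* **Interactions:** start node from a `Dir(1_N)`-drawn start distribution,
  successor from the ground-truth row. Implemented as one multinomial over
  the joint edge distribution `p_ij = s_i T_ij`, which is distributionally
  identical to the two-stage draw.
* **Partial knowledge:** `add_spurious_edges` adds `k` distinct uniformly
  random directed non-self-loop edges from the complement of `E`. Filling
  the whole complement reduces the constrained model to the noninformative
  one exactly.

Every generator is a pure function of (parameters, seed); RNG streams are
derived from `(seed, operation tag)` so a pipeline's pieces are individually
reproducible and replicable in parallel.

What the generators do **not** emulate: degree-sequence or temporal
structure of real systems, weight distributions with extreme skew (the
empirical regime that motivates `α < 1`), measurement noise in the
constraint other than uniformly random spurious edges, and sink nodes
(deliberately excluded). Passing tests on these systems therefore
demonstrates correct behaviour under the stated generative assumptions, not
performance on any particular empirical network; empirical weighted
networks enter through `constraint_from_weights` + `sample_from_weighted`.

## Evaluation

* **Matrix recovery:** Frobenius distance `sqrt(Σ (ΔT)²)` (the only norm
  validated; a generic hook is not provided beyond it).
* **Ranking:** PageRank by power iteration of
  `s = d·Tᵀs + (1−d)·u` with damping `d = 0.85` (exposed; the choice is
  conventional), uniform teleport rows for undefined rows, L1 convergence
  at 1e-12. Agreement via Kendall tau-b (tie-corrected, since inferred
  matrices at small samples produce heavy ties). A completely tied score
  vector induces no ranking; its correlation is reported as 0.
* **Clustering:** map-equation community detection on the directed weighted
  graph of the inferred matrix. The default backend is igraph's InfoMap;
  a bundled two-level map-equation optimizer (Louvain-style moves plus
  module aggregation, node visit rates taken as normalised out-flows)
  serves as a dependency-free fallback and as an independent cross-check.
  igraph row-normalises edge weights internally, so pre-scaling
  probabilities by the source's PageRank visit rate (the flow form) is
  observationally neutral there; the option matters only for the builtin
  backend. Agreement via adjusted mutual information (permutation-model
  correction, arithmetic averaging).
* **Data efficiency:** per-method error curves over a log-spaced sample
  grid with replicated draws; summaries are means and 2.5/97.5 percentiles
  (linear-interpolation convention, recorded in sweep metadata). The
  sample size at which a mean curve first drops below a threshold is
  located by log-linear interpolation between the bracketing grid points,
  and ratios of crossings give "method A needs r× more data than B"
  statements. A curve that never crosses raises an explicit error carrying
  its last mean.

## Experiment protocol and problem sizes

Sweeps regenerate the full ground truth (topology, rows, start
probabilities) for every replicate, so confidence intervals summarise total
variability; with spurious edges, inference sees the degraded constraint
while sampling uses the true system. Everything is deterministic given the
master seed, and failing cells are recorded (with the exception) rather
than aborting the sweep.

Problem sizes used by the shipped test protocol, chosen once as this
package's study scale: matrix-recovery sweeps run 20 replicates on a
20-point log grid of sample sizes spanning 10..10^7 — the upper end is set
by where the noninformative baseline's mean error crosses the 2.5 reference
threshold (between 10^6 and 3·10^6 on all three families), which the
data-requirement ratios need to exist. Downstream sweeps use sample sizes
{10^2, 10^3, 10^4} with 6 replicates (the regime where the methods differ
most), and model-selection direction checks use 50-node systems at
m = 10^5 with generating concentrations 10 and 0.01.

## Known limitations

* On Erdős–Rényi topologies the constraint carries no community
  information by construction, and the constrained model's near-uniform
  matrix is a single map-equation module until the observations overwhelm
  the prior (around 10^5 samples at the study scale). In that window the
  frequentist's fragmented partitions correlate weakly but positively with
  the reference clusters, so cluster-detection dominance of the
  constrained method does not hold on this family; it holds clearly on
  both geometric families and for ranking on all families.
* The builtin map-equation optimizer is a compact greedy reference, not a
  tuned InfoMap replacement; on large or weakly modular graphs it can stop
  at local optima the igraph backend escapes.
* The evidence-based selection chooses a single shared `α`; hierarchical
  treatment of `α` is out of scope.
* Readers/writers target in-memory graphs (dense CSV for small matrices,
  sparse triplets otherwise); there is no streaming I/O.
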