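# Methods

This note records the model, the numerical choices and the open design
decisions behind the package, and what the synthetic generators do and do
not emulate.

## Model and scope

All learning and inference operate on discrete Bayesian networks: a DAG
over named variables with one CPT per node. Continuous inputs enter only
through the augmentation/discretization front end. Networks in scope are
small (≤ ~40 nodes, ≤ 3 states per variable in practice; the test surface
is binary), which is why inference is exact everywhere — variable
elimination with a min-degree heuristic — and no approximate inference is
provided.

## Skeleton stage

- **Test.** Pearson's χ² form of the deviance on stratified 2-way tables:
  per conditioning stratum `u`, expected counts `N(x,u)·N(y,u)/N(u)`;
  cells with `E = 0` inside a kept stratum contribute 0; strata with zero
  count contribute neither statistic nor degrees of freedom. Degrees of
  freedom are `(r_X−1)(r_Y−1)` times the number of observed strata,
  floored at 1. This is the documented small-sample policy; a
  likelihood-ratio G² variant is deliberately not offered.
- **Loop.** Conditioning sets are drawn from the *current neighbours* of
  each endpoint (not all variable subsets): with the level-wise adjacency
  snapshot ("stable" refresh) this is the standard constraint-based
  convention, bounds the number of tests, and makes the output invariant
  to column order (tested by permutation).
- **Parameters.** `alpha = 0.01` follows the reference protocol;
  `max_cond_size` defaults to 3 — the protocol names a maximum without
  fixing it, and 3 is ample for the 8–10-variable problems in scope while
  keeping the level-3 subset count manageable. Both are exposed.

## Search stage

- **Configurations.** Admissibility of an immorality subset = induced
  arcs never conflict (no pair directed both ways) and stay acyclic.
  Subsets are enumerated with an early-pruned depth-first walk, so `2^r`
  is an upper bound rather than the typical cost. A chosen subset whose
  colliders share a centre can *imply* further colliders (selecting
  parents A,B and A,D of C also creates B→C←D when B,D are nonadjacent);
  such non-closed subsets are still enumerated — matching the `2^r`
  accounting — but the orientation stage constrains the search to the
  v-structure set of the *initial fixed-arc graph*, i.e. the closure.
  Duplicated subsets of the same closure re-explore one class; this costs
  time, never correctness.
- **Orientation.** The start state scores only the fixed arcs: an
  undirected skeleton edge contributes no parent until oriented (scoring
  a half-oriented edge would require semantics the model does not have).
  Legal moves are orient (either way), delete, reverse — never an edge
  outside the skeleton — subject to acyclicity and an *unchanged*
  v-structure set, enforced conservatively by recomputing v-structures
  after each candidate move. Deletion of non-fixed edges is what lets the
  orientation stage drop spurious skeleton edges (a false-positive
  adjacency usually buys less likelihood than its BIC penalty).
- **Score.** Natural logarithm throughout; the BIC penalty is
  `(ln M / 2)·Dim[G]` with `Dim[G] = Σ (r_i − 1)·q_i` counted over full
  parent-configuration grids (not only observed ones). Family scores are
  cached per `(node, parent set)`, so a greedy step costs two cache
  lookups per candidate move.
- **Determinism.** Strict improvement uses an absolute margin of 1e-10.
  All ties — among moves, and among configurations — resolve by fewest
  edges, then lexicographically smallest edge list. Node identity is by
  string name with lexicographic canonical order. Under a fixed seed the
  whole pipeline is bit-reproducible.
- **Baseline.** `hc_search` is the plain greedy add/delete/reverse
  hill-climb over all pairs with the same score, margin and tie-breaks,
  and no restarts or tabu list.

## Parameters, prediction, indices

- Dirichlet prior defaults to `α_k = 1` (uniform): the estimator is the
  posterior predictive `(M[k]+α_k)/(M+α)`, strictly positive so
  inference never conditions on an impossible event by accident.
  `α_k = 0` is accepted and yields the MLE relative frequencies, with a
  uniform fallback for parent configurations never observed.
- Binary predictions use the 0.5 threshold (identical to argmax for
  K = 2); an exact 0.5 tie resolves to the first declared state and is
  flagged on the prediction object. Evidence with zero probability under
  the joint raises `ZeroProbabilityEvidence` explicitly.
- PPCI is clipped into [0, 100] against ulp-level negativity at the
  uniform point; zero-probability terms contribute 0 by the piecewise
  definition.
- Sensitivity treats multi-variable evidence as one joint variable and
  conditions exactly; the cost is exponential in |F| and refused beyond
  |F| = 8. A deterministic target (H(Q)=0) is an error, not a 0/0.

## Augmentation and discretization

- **1-D k-means (k=2).** Centroids initialise at the observed extremes
  and Lloyd-iterate to convergence — deterministic, no seed sensitivity —
  and the cutoff is the centroid midpoint, giving the single-threshold
  Low/High rule that a per-variable cut-off table implies. Constant
  columns are an error naming the column. Only k=2 is supported; finer
  discretizers are out of scope.
- **KDE.** Product-Gaussian kernel on per-column standardised data with
  one shared bandwidth (the multivariate bandwidth structure is an open
  choice; a single standardised bandwidth is the simplest defensible
  one). Bandwidth is selected by likelihood cross-validation over a
  20-point log-spaced grid spanning 0.1×–10× the d-dimensional
  rule-of-thumb value, ties toward the smaller bandwidth; a degenerate
  all-duplicate sample makes every held-out likelihood −∞ and is
  rejected rather than floored. Sampling picks a training row uniformly
  and adds `N(0, h²)` per standardised coordinate, so draw variance is
  (empirical variance)·(1 + h²) per coordinate — the property the tests
  assert.
- **Splits.** Train/test is a seeded shuffle with sizes
  `⌊fraction·n⌋`/rest, default 80/20. Cutoffs fitted on training data are
  *reused* on the test set by default: recomputing them independently
  could flip label semantics between splits. Recomputation is available
  by simply calling `discretize_kmeans` on the test set where an
  independent protocol is wanted. Bootstrap resampling fits the KDE and
  the cutoffs once on the supplied data (pass the training split to keep
  augmentation blind to the test set).

## Evaluation conventions

- **SHD** compares DAG adjacency with reversals costing 1 (the common
  convention; the variant choice is open in the literature). A
  pattern-based variant (`pattern=True`) compares skeleton +
  v-structure arcs instead — note this is the pattern graph, not a
  Meek-completed CPDAG; Meek rules are out of scope throughout.
- **F1** is over directed edges by default (stricter); a skeleton
  variant is exposed.
- **Benchmarks.** The classic published benchmark networks are not
  bundled (their CPTs are not reproducible from the text this package
  follows); instead the package ships four hand-built ground truths —
  chain, fork, collider, and an 8-node two-collider network — with fully
  documented CPTs, plus a BIF reader so any published network file can be
  used. Recovery experiments default to 20 seeded replicates of n = 3000
  (n per the reference protocol; the replicate count is this package's
  choice for stable means at desk scale).

## Synthetic cohort

`make_marker_cohort` draws from a linear-Gaussian structural model over
ten named markers in three blocks — psychology (VWM, VSM, VCI, PRI),
functional imaging (PRF, DGM, SMA), neural density (PDN, PSN, DSN) —
with within-block chain coefficients 0.9, cross-block couplings 0.15 and
unit noise. The implied covariance `Σ = (I−W)⁻¹D(I−W)⁻ᵀ` puts every
within-block correlation above every cross-block one, which is the
qualitative signature the pipeline is meant to expose. What it does *not*
emulate: non-Gaussian marginals, measurement floors/ceilings of
psychometric scores, site effects, missingness, or a realistic cohort
size's sampling noise in the KDE — so passing end-to-end tests show the
pipeline's mechanics and consistency, not clinical validity.

## Known limitations

- Configuration enumeration is exponential in the number of candidate
  immoralities; dense skeletons (high α, small samples) can make the
  search impractical. No cap is imposed — the caller controls α and the
  conditioning depth.
- Constraint-stage false positives/negatives at finite n propagate: a
  spurious adjacency can survive orientation when the sampled data
  genuinely supports it (observed in roughly 1 in 20 collider draws at
  n = 3000, α = 0.01).
- Exact inference and sensitivity are exponential in evidence/network
  treewidth; fine for the intended scale, wrong tool beyond it.
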