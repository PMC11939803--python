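# Methods

## Model

Each sample's weighted network is a stationary Markov chain on a fixed
directed gene-interaction topology.  Two assumptions define the fit:

1. the L1-normalised expression profile `π = x/‖x‖₁` is the chain's
   invariant distribution on the self-loop-augmented adjacency `A`;
2. among all transition matrices consistent with `π` and `A`, the one with
   maximal edge-flow entropy is selected (maximum-entropy principle).

Writing flows `q_ij = π_i p_ij`, the program is

    maximise  −Σ q_ij log q_ij
    subject to  Σ_j q_ij = π_i  (rows: P stochastic),
                Σ_i q_ij = π_j  (columns: stationarity),
                q ≥ 0 supported on A,

i.e. maximum-entropy matrix scaling with both margins `π`.  The optimum is
`q = diag(u) A diag(v)` and the implementation alternates the two margin
updates (Sinkhorn / iterative proportional fitting).  The self-loops make
the identity chain feasible for every strictly positive `π`, so the program
is never infeasible.

Two exact limits are useful as anchors: identity support forces `P = I`
and `MCE = H(π)`; complete support gives the i.i.d. chain `p_ij = π_j` and
`MCE = 2H(π)`.

### Feasibility presolve (strong components)

Stationary flow cannot cross between strongly connected components of the
support: a source component of the condensation receives no flow, so its
row constraints force it to export none; removing it makes the next
component a source, and so on.  Every between-component entry is therefore
zero in *every* feasible matrix, and the fit restricts the support to
within-component edges before scaling.  This changes nothing about the
optimum but removes all boundary structure of this type: within a strongly
connected component whose nodes carry self-loops an interior feasible flow
always exists (push a small constant flow around a cycle through each edge
and absorb the remainder on the self-loops), so the scaling iteration
converges linearly.  Without the presolve, Sinkhorn approaches forced-zero
entries like `1/k` and tight residuals are unreachable.  Nodes forming
singleton components are reported with `p_ii = 1`, as the constraints
require.  No fitted value is ever thresholded or pruned; the removed
entries are implied zeros of the constraint set, not small numbers.

### Numerical choices

* Natural logarithm everywhere; entropies in nats; `0·log 0 := 0`
  (`scipy.special.entr`).
* Convergence metric: max of the L∞ row-sum residual and the L∞
  stationarity residual; default tolerance `1e-8`, iteration cap `50 000`
  (at 200–300 genes the updates are sparse mat-vecs of ~25 µs, and the
  hardest instances we generate need ~18 000 iterations at `1e-8`).
* `β⁰ = 1` (all-ones start); two identical calls are bitwise identical.
* Residual certificates are recomputed from the assembled matrix and are
  authoritative; non-convergence returns a flagged result with a warning,
  never silently.
* Zero-expression genes: `drop_zero` removes them from the sample's network
  (the invariant distribution must be strictly positive); a `pseudocount`
  mode adds ε to every entry instead, for sensitivity analysis.
* The brute-force oracle solves the same program over the dense flow vector
  with SLSQP; one redundant margin constraint is dropped (the two margin
  sets are rank-deficient by one), which is required for the solver to
  behave.  It is only defined for n ≤ 8 and is used purely as an
  independent cross-check.

## Methylation index

Beta values are thresholded per gene and sample: ≥ 0.6 fully methylated,
≤ 0.2 unmethylated, otherwise partial; missing entries propagate.  G1 is
the network with fully methylated genes deleted (self-loops retained on
survivors) and `π` renormalised; its transition matrix is refitted from
scratch on the pruned topology — renormalising rows of the G0 matrix would
not satisfy the maximum-entropy program on G1.  Genes with a missing beta
are retained in G1 (absence of evidence of methylation), and the retention
is logged per sample.

The per-gene Markov Flow Entropy follows the out-edge form
`MFE(i) = −Σ_j q_ij log q_ij`, which partitions the MCE exactly; an in-flow
variant (column sums) is available behind `direction="in"` since the
surrounding prose of the method is about incoming regulation while its
formula sums over outgoing edges.  `ρ(i) = (MFE₁−MFE₀)/MFE₀` is reported
per sample; it is missing where the gene was pruned from G1, dropped as
zero-expressed, or where `MFE₀ = 0`.  ρ is invariant to positive rescaling
of the raw expression vector.

## Ranking and core genes

PageRank uses damping 0.85 and, by default, the reconstructed transition
probabilities as weights with the mass-conserving update
`PR ← (1−d)/N + d·WᵀPR` (the weights are already row-stochastic).  The
printed in-degree-normalised variant
(`PR(v) = (1−d)/N + d Σ_u w_uv PR(u)/C_in(u)`, `C_in(u)=0` replaced by 1)
is kept as `mode="as_printed"`; it does not conserve mass, so scores are
renormalised each sweep in both modes.

K-means (k = 10, k-means++ with 10 restarts, fixed seed) clusters the
scalar scores.  Scores on scale-free networks span several decades and are
power-law distributed, so clustering operates on log10 scores by default;
on the raw scale 1-d k-means spends nearly all clusters on the few extreme
hub scores.  Cluster ids are canonicalised by ascending cluster mean so
assignments are comparable across samples, and a cluster-size entropy curve
over k ∈ [5, 15] is provided as the cluster-count diagnostic.  In heavily
pruned G1 networks many genes tie at exactly `1/N` (singleton components);
the pipeline clamps k to the number of distinct scores for such samples.

Triplet co-occurrence is counted over an explicit candidate gene list
(≤ 200 genes; all-gene triplets are combinatorially infeasible): per
sample, every 3-subset of candidates inside one cluster gains one count.
The top `top_n` triples per network label (ties broken lexicographically on
the sorted triple) are flattened and deduplicated, and the G0/G1
intersection is the stable core set.  The cohort-scale default is
`top_n = 100`; note that a stable set of s genes contributes `C(s, 3)`
persistent triples, so 100 corresponds to a stable set of 9–10 genes, and
smaller experiments should scale `top_n` accordingly (the recovery harness
uses `C(6,3) = 20` for its 6-gene module).  Bridge genes are non-core
genes adjacent — ignoring edge direction — to at least two core genes in
the core subnetwork (core genes plus first-order neighbors).

## Synthetic data

The generators reproduce the qualitative features the method assumes:

* **Topology**: preferential attachment (attachment probability
  ∝ degree + 1) from a seed clique, giving heavy-tailed degrees with a
  log-log slope around −2 to −3.  Edges are oriented uniformly at random:
  orienting every edge from newer to older nodes would give an acyclic
  graph, on which the only stationary chain is the identity and the whole
  pipeline degenerates, so the random orientation is the default (the
  acyclic variant remains available as `orientation="forward"`).
  `simulate_dataset` uses `m_attach = 5` (mean degree 10): at lower
  density, removing the ~45 % fully methylated genes leaves a recurrent
  core of only a few dozen genes, a degeneracy that the much denser real
  interactome does not exhibit.
* **Expression**: background log-normal(0, 1) per gene and sample.  Module
  genes share a per-sample factor `exp(effect·g_s)` (`g_s ≈ 1`) over a
  mean-compensated log-normal with residual σ = 0.25 — a co-regulated
  module fluctuates coherently, with less independent noise than unrelated
  genes.  At `effect = 0` module genes are exactly background.  The default
  `effect = 4` makes the module occupy the top score ranks in every sample.
* **Methylation**: the mixture `0.45·Beta(3,19) + 0.45·Beta(19,3) +
  0.10·U(0,1)` has modes exactly at 0.1 and 0.9.  Forced-methylation
  entries are drawn from Beta(19,3) truncated to [0.6, 1] and always
  classify as fully methylated.  Module genes draw from the low component
  only, matching the observed methylation stability of core genes.
* **Planting**: the module is drawn from the mid-degree recurrent part of
  the network, on genes sharing one degree value, and is wired as a
  directed cycle — a feedback motif.  The cycle keeps the module inside the
  recurrent part of every pruned G1; without it, random pruning disconnects
  one or two module genes per sample, pinning their scores to the
  uninformative `1/N` and destroying co-clustering.  Candidates are the
  module plus random recurrent-part genes.

What the generator does **not** emulate: probe-level methylation structure,
gene-length or library-size biases in expression, correlated background
co-expression, clinical covariates, or the size (≈ 20 000 genes) and degree
distribution of the real interactome.  Passing recovery tests therefore
show that the pipeline's inference chain is sound under its own
assumptions, not that the biological findings on any cohort are reproduced.

## Problem sizes

The test suite and `scripts/acceptance.py` use: 50 random strongly
connected 5-node graphs for oracle agreement (the dense oracle is only
well-posed when the flow polytope has interior points; degenerate supports
are checked against exact closed forms instead); ten 200-gene networks for
residual certificates and the flow-entropy partition; and ten seeds of the
recovery experiment (300 genes, 20 samples, 6-gene module among 30
candidates).  These sizes keep a full run in the low minutes on one CPU
while exercising every stage at realistic sparsity.

## Known limitations

* The fitted chain is per sample; no information is shared across samples,
  so small-sample noise in expression propagates directly into `P`.
* The methylation model is binary (pruned or not); partial methylation
  does not attenuate edges.
* On supports whose feasible polytope has boundary structure beyond the
  strong-component decomposition (none observed on the generated graphs),
  the scaling iteration can still converge sublinearly; the residual
  certificate reports this honestly via the convergence flag.
* The triplet stage requires a candidate list; results depend on its
  composition, as they do in any driver-gene-anchored analysis.
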