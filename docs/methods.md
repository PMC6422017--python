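# Methods

## Scope and model

`cladesig` quantifies phylogenetic signal — the tendency of closely
related species to share trait values — using only the topology of a
rooted tree.  This is the appropriate regime for supertrees and
cladograms assembled from heterogeneous sources (morphological and
molecular, extinct and extant taxa), where branch lengths are absent or
untrustworthy.  Branch lengths present in input Newick are parsed and
discarded with a logged warning; no operation ever reads them, and all
simulations treat every edge as having length one.

## Orthogram decomposition

For a rooted tree with *n* tips, each internal node *v* with ordered
children c₁…cₘ contributes *m − 1* contrast columns: column *j*
(2 ≤ j ≤ m) takes a constant value *a* on the tips of c₁…c₍ⱼ₋₁₎ and
*b* on the tips of cⱼ, zero elsewhere, with *a, b* fixed by centering
and unit norm.  Because supports are nested, the *n − 1* columns are
exactly orthonormal and orthogonal to the constant vector by
construction — no Gram–Schmidt pass is needed, and the result is
independent of processing order.  Columns are indexed by decreasing
node complexity np (descendant-tip count), ties by preorder rank, so
basal contrasts come first; within a polytomy, column order follows
child order as written in the Newick.  Individual columns inside a
polytomy are convention-dependent (any orthonormal basis of the same
per-node subspace is equally valid), but the summed R² per node is
invariant, which is the property tests assert.

A trait is standardized by centering and scaling to unit Euclidean
norm with uniform tip weights, so the squared coefficients sum to one
(Parseval on the complete centered subspace).  The four summary
statistics and their tails:

| statistic | definition | tail |
|---|---|---|
| R2Max | max R²ₖ | upper |
| SkR2k | Σ k·R²ₖ, k = 1…n−1 in column order | two-sided |
| Dmax  | max |Cₘ − m/(n−1)| | upper |
| SCE   | Σ (Cₘ − m/(n−1))² | upper |

SkR2k is tested two-sided because signal may skew variance toward the
root (basal concentration, the typical signature) or toward the tips;
Dmax uses the absolute deviation (two-sided KS form).  P-values use the
add-one permutation estimator p = (1 + #{T\* ≥ T}) / (n_perm + 1)
(two-sided: doubled smaller tail, capped at 1), which can never return
zero and gives an exactly valid level under exchangeability.  The
default n_perm = 999 puts the Monte-Carlo standard error of a p-value
near 0.05 at about 0.007.  Envelopes are pointwise permutation
quantiles: the upper 1 − α quantile per R² position, and the bilateral
α/2, 1 − α/2 quantiles of the cumulative curve.  Pointwise envelopes
control the level per position, not family-wise; node flagging is
exploratory by design.

## Abouheif proximity and C-mean

The proximity between tips *i* ≠ *j* is Π 1/dd(v) over internal nodes
*v* on the i↔j path, MRCA included, where dd is the number of direct
descendants; the diagonal is the row-sum complement, making W symmetric
and bistochastic with a non-null diagonal.  This path definition is
validated exhaustively against an independent graph-shortest-path
recomputation on every rooted topology with up to six tips.  The
C-mean is zᵀWz/zᵀz for centered z — invariant to shifting and positive
scaling of the trait, and exactly zero on a star tree, where W reduces
to the flat matrix J/n and no topological structure exists.  The test
is one-sided (upper): phylogenetic signal is positive autocorrelation.

## Geometric morphometrics

TPS records (LM=, coordinate lines, ID=/IMAGE=/SCALE=) are read with
SCALE applied multiplicatively.  GPA translates each configuration to
centroid origin, scales to unit centroid size (full Procrustes), and
iteratively rotates to the mean shape using the proper orthogonal
Procrustes rotation — reflections are disallowed, since a mirror-image
basicranium is not an admissible alignment.  The initial reference is
the normalized average of the scaled configurations, which makes GPA
output an exact fixed point (re-running it changes nothing);
convergence is declared when the mean shape moves by less than 1e−10
in Frobenius norm (max 100 iterations).  Centroid size is recorded
before scaling and is the size variable analysed downstream.  Shape
PCA is an eigendecomposition of the covariance of the flattened
aligned coordinates — covariance, not correlation, as landmark
coordinates share units.  Per-species tip traits are specimen means of
PC scores and centroid size.

## Ancestral reconstruction

Under the squared criterion the tree score Σ‖Xₐ − X_d‖²_F over branches
is minimized exactly: stationarity makes each internal node the mean of
its tree neighbours, a symmetric diagonally dominant linear system
solved densely (trees here have at most a few hundred nodes).  The
optimum is unique and is verified against an independent BFGS
minimization on every topology with ≤ 5 tips.  Under unit edge lengths
the squared-change solution is also the best linear predictor of
ancestral states under Brownian motion, which is what the
parameter-recovery simulations exploit.  The linear criterion
(Σ‖Xₐ − X_d‖_F) has no closed form; it is minimized by Weiszfeld-style
fixed-point updates started from the squared solution, stopping when
the score improves by less than `tol` (default 1e−8), with the
standard guard when an iterate lands on a neighbour.  Inputs must be
pre-superimposed; reconstruction deliberately does not re-run GPA so
the stages stay composable.  The squared tree score is invariant under
joint rotation and translation of all input configurations.

Binary characters use the Hartigan generalization of Fitch parsimony,
needed because trees may be polytomous: bottom-up, a node keeps the
states attaining the maximal count over its children's sets and adds
(#children − max count) steps — on binary trees exactly the
intersection/union rule; top-down, a node takes its parent's state
when available, else the smallest state in its set.  Step counts are
verified against exhaustive enumeration of all internal assignments.

## Ratios and group tests

bsL/stL is computed per specimen (validation rejects nonpositive
lengths and bsL > stL); species means are reported alongside.
Subfamily comparisons use specimen-level ratios: Kruskal–Wallis with
tie correction, then pairwise two-sided Wilcoxon rank-sum tests —
exact null when both sides have ≤ 12 observations and no ties, normal
approximation with tie correction otherwise — adjusted by Holm
step-down (the default of the standard pairwise-comparison
convenience routines; monotone, so adjusted p ≥ raw p).

## Synthetic data and what the tests show

The generator produces Yule topologies (uniform tip splitting; labels
assigned by a random permutation so labelled shapes are equidistributed),
Brownian traits (root 0, unit edges, per-edge sd σ) and white-noise
traits (i.i.d. Gaussian), plus landmark datasets where every coordinate
evolves by independent Brownian motion from a base shape (default:
eight points on the unit circle).  Calibration and power studies use
32-tip trees, 999 permutations, α = 0.05, σ = 1.0 for traits and
σ = 0.1 for landmarks, with 500 replicate datasets for per-statistic
rates and 100 for the heavier end-to-end landmark screen — sizes at
which a binomial 99% interval around the nominal level is about
±0.025 wide and runs take seconds to minutes.

What passing shows: the permutation tests hold their level under
exchangeability, detect Brownian structure with high power, and the
whole landmark pipeline recovers simulated signal with flagged nodes
concentrating at basal (high-np) nodes.  What it does not show: real
landmark data violate the independent-coordinate BM model (landmarks
covary, evolution is not homogeneous, fossils sample tips unevenly,
and measurement error is not isotropic), so these rates are best-case
calibrations of the machinery, not guarantees about empirical data.
The combined screen verdict ("signal" if ≥ 2 of the four orthogram
statistics are significant or the C-mean is) unions several positively
correlated level-α tests; its realized null "signal" rate therefore
sits somewhat above α (measured near 0.06 at these settings), which is
the price of a single headline call.  All individual p-values are
reported so users can apply their own rule.

## Numerical choices and edge cases

- Constant (zero-variance) traits are rejected with a clear error, as
  are degenerate (zero-size or collinear) landmark configurations.
- Orthonormality, row-sum and score invariants are asserted at 1e−10
  to 1e−12; the squared-change oracle comparison at 1e−4 (limited by
  the independent numerical minimizer, not the exact solver).
- Permutation streams use numpy's PCG64 generators; a single user seed
  deterministically spawns all sub-streams, so every result is
  bit-reproducible and every output artifact is stamped with seed and
  n_perm.
- Tip/trait-table reconciliation defaults to strict label equality;
  the `prune` policy intersects and logs dropped labels, collapsing
  unifurcations created by pruning.

## Known limitations

- No branch-length-aware statistics (Pagel's λ, Blomberg's K) — out of
  scope for topology-only data.
- Semilandmark sliding, 3-D landmarks and allometric correction are
  not implemented; PC scores from studies using them will not be
  reproduced exactly by the GPA + PCA stage here.
- The linear ancestral criterion is a local fixed-point method; it is
  guaranteed non-increasing from the squared start but not certified
  globally optimal.
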