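# Methods

This note records the models, conventions and numerical choices behind
`microcensus`, in the order a dataset meets them.

## The experiment container

An `Experiment` holds an abundance matrix (taxa × samples, non-negative
reals) and optional sample variables, taxonomy, tree and reference
sequences. The constructor (`build_experiment`) is the single place
where validity is established: component ID sets are **intersected**
rather than required to match (multi-source assembly rarely yields
identical sets), the counts of dropped taxa/samples are logged, and an
*empty* intersection is the error. Everything downstream may then assume
one canonical taxon order and one canonical sample order. The abundance
matrix is stored taxa-as-rows regardless of the source file's
orientation (one code path for all arithmetic); the original orientation
flag is kept only for faithful re-export.

Tree pruning contracts degree-2 nodes by summing the two adjacent branch
lengths, so patristic distances among retained tips are invariant —
this matters because `tip_glom` and DPCoA consume those distances.
Missing taxonomy entries (empty string, NA-like tokens) are normalized
to a single missing representation.

## Preprocessing

- `transform_counts`: relative abundance, `log(1+x)/log(b)`, per-sample
  ranks (average ties), or real-valued rescaling of each sample to a
  common total. The rescaling is *not* subsampling; it preserves
  proportions exactly.
- `rarefy_even_depth`: true random subsampling without replacement
  (with-replacement behind a flag) to an integer depth; samples below
  the depth are dropped with a logged warning, all-zero taxa removed.
  The seed is a required argument — there is no hidden global RNG, and
  an unreported seed is exactly the reproducibility failure this package
  tries to design away.
- `filter_taxa_k_over_a(k_fraction, a)`: keep taxa with count > a in at
  least `ceil(k_fraction·n)` samples. "Observed at least 3 times in 20%
  of samples" is `(0.2, 2)` — strict inequality over an integer
  threshold, the genefilter kOverA convention.
- `filter_taxa_cv(cv_min)`: keep taxa whose coefficient of variation
  (sample s.d., n−1 denominator, over the mean) strictly exceeds
  `cv_min`; all-zero taxa always go.
- `tax_glom(rank)`: merge taxa sharing the full assignment path down to
  `rank`; the archetype keeping the merged row is the most abundant
  member, ties broken by lexicographically smallest ID. Unassigned taxa
  are dropped (`na_rm=True`) or grouped by exact shared prefix.
- `tip_glom(h)`: complete-linkage clustering of patristic distances cut
  at height `h`. Complete linkage was chosen because it guarantees every
  pair inside a merged cluster is within `h` on the tree; single or
  average linkage would not.

Both agglomerations conserve per-sample totals exactly (they are sums of
`merge_taxa` operations).

## Distances

The registry holds 44 methods. Conventions worth stating:

- `canberra` and `altGower` average over the columns that are not
  double zeros; `gower` range-standardizes each column over the whole
  matrix and averages over **all** columns.
- `jaccard` is the quantitative form `2B/(1+B)` of Bray–Curtis `B`;
  with `binary=True` (or on presence/absence data) it reduces to the
  classic incidence Jaccard.
- `morisita` requires integer counts (its unbiasedness correction uses
  `x(x−1)`); use `horn` for transformed data. The Morisita similarity
  can exceed 1 for under-dispersed counts, so the dissimilarity is
  clamped at 0 to keep the matrix contract.
- `mountford` solves `exp(θA) + exp(θB) = 1 + exp(θ(A+B−j))` for θ > 0
  (A, B species counts, j shared) and reports `log 2 − θ`; nested
  species sets give 0, disjoint sets `log 2`.
- `raup` is the probabilistic Raup–Crick form: the upper-tail
  hypergeometric probability of drawing at least the observed number of
  shared species, with the species pool taken as all taxa present
  anywhere in the matrix.
- `chao` is the abundance-based Chao–Jaccard estimator with the
  rare-species correction terms; `cao` is the CYd index with zeros
  replaced by 0.1 (both following the conventions of the vegan
  implementation, against which all of the above were cross-checked
  numerically; the frozen reference values sit in the test suite).
- `jsd` is the Jensen–Shannon divergence of the relative-abundance
  profiles, natural logarithm, not its square root.
- The 24 incidence indices are expressed in (a, b, c) = (shared, unique
  to first, unique to second); the one asymmetric index (`rlb`) takes
  "first" as the earlier-indexed sample of the pair.
- Any pair involving an all-zero sample is an error naming the sample,
  never a silent NaN.

**UniFrac.** `branch_abundance` performs one post-order traversal,
O(edges × samples), storing per-branch lengths and descendant totals;
tip depths come from one pre-order pass. Unrooted trees (basal
multifurcation) are midpoint-rooted deterministically first — a random
root would silently break reproducibility, and midpoint rooting is the
convention users expect. Zero-length branches contribute nothing.
The weighted normalized variant divides by
`Σ_j d_j (A_j/A_T + B_j/B_T)`, its maximum attainable value, putting it
in [0, 1]. Correctness is established against a brute-force oracle that
enumerates every edge's leaf set independently (no shared precompute)
on 100 random trees, and cross-checked against scikit-bio.

**Parallel contract.** All pairwise methods are pure per-pair functions;
`workers=n` partitions the pair list round-robin over a thread pool.
Because each pair is computed by the same function on the same inputs,
the merged matrix is bitwise identical to serial evaluation — asserted
in the tests, not just claimed.

## Ordination

- **CA**: SVD of the standardized residuals
  `(P − rcᵀ)/√(rcᵀ)` of the correspondence matrix; eigenvalues are
  squared singular values and total inertia equals χ²/N (oracle-tested
  to 1e-10). Scores are reported in *symmetric* scaling (both sides
  scaled by √singular value) so sample and taxon clouds are directly
  overlayable in biplots; the scaling is recorded in the result
  metadata.
- **PCoA**: double-centering of −½D², symmetric eigendecomposition.
  Negative eigenvalues (non-Euclidean input) are *retained and
  reported* with a logged warning; coordinates are returned only for
  positive axes. No Lingoes/Cailliez correction is applied — hiding
  non-Euclideanity by default felt worse than reporting it.
- **NMDS**: Kruskal stress-1,
  `√(Σ(d̂−δ)²/Σδ²)`, with pool-adjacent-violators isotonic regression of
  configuration distances δ on the input order and Guttman-transform
  updates; one PCoA-initialized start plus `n_starts=20` seeded random
  starts, best stress kept. The iteration stops the moment an update
  would fail to decrease stress, so the recorded stress trace is
  non-increasing by construction and the best configuration is never
  discarded. The final configuration is centered and principal-axis
  rotated with a deterministic sign convention. Near-zero stress on
  clearly multi-point data triggers a warning: it usually means the
  configuration collapsed into a few clumps (the classic NMDS
  degeneracy) rather than a genuinely perfect fit.
- **PCA**: SVD of the (optionally centered/scaled) matrix; eigenvalues
  are score variances (n−1).
- **RDA**: least-squares projection of centered abundances onto the
  constraint span (QR), PCA of the fitted values; constrained plus
  residual inertia equals total to 1e-8 by construction of the
  orthogonal projection. **CCA**: the same scheme applied to the CA
  standardized residuals with square-root column-mass row weighting of
  the constraint matrix. Categorical constraints expand to indicator
  columns; an intercept-only (rank-0 after centering) constraint is an
  error.
- **DPCoA**: taxa embedded by PCoA of √(patristic) distances (tree
  metrics make this embeddable; a failure is reported as a tree
  problem), samples placed at abundance-weighted centroids, then a
  weighted PCA of the sample cloud with sample-total weights. The
  squared sample distances in the full space equal the Rao
  dissimilarities computed directly from abundances and patristic
  distances — the identity is asserted in tests.
- **DCA is deliberately absent**: detrending-by-segments is an
  algorithmic thicket orthogonal to this package's purpose, and a
  half-faithful reimplementation would be worse than a clear error
  pointing at CA/NMDS.

## Diversity and testing

- **Chao1** uses the bias-corrected form
  `S_obs + F1(F1−1)/(2(F2+1))` everywhere — unlike the classic
  `F1²/(2F2)` it is defined at F2=0 and never below `S_obs`. The
  standard error comes from the usual partial-derivative variance of
  the corrected estimator.
- **ACE** splits taxa at 10 individuals into rare/abundant, estimates
  coverage from singletons among the rare, and falls back to Chao1 when
  every rare taxon is a singleton (coverage undefined).
- **Shannon** uses natural logs over nonzero proportions; **Simpson**
  is `1 − Σp²`.
- **mt_minp**: statistics are one-way ANOVA F (any number of levels) or
  two-sample t / Welch t, fully vectorized over taxa × permutations.
  Raw p-values use `(1+count)/(B+1)`, so p > 0 and the resolution at
  B=9999 is 1e-4. Adjusted p-values are Westfall–Young step-down minP:
  each permuted statistic is converted to a p-value by its rank *within
  the pooled set of B+1 values including the observed statistic* — the
  pooling is essential; ranking permutations only among themselves
  makes the null minima stochastically larger than the observed minimum
  and the procedure anticonservative (empirically ~0.076 instead of
  0.05 at B=999 before the fix; ~0.037, i.e. valid and slightly
  conservative through ties, after). Step-down successive minima are
  taken in the order of increasing raw p (ties by decreasing |stat|),
  monotonicity is enforced by a running maximum, and `adj ≥ raw` is
  enforced explicitly. Taxa with degenerate statistics (no variance
  anywhere) get statistic 0 and p = 1, never NaN. With
  `exhaustive=True` all distinct label orderings are enumerated
  instead — on 4 samples in two groups of two this reproduces the exact
  24-permutation enumeration.
- **hypergeom_enrichment** is the upper-tail hypergeometric (Fisher)
  probability, evaluated by exact summation via scipy.

## Plot-layout computations

All `viz` outputs are pure functions of (experiment, parameters, seed);
rerun equality is tested. Conventions: heatmap orderings sort objects by
their `atan2` angle in the first two ordination axes, ascending in
(−π, π], ties broken by ID; taxa get their own ordination over taxa when
the sample ordination carries no taxon scores. Networks connect units
with distance strictly below the threshold (default jaccard/0.4, both
echoed in CLI output headers since they materially shape the graph);
layouts are seeded spring embeddings centered at the origin. Tree plots
assign tips integer vertical positions in post-order, internal nodes the
mean of their children, horizontal positions by cumulative branch
length; one marker per (tip, sample observed), offset in successive
columns; >200 tips triggers a readability warning. Stacked bars sort
segments within each position by descending abundance so the aggregate
height equals the group total. The heatmap's suggested color transform
`log(1+x)/log(4)` is a rendering hint recorded in the output, nothing
more.

## Synthetic data

`simulate_experiment` draws one community profile from Dirichlet(1) over
`n_taxa`, multiplies the first `effect_taxa` proportions by
`effect_size` in alternating groups (renormalizing), and draws each
sample as multinomial(depth) — so column sums are exactly `depth`,
matching the even-depth assumption of several downstream methods
(per-taxon Poisson sampling would not give that). `effect_size=1` makes
the group label independent of the counts: the exchangeable null used
for the family-wise error calibration (20 samples, 50 taxa, B=999, 200
replicates — sizes chosen so the calibration is statistically meaningful
while the whole suite stays interactive). Trees are random coalescents
with exponential waiting times; taxonomy is a nested random hierarchy,
so rank-agglomeration has real structure to find.

What the generator does *not* emulate: compositional zero-inflation,
overdispersion beyond the multinomial, lineage-correlated abundances
(tree and counts are independent), or uneven sequencing depth. Passing
tests therefore demonstrate correctness of the algorithms under clean
sampling assumptions, not robustness to the messiness of real surveys.
The external Enterotypes genus table (loaded at run time from the
Bioconductor phyloseq data package when R is available, never shipped)
covers the one check that needs real data: the per-genus F statistics
and their ranking reproduce the published table to the printed
precision.

## Known limitations

- No variance-stabilizing model-based normalization; no FDR procedures
  beyond FWER minP; no per-axis permutation tests for constrained
  ordination.
- BIOM v2 (HDF5) is detected and rejected, not read.
- NMDS offers no explicit anti-degeneracy penalty; it warns instead.
- `patristic_matrix` is O(n²) dendropy queries — fine below ~10³ tips,
  the intended scale for tree-aware analyses here.
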