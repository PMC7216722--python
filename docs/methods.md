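# Methods notes

This note documents the statistical model, the numerical and design
choices that were genuinely open, the simulation machinery and what it
does (and does not) emulate, and the known limitations.

## Null model and marginal score statistics

The phenotype follows a GLM in the exponential dispersion family with
canonical link; only the Gaussian (identity link) and binomial (logit
link) families are implemented, but the `NullFit` contract carries the
variance weights `W` and dispersion generically so other families can be
added.  The null model contains the covariates only and is fitted once:
ordinary least squares for Gaussian, IRLS (statsmodels, tolerance 1e-8,
100 iterations) for binomial.  Marginal score statistics are

    Z_j = o_j'(y - mu0) / sqrt(o_j' P o_j),   P = W - WX(X'WX)^-1 X'W,

computed without materializing the n x n matrix P (via X'W projections
and a Cholesky solve); a dense-P oracle in the test suite pins the
optimized path to 1e-10.

**Dispersion (Gaussian).**  The dispersion is the maximum-likelihood
estimate RSS/n, not the unbiased RSS/(n - rank X).  This is a deliberate
calibration choice: Z_j is self-normalized (the same residual vector
drives both the numerator and the dispersion estimate), which makes its
exact null law a scaled sphere coordinate with *lighter*-than-normal
tails — bounded by sqrt(n).  The MLE's sqrt(n/(n-rank)) inflation
compensates almost exactly, so two-sided N(0,1) p-values (and therefore
the analytic Simes test, which lives in the far tail p ~ alpha/m) are
calibrated: in a null simulation at n = 50, m = 100 the empirical Simes
level at alpha = 0.05 moves from ~0.02 (unbiased form) to ~0.046 (MLE).
Permutation-calibrated tests are essentially invariant to this choice,
since the factor is common to the observed and every permuted statistic.

**Degenerate inputs.**  A rank-deficient design, a constant binomial
phenotype, perfect separation (any fitted probability at 0/1 within
1e-10), and OTUs that are constant or collinear with the covariates
(score denominator <= 1e-12) are hard errors with actionable messages;
p-values are clamped to [1e-12, 1 - 1e-12] before the HC transform so a
p of exactly 1 yields a large negative deviation that can never become
the maximum.  Rank ties in p are broken by ascending |Z| then OTU index;
the multiset {(p_j, r_j)} and hence every statistic is tie-break
invariant, the choice only stabilizes printed ranks.

## Phylogenetic weights

Cophenetic distances (sum of branch lengths through the most recent
common ancestor) are computed by a single postorder sweep,
D[a,b] = depth(a) + depth(b) - 2 depth(mrca); dendropy's distance matrix
is the independent oracle in tests.  OTUs are partitioned by PAM
(k-medoids) on D with deterministic BUILD initialization and a
vectorized SWAP phase — no random restarts, so cluster assignments are a
function of the tree alone and identical across permutations.  The
cluster count maximizes the average silhouette width over k = 2..30
(silhouette is undefined at k = 1, so the search starts at 2); ties
break toward smaller k, and fewer than 3 OTUs fall back to a single
cluster.  Weights are

    w_j = [ sum_{j' in cluster(j), j' != j} |Z_j'| / D_jj' ] /
          [ sum 1 / D_jj' ] + 1,

i.e. 1 plus an inverse-distance-weighted mean of the neighbours'
absolute signals; singleton clusters get w_j = 1 (neither up- nor
down-weighted), zero distances are floored at 1e-10 so a co-placed
neighbour dominates the mean (the continuous limit of the formula),
and w(D) = w(cD) exactly for any c > 0.  Weights are recomputed from
each permuted Z vector; the within-cluster inverse-distance operator is
precomputed once, so a batch of permutations costs one matrix product.

## Omnibus calibration

Individual statistics uHC_(h)/wHC_(h) (mean of the h largest deviations,
h in Gamma = {1,3,5,7,9} by default, entries clipped to m and deduped)
and the Simes p-value are combined by minimum-p.  Calibration follows a
residual-permutation scheme: B shuffles of the null residuals (default
B = 5000 for data analysis; p-value resolution 1/(B+1)), each shuffle
shared across all OTUs and all h, with the score denominators held at
their observed values.  Permutation p-values use the add-one estimator
(1 + count)/(B + 1) with strict comparisons (larger is extreme for HC
statistics, smaller for Simes and for the omnibus minimum-p); the
observed Simes entry in the minima is its analytic value while the null
Simes entries are leave-one-out permutation p-values of the permuted
Simes statistics.  With strict comparisons the leave-one-out count over
b' != b equals the count over all b', which gives an O(B log B)
closed form (verified against the explicit double loop in tests).  All
randomness descends from one integer seed through a single sequential
generator; chunking the permutation loop does not change results, and
stored null artifacts are O(B |Gamma|).

A run without a tree computes the unweighted family and Simes only and
reports uHC_A as the headline omnibus test, with an explicit note in the
output.

## Simulation machinery

The simulator emulates a 16S-style association study:

* **Counts** — Dirichlet-multinomial with mean proportions pi and
  dispersion theta, at fixed depth 1000 reads/sample (the compositional
  constraint).  The packaged default profile is synthetic: the top 100
  of 400 log-normal(0, 2) draws, normalized (most-abundant-first),
  theta = 0.01.  Keeping only the top slice of a larger pool bounds the
  rare tail the way an abundance-ranked selection from a real survey
  does; `estimate_dm` (depth-weighted moment estimator for pi, classical
  between/within variance decomposition for theta, truncated to
  [0, 1 - 1e-6]) lets users substitute parameters fitted to any count
  table.
* **Tree** — random rooted binary topology by recursive uniform splits
  of a shuffled leaf list, branch lengths iid Uniform(0,1), 100 leaves
  by default.  By default a fresh tree is drawn per replicate
  (`tree_per_rep=False` holds one fixed).
* **Phenotype** — y = 0.5 scale(x1) + 0.5 scale(x2) +
  beta * sum_{j in Lambda} scale(o_j) + eps with x1 ~ Bernoulli(0.5),
  x2, eps ~ N(0,1); scale() standardizes to mean 0, sd 1 (n-1
  denominator), and an exactly-constant OTU column contributes 0 with a
  warning.  The associated set Lambda (2%-12% of OTUs) is drawn either
  uniformly or as a random seed OTU plus its nearest cophenetic
  neighbours (ties by OTU index).
* **Operating characteristics** — `estimate_rejection_rate` runs the
  full pipeline per replicate and reports the rejection fraction at
  alpha per test with exact Clopper-Pearson intervals.  OTU columns
  that come out constant in a replicate (possible for the rarest taxa
  at depth 1000) are dropped for that replicate before testing.

Problem sizes used by the shipped checks — 1000 replicates at B = 500
for the n = 50 null surface, 500 for n = 100, 300 per power scenario —
were chosen so that exact binomial bands around the reference rates are
decisive while a full run stays in the minutes range on one CPU.

What the simulator does *not* emulate: real taxonomic structure
(coupling between abundance profile and tree), spatial/temporal
dependence between samples, variable sequencing depth, or zero
inflation beyond what the Dirichlet-multinomial induces.  Passing
simulation checks therefore demonstrates calibration and the intended
power orderings under an idealized generating process, not performance
guarantees on any particular real survey.

## Visualization

Q-Q diagnostics plot the expected significance quantile
w_j (r_j/m) / sqrt(p_j(1-p_j)/m) on x against the observed
w_j p_j / sqrt(p_j(1-p_j)/m) on y (either orientation preserves the
deviations; x = expected is chosen and documented here).  The signed gap
is exactly the HC deviation d_j, and the top-10 influential OTUs are
ranked by |d_j| — magnitude rather than signed value, since influence is
read as distance from the diagonal.  Vertical guides go darker to
lighter with decreasing rank; output is PNG and PDF.

## Known limitations

* The binomial family is implemented and unit-tested but the calibration
  study is Gaussian; binomial calibration inherits whatever
  small-sample behaviour the score/permutation approximation has there.
* Permuted residuals are not re-orthogonalized against the covariates
  (the shuffle breaks X'e = 0), which makes permutation calibration
  slightly conservative when covariates explain much of the phenotype;
  at the study's scale the effect is within the reported bands.
* The analytic Simes component relies on the far-tail calibration of
  the marginal p-values discussed above; with very small n (n - rank
  < ~20) it will drift conservative.
* No exact or asymptotic HC p-values: with microbiome-scale m and
  inter-OTU dependence those approximations are invalid, which is the
  reason the permutation scheme exists.
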