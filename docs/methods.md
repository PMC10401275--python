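# Methods

## The prediction problem

A two-group testcross factorial crosses `n1` inbred lines of one parent
group with `n2` lines of a second group.  Only a fraction of the `n1·n2`
possible hybrids is field-tested, and the tested subset is typically
*unbalanced*: a few widely used lines appear in dozens or hundreds of
crosses while most appear in one or two.  Each tested hybrid contributes a
single adjusted entry mean for yield.  The task is to predict the yields of
hybrids that were not tested (or held out), using the identities of their
parents, the yields of the parents' other crosses, and — when available —
SNP genotypes of the inbred parents.

## Combining-ability model

The classical decomposition is

    y_ij = mu + GCA1_i + GCA2_j + SCA_ij

with general combining abilities (GCA) as crossed random parent effects and
specific combining ability (SCA) as the cross-specific deviation.  With one
entry mean per hybrid, SCA is statistically inseparable from residual
error: any SCA value can be absorbed into the residual and vice versa.  The
model is therefore fit as

    y ~ intercept + random(GCA1) + random(GCA2) + residual

and the residual variance is *reported as* `sigma2_SCA`, with the error
variance flagged as confounded.  `SCA_ij` is defined as the raw residual
`y_ij − mu − GCA1_i − GCA2_j`.  This is the only identifiable reading of
the model on entry means and matches the convention of reporting a single
SCA variance per factorial.  A consequence worth remembering when
interpreting recovery tests: the estimated SCA variance targets
`sigma2_SCA + sigma2_e` of the generator, and the estimated SCA share

    tau = sigma2_SCA / (sigma2_GCA1 + sigma2_GCA2 + sigma2_SCA)

is accordingly shifted upward by the (small) error variance.

## GBLUP with a Kronecker SCA kernel

With parent SNP panels, the model becomes

    y = 1 b0 + Z1 g1 + Z2 g2 + Z_S s + e,
    var(g1) = s1 G1,  var(g2) = s2 G2,  var(s) = ss S,  var(e) = se I

where `G1`, `G2` are VanRaden genomic relationship matrices computed
*within parent group*: `G = W W'/c`, `w_uv = x_uv + 1 − 2 p_v`,
`c = 2 Σ_v p_v (1 − p_v)`, with `x_uv ∈ {−1, 1}` the homozygous dosage and
`p_v` the within-group frequency of the 1 allele, always estimated from the
filtered, pre-imputation panel.  The SCA kernel is the Kronecker product
`S = G1 ⊗ G2`, but only its entries for realized (or queried) hybrids are
ever formed: `S[(i,j),(k,l)] = G1[i,k]·G2[j,l]`.  For a factorial with
hundreds of parents per group the full Kronecker product would have tens of
millions of rows; the entry-wise rule reduces it to the `n × n` block of
the training hybrids.

Marker preprocessing mirrors standard practice: markers are dropped when
expected heterozygosity `2p(1−p)` is below 0.10 or more than 1% of calls
are missing; remaining missing calls are imputed with the marker mean.
A diagonal jitter of 1e-6 is added to `G1`/`G2` before factorization
because VanRaden matrices from modest marker counts are often
rank-deficient.

Prediction is multivariate-normal conditioning: for target hybrid (i, j),

    yhat = b0 + Cov((i,j), train) · V^{-1} (y − b0)

with the covariance assembled from `G1`, `G2` and the Kronecker rule.
Parents need only rows in the kernels, not training crosses, so untested
hybrids of genotyped parents are predictable.

## REML machinery

All mixed models above share the shape `y = Xb + Σ_k u_k + e` with
observation-level kernels `K_k`.  One engine (`reml.fit_reml`) maximizes
the restricted likelihood over the variance *ratios*
`gamma_k = sigma2_k / sigma2_e`, with the residual variance profiled out
analytically.  Numerical choices:

* Nelder–Mead on `log gamma` (derivative-free; robust at the `gamma → 0`
  boundary), log-ratios clipped to ±25, ratios below `exp(−25)` reported
  as exactly zero;
* the equal-ratio point `gamma = 1` plus one dispersed start; the best
  terminating optimum is kept, and a failure of all starts raises a
  convergence error carrying the last criterion value;
* relative likelihood tolerance 1e-8, up to 1000–3000 criterion
  evaluations depending on the model;
* a response that is exactly constant (after the fixed effects) bypasses
  optimization: all components at the 1e-12 lower bound, intercept at the
  mean;
* BLUPs come from the identity `u_k = gamma_k C_k V0^{-1} (y − Xb)` at the
  optimum, which also yields the exact-zero sum of GCA BLUPs (the GLS
  residual is orthogonal to the intercept).

A brute-force profile of the criterion on a log-ratio grid
(`reml.reml_grid_profile`) serves as an independent oracle in the tests.

## Feature encodings for the ML learners

* **parentage** — the two parent IDs, either as two categorical columns or
  one-hot expanded to `n1 + n2` indicators (no reference level is dropped;
  downstream learners are regularized or tree-based);
* **yield features** — for hybrid (i, j), one column per parent line of
  the factorial: the column of group-2 parent `q` holds `y(i, q)`, the
  column of group-1 parent `p` holds `y(p, j)`, each only when realized
  and not excluded.  The hybrid's own yield never appears in its row, and
  the exclusion set must contain all test pairs of the current split —
  this is the leakage guard the protocol requires.  These tables are
  extremely sparse on realistic factorials (well over 75% missing);
* **hybrid genotypes** — the virtual F1 dosage `(x_parent1 + x_parent2)/2`
  per marker, exactly −1/0/1 for pure inbred panels;
* **combined** — column-wise concatenation of parentage and genotype
  features (name collisions suffixed deterministically).

Missing-value policy by learner family: tree learners receive missing
values natively; kernel/linear learners (SVM, RKHS) receive
training-column-mean imputation and z-scaling computed on training rows
only.  Constant and all-missing columns are dropped per split, with a log
record.

## Base learners

* **GB** (LightGBM, native training API): tuned over `n_trees`
  {50,100,200,400,800}, `max_depth` 2–12, `min_rows` {1,2,5,10,20},
  `sample_rate` {0.5,0.632,0.8,1.0}, `nbins_cats`
  {8,…,1024}; learning rate fixed at 0.1.  Categorical parent columns are
  passed to LightGBM's native categorical split search (per-node
  gradient-sorted level grouping), with `nbins_cats` mapped to
  `max_cat_threshold`, the bound on how many level groups one split may
  consider — the histogram treatment of high-cardinality factors.  The
  per-group observation floor (`min_data_per_group`) is lifted to 1
  because parent lines in unbalanced factorials can appear in very few
  crosses; `min_rows` alone governs leaf sizes.  The wrapper caps
  `num_leaves` at
  min(2^depth, 128): on factorial-scale data (hundreds to ~1500 rows, two
  categorical predictors) wider trees only memorize single cells while
  dominating runtime.
* **GB-marker** (for genotype matrices): fixed 1000 trees with early
  stopping (patience 10 on a 10% carve-out), tuned learning rate
  {0.01,0.05,0.1,0.3}, pruning `gamma` {0,0.1,1,10} (LightGBM
  `min_split_gain`), per-tree column subsampling {0.3,0.5,0.8,1.0}.
* **RF** (scikit-learn): the GB grid minus the learning rate;
  `sample_rate` maps to bootstrap `max_samples`.  scikit-learn trees have
  no categorical-split support, so the RF wrapper applies target-statistic
  binning instead: levels ranked by training target mean and grouped into
  at most `nbins_cats` ordered bins fed to the trees as ordinals.
* **SVM** (scikit-learn SVR): `C` {0.1,1,10,100}, `epsilon`
  {0.01,0.1,0.5}, kernels linear / polynomial (degree 2–4) / radial.
* **RKHS**: three Gaussian kernels `exp(−h D)`, `h ∈ {0.1, 0.5, 2.5}`,
  `D` the squared Euclidean marker distance divided by its training mean;
  per-kernel variances by REML (the same engine as the BLUP models), so
  the predictor is a deterministic multi-kernel ridge, linear in `y`.  No
  tuning.  Known limitation: the three bandwidths produce strongly
  correlated kernels, so the attribution of variance *between* them is
  weakly identified; predictions are much more stable than weights.
* **MF**: SGD matrix factorization of the `n1 × n2` yield matrix over
  observed cells, squared error plus L1 penalties on both factor matrices,
  no bias terms; learning rate fixed at 0.05, 500 epochs; tuned over `dim`
  {2,4,8,16,32} and L1 costs {0, 0.001, 0.01, 0.1} per side.  Factors are
  initialized near `sqrt(|mean(y)|/dim)` so the initial product sits at
  the grand mean, which stabilizes SGD on uncentered yields.  The mean
  squared training error is recorded per epoch as a convergence monitor.

The exact hyperparameter grids are this package's documented defaults,
chosen to span the named tunable parameters widely: grid searches on
factorial data often place optima at the extremes of typical ranges, so
the ranges are generous.

## Random grid search and stacking

For each tunable algorithm, up to 50 distinct hyperparameter combinations
are drawn uniformly without replacement (a smaller space is used whole) and
scored by 10-fold cross-validation MSE on one shared random fold partition;
the lowest MSE wins, ties to sampling order.  A learner failure on any fold
marks that combination failed (logged, excluded from ranking) without
aborting the search.

The stacked ensemble ranks the non-failed GB models by CV MSE and, for each
`k ∈ {5, 10, …, 50}`, trains a ridge super learner (intercept + k
coefficients) on the `n × k` matrix of out-of-fold base predictions — the
super learner never sees a base model's in-fold predictions.  The ridge
penalty is chosen by an internal 5-fold CV over a geometric grid
1e-4…1e2.  The ensemble size `k*` maximizes the Pearson correlation
between the response and the super learner's own out-of-fold predictions
(same folds), ties to the smallest `k`.  If the base out-of-fold
predictions are constant the correlation is undefined; that `k` is scored 0
with a warning.  Non-negative-coefficient stacking is not implemented; the
ridge coefficients are unconstrained, which is the standard reading of a
ridge super learner.  At prediction time the `k*` base models are refit on
the full training set and combined with the frozen ridge weights.

## Cross-validation protocol and metrics

Each replicate draws a uniform random 10% of the realized hybrids as the
test set.  Test hybrids with a parent absent from the training crosses are
moved to a `removed` list (combining-ability prediction requires both
parents to be estimable).  When yield features are used, the yields of
*all* originally drawn test hybrids — including removed ones — are excluded
from every training-side feature cell.  A replicate whose filtered test set
is empty is regenerated from a perturbed sub-seed (up to 10 attempts,
logged) so replicate counts stay interpretable.

Metrics per replicate and algorithm: **prediction accuracy**, the Pearson
correlation between observed and predicted test yields (constant
predictions score 0 with a warning), and **top-20 overlap**, the percentage
of the 20 best observed hybrids that also rank in the 20 best predicted
(k capped at the test-set size; ranking ties broken by stable input
order).  The reported point estimate per algorithm is the median across
replicates.  Grid search and stacking are re-run inside every training set
by default; a `reuse_tuning` switch exists for exploratory runs.

## Synthetic factorial generator

The generator is the package's study system.  It draws:

* a crossing design covering every parent, with per-parent sampling
  weights proportional to `rank^skew` (rank randomly assigned within
  group); `skew = 0` gives uniform designs, larger values reproduce the
  long-tailed cross-count distributions of real factorials with one knob;
* i.i.d. Gaussian GCA, SCA and error effects at configured variances
  (Gaussian matches the BLUP working model; real factorials carry no
  published generative model, so this is a modeling convention, not a
  claim about real data);
* optionally, inbred marker panels for both groups (allele frequencies
  uniform on a configurable range, independent across groups and markers).

Under the `marker-driven` architecture the yields are *regenerated from
the markers*: group-wise additive effects give GCA (`GCA_i = Σ_v a_v
x_iv`, centered), dominance effects on heterozygous hybrid loci give SCA
(`SCA_ij = Σ_v d_v [x_iv ≠ x_jv]`, centered over realized crosses), and
both are rescaled so the realized sample variances equal the configured
components exactly.  This is the simplest architecture that makes `G1`,
`G2` and `S` informative.  Under `effects-direct` the panels are
independent of the yields and serve as a negative control.  SCA and error
are always drawn separately, even though the combining-ability model
cannot separate them, so recovery tests know the true split.

Defaults represent a mid-size program: 60 × 20 parents, 600 realized
crosses (50% of the factorial), unit GCA variances, grand mean 100,
error variance 0.25, 400 markers with minor-allele frequencies in
[0.05, 0.5].  What the generator does **not** emulate: linkage and LD
structure along chromosomes, heterozygous parents, genotype-by-environment
interaction, multi-environment trial error, and selection-induced
correlation between parent usage and parent quality.  Passing tests on
this generator therefore demonstrate correctness of the estimators and the
protocol, not field-data performance.

## Problem sizes used in the test suite

The acceptance-style tests run at desk scale, chosen as the smallest sizes
at which the checked properties are stable: published-table arithmetic is
exact and instantaneous; oracle-equivalence checks use ≤ 12 observations
(dense GLS) and ≤ 64-cell designs (materialized Kronecker); REML recovery
uses 60 × 20 parents / 600 crosses over 20 seeds; the directional
benchmarks use a 60 × 14 / 750-cross SCA-dominated factorial and a
60 × 20 / 600-cross low-SCA marker-driven factorial, each over 20
replicate splits with the full 50-model grid search per split.  On the
SCA-dominated synthetic factorial, i.i.d. cell-specific SCA is
unpredictable for held-out cells by construction, so the stacked ensemble
is expected to *match* GCA prediction (the assertion is one-sided with a
0.02 tolerance), not to beat it; improvements like those seen on real
SCA-rich factorials require SCA structure that parentage encodes, which an
i.i.d. generator deliberately does not provide.

## Known limitations

* The combining-ability model reports SCA and error as one confounded
  component; analyses needing a separated error variance require
  replicated plot data, which is out of scope.
* REML on dense `n × n` covariance matrices scales to a few thousand
  crosses; very large factorials would need sparse or low-rank solvers.
* The RKHS kernel weights are weakly identified (see above).
* MF without bias terms depends on the grand-mean initialization for
  uncentered responses; heavily imbalanced matrices with near-empty rows
  fall back to grand-mean pseudo-cells.
* The benchmark harness treats algorithms independently per split; no
  significance testing across algorithms is performed.
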