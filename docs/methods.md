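# Methods

## Model and data preparation

A corpus `D` is a set of paths over a finite label alphabet `S`.  Paths are
kept only if they contain at least two visited states (`filter_min_length`,
default 2), matching standard practice for navigation sessions where a single
click carries no transition information.  For an order-`k` analysis every path
is independently augmented with `k` leading `RESET` symbols and one trailing
`RESET`.  `RESET` is a first-class state: it both resets the history between
paths and makes path termination a predictable event, so the effective state
count is `m = |S| + 1`.  Windows never span two paths — the counting is
strictly per path, so no artificial `RESET -> RESET` transitions arise between
consecutive paths, and a path of length `L` contributes exactly `L + 1`
transitions regardless of `k`.  Time-homogeneity is assumed throughout:
estimates depend only on counts, never on within-path position.

Histories are encoded as base-`m` integers (oldest symbol most significant),
which keeps the count table sparse in the observed histories while windows are
tallied with vectorised integer arithmetic.

## Estimators

* **MLE** (`mle_estimate`): `p(j|i) = n_ij / n_i` per observed history row.
  Unobserved histories are deliberately *undefined* rather than uniform: the
  training log-likelihood is then always finite and equal to the count tally,
  and all smoothing is the Bayesian estimator's job.
* **Posterior mean** (`posterior_mean_model`): with a Dirichlet prior
  (`alpha` scalar or per-target vector, default 1 — Laplace smoothing) the row
  is `(alpha_ij + n_ij) / (A_i + n_i)`, a convex combination of MLE and prior
  mean; unobserved histories return the prior mean row.  The posterior
  variance of one cell is `u (1 - u) / (A + n_i + 1)`.
* Prior pseudo-counts are placed on the full nominal target set of each row,
  including structurally impossible cells (e.g. transitions into `RESET` out
  of a start history).  This is the simplest consistent convention; its only
  effect is a slightly stronger evidence penalty on higher orders, shared by
  all candidate orders.

Row sums are validated to 1 within 1e-9; log-space computation is used
wherever products of probabilities would occur; `-inf` is a legal
log-likelihood (a model that cannot explain a test transition), not an error.

## Order selection

For candidate orders `k = 0..k_max` (default 5, configurable — all analyses in
the tests use `k_max = 4`):

* **LRT**: statistic `2 (logL_alt - logL_null)` with upper-tail chi-square
  p-value.  The default df is the nominal difference in free parameters,
  `(m^k1 - m^k0)(m - 1)`.  Because RESET augmentation creates structural
  zeros (mid-history RESET rows can never occur, and targets such as
  `RESET` out of a start history may be impossible), the nominal df badly
  overstates the realisable table in sparse regimes and the test becomes
  fully conservative.  A support-based alternative
  (`observed_degrees_of_freedom`): df = difference of `sum over observed rows
  (observed targets - 1)`, asymptotically the structural df, is provided and
  is what the calibration study uses.  Significance is flagged at the 1% and
  0.1% levels; no multiple-testing correction is applied to the LRT table.
* **AIC / BIC**: `-2 logL + 2p` and `-2 logL + p ln N`.  AIC is reported in
  its standard form; rank-equivalent variants (relative to the top order)
  differ only by a k-independent constant, so the minimum-AIC choice is
  unchanged.
* **Bayesian evidence**: per row
  `Gamma(A_i)/Gamma(A_i + n_i) * prod_j Gamma(alpha_ij + n_ij)/Gamma(alpha_ij)`,
  summed in log space with `gammaln`.  Rows without observations contribute a
  factor of one, so computing over observed rows equals the full-table value
  exactly.  Model posteriors use a uniform prior and an exponential penalty
  `prior(M_k) ∝ exp(-m^k)`, where `m^k` is the state count of the order-`k`
  chain converted to first order; `m` is the full vocabulary including RESET.
  Normalisation pulls the largest log term out of the sum (log-sum-exp), so
  evidences of order -1e5 normalise without underflow.
* **Cross-validation**: stratified 10-fold.  Whole paths are shuffled
  (seeded) and greedily packed into the currently lightest fold by click
  count; fold totals then differ by at most the longest path, giving
  approximately 10% of all clicks per fold without splitting any path between
  train and test (which would leak history).  Prediction uses posterior-mean
  matrices (`alpha = 1`); an MLE mode exists behind a flag for sensitivity
  analysis.  The score is the average modified-competition rank of the true
  next state; unseen test histories score the maximum rank `m` for every
  state.  Because sparser higher-order tables produce more smoothed-floor
  ties (all scored at the group's worst rank) and more unseen histories, this
  criterion carries a natural complexity penalty.  A Top-K hit rate
  (default K = 5) is available; boundary tie groups are resolved by seeded
  uniform draws, one per test transition.  Transitions into `RESET` are
  scored by default (they are counted transitions); a flag excludes them.

## Synthetic generators — what they emulate

* `generate_uniform_corpus(n_states=26, ...)`: every draw is uniform over
  `n_states` symbols, one of which is a terminal marker that ends the current
  path and is not emitted.  This reproduces the classic memoryless control:
  path lengths are geometric, raw log-likelihood still rises with order, and
  only complexity-aware criteria recover the truth.  Defaults (26 symbols,
  ~1e5 clicks) mirror a topic-level navigation corpus scale.
* `generate_markov_corpus(GeneratorSpec)`: an explicit order-`k` tensor over
  data states, uniform initial histories, geometric termination with
  `stop_prob` (default 0.125, i.e. mean path length 8 clicks, in line with
  observed navigation datasets at ~6-7) or a fixed length.  `random_stochastic_tensor`
  draws rows from a symmetric Dirichlet (default concentration 1.0 — uniform
  over the simplex).

Two caveats documented deliberately:

1. **The min-length filter breaks exact first-orderness.**  Filtering out
   single-click paths removes the event "the path ends after one click", so in
   a filtered corpus `RESET` can never follow the first click — a genuine
   second-order effect at the path boundary.  The LRT calibration study
   therefore scores *unfiltered* corpora, where geometric termination makes
   the augmented chain exactly first order.  (Filtered, the 1-vs-2 test
   correctly rejects essentially always — the structure is real.)
2. **Chi-square validity needs populated cells.**  The calibration fixture
   draws generating rows with concentration 5.0 so that every feasible cell
   has expected counts far above the usual chi-square threshold; with
   concentration 1.0 near-zero cells make the test mildly anticonservative.

What the generators do *not* emulate: heavy-tailed path-length distributions,
non-stationary (position-dependent) behaviour, semi-Markov dwell times, or
state spaces of real page-level data (~1e5 states).  Passing tests therefore
validate the estimators and criteria, not any claim about a particular
empirical system.

## Numerical choices

* Row-sum tolerance 1e-9; posterior/MLE comparison tolerances 1e-6; evidence
  vs. quadrature agreement 1e-6 (achieved ~1e-13).
* History codes are int64; the counting layer refuses orders where
  `m^(k+1)` would overflow, and `free_parameters` caps the order at 16.
* Tie-breaking: `top_transitions` breaks probability ties by label order;
  ranking uses worst-of-tie-group; Top-K boundary ties are seeded uniform
  draws.
* Problem sizes in the test and acceptance studies: 1e5 clicks for the
  26-state control, 5e4 clicks for the 5-state recovery study, 500 replicates
  of 1e4 clicks for the LRT calibration — sizes at which every criterion's
  behaviour is already unambiguous while the whole suite runs in well under a
  minute.

## Estimator shape

The core API follows scikit-learn conventions (`MarkovChain`,
`MarkovOrderSelector`: `fit`, `score`, `get_params`/`set_params`, fitted
attributes with trailing underscores).  Samples are path corpora rather than
feature matrices, so composition with sklearn pipelines is limited to the
parameter/cloning API; the module-level functions remain the primitive
interface and the CLI wraps them.

## Known limitations

* MSNBC-dialect ingestion expects the published single-legend layout; other
  UCI variants are not auto-detected.
* The relabeling step takes the label-to-category mapping as given (one
  uniform draw per label under a seed for multi-category ties); computing
  such mappings from a category graph is out of scope.
* The exponential model prior uses the full nominal state count `m^k`;
  restricting it to feasible histories would weaken the penalty but is not
  implemented (the uniform-prior posterior is reported alongside and has
  agreed with it in every study here).
* Evidence, AIC/BIC and LRT all condition on a single global `alpha`; no
  empirical-Bayes tuning of hyperparameters is attempted.
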