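# markov-memory

Toolkit for detecting **memory** in categorical event sequences — clickstreams,
navigation sessions, or any corpus of paths over a finite alphabet — by fitting
discrete Markov chains of varying order *k* and deciding which memory length the
data actually supports.  It is aimed at researchers in computational social
science, web analytics and biostatistics who need a defensible answer to "is
this process memoryless, or does the next state depend on a longer history?"

## The model

A corpus is a set of paths `p = (x_1, ..., x_L)` over states `S`.  For an
order-*k* chain, each path is augmented with *k* leading `RESET` symbols and one
trailing `RESET`, so histories never leak across paths and path termination is
itself predicted; with `RESET` the state count is `m = |S| + 1`.  Transition
probabilities are estimated per history row either by maximum likelihood,
`p(j|i) = n_ij / n_i`, or as the Dirichlet posterior mean
`(alpha_ij + n_ij) / (A_i + n_i)` (`alpha = 1` is Laplace smoothing).

Four complementary order-selection criteria are implemented:

* **Likelihood-ratio tests** of nested orders: `2 (logL_k1 - logL_k0)` against a
  chi-square law, with either the nominal `df = (m^k1 - m^k0)(m - 1)` or a
  support-based df for sparse, structurally-zeroed tables;
* **AIC** `= -2 logL + 2p` and **BIC** `= -2 logL + p ln N` with
  `p = m^k (m - 1)` free parameters;
* **Bayesian evidence**: the closed-form Dirichlet-multinomial marginal
  likelihood per row, combined into model posteriors under a uniform prior and
  under an exponential complexity penalty `prior(M_k) ∝ exp(-m^k)`
  (log-sum-exp normalised);
* **Cross-validated prediction rank**: stratified 10-fold evaluation of the
  average rank of the true next state under modified competition ranking
  (ties share their group's worst rank, "14445"), plus an optional Top-K hit
  rate.

A structural layer exports globally-normalised transition tables (heatmap
matrices), per-history top transitions, self-transition ("stickiness")
profiles by conditioning order, and endpoint-conditioned corpus splits.

## Worked example

Recover the order of a known second-order chain over 4 data states
(`m = 5` with `RESET`), ~50,000 clicks:

```python
from markov_memory import (GeneratorSpec, filter_min_length, generate_markov_corpus,
                           random_stochastic_tensor, select_order, cv_order_evaluation)

tensor = random_stochastic_tensor(4, 2, concentration=1.0, seed=11)
spec = GeneratorSpec(n_states=4, order=2, tensor=tensor, total_clicks=50_000, seed=12)
corpus = filter_min_length(generate_markov_corpus(spec), min_len=2)

report = select_order(corpus, k_max=4)
print(report.orders.round(2))
print(report.selected)

cv = cv_order_evaluation(corpus, k_max=4, n_folds=10, seed=5)
print(cv.mean_rank.round(3), cv.selected_order)
```

prints

```
           logL  free_params        aic        bic  log_evidence  posterior_uniform  posterior_exp_penalty
order
0     -85639.76            4  171287.51  171323.14     -85658.86                0.0                    0.0
1     -83363.12           20  166766.24  166944.38     -83446.11                0.0                    0.0
2     -72607.82          100  145415.64  146306.36     -72908.11                1.0                    1.0
3     -72481.67          500  145963.35  150416.90     -73361.17                0.0                    0.0
4     -71975.11         2500  148950.21  171217.99     -74308.66                0.0                    0.0
{'aic': 2, 'bic': 2, 'log_evidence': 2, 'posterior_uniform': 2, 'posterior_exp_penalty': 2, 'lrt': 2}
order
0    2.678
1    2.512
2    2.160
3    2.169
4    2.190
cv selected: 2
```

Read it as: raw log-likelihood keeps rising with the order (it always does —
higher orders nest lower ones), but every complexity-aware criterion points at
`k = 2`: AIC/BIC are minimised there, the Bayesian posterior concentrates on 2
under both model priors, the LRT chain stops improving significantly past 2,
and held-out prediction rank bottoms out at 2 with order 3 only marginally
behind.

The same machinery is exposed as scikit-learn style estimators
(`MarkovChain`, `MarkovOrderSelector`) and as a CLI:

```bash
markov-memory synth uniform --states 26 --clicks 100000 --seed 1 --out corpus.tsv
markov-memory corpus stats corpus.tsv
markov-memory select corpus.tsv --kmax 4 --out report.tsv
markov-memory cv corpus.tsv --kmax 4 --folds 10 --seed 1 --out cv.tsv
markov-memory structure corpus.tsv --order 1 --out heatmap.tsv
```

Input formats: plain delimited text (one path per line) and the UCI-KDD
anonymous web-data sequence dialect (legend line plus 1-based integer-coded
sessions).

## Documentation

`docs/methods.md` describes the statistical model, the numerical choices
(log-gamma evidence, log-sum-exp normalisation, tie policies, degrees of
freedom for sparse tables), the synthetic generators and what they do and do
not emulate, and known limitations.
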