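"""Markov-order selection: likelihood-ratio tests, AIC/BIC, Bayesian evidence.

Four complementary criteria decide the memory length k of a chain over m
states (including RESET):

* nested likelihood-ratio tests, 2*(logL_alt - logL_null) against a
  chi-square law;
* AIC = -2 logL + 2 p and BIC = -2 logL + p ln N with p = m^k (m - 1) free
  parameters;
* the Dirichlet-multinomial log-evidence (marginal likelihood with the
  transition probabilities integrated out), turned into model posteriors
  under a uniform prior and under an exponential complexity penalty
  prior(M_k) proportional to exp(-m^k), normalised with the log-sum-exp
  trick.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .corpus import PathCorpus, TransitionCounts, augment_and_count
from .estimation import _alpha_vector, log_likelihood, mle_estimate

__all__ = [
    "free_parameters",
    "LRTResult",
    "likelihood_ratio_test",
    "observed_degrees_of_freedom",
    "aic",
    "bic",
    "log_evidence",
    "model_posterior",
    "OrderSelectionReport",
    "select_order",
    "MarkovOrderSelector",
]

MAX_ORDER = 16
_NESTING_TOL = 1e-8


def free_parameters(m: int, k: int, max_order: int = MAX_ORDER) -> int:
    """Number of free probabilities of an order-k chain: m^k rows times (m-1)."""
    if m < 2:
        raise ValueError("m must be >= 2")
    if k < 0:
        raise ValueError("order must be >= 0")
    if k > max_order:
        raise ValueError(f"order {k} beyond configured cap {max_order}")
    return m**k * (m - 1)


@dataclass(frozen=True)
class LRTResult:
    order_null: int
    order_alt: int
    statistic: float
    df: int
    p_value: float
    significant_1pct: bool = field(init=False)
    significant_01pct: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "significant_1pct", self.p_value < 0.01)
        object.__setattr__(self, "significant_01pct", self.p_value < 0.001)


def likelihood_ratio_test(
    logL_null: float,
    logL_alt: float,
    m: int,
    k0: int,
    k1: int,
    df: int | None = None,
) -> LRTResult:
    """Test a nested lower-order chain against a higher-order alternative.

    The statistic is -2 log(lambda) = 2 (logL_alt - logL_null); under the null
    it approximately follows chi-square with ``df`` degrees of freedom
    (default: the nominal difference in free parameters).
    """
    if k0 >= k1:
        raise ValueError("null order must be smaller than alternative order")
    if logL_alt < logL_null - _NESTING_TOL:
        raise ValueError("models not nested / likelihood inversion")
    statistic = max(0.0, 2.0 * (logL_alt - logL_null))
    if df is None:
        df = free_parameters(m, k1) - free_parameters(m, k0)
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    p_value = float(chi2.sf(statistic, df))
    return LRTResult(order_null=k0, order_alt=k1, statistic=statistic, df=int(df), p_value=p_value)


def observed_degrees_of_freedom(counts_null: TransitionCounts, counts_alt: TransitionCounts) -> int:
    """Support-based df for sparse tables with structural zeros.

    RESET augmentation makes many nominal rows (and some targets) impossible,
    so the realizable difference in free parameters is the difference of
    sum over observed rows of (number of observed targets - 1).
    """

    def _df(counts: TransitionCounts) -> int:
        support = (counts.matrix > 0).sum(axis=1)
        return int((support - 1).sum())

    return _df(counts_alt) - _df(counts_null)


def aic(logL: float, m: int, k: int) -> float:
    """Akaike information criterion -2 logL + 2 p (minimised by MAICE)."""
    if not np.isfinite(logL):
        raise ValueError("log-likelihood must be finite")
    return -2.0 * logL + 2.0 * free_parameters(m, k)


def bic(logL: float, m: int, k: int, N: int) -> float:
    """Bayesian information criterion -2 logL + p ln N."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return -2.0 * logL + free_parameters(m, k) * float(np.log(N))


def log_evidence(
    counts: TransitionCounts,
    alpha: Union[float, Sequence[float], np.ndarray] = 1.0,
) -> float:
    """Dirichlet-multinomial log marginal likelihood of the counts.

    Product over histories of
    Gamma(A_i)/Gamma(A_i + n_i) * prod_j Gamma(alpha_ij + n_ij)/Gamma(alpha_ij)
    computed entirely through log-gamma.  Rows with no observations contribute
    a factor of one, so summing over observed histories equals the full-table
    value exactly.
    """
    m = counts.m
    alpha_vec = _alpha_vector(alpha, m)
    A = alpha_vec.sum()
    if counts.n_histories == 0:
        return 0.0
    totals = counts.row_totals().astype(float)
    row_terms = gammaln(A) - gammaln(A + totals)
    cell_terms = gammaln(alpha_vec + counts.matrix) - gammaln(alpha_vec)
    return float(row_terms.sum() + cell_terms.sum())


def model_posterior(
    log_evidences: Mapping[int, float],
    prior: str = "uniform",
    m: int | None = None,
) -> dict[int, float]:
    """Posterior probability of each candidate order from its log-evidence.

    ``prior="uniform"`` weights all orders equally; ``prior="exp_penalty"``
    uses prior(M_k) proportional to exp(-m^k) (the state count of the
    order-k chain converted to first order).  Normalisation pulls the largest
    term out of the sum (log-sum-exp), so evidences around -1e5 are safe.
    """
    if not log_evidences:
        raise ValueError("empty candidate set")
    orders = sorted(log_evidences)
    logev = np.array([log_evidences[k] for k in orders], dtype=float)
    if not np.all(np.isfinite(logev)):
        raise ValueError("log-evidences must be finite")
    if prior == "uniform":
        logprior = np.zeros_like(logev)
    elif prior == "exp_penalty":
        if m is None:
            raise ValueError("exp_penalty prior requires the state count m")
        logprior = -np.array([float(m) ** k for k in orders])
    else:
        raise ValueError(f"unknown model prior {prior!r}")
    logpost = logev + logprior
    logpost -= logsumexp(logpost)
    post = np.exp(logpost)
    post /= post.sum()
    return {k: float(p) for k, p in zip(orders, post)}


@dataclass
class OrderSelectionReport:
    """Per-order fit/criterion table plus the LRT table and per-criterion picks."""

    orders: pd.DataFrame  # index k; logL, free_params, aic, bic, log_evidence, posteriors
    lrt: pd.DataFrame  # one row per tested (k0, k1) pair
    selected: dict[str, int]
    m: int
    n_transitions: int
    alpha: float | np.ndarray = 1.0

    def to_tsv(self, file, lrt_file=None) -> None:
        self.orders.to_csv(file, sep="\t", index_label="order")
        if lrt_file is not None:
            self.lrt.to_csv(lrt_file, sep="\t", index=False)


def select_order(
    corpus: PathCorpus,
    k_max: int = 5,
    alpha: Union[float, Sequence[float], np.ndarray] = 1.0,
    df_mode: str = "nominal",
) -> OrderSelectionReport:
    """Fit orders 0..k_max by MLE and compare them under every criterion.

    Returns the per-order table (log-likelihood, parameter count, AIC, BIC,
    log-evidence, model posteriors under both priors), the LRT table over
    consecutive and versus-k_max pairs, and the per-criterion selected order.
    Deterministic given the corpus and alpha.
    """
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    if df_mode not in ("nominal", "observed"):
        raise ValueError(f"unknown df_mode {df_mode!r}")
    m = corpus.vocabulary.m
    ks = list(range(k_max + 1))
    counts = {k: augment_and_count(corpus, k) for k in ks}
    N = counts[0].total_transitions
    logL = {}
    for k in ks:
        model = mle_estimate(counts[k])
        logL[k] = log_likelihood(model, counts[k])
    logev = {k: log_evidence(counts[k], alpha) for k in ks}

    table = pd.DataFrame(
        {
            "logL": [logL[k] for k in ks],
            "free_params": [free_parameters(m, k) for k in ks],
            "aic": [aic(logL[k], m, k) for k in ks],
            "bic": [bic(logL[k], m, k, N) for k in ks],
            "log_evidence": [logev[k] for k in ks],
        },
        index=pd.Index(ks, name="order"),
    )
    if len(ks) > 1:
        post_u = model_posterior(logev, prior="uniform")
        post_e = model_posterior(logev, prior="exp_penalty", m=m)
    else:
        post_u = {ks[0]: 1.0}
        post_e = {ks[0]: 1.0}
    table["posterior_uniform"] = [post_u[k] for k in ks]
    table["posterior_exp_penalty"] = [post_e[k] for k in ks]

    pairs = [(k, k + 1) for k in ks[:-1]] + [(k, k_max) for k in ks[:-2]]
    rows = []
    for k0, k1 in pairs:
        df = None
        if df_mode == "observed":
            df = observed_degrees_of_freedom(counts[k0], counts[k1])
        res = likelihood_ratio_test(logL[k0], logL[k1], m, k0, k1, df=df)
        rows.append(
            {
                "order_null": k0,
                "order_alt": k1,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "significant_1pct": res.significant_1pct,
                "significant_01pct": res.significant_01pct,
            }
        )
    lrt = pd.DataFrame(
        rows,
        columns=[
            "order_null",
            "order_alt",
            "statistic",
            "df",
            "p_value",
            "significant_1pct",
            "significant_01pct",
        ],
    )

    selected = {
        "aic": int(table["aic"].idxmin()),
        "bic": int(table["bic"].idxmin()),
        "log_evidence": int(table["log_evidence"].idxmax()),
        "posterior_uniform": int(max(post_u, key=post_u.__getitem__)),
        "posterior_exp_penalty": int(max(post_e, key=post_e.__getitem__)),
    }
    # LRT pick: smallest order whose consecutive upgrade is not significant at 1%.
    lrt_pick = k_max
    for k in ks[:-1]:
        row = lrt[(lrt.order_null == k) & (lrt.order_alt == k + 1)]
        if len(row) and not bool(row.iloc[0]["significant_1pct"]):
            lrt_pick = k
            break
    selected["lrt"] = int(lrt_pick)

    return OrderSelectionReport(
        orders=table, lrt=lrt, selected=selected, m=m, n_transitions=N, alpha=alpha
    )


class MarkovOrderSelector(BaseEstimator):
    """Estimator wrapper around :func:`select_order`.

    ``selected_order_`` follows the Bayesian model posterior under the uniform
    prior (the criterion the full report also tabulates alongside AIC, BIC and
    the LRT table in ``report_``).
    """

    def __init__(self, k_max: int = 5, alpha: float = 1.0, df_mode: str = "nominal"):
        self.k_max = k_max
        self.alpha = alpha
        self.df_mode = df_mode

    def fit(self, X, y=None) -> "MarkovOrderSelector":
        corpus = X if isinstance(X, PathCorpus) else PathCorpus.from_paths(X)
        self.report_ = select_order(corpus, k_max=self.k_max, alpha=self.alpha, df_mode=self.df_mode)
        self.selected_order_ = self.report_.selected["posterior_uniform"]
        self.selected_orders_ = dict(self.report_.selected)
        return self
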