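"""Beta-binomial conjugate machinery for single-arm response-rate monitoring.

The single-arm model treats the number of responders among ``n`` evaluable
patients as Binomial(n, p) with a conjugate Beta prior on the response rate
``p``.  Everything downstream — the final success rule ("at least a 90%
posterior probability that the response rate exceeds 0.1"), the discretized
responder boundary at the final analysis, and the posterior-predictive
probability of success (PPoS) used at the interim look — is closed form or a
finite sum over the beta-binomial predictive distribution of the remaining
patients.

The default prior is the near-improper Beta(1e-3, 1e-3), which places almost
all its mass at the boundary of the unit interval; tail probabilities are
therefore computed with scipy's regularized-incomplete-beta routines, which
remain accurate for such shapes, rather than with naive density integration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BetaParams",
    "BinomialData",
    "SuccessRule",
    "update_posterior",
    "prob_rate_exceeds",
    "posterior_predictive_pmf",
    "min_responders_final",
    "predictive_prob_success",
    "DEFAULT_PRIOR",
    "DEFAULT_RULE",
]


@dataclass(frozen=True)
class BetaParams:
    """Shape pair (a, b) of a Beta distribution on the response rate."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and np.isfinite(self.a)):
            raise ValueError(f"Beta shape a must be positive and finite, got {self.a}")
        if not (self.b > 0 and np.isfinite(self.b)):
            raise ValueError(f"Beta shape b must be positive and finite, got {self.b}")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)


@dataclass(frozen=True)
class BinomialData:
    """Observed responders ``x`` out of ``n`` evaluable patients."""

    x: int
    n: int

    def __post_init__(self) -> None:
        if int(self.x) != self.x or int(self.n) != self.n:
            raise ValueError("x and n must be integers")
        if self.n < 0:
            raise ValueError(f"n must be non-negative, got {self.n}")
        if not (0 <= self.x <= self.n):
            raise ValueError(f"need 0 <= x <= n, got x={self.x}, n={self.n}")


@dataclass(frozen=True)
class SuccessRule:
    """Final success rule: P(p > rate_threshold | data) >= confidence.

    The comparison with ``confidence`` is non-strict: "a 90% posterior
    probability" is read as meeting the 90% level.  Both fields are
    parameters so the rule can be reused outside the default (0.1, 0.90)
    setting.
    """

    rate_threshold: float = 0.1
    confidence: float = 0.90

    def __post_init__(self) -> None:
        if not (0 < self.rate_threshold < 1):
            raise ValueError(f"rate_threshold must be in (0,1), got {self.rate_threshold}")
        if not (0 < self.confidence < 1):
            raise ValueError(f"confidence must be in (0,1), got {self.confidence}")


#: Near-improper default prior on the response rate.
DEFAULT_PRIOR = BetaParams(1e-3, 1e-3)

#: Default final rule: 90% posterior probability that the rate exceeds 0.1.
DEFAULT_RULE = SuccessRule()


def update_posterior(prior: BetaParams, data: BinomialData) -> BetaParams:
    """Conjugate update: Beta(a, b) x Binomial(x, n) -> Beta(a+x, b+n-x)."""
    return BetaParams(prior.a + data.x, prior.b + data.n - data.x)


def prob_rate_exceeds(post: BetaParams, threshold: float) -> float:
    """Posterior probability that the response rate exceeds ``threshold``.

    Equals one minus the regularized incomplete beta function at
    ``threshold`` — i.e. the survival function of Beta(a, b).
    """
    if not (0 < threshold < 1):
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    return float(stats.beta.sf(threshold, post.a, post.b))


def posterior_predictive_pmf(post: BetaParams, m: int) -> np.ndarray:
    """Beta-binomial predictive pmf over 0..m future responders.

    ``m`` is the number of patients still to be enrolled; the returned vector
    has length m+1 and sums to 1.
    """
    if int(m) != m or m < 0:
        raise ValueError(f"m must be a non-negative integer, got {m}")
    if m == 0:
        return np.ones(1)
    k = np.arange(m + 1)
    return stats.betabinom.pmf(k, m, post.a, post.b)


def min_responders_final(
    n_total: int,
    prior: BetaParams = DEFAULT_PRIOR,
    rule: SuccessRule = DEFAULT_RULE,
) -> int | None:
    """Smallest total responder count declaring final success, or None.

    Scans r = 0..n_total and returns the least r whose posterior satisfies
    the success rule.  ``None`` signals that no responder count at this
    sample size can satisfy the rule ("no feasible boundary"); callers such
    as the design search must treat that explicitly rather than receive a
    silently out-of-range integer.
    """
    if int(n_total) != n_total or n_total < 1:
        raise ValueError(f"n_total must be a positive integer, got {n_total}")
    for r in range(n_total + 1):
        post = update_posterior(prior, BinomialData(r, n_total))
        if prob_rate_exceeds(post, rule.rate_threshold) >= rule.confidence:
            return r
    return None


def predictive_prob_success(
    prior: BetaParams,
    interim: BinomialData,
    n_total: int,
    rule: SuccessRule = DEFAULT_RULE,
) -> float:
    """Posterior predictive probability of final success (PPoS) at an interim.

    Integrates the final success indicator over the beta-binomial predictive
    distribution of the remaining ``n_total - interim.n`` patients:

        PPoS = sum_k  P(K = k | posterior) * 1{interim.x + k >= r_min},

    where r_min is the discretized final boundary from
    :func:`min_responders_final`.  If no boundary is feasible the trial
    cannot succeed and the PPoS is 0.  With no patients remaining the value
    is exactly the 0/1 indicator of final success.
    """
    if int(n_total) != n_total or n_total < interim.n:
        raise ValueError(
            f"n_total must be an integer >= interim.n, got n_total={n_total}, interim.n={interim.n}"
        )
    r_min = min_responders_final(n_total, prior, rule)
    if r_min is None:
        return 0.0
    m = n_total - interim.n
    if interim.x >= r_min:
        return 1.0
    if interim.x + m < r_min:
        return 0.0
    post = update_posterior(prior, interim)
    pmf = posterior_predictive_pmf(post, m)
    return float(pmf[r_min - interim.x :].sum())
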