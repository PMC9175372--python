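"""Shared independent oracles for the test suite.

These deliberately avoid the package's own computational paths: the
two-stage oracle walks patient-level outcome sequences, the PPoS oracle
integrates the binomial tail against the posterior density by adaptive
quadrature on the rate scale, and the two-arm oracle is self-normalized
importance sampling from the exactly-sampleable part of the model.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import integrate, stats


def two_stage_oc_by_sequences(n1: int, r1: int, n: int, r_total: int, p: float):
    """Exact OC by enumerating all 2^n patient response sequences.

    Walks every binary outcome sequence, applies the sequential rule
    (stop at n1 if stage-1 responders <= r1), and accumulates the exact
    sequence probability.  Exponential cost: only for small n.
    """
    success = 0.0
    pet = 0.0
    en = 0.0
    for bits in range(2**n):
        seq = [(bits >> i) & 1 for i in range(n)]
        prob = p ** sum(seq) * (1 - p) ** (n - sum(seq))
        x1 = sum(seq[:n1])
        if x1 <= r1:
            pet += prob
            en += n1 * prob
        else:
            en += n * prob
            if sum(seq) >= r_total:
                success += prob
    return success, pet, en


def monitored_oc_by_joint_outcomes(decisions: list[str], n1: int, n: int, r_total: int, p: float):
    """Exact OC of an interim decision table by (x1, x2) joint enumeration.

    Uses math.comb directly so the probability arithmetic is independent
    of the package's scipy-based tail sums.
    """
    n2 = n - n1
    success = 0.0
    pet = 0.0
    for x1 in range(n1 + 1):
        w1 = math.comb(n1, x1) * p**x1 * (1 - p) ** (n1 - x1)
        d = decisions[x1]
        if d == "stop-efficacy":
            success += w1
            pet += w1
        elif d == "stop-futility":
            pet += w1
        else:
            for x2 in range(n2 + 1):
                if x1 + x2 >= r_total:
                    success += w1 * math.comb(n2, x2) * p**x2 * (1 - p) ** (n2 - x2)
    return success, pet


def ppos_by_rate_integration(a: float, b: float, m: int, r_needed: int) -> float:
    """PPoS oracle: E_p[ P(Bin(m, p) >= r_needed) ] under Beta(a, b).

    Adaptive quadrature of the posterior density times the binomial tail
    on the rate scale — a route through continuous integration rather
    than the beta-binomial pmf.
    """
    if r_needed <= 0:
        return 1.0
    if r_needed > m:
        return 0.0
    val, _ = integrate.quad(
        lambda p: stats.beta.pdf(p, a, b) * stats.binom.sf(r_needed - 1, m, p),
        0.0,
        1.0,
        points=[1e-12, 1 - 1e-12],
        limit=200,
    )
    return val


def mc_prob_or_gt1(
    x_b: int,
    n_b: int,
    x_c: int,
    n_c: int,
    n_draws: int = 1_000_000,
    seed: int = 20240501,
    a: float = 1e-3,
    b: float = 1e-3,
    var: float = 1000.0,
) -> tuple[float, float]:
    """Importance-sampling oracle for P(log-OR > 0 | data), with its SE.

    Samples the control rate exactly from the arm-B-only posterior
    Beta(a + x_b, b + n_b - x_b) and delta from its Gaussian prior, then
    weights by the arm-C likelihood.  Returns (estimate, standard error)
    of the self-normalized ratio.
    """
    rng = np.random.default_rng(seed)
    p = rng.beta(a + x_b, b + n_b - x_b, size=n_draws)
    delta = rng.normal(0.0, math.sqrt(var), size=n_draws)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.log(p) - np.log1p(-p)
        t = theta + delta
        log_e = -np.logaddexp(0.0, -t)
        log_ne = -np.logaddexp(0.0, t)
        logw = (0.0 if x_c == 0 else x_c * log_e) + (
            0.0 if n_c - x_c == 0 else (n_c - x_c) * log_ne
        )
    logw = np.nan_to_num(logw, nan=-np.inf)
    w = np.exp(logw - logw.max())
    sw = w.sum()
    phat = float((w * (delta > 0)).sum() / sw)
    resid = w * ((delta > 0) - phat)
    se = float(np.sqrt((resid**2).sum()) / sw)
    return phat, se


@pytest.fixture(scope="session")
def paper_design_search():
    """The exhaustive search under the trial's constraints, run once."""
    from phase2bayes import search_designs

    return search_designs()
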