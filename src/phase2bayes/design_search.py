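"""Exact two-stage design evaluation and exhaustive optimal/minimax search.

A two-stage design (n1, r1, n, r_total) enrolls n1 patients, stops for
futility if stage-1 responders are <= r1 (r1 = -1 disables the futility
stop), otherwise enrolls to n and declares success when total responders
reach r_total.  Note the success convention: r_total is the *minimum total
responders declaring success*; the common alternative "reject H1 if total
<= r" converts as r_total = r + 1.

Operating characteristics are exact binomial tail sums, so the search can
certify type-I error and power to machine precision.  The search enumerates
every design up to a sample-size cap and reports the Simon-type "optimal"
design (minimum expected sample size under the null rate p0) and "minimax"
design (minimum total n), with deterministic tie-breaking.

The module also translates the Bayesian interim monitoring rules — stop for
futility when the posterior-predictive probability of success (PPoS) falls
below a futility cut, stop for efficacy when it exceeds an efficacy cut —
into an explicit stage-1 decision table, and evaluates the exact operating
characteristics of the monitored design so the frequentist and Bayesian
descriptions of the same trial can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .bayes_conjugate import (
    DEFAULT_PRIOR,
    DEFAULT_RULE,
    BetaParams,
    BinomialData,
    SuccessRule,
    min_responders_final,
    predictive_prob_success,
)

__all__ = [
    "DesignConstraints",
    "TwoStageDesign",
    "OperatingChars",
    "InterimDecision",
    "InterimDecisionTable",
    "SearchResult",
    "exact_operating_chars",
    "search_designs",
    "bayesian_interim_rules",
    "evaluate_monitored_design",
]


@dataclass(frozen=True)
class DesignConstraints:
    """Frequentist design constraints for the two-stage search."""

    p0: float = 0.1
    p1: float = 0.3
    alpha_max: float = 0.1
    power_min: float = 0.8
    n_max: int = 60

    def __post_init__(self) -> None:
        if not (0 < self.p0 < self.p1 < 1):
            raise ValueError(f"need 0 < p0 < p1 < 1, got p0={self.p0}, p1={self.p1}")
        if not (0 < self.alpha_max < 1) or not (0 < self.power_min < 1):
            raise ValueError("alpha_max and power_min must be in (0,1)")
        if int(self.n_max) != self.n_max or self.n_max < 2:
            raise ValueError(f"n_max must be an integer >= 2, got {self.n_max}")


@dataclass(frozen=True)
class TwoStageDesign:
    """Two-stage design: interim at n1 with futility bound r1, success at r_total/n."""

    n1: int
    r1: int
    n: int
    r_total: int

    def __post_init__(self) -> None:
        if not (1 <= self.n1 < self.n):
            raise ValueError(f"need 1 <= n1 < n, got n1={self.n1}, n={self.n}")
        if not (-1 <= self.r1 < self.r_total <= self.n):
            raise ValueError(
                f"need -1 <= r1 < r_total <= n, got r1={self.r1}, "
                f"r_total={self.r_total}, n={self.n}"
            )


@dataclass(frozen=True)
class OperatingChars:
    """Exact operating characteristics of a design at one true rate."""

    success_prob: float
    pet: float
    expected_n: float


@dataclass(frozen=True)
class InterimDecision:
    x1: int
    ppos: float
    decision: str  # "stop-futility" | "continue" | "stop-efficacy"


@dataclass(frozen=True)
class InterimDecisionTable:
    """Per-x1 interim decisions for stage-1 responder counts 0..n1."""

    n1: int
    n_total: int
    rows: tuple[InterimDecision, ...]

    def decision(self, x1: int) -> str:
        return self.rows[x1].decision

    @property
    def futility_boundary(self) -> int:
        """Largest x1 stopped for futility (-1 if none): the induced r1."""
        r1 = -1
        for row in self.rows:
            if row.decision == "stop-futility":
                r1 = row.x1
        return r1

    @property
    def efficacy_boundary(self) -> int | None:
        """Smallest x1 stopped for efficacy (None if no efficacy stop)."""
        for row in self.rows:
            if row.decision == "stop-efficacy":
                return row.x1
        return None


@dataclass(frozen=True)
class SearchResult:
    optimal: TwoStageDesign
    minimax: TwoStageDesign
    admissible: tuple[TwoStageDesign, ...]
    optimal_oc_p0: OperatingChars
    optimal_oc_p1: OperatingChars
    constraints: DesignConstraints = field(repr=False, default=DesignConstraints())


class InfeasibleDesignError(RuntimeError):
    """No design within the sample-size cap meets the constraints."""


def exact_operating_chars(design: TwoStageDesign, p: float) -> OperatingChars:
    """Exact success probability, PET and expected sample size at true rate p.

    success_prob = sum_{x1 > r1} Binom(x1; n1, p) P(X2 >= r_total - x1),
    PET = P(X1 <= r1), expected_n = n1 + (1 - PET)(n - n1).
    """
    if not (0 < p < 1):
        raise ValueError(f"p must be in (0,1), got {p}")
    n1, r1, n, r_total = design.n1, design.r1, design.n, design.r_total
    n2 = n - n1
    x1 = np.arange(r1 + 1, n1 + 1)
    pmf1 = stats.binom.pmf(x1, n1, p)
    need = np.clip(r_total - x1, 0, None)
    sf2 = stats.binom.sf(need - 1, n2, p)
    success = float(np.sum(pmf1 * sf2))
    pet = float(stats.binom.cdf(r1, n1, p)) if r1 >= 0 else 0.0
    expected_n = n1 + (1.0 - pet) * n2
    return OperatingChars(success, pet, expected_n)


def search_designs(constraints: DesignConstraints = DesignConstraints()) -> SearchResult:
    """Exhaustively enumerate two-stage designs and pick optimal and minimax.

    Admissible designs satisfy success_prob(p0) <= alpha_max and
    success_prob(p1) >= power_min.  The optimal design minimizes the
    expected sample size at p0 (ties: smaller n, then smaller n1, then
    smaller r1, then smaller r_total); the minimax design minimizes n
    (ties: smaller expected sample size at p0, then the same chain).

    For each (n1, r1, n) only the smallest admissible r_total is retained:
    raising r_total strictly lowers both the type-I error and the power
    while leaving the expected sample size unchanged, so the least r_total
    clearing the alpha constraint is the unique undominated choice.

    Raises :class:`InfeasibleDesignError` when no design up to n_max works.
    """
    p0, p1 = constraints.p0, constraints.p1
    admissible: list[tuple[float, TwoStageDesign]] = []
    for n in range(2, constraints.n_max + 1):
        for n1 in range(1, n):
            n2 = n - n1
            x1 = np.arange(n1 + 1)
            pmf1_0 = stats.binom.pmf(x1, n1, p0)
            pmf1_1 = stats.binom.pmf(x1, n1, p1)
            cdf1_0 = np.cumsum(pmf1_0)
            j = np.arange(n2 + 2)
            sf2_0 = stats.binom.sf(j - 1, n2, p0)
            sf2_1 = stats.binom.sf(j - 1, n2, p1)
            for r1 in range(-1, n1):
                pet0 = cdf1_0[r1] if r1 >= 0 else 0.0
                en0 = n1 + (1.0 - pet0) * n2
                xs = np.arange(r1 + 1, n1 + 1)
                w0 = pmf1_0[xs]
                w1 = pmf1_1[xs]
                for r_total in range(max(r1 + 1, 0), n + 1):
                    if r_total <= r1:
                        continue
                    need = np.clip(r_total - xs, 0, n2 + 1)
                    alpha = float(np.sum(w0 * sf2_0[need]))
                    if alpha > constraints.alpha_max:
                        continue  # raise r_total to shrink alpha
                    power = float(np.sum(w1 * sf2_1[need]))
                    if power >= constraints.power_min:
                        admissible.append(
                            (en0, TwoStageDesign(n1, r1, n, r_total))
                        )
                    break  # larger r_total only loses power
    if not admissible:
        raise InfeasibleDesignError(
            f"no two-stage design with n <= {constraints.n_max} attains "
            f"alpha <= {constraints.alpha_max} and power >= {constraints.power_min}"
        )

    def chain(item: tuple[float, TwoStageDesign]) -> tuple:
        en0, d = item
        return (en0, d.n, d.n1, d.r1, d.r_total)

    optimal = min(admissible, key=chain)[1]
    minimax = min(admissible, key=lambda it: (it[1].n, chain(it)))[1]
    return SearchResult(
        optimal=optimal,
        minimax=minimax,
        admissible=tuple(d for _, d in sorted(admissible, key=chain)),
        optimal_oc_p0=exact_operating_chars(optimal, p0),
        optimal_oc_p1=exact_operating_chars(optimal, p1),
        constraints=constraints,
    )


def bayesian_interim_rules(
    design_n1: int,
    n_total: int,
    prior: BetaParams = DEFAULT_PRIOR,
    rule: SuccessRule = DEFAULT_RULE,
    futility_cut: float = 0.10,
    efficacy_cut: float = 0.90,
) -> InterimDecisionTable:
    """Tabulate the PPoS interim decision for every stage-1 responder count.

    Stop for futility when PPoS < futility_cut, stop for efficacy when
    PPoS > efficacy_cut (both comparisons strict, matching the "less than
    10% / greater than 90% chance of success" wording); otherwise continue.
    PPoS is non-decreasing in x1, so the table is monotone: a futility
    region, then a continue region, then an efficacy region.
    """
    if not (0 <= futility_cut < efficacy_cut <= 1):
        raise ValueError(
            f"need 0 <= futility_cut < efficacy_cut <= 1, got "
            f"{futility_cut}, {efficacy_cut}"
        )
    if not (1 <= design_n1 < n_total):
        raise ValueError(f"need 1 <= n1 < n_total, got n1={design_n1}, n_total={n_total}")
    rows = []
    for x1 in range(design_n1 + 1):
        ppos = predictive_prob_success(prior, BinomialData(x1, design_n1), n_total, rule)
        if ppos < futility_cut:
            decision = "stop-futility"
        elif ppos > efficacy_cut:
            decision = "stop-efficacy"
        else:
            decision = "continue"
        rows.append(InterimDecision(x1, ppos, decision))
    return InterimDecisionTable(design_n1, n_total, tuple(rows))


_DECISION_ORDER = {"stop-futility": 0, "continue": 1, "stop-efficacy": 2}


def evaluate_monitored_design(
    rules: InterimDecisionTable,
    n_total: int,
    r_total: int,
    p: float,
) -> OperatingChars:
    """Exact OC of a trial monitored by an interim decision table.

    Efficacy stops count as success, futility stops as failure; on
    continuation, final success requires total responders >= r_total.
    PET counts both kinds of stage-1 stop.
    """
    if not (0 < p < 1):
        raise ValueError(f"p must be in (0,1), got {p}")
    if n_total != rules.n_total:
        raise ValueError(f"n_total={n_total} does not match table ({rules.n_total})")
    levels = [_DECISION_ORDER[row.decision] for row in rules.rows]
    if any(b < a for a, b in zip(levels, levels[1:])):
        raise ValueError("decision table is not monotone in x1")
    n1 = rules.n1
    n2 = n_total - n1
    pmf1 = stats.binom.pmf(np.arange(n1 + 1), n1, p)
    success = 0.0
    pet = 0.0
    p_continue = 0.0
    for row in rules.rows:
        w = pmf1[row.x1]
        if row.decision == "stop-efficacy":
            success += w
            pet += w
        elif row.decision == "stop-futility":
            pet += w
        else:
            p_continue += w
            need = max(r_total - row.x1, 0)
            success += w * float(stats.binom.sf(need - 1, n2, p))
    expected_n = n1 + p_continue * n2
    return OperatingChars(float(success), float(pet), float(expected_n))


def induced_two_stage_design(
    rules: InterimDecisionTable,
    r_total: int | None = None,
    prior: BetaParams = DEFAULT_PRIOR,
    rule: SuccessRule = DEFAULT_RULE,
) -> TwoStageDesign:
    """Recover the futility-only TwoStageDesign implied by a decision table.

    The monotone futility region maps to an integer stage-1 bound r1.  When
    ``r_total`` is omitted it is tied to the Bayesian final boundary
    :func:`min_responders_final`, so the frequentist and Bayesian designs
    describe one trial.
    """
    if r_total is None:
        r_total = min_responders_final(rules.n_total, prior, rule)
        if r_total is None:
            raise InfeasibleDesignError(
                f"no feasible final boundary at n={rules.n_total} under the rule"
            )
    return TwoStageDesign(rules.n1, rules.futility_boundary, rules.n_total, r_total)
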