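"""Synthetic trial generator and simulation-based operating characteristics.

The generator emulates the structure of a three-arm phase-II osteosarcoma
trial: resectable patients are registered to a single-agent arm A, while
unresectable patients are randomized 1:1 between a control arm B and an
experimental arm C using permuted blocks of sizes 2 and 4.  Each patient
carries two correlated binary co-primary endpoints — a radiological
response (complete or partial response under RECIST 1.1-style target-lesion
rules at a single six-week assessment) and a biological response (a >= 30%
relative change in an immune-activation biomarker score) — combined by the
"responder if at least one endpoint is met" rule.

Endpoint dependence is modeled with a Plackett-type construction: the
unique 2x2 cell table with the two given margins and a given cell odds
ratio.  The composite responder probability is then 1 - p00, and per-arm
component marginals are rescaled so that each arm attains its stated true
composite rate.

Simulated operating characteristics cross-validate the exact calculators:
empirical Arm-A success frequencies against the exact two-stage operating
characteristics, and the B-vs-C "recommend further research" frequency
against the posterior odds-ratio rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .arm_comparison import (
    ComparisonPriors,
    TwoArmData,
    posterior_prob_or_gt1,
    recommend_further_research,
)
from .design_search import InterimDecisionTable, TwoStageDesign

__all__ = [
    "SimulationConfig",
    "JointBinaryCells",
    "OCReport",
    "joint_binary_cells",
    "calibrate_component_rates",
    "permuted_block_randomization",
    "classify_recist",
    "biological_response",
    "combine_biomarker_criteria",
    "simulate_trial",
    "estimate_operating_characteristics",
]

#: Default marginal probability of each co-primary component, chosen so the
#: composite responder rate under independence equals the null rate 0.10:
#: 1 - (1 - p)^2 = 0.10.
_DEFAULT_COMPONENT = 1.0 - np.sqrt(0.9)

PATIENT_COLUMNS = [
    "patient_id",
    "arm",
    "baseline_sum_mm",
    "current_sum_mm",
    "new_lesions",
    "radiological_category",
    "biological_change_pct",
    "biological_response",
    "composite_responder",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of one simulated trial.

    The per-arm true rates are *composite* responder rates; the component
    marginals (p_radiological, p_biological) fix the radiological/biological
    mix and are rescaled within each arm to attain its composite rate.
    Arm C's rate may alternatively be induced from arm B's by a true
    log-odds ratio.  ``biomarker_direction`` selects whether a biomarker
    change counts in either direction or only as an increase.
    """

    n_arm_a: int = 18
    n_randomized: int = 22
    true_rate_a: float = 0.1
    true_rate_b: float = 0.1
    true_rate_c: float | None = None
    true_log_or: float | None = None
    p_radiological: float = _DEFAULT_COMPONENT
    p_biological: float = _DEFAULT_COMPONENT
    endpoint_or: float = 1.0
    block_sizes: tuple[int, ...] = (2, 4)
    biomarker_direction: str = "either"  # "either" | "increase"
    seed: int = 0
    n_reps: int = 10_000

    def __post_init__(self) -> None:
        for name in ("true_rate_a", "true_rate_b", "p_radiological", "p_biological"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.true_rate_c is not None and self.true_log_or is not None:
            raise ValueError("give true_rate_c or true_log_or, not both")
        if self.true_rate_c is not None and not (0.0 <= self.true_rate_c <= 1.0):
            raise ValueError(f"true_rate_c must be in [0,1], got {self.true_rate_c}")
        if self.endpoint_or <= 0:
            raise ValueError(f"endpoint_or must be positive, got {self.endpoint_or}")
        if not self.block_sizes or any(b <= 0 or b % 2 for b in self.block_sizes):
            raise ValueError(f"block sizes must be positive and even, got {self.block_sizes}")
        if self.biomarker_direction not in ("either", "increase"):
            raise ValueError(f"biomarker_direction must be either/increase")
        if self.n_arm_a < 0 or self.n_randomized < 0 or self.n_reps < 0:
            raise ValueError("sizes must be non-negative")

    @property
    def rate_c(self) -> float:
        """Arm C composite rate, possibly induced by the true log-OR."""
        if self.true_rate_c is not None:
            return self.true_rate_c
        log_or = 0.0 if self.true_log_or is None else self.true_log_or
        pb = self.true_rate_b
        if pb in (0.0, 1.0):
            return pb
        odds_c = pb / (1.0 - pb) * np.exp(log_or)
        return float(odds_c / (1.0 + odds_c))


@dataclass(frozen=True)
class JointBinaryCells:
    """Cell probabilities of the (radiological, biological) 2x2 table."""

    p11: float
    p10: float
    p01: float
    p00: float

    def __post_init__(self) -> None:
        cells = (self.p11, self.p10, self.p01, self.p00)
        if any(c < -1e-12 for c in cells):
            raise ValueError(f"negative cell probability in {cells}")
        if abs(sum(cells) - 1.0) > 1e-12:
            raise ValueError(f"cells must sum to 1, got {sum(cells)}")

    @property
    def composite_rate(self) -> float:
        """P(at least one endpoint met) = 1 - p00."""
        return 1.0 - self.p00


def joint_binary_cells(p1: float, p2: float, or_assoc: float) -> JointBinaryCells:
    """Unique 2x2 table with margins (p1, p2) and cell odds ratio or_assoc.

    Solves the Plackett quadratic for p11; or_assoc = 1 gives independence
    and degenerate margins (0 or 1) short-circuit to the forced table.
    """
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError(f"margins must be in [0,1], got {p1}, {p2}")
    if or_assoc <= 0:
        raise ValueError(f"or_assoc must be positive, got {or_assoc}")
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        # with a margin at 0 or 1 the table is forced regardless of the OR
        p11 = p1 * p2 if (p1 in (0.0, 1.0) and p2 in (0.0, 1.0)) else (
            p2 if p1 == 1.0 else p1 if p2 == 1.0 else 0.0
        )
    elif abs(or_assoc - 1.0) < 1e-12:
        p11 = p1 * p2
    else:
        s = 1.0 + (p1 + p2) * (or_assoc - 1.0)
        disc = s * s - 4.0 * or_assoc * (or_assoc - 1.0) * p1 * p2
        p11 = (s - np.sqrt(disc)) / (2.0 * (or_assoc - 1.0))
    p11 = float(min(max(p11, 0.0), min(p1, p2)))
    return JointBinaryCells(p11, p1 - p11, p2 - p11, 1.0 - p1 - p2 + p11)


def calibrate_component_rates(
    p_rad: float, p_bio: float, or_assoc: float, composite_rate: float
) -> tuple[float, float]:
    """Scale both component marginals to hit a target composite rate.

    A common factor c is applied to (p_rad, p_bio); the composite rate
    1 - p00 is strictly increasing in c, so bisection on
    c in [0, min(1/p_rad, 1/p_bio)] finds the unique solution.
    """
    if not (0.0 <= composite_rate <= 1.0):
        raise ValueError(f"composite_rate must be in [0,1], got {composite_rate}")
    if composite_rate == 0.0:
        return 0.0, 0.0
    if p_rad == 0.0 and p_bio == 0.0:
        raise ValueError("cannot attain a positive composite rate with zero components")
    c_max = min(1.0 / p_rad if p_rad > 0 else np.inf, 1.0 / p_bio if p_bio > 0 else np.inf)

    def gap(c: float) -> float:
        cells = joint_binary_cells(min(c * p_rad, 1.0), min(c * p_bio, 1.0), or_assoc)
        return cells.composite_rate - composite_rate

    if gap(c_max) < 0:  # even saturated margins fall short (cannot happen for c_max finite)
        raise ValueError("target composite rate unattainable from these components")
    c = optimize.brentq(gap, 0.0, c_max, xtol=1e-14)
    return float(min(c * p_rad, 1.0)), float(min(c * p_bio, 1.0))


def _draw_blocks(n: int, block_sizes: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    labels: list[str] = []
    sizes = tuple(block_sizes)
    while len(labels) < n:
        bs = int(sizes[rng.integers(len(sizes))])
        block = np.array(["B"] * (bs // 2) + ["C"] * (bs // 2))
        labels.extend(rng.permutation(block).tolist())
    return np.array(labels[:n])


def permuted_block_randomization(
    n: int, block_sizes: tuple[int, ...] = (2, 4), seed: int = 0
) -> np.ndarray:
    """1:1 permuted-block allocation sequence over arms B and C.

    Block sizes are drawn uniformly from ``block_sizes`` (default {2, 4});
    each block is a random permutation of a balanced half-B half-C block,
    and the sequence is truncated to length n.  Any prefix imbalance is at
    most half the largest block.  Same seed, same sequence.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if any(b <= 0 or b % 2 for b in block_sizes):
        raise ValueError(f"block sizes must be positive and even, got {block_sizes}")
    return _draw_blocks(n, tuple(block_sizes), np.random.default_rng(seed))


def classify_recist(
    baseline_sum_mm: float, current_sum_mm: float, new_lesions: bool = False
) -> str:
    """Target-lesion RECIST 1.1-style category at a single assessment.

    PD: new lesions, or >= 20% increase that is also >= 5 mm absolute;
    CR: disappearance of all target lesions; PR: >= 30% decrease; else SD.
    Single-assessment simplification: the baseline sum stands in for the
    nadir.
    """
    if baseline_sum_mm <= 0:
        raise ValueError(f"baseline sum must be positive, got {baseline_sum_mm}")
    if current_sum_mm < 0:
        raise ValueError(f"current sum must be non-negative, got {current_sum_mm}")
    change = current_sum_mm - baseline_sum_mm
    if new_lesions or (change / baseline_sum_mm >= 0.20 and change >= 5.0):
        return "PD"
    if current_sum_mm == 0.0:
        return "CR"
    if -change / baseline_sum_mm >= 0.30:
        return "PR"
    return "SD"


def biological_response(
    pre_score: float,
    post_score: float,
    threshold_pct: float = 30.0,
    direction: str = "either",
) -> bool:
    """Whether the biomarker changed by at least threshold_pct percent.

    ``direction='either'`` (default) counts a change of the stated relative
    magnitude in either direction; ``'increase'`` counts only increases.
    """
    if pre_score <= 0:
        raise ValueError(f"pre_score must be positive, got {pre_score}")
    if post_score < 0:
        raise ValueError(f"post_score must be non-negative, got {post_score}")
    if direction not in ("either", "increase"):
        raise ValueError("direction must be 'either' or 'increase'")
    rel = (post_score - pre_score) / pre_score
    if direction == "increase":
        return rel >= threshold_pct / 100.0
    return abs(rel) >= threshold_pct / 100.0


def combine_biomarker_criteria(
    gene_expression_met: bool, cd14_met: bool, rule: str = "either"
) -> bool:
    """Combine the gene-expression and CD14 biomarker criteria.

    Whether the biological endpoint requires both criteria or either one is
    genuinely open; both readings are available (``rule='either'`` or
    ``'both'``), defaulting to the more permissive one.
    """
    if rule == "either":
        return gene_expression_met or cd14_met
    if rule == "both":
        return gene_expression_met and cd14_met
    raise ValueError("rule must be 'either' or 'both'")


def _arm_components(config: SimulationConfig, rate: float) -> JointBinaryCells:
    p_rad, p_bio = calibrate_component_rates(
        config.p_radiological, config.p_biological, config.endpoint_or, rate
    )
    return joint_binary_cells(p_rad, p_bio, config.endpoint_or)


def _synthesize_patient(
    pid: str, arm: str, rad: bool, bio: bool, rng: np.random.Generator, direction: str
) -> dict:
    baseline = float(rng.uniform(50.0, 150.0))
    new_lesions = False
    if rad:
        if rng.random() < 0.15:
            current = 0.0  # complete response
        else:
            current = baseline * (1.0 - rng.uniform(0.30, 0.75))
    else:
        u = rng.random()
        if u < 0.5:  # stable disease
            current = baseline * (1.0 + rng.uniform(-0.25, 0.15))
        elif u < 0.75:  # progression by new lesions
            new_lesions = True
            current = baseline * (1.0 + rng.uniform(-0.10, 0.10))
        else:  # progression by target-lesion growth
            current = baseline * (1.0 + rng.uniform(0.25, 0.60))
    category = classify_recist(baseline, current, new_lesions)

    if bio:
        mag = rng.uniform(0.30, 1.0)
    else:
        mag = rng.uniform(0.0, 0.295)
    sign = 1.0 if direction == "increase" else (1.0 if rng.random() < 0.5 else -1.0)
    change_pct = sign * mag * 100.0
    pre = 100.0
    post = pre * (1.0 + change_pct / 100.0)
    bio_flag = biological_response(pre, post, direction=direction)
    assert bio_flag == bio
    return {
        "patient_id": pid,
        "arm": arm,
        "baseline_sum_mm": round(baseline, 3),
        "current_sum_mm": round(current, 3),
        "new_lesions": new_lesions,
        "radiological_category": category,
        "biological_change_pct": round(change_pct, 3),
        "biological_response": bio_flag,
        "composite_responder": (category in ("CR", "PR")) or bio_flag,
    }


def simulate_trial(config: SimulationConfig) -> pd.DataFrame:
    """One synthetic trial: registered arm-A patients plus randomized B/C.

    Per-patient endpoint pairs are drawn from the arm's calibrated joint
    cell table, then consistent continuous measurements (target-lesion sums,
    biomarker change) are synthesized so that the categorical classifiers
    reproduce the drawn binary outcomes.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed)
    arms = ["A"] * config.n_arm_a
    if config.n_randomized:
        arms += _draw_blocks(config.n_randomized, config.block_sizes, rng).tolist()
    rates = {"A": config.true_rate_a, "B": config.true_rate_b, "C": config.rate_c}
    cells = {arm: _arm_components(config, rate) for arm, rate in rates.items()}
    records = []
    for i, arm in enumerate(arms, start=1):
        c = cells[arm]
        u = rng.random()
        rad = u < c.p11 + c.p10
        bio = (u < c.p11) or (c.p11 + c.p10 <= u < c.p11 + c.p10 + c.p01)
        records.append(
            _synthesize_patient(
                f"{arm}{i:03d}", arm, rad, bio, rng, config.biomarker_direction
            )
        )
    return pd.DataFrame.from_records(records, columns=PATIENT_COLUMNS)


@dataclass(frozen=True)
class OCReport:
    """Empirical operating characteristics with Monte-Carlo standard errors."""

    arm_a_true_rate: float
    arm_a_success_rate: float
    arm_a_success_se: float
    arm_a_early_stop_rate: float
    arm_a_expected_n: float
    bc_recommend_rate: float | None
    bc_recommend_se: float | None
    n_reps: int


def _simulate_arm_a_success(
    design: TwoStageDesign,
    rules: InterimDecisionTable | None,
    p: float,
    n_reps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-replicate (success, stopped-early) indicators."""
    n1, n2 = design.n1, design.n - design.n1
    x1 = rng.binomial(n1, p, size=n_reps)
    if rules is None:
        stop_fut = x1 <= design.r1
        stop_eff = np.zeros(n_reps, dtype=bool)
    else:
        decisions = np.array([row.decision for row in rules.rows])
        stop_fut = decisions[x1] == "stop-futility"
        stop_eff = decisions[x1] == "stop-efficacy"
    cont = ~(stop_fut | stop_eff)
    x2 = np.where(cont, rng.binomial(n2, p, size=n_reps), 0)
    success = stop_eff | (cont & (x1 + x2 >= design.r_total))
    return success, stop_fut | stop_eff


def estimate_operating_characteristics(
    config: SimulationConfig,
    design: TwoStageDesign,
    rules: InterimDecisionTable | None = None,
    priors: ComparisonPriors = ComparisonPriors(),
    recommend_threshold: float = 0.80,
    n_reps_bc: int | None = None,
) -> OCReport:
    """Empirical OC of the monitored arm-A design and the B/C comparison.

    Arm-A replicates draw composite responders directly from the calibrated
    binary model (the exact marginal of the full patient generator) and
    apply either the frequentist futility bound or, when ``rules`` is
    given, the Bayesian interim decision table.  B/C replicates randomize
    ``config.n_randomized`` patients by permuted blocks, then apply the
    posterior odds-ratio recommendation rule; the posterior is cached by
    the responder counts, so large replicate numbers stay cheap.  Set
    ``n_reps_bc=0`` to skip the comparison (reported as None).
    """
    if config.n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(config.seed)
    success, stopped = _simulate_arm_a_success(
        design, rules, config.true_rate_a, config.n_reps, rng
    )
    n = config.n_reps
    s_rate = float(success.mean())
    stop_rate = float(stopped.mean())
    expected_n = design.n1 + (1.0 - stop_rate) * (design.n - design.n1)

    n_bc = config.n_reps if n_reps_bc is None else n_reps_bc
    rec_rate = rec_se = None
    if n_bc > 0 and config.n_randomized >= 2:
        cache: dict[tuple[int, int, int, int], bool] = {}
        hits = 0
        for _ in range(n_bc):
            alloc = _draw_blocks(config.n_randomized, config.block_sizes, rng)
            n_b = int((alloc == "B").sum())
            n_c = int((alloc == "C").sum())
            x_b = int(rng.binomial(n_b, config.true_rate_b))
            x_c = int(rng.binomial(n_c, config.rate_c))
            key = (x_b, n_b, x_c, n_c)
            if key not in cache:
                post = posterior_prob_or_gt1(TwoArmData(*key), priors)
                cache[key] = recommend_further_research(post, recommend_threshold)
            hits += cache[key]
        rec_rate = hits / n_bc
        rec_se = float(np.sqrt(rec_rate * (1.0 - rec_rate) / n_bc))

    return OCReport(
        arm_a_true_rate=config.true_rate_a,
        arm_a_success_rate=s_rate,
        arm_a_success_se=float(np.sqrt(s_rate * (1.0 - s_rate) / n)),
        arm_a_early_stop_rate=stop_rate,
        arm_a_expected_n=float(expected_n),
        bc_recommend_rate=rec_rate,
        bc_recommend_se=rec_se,
        n_reps=n,
    )
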