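# Methods

## Single-arm model and monitoring rules

Responders on the single-agent arm follow *R* ~ Binomial(*N*, *p*) with a
conjugate Beta(*a*, *b*) prior on the response rate, default
Beta(10⁻³, 10⁻³). This prior is proper but nearly improper: its mass
piles up at 0 and 1, and the posterior after *x*/*n* is
Beta(*x* + 10⁻³, *n* − *x* + 10⁻³), numerically close to the
integer-shape Beta(*x*, *n* − *x*) away from the boundary. Tail
probabilities are regularized incomplete beta functions evaluated through
scipy's `beta.sf`, which remains accurate for shapes this small; the test
suite pins the integer-shape cases to the classical binomial-tail
identity P(Beta(a,b) > x) = P(Bin(a+b−1, x) ≤ a−1) at 10⁻¹⁰.

**Final rule.** Success at the final analysis means
P(*p* > ρ | data) ≥ γ with defaults ρ = 0.1, γ = 0.90. The comparison
with γ is non-strict: "a 90% posterior probability" is read as meeting
the level. Because the posterior tail is strictly increasing in the
responder count, the rule discretizes to a minimum responder boundary
`min_responders_final`; if no count at the given *n* satisfies the rule
the function returns an explicit `None` rather than a silently
out-of-range integer, so the design search can see infeasibility.

**Interim rule.** The posterior predictive probability of success (PPoS)
integrates the final success indicator over the beta-binomial predictive
distribution of the remaining patients. The interim decision is strict on
both sides — stop for futility when PPoS < 0.10, stop for efficacy when
PPoS > 0.90, continue otherwise — matching the "less than a 10% / greater
than a 90% chance of success" phrasing; a PPoS exactly at a cut
continues. PPoS is non-decreasing in the interim responder count, so the
decision table is always monotone.

## Two-stage design search

A design (*n*₁, *r*₁, *n*, *r*) enrolls *n*₁ patients, stops for futility
when stage-1 responders ≤ *r*₁ (with *r*₁ = −1 meaning no stop), and
otherwise continues to *n*, declaring success when total responders reach
*r*. Note the convention: *r* is the *minimum count declaring success*,
one more than the usual "reject if ≤ r" boundary. Operating
characteristics are exact binomial tail sums; the suite verifies them
against an exponential-cost oracle that enumerates entire patient-level
outcome sequences for all designs with *n* ≤ 9, and against independent
joint-outcome enumeration for the selected trial design, both at 10⁻¹².

The search enumerates every design up to `n_max` (default 60). Admissible
designs satisfy the type-I error cap at *p*₀ and the power floor at *p*₁.
For each (*n*₁, *r*₁, *n*) only the smallest admissible success boundary
is retained: raising it lowers both error rates while leaving the
expected sample size unchanged, so the smallest boundary clearing the α
constraint is the unique undominated choice. The *optimal* design
minimizes the expected sample size at *p*₀,
EN = *n*₁ + (1 − PET)(*n* − *n*₁); the *minimax* design minimizes *n*.
Ties break deterministically by smaller *n*, then *n*₁, then *r*₁, then
*r* (the study source states no tie policy; this chain makes repeated
runs bit-identical). No stage-1 efficacy stopping enters the frequentist
search — the classical futility-only formulation — while the
Bayesian-monitored evaluation does allow efficacy stops and counts them
as successes.

Under (*p*₀ = 0.1, *p*₁ = 0.3, α = 0.1, power = 0.8) the search returns
(*n*₁ = 7, *r*₁ = 0, *n* = 18, *r* = 4) with exact type-I error 0.0893
and power 0.8000. The Bayesian final rule at *n* = 18 discretizes to the
same boundary of 4 responders, and the PPoS futility region at the
interim is exactly {0/7}: the frequentist and Bayesian descriptions
coincide for this trial, which the package verifies rather than assumes
(`induced_two_stage_design`).

## Two-arm log-odds-ratio posterior

The randomized comparison models responders on control arm B and
experimental arm C as independent binomials with
logit(*p*_C) = logit(*p*_B) + δ, a Beta(10⁻³, 10⁻³) prior on *p*_B and a
Gaussian prior on the log-odds ratio δ. "N(0, 1000)" is read as
N(mean, variance) — sd ≈ 31.6 — following the conventional notation; the
`scale_interpretation` field accepts `variance`, `sd` or `precision` so
the reading is an explicit, reproducible choice rather than a silent one
(all three are effectively non-informative at this magnitude).

P(OR > 1 | data) = P(δ > 0 | data) is computed by deterministic nested
quadrature that exploits the model's structure. Conditional on δ, the
unnormalized δ-marginal is the Gaussian prior times a convolution of the
*closed-form* arm-B-only posterior density of the control logit with the
arm-C likelihood. The θ-integral uses composite Gauss–Legendre panels
(width 1, 12 nodes) on the fixed window |θ + δ| ≤ 40 where the arm-C
likelihood varies, plus *exact* incomplete-beta corrections for the mass
beyond the window, where that likelihood is constant to within
*n*_C·e⁻⁴⁰. The tail corrections are essential, not cosmetic: with zero
observed responders the boundary-spiked prior leaves the control-logit
posterior decaying at rate 10⁻³ per logit unit, so a large share of its
mass sits hundreds of units out and any naive truncation or
unit-interval grid loses it. The δ-integral is a trapezoid rule on a
grid sized by a coarse scan over ±13 prior sd, refined to mean ± 12 sd
of the scan, with 0 always an exact node so the sign split is exact.

The normalization diagnostic is the larger of a half-resolution grid
refinement and an 8-node re-computation of P(OR > 1); exceeding the
tolerance (default 5·10⁻³) raises `QuadratureError` instead of returning
a silently inaccurate value. Repeated calls are bit-identical.
Monte-Carlo appears only as an independent test oracle: self-normalized
importance sampling that draws the control rate exactly from the
arm-B-only posterior and δ from its prior, with the arm-C likelihood as
weight.

One subtlety the tests document: the model is *not* exactly symmetric
under swapping the arms, because the Beta prior sits on the control arm
alone while arm C inherits it through the Gaussian δ. For informative
symmetric data the asymmetry is negligible (2/10 vs 2/10 gives 0.4998),
but for nearly empty data it is visible (0/1 vs 0/1 gives 0.4937, which
the sampling oracle confirms); arm-swap antisymmetry
P + P_swapped = 1 holds to a few 10⁻⁵ in informative cases.

The recommendation rule is strict: further research is recommended iff
P(OR > 1) > 0.80. The credible-interval level defaults to 95% (no level
is prescribed by the study design).

Applicability: the quadrature's grid heuristics are tuned for the
small-trial regime (tens of patients per arm, where the δ-marginal's
features are no narrower than ~0.5 logit units). For arms of many
hundreds of patients the fixed panel width would deserve re-examination.

## Trial simulator

The generator emulates the study's structure at desk scale:

- **Allocation.** Single-agent patients are registered, never
  randomized. The randomized patients are assigned 1:1 to arms B/C in
  permuted blocks whose sizes are drawn uniformly from {2, 4}; the block
  sizes are part of the design, their mixing distribution is not, and
  uniform mixing is the package's choice. Any allocation prefix is
  imbalanced by at most 2.
- **Endpoints.** Each patient carries a radiological endpoint (CR/PR
  under single-assessment RECIST 1.1 target-lesion rules: PD on new
  lesions or ≥ 20% and ≥ 5 mm growth, CR on disappearance, PR on ≥ 30%
  shrinkage) and a biological endpoint (≥ 30% relative change in a
  biomarker score). The 30% change counts in either direction by
  default — the direction is unspecified in the study definition — with
  an increase-only flag; similarly, whether the biological endpoint
  requires both the gene-expression and CD14 criteria or either is open,
  and `combine_biomarker_criteria` implements both readings.
- **Dependence.** The two binary endpoints are joined by a
  Plackett-type construction: the unique 2×2 table with the given
  margins and a given cell odds ratio (default 1, independence). The
  composite responder rule is "at least one endpoint met", so the
  composite rate is 1 − p₀₀.
- **Calibration.** Default component marginals are
  1 − √0.9 ≈ 0.0513 each, chosen so the composite rate under
  independence equals the null rate 0.10. Per arm, both components are
  rescaled by a common factor (bisection on the monotone composite rate)
  so the arm attains its stated true composite rate; arm C's rate may be
  induced from arm B's via a true log-odds ratio. Default cohort sizes
  are 18 registered (the designed single-arm size) and 22 randomized
  (completing the study's planned accrual of 40).
- **Consistency.** Continuous measurements (lesion sums, biomarker
  change) are synthesized to be consistent with the drawn binary pair,
  then re-classified through the categorical rules, so every record
  satisfies the composite invariant by construction *and* by check.

Operating-characteristic runs draw single-arm composite responders
directly from the calibrated binary model — the exact marginal of the
full patient generator — and apply either the frequentist futility bound
or the Bayesian decision table (10⁴ replicates by default). B/C runs
randomize, draw per-arm responders, and apply the posterior
recommendation rule, caching posteriors by the responder counts so the
quadrature runs at most once per distinct table.

What passing simulator tests do **not** show about real data: the
generator has no accrual timing, dropout, assessment-schedule effects,
nadir tracking across multiple scans, non-target lesions, biomarker
assay noise, or dependence between allocation and outcome. It validates
the decision machinery, not the clinical realism of any particular
dataset.

## Numerical and design choices

- All randomness flows through `numpy.random.Generator` seeded from the
  configuration; identical configurations give byte-identical outputs.
- Beta-binomial predictive pmfs come from `scipy.stats.betabinom`;
  normalization is tested to 10⁻¹² out to 200 future patients.
- Degenerate inputs are explicit: empty data returns the prior; an
  unattainable final boundary is `None`; an infeasible design search
  raises `InfeasibleDesignError` listing the cap; quadrature failure
  raises rather than returns.
- The CLI prints probabilities at 6 significant digits by default
  (configurable) and writes a provenance block (package, version,
  parameters, seed) into every JSON output.

## Known limitations

- No three-stage or continuously monitored designs, no alpha-spending.
- No covariate adjustment, survival endpoints, toxicity modelling or
  hierarchical borrowing between arms.
- `min_responders_final` scans linearly; fine for phase-II sample sizes.
- The two-arm quadrature tolerance bounds self-consistency
  (grid-refinement and order-reduction checks), not a proven global
  error bound; the importance-sampling oracle in the test suite guards
  against structural bias on a 20-dataset panel.
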