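# phase2bayes

Bayesian design machinery for small phase-II oncology trials with a
registered single-agent arm and a randomized two-arm comparison — the
setting of a multi-arm osteosarcoma study of mifamurtide (liposomal
MTP-PE) with correlated radiological and biological co-primary endpoints.

The package provides four things for trial statisticians:

1. **Conjugate beta-binomial monitoring** of a single-arm response rate
   *p*: with responders *R* ~ Binomial(*N*, *p*) and a Beta(*a*, *b*)
   prior (default the near-improper Beta(10⁻³, 10⁻³)), the posterior is
   Beta(*a* + *x*, *b* + *N* − *x*). The final success rule declares the
   treatment worth further study when
   P(*p* > 0.1 | data) ≥ 0.90, and the interim look computes the
   posterior predictive probability of success (PPoS) over the remaining
   patients: stop for futility when PPoS < 10%, for efficacy when
   PPoS > 90%.
2. **Exact two-stage design search**: enumerate every design
   (*n*₁, *r*₁, *n*, *r*) up to a sample-size cap, compute exact binomial
   operating characteristics, and return the Simon-type *optimal* design
   (minimum expected sample size under the null rate) and *minimax*
   design among those with type-I error ≤ α at *p*₀ and power ≥ 1 − β at
   *p*₁.
3. **A log-odds-ratio posterior** for the randomized comparison of a
   control arm B and experimental arm C: independent binomial likelihoods
   linked by logit(*p*_C) = logit(*p*_B) + δ, a Beta(10⁻³, 10⁻³) prior on
   *p*_B and a N(0, 1000) prior on δ, evaluated by deterministic
   quadrature; further research is recommended when P(OR > 1 | data) > 80%.
4. **A synthetic trial simulator**: permuted-block 1:1 randomization
   (blocks of 2 and 4), two correlated binary co-primary endpoints
   (RECIST-style CR/PR and a ≥ 30% biomarker change) joined by an
   "at least one endpoint" composite responder rule, plus
   simulation-based operating characteristics that cross-validate the
   exact calculators.

## Worked example

Search for the design under the study's constraints
(*p*₀ = 0.1, *p*₁ = 0.3, α = 0.1, power = 0.8):

```python
>>> from phase2bayes import search_designs, bayesian_interim_rules
>>> result = search_designs()
>>> result.optimal
TwoStageDesign(n1=7, r1=0, n=18, r_total=4)
>>> result.optimal_oc_p0.success_prob   # exact type-I error
0.08933172260123708
>>> result.optimal_oc_p1.success_prob   # exact power
0.8000011257836125
```

The optimal design enrolls 18 patients with the interim after 7; it stops
at stage 1 only on 0/7 responders and declares success on ≥ 4/18 — and
4/18 is exactly the boundary the Bayesian final rule discretizes to:

```python
>>> from phase2bayes import min_responders_final
>>> min_responders_final(18)
4
>>> [r.decision for r in bayesian_interim_rules(7, 18).rows]
['stop-futility', 'continue', 'continue', 'stop-efficacy', 'stop-efficacy',
 'stop-efficacy', 'stop-efficacy', 'stop-efficacy']
```

so the frequentist futility bound (*r*₁ = 0) and the PPoS futility rule
coincide: the design is the same trial described in either framework.

For the randomized comparison, 2/10 responders on control B versus 5/10
on C gives

```python
>>> from phase2bayes import TwoArmData, posterior_prob_or_gt1
>>> post = posterior_prob_or_gt1(TwoArmData(x_b=2, n_b=10, x_c=5, n_c=10))
>>> round(post.prob_or_gt_1, 4)
0.9342
```

a 93.4% posterior probability that arm C has higher response odds — above
the 80% bar, so further research would be recommended.

The same operations are available from a shell:

```
phase2bayes design --out design.json --table-out interim_table.csv
phase2bayes interim --x1 1 --n1 7 --n-total 18
phase2bayes compare --xb 2 --nb 10 --xc 5 --nc 10
phase2bayes simulate --seed 7 --out patients.csv
phase2bayes oc --seed 7 --out oc.json
```

Patient tables are CSV with columns `patient_id, arm, baseline_sum_mm,
current_sum_mm, new_lesions, radiological_category,
biological_change_pct, biological_response, composite_responder`, with a
JSON sidecar recording the full configuration and seed.

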