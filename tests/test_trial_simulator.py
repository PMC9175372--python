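import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phase2bayes import (
    SimulationConfig,
    TwoStageDesign,
    bayesian_interim_rules,
    biological_response,
    calibrate_component_rates,
    classify_recist,
    combine_biomarker_criteria,
    estimate_operating_characteristics,
    exact_operating_chars,
    joint_binary_cells,
    permuted_block_randomization,
    simulate_trial,
)


class TestJointBinaryCells:
    def test_independence(self):
        cells = joint_binary_cells(0.3, 0.4, 1.0)
        assert cells.p11 == pytest.approx(0.12, abs=1e-12)

    def test_comonotone_limit(self):
        cells = joint_binary_cells(0.5, 0.5, 1e9)
        assert cells.p11 == pytest.approx(0.5, abs=1e-4)
        assert cells.p10 == pytest.approx(0.0, abs=1e-4)

    @pytest.mark.parametrize("p1", [0.05, 0.3, 0.7])
    @pytest.mark.parametrize("p2", [0.1, 0.4, 0.9])
    @pytest.mark.parametrize("orr", [0.2, 1.0, 3.0, 25.0])
    def test_margins_and_odds_ratio_recovered(self, p1, p2, orr):
        c = joint_binary_cells(p1, p2, orr)
        assert c.p11 + c.p10 == pytest.approx(p1, abs=1e-10)
        assert c.p11 + c.p01 == pytest.approx(p2, abs=1e-10)
        if abs(orr - 1.0) > 1e-9:
            assert (c.p11 * c.p00) / (c.p10 * c.p01) == pytest.approx(orr, rel=1e-8)
        assert c.p11 + c.p10 + c.p01 + c.p00 == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_margins_forced(self):
        assert joint_binary_cells(0.0, 0.4, 3.0).p11 == 0.0
        assert joint_binary_cells(1.0, 0.4, 3.0).p11 == pytest.approx(0.4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            joint_binary_cells(0.3, 0.4, -1.0)
        with pytest.raises(ValueError):
            joint_binary_cells(1.3, 0.4, 1.0)


class TestCalibration:
    @pytest.mark.parametrize("target", [0.0, 0.1, 0.3, 0.8])
    @pytest.mark.parametrize("orr", [1.0, 2.5])
    def test_composite_rate_attained(self, target, orr):
        p1, p2 = calibrate_component_rates(0.0513, 0.0513, orr, target)
        assert joint_binary_cells(p1, p2, orr).composite_rate == pytest.approx(
            target, abs=1e-9
        )


class TestBlockRandomization:
    def test_single_balanced_block(self):
        alloc = permuted_block_randomization(2, (2,), seed=5)
        assert sorted(alloc) == ["B", "C"]

    @given(seed=st.integers(0, 10_000), n=st.integers(1, 60))
    @settings(max_examples=60, deadline=None)
    def test_prefix_imbalance_bounded_by_half_largest_block(self, seed, n):
        alloc = permuted_block_randomization(n, (2, 4), seed=seed)
        running = np.cumsum(np.where(alloc == "B", 1, -1))
        assert np.abs(running).max() <= 2

    def test_seed_determinism_and_variation(self):
        a = permuted_block_randomization(20, (2, 4), seed=42)
        b = permuted_block_randomization(20, (2, 4), seed=42)
        np.testing.assert_array_equal(a, b)
        assert any(
            not np.array_equal(a, permuted_block_randomization(20, (2, 4), seed=s))
            for s in (43, 44, 45)
        )

    def test_odd_block_size_rejected(self):
        with pytest.raises(ValueError):
            permuted_block_randomization(10, (3,), seed=1)


class TestEndpointClassifiers:
    @pytest.mark.parametrize(
        "baseline, current, new, expected",
        [
            (100, 70, False, "PR"),     # exactly -30%
            (100, 120, False, "PD"),    # +20% and +20 mm
            (100, 115, False, "SD"),
            (100, 0, False, "CR"),
            (100, 90, True, "PD"),      # new lesions dominate
            (20, 23, False, "SD"),      # +15% increase, < 5 mm absolute
            (20, 26, False, "PD"),      # +30%, +6 mm
        ],
    )
    def test_recist_categories(self, baseline, current, new, expected):
        assert classify_recist(baseline, current, new) == expected

    def test_recist_validation(self):
        with pytest.raises(ValueError):
            classify_recist(0, 10)
        with pytest.raises(ValueError):
            classify_recist(100, -1)

    @pytest.mark.parametrize(
        "post, direction, expected",
        [(130, "either", True), (125, "either", False), (70, "either", True),
         (70, "increase", False), (130, "increase", True)],
    )
    def test_biomarker_threshold(self, post, direction, expected):
        assert biological_response(100, post, direction=direction) is expected

    def test_biomarker_validation(self):
        with pytest.raises(ValueError):
            biological_response(0, 50)

    def test_combining_the_two_biomarker_criteria(self):
        assert combine_biomarker_criteria(True, False, "either")
        assert not combine_biomarker_criteria(True, False, "both")
        assert combine_biomarker_criteria(True, True, "both")


class TestSimulateTrial:
    def test_zero_rates_give_zero_responders(self):
        cfg = SimulationConfig(n_arm_a=30, n_randomized=20, true_rate_a=0.0,
                               true_rate_b=0.0, true_rate_c=0.0, seed=3)
        table = simulate_trial(cfg)
        assert len(table) == 50
        assert table["composite_responder"].sum() == 0

    def test_saturated_rates_make_everyone_respond(self):
        cfg = SimulationConfig(n_arm_a=10, n_randomized=10, true_rate_a=1.0,
                               true_rate_b=1.0, true_rate_c=1.0, seed=3)
        assert simulate_trial(cfg)["composite_responder"].all()

    def test_composite_rule_holds_for_every_record(self):
        table = simulate_trial(SimulationConfig(n_arm_a=200, n_randomized=200,
                                                true_rate_a=0.3, true_rate_b=0.25,
                                                true_log_or=1.0, endpoint_or=2.0,
                                                seed=11))
        rad = table["radiological_category"].isin(["CR", "PR"])
        expected = rad | table["biological_response"]
        pd.testing.assert_series_equal(
            table["composite_responder"], expected, check_names=False
        )
        # the categorical layer must agree with its own classifier inputs
        assert (table.loc[table["new_lesions"], "radiological_category"] == "PD").all()

    def test_block_balance_overall(self):
        table = simulate_trial(SimulationConfig(n_arm_a=0, n_randomized=57, seed=9))
        counts = table["arm"].value_counts()
        assert abs(counts.get("B", 0) - counts.get("C", 0)) <= 2

    def test_seed_determinism(self):
        cfg = SimulationConfig(n_arm_a=25, n_randomized=25, seed=123)
        pd.testing.assert_frame_equal(simulate_trial(cfg), simulate_trial(cfg))

    def test_responder_fraction_matches_cell_probability(self):
        """Empirical composite rate over 1e5 patients within 3 SE of 1 - p00."""
        cfg = SimulationConfig(n_arm_a=100_000, n_randomized=0, true_rate_a=0.3,
                               endpoint_or=2.0, seed=2024)
        frac = simulate_trial(cfg)["composite_responder"].mean()
        se = np.sqrt(0.3 * 0.7 / 100_000)
        assert abs(frac - 0.3) < 3 * se

    def test_log_or_induces_arm_c_rate(self):
        cfg = SimulationConfig(true_rate_b=0.1, true_log_or=np.log(3.0))
        odds = 0.1 / 0.9 * 3.0
        assert cfg.rate_c == pytest.approx(odds / (1 + odds))


class TestOperatingCharacteristics:
    DESIGN = TwoStageDesign(7, 0, 18, 4)

    @pytest.mark.parametrize("p", [0.1, 0.3])
    def test_arm_a_empirical_matches_exact(self, p):
        cfg = SimulationConfig(true_rate_a=p, n_reps=10_000, seed=77)
        report = estimate_operating_characteristics(cfg, self.DESIGN, n_reps_bc=0)
        exact = exact_operating_chars(self.DESIGN, p).success_prob
        se = max(np.sqrt(exact * (1 - exact) / cfg.n_reps), 1e-4)
        assert abs(report.arm_a_success_rate - exact) < 3 * se
        assert report.bc_recommend_rate is None

    def test_bayesian_monitored_matches_frequentist_when_rules_coincide(self):
        """With the induced boundary, efficacy stopping does not change the
        success probability (stopping early for efficacy still succeeds)."""
        rules = bayesian_interim_rules(7, 18)
        cfg = SimulationConfig(true_rate_a=0.3, n_reps=10_000, seed=78)
        rep = estimate_operating_characteristics(cfg, self.DESIGN, rules, n_reps_bc=0)
        exact = exact_operating_chars(self.DESIGN, 0.3).success_prob
        se = np.sqrt(exact * (1 - exact) / cfg.n_reps)
        assert abs(rep.arm_a_success_rate - exact) < 3 * se

    def test_null_comparison_recommendation_is_symmetric(self):
        """Under a true OR of 1 with symmetric arms, 'evidence favouring C'
        (P > 0.8) and 'evidence favouring B' (P < 0.2) should be equally
        frequent: a two-sided binomial check on the split."""
        from phase2bayes import TwoArmData, posterior_prob_or_gt1
        from phase2bayes.trial_simulator import _draw_blocks
        from scipy import stats

        rng = np.random.default_rng(5150)
        cache = {}
        favour_c = favour_b = 0
        for _ in range(150):
            alloc = _draw_blocks(12, (2, 4), rng)
            n_b = int((alloc == "B").sum())
            n_c = 12 - n_b
            key = (int(rng.binomial(n_b, 0.25)), n_b, int(rng.binomial(n_c, 0.25)), n_c)
            if key not in cache:
                cache[key] = posterior_prob_or_gt1(TwoArmData(*key)).prob_or_gt_1
            if cache[key] > 0.8:
                favour_c += 1
            elif cache[key] < 0.2:
                favour_b += 1
        n_calls = favour_b + favour_c
        assert n_calls > 0
        pval = stats.binomtest(favour_c, n_calls, 0.5).pvalue
        assert pval > 1e-3

    def test_zero_reps_rejected(self):
        with pytest.raises(ValueError):
            estimate_operating_characteristics(
                SimulationConfig(n_reps=0), self.DESIGN
            )
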