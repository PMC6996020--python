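import numpy as np
import pytest

import tmazephys as tp
from tmazephys.group_stats import watson_williams

rng0 = np.random.default_rng(0)


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        comp = tp.compare_groups(x, x.copy())
        assert comp.p_value > 0.9

    def test_gate_selects_t_for_normal_samples(self):
        rng = np.random.default_rng(1)
        comp = tp.compare_groups(rng.normal(0, 1, 20), rng.normal(0, 1, 20))
        assert comp.test == "t" and comp.normal

    def test_gate_selects_ranksum_for_heavy_tails(self):
        rng = np.random.default_rng(2)
        a = rng.standard_cauchy(30)
        b = rng.standard_cauchy(30)
        comp = tp.compare_groups(a, b)
        assert comp.test == "mann-whitney" and not comp.normal

    def test_two_sd_shift_detected_with_high_power(self):
        """Monte-Carlo power > 0.9 for a 2-SD shift at n=10 per group."""
        rng = np.random.default_rng(3)
        hits = 0
        reps = 200
        for _ in range(reps):
            a = rng.normal(0, 1, 10)
            b = rng.normal(2, 1, 10)
            hits += tp.compare_groups(a, b).p_value < 0.05
        assert hits / reps > 0.9

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(4)
        hits = sum(tp.compare_groups(rng.normal(size=10),
                                     rng.normal(size=10)).p_value < 0.05
                   for _ in range(400))
        assert hits / 400 <= 0.07

    def test_paired_uses_differences(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 12)
        comp = tp.compare_groups(base + 0.5, base, paired=True)
        assert comp.test in ("paired-t", "wilcoxon")
        assert comp.p_value < 0.01

    def test_all_equal_paired_p_one(self):
        x = np.array([0.1, 0.5, 0.9, 0.3])
        comp = tp.compare_groups(x, x.copy(), paired=True)
        assert comp.p_value == 1.0

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            tp.compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestChanceTest:
    def test_all_at_chance_p_one(self):
        comp = tp.chance_test(np.full(8, 0.5))
        assert comp.p_value == 1.0

    def test_strong_alternation_detected(self):
        """alternation_prob 0.75 rejects chance in most seeded cohorts."""
        hits = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            rates = rng.binomial(10, 0.75, size=10) / 10.0
            hits += tp.chance_test(rates).p_value < 0.05
        assert hits / 25 > 0.8

    def test_null_calibrated(self):
        hits = 0
        reps = 300
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            rates = rng.binomial(10, 0.5, size=10) / 10.0
            hits += tp.chance_test(rates).p_value < 0.05
        assert 0.005 <= hits / reps <= 0.09


class TestResidualize:
    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            tp.residualize([1, 2, 3, 4, 5, 6], np.ones(6),
                           ["a"] * 3 + ["b"] * 3)

    def test_group_offset_survives_residualization(self):
        rng = np.random.default_rng(6)
        n = 12
        imm = rng.uniform(0.1, 0.5, 2 * n)
        labels = np.array(["wt"] * n + ["mut"] * n)
        vals = 0.2 + 0.01 * imm + 0.05 * (labels == "mut") + rng.normal(0, 0.005, 2 * n)
        rc = tp.residualize(vals, imm, labels)
        diff = rc.residuals_b.mean() - rc.residuals_a.mean()
        assert diff == pytest.approx(0.05, abs=0.01)
        assert rc.comparison.p_value < 0.01

    def test_fully_mediated_difference_nulled(self):
        rng = np.random.default_rng(7)
        n = 12
        labels = np.array(["wt"] * n + ["mut"] * n)
        imm = np.where(labels == "mut", 0.4, 0.2) + rng.normal(0, 0.02, 2 * n)
        vals = 0.2 + 0.5 * imm + rng.normal(0, 0.005, 2 * n)
        rc = tp.residualize(vals, imm, labels)
        diff = rc.residuals_b.mean() - rc.residuals_a.mean()
        assert abs(diff) < 0.01

    def test_residuals_sum_to_zero_over_pooled_fit(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=20)
        cov = rng.normal(size=20)
        rc = tp.residualize(vals, cov, ["a"] * 10 + ["b"] * 10)
        assert np.concatenate([rc.residuals_a, rc.residuals_b]).sum() == pytest.approx(0.0, abs=1e-9)

    def test_balanced_unrelated_covariate_preserves_comparison(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0.0, 1, 15)
        b = rng.normal(1.0, 1, 15)
        cov = np.tile(rng.normal(size=15), 2)
        raw = tp.compare_groups(a, b)
        rc = tp.residualize(np.concatenate([a, b]), cov,
                            ["a"] * 15 + ["b"] * 15)
        raw_diff = b.mean() - a.mean()
        res_diff = rc.residuals_b.mean() - rc.residuals_a.mean()
        assert res_diff == pytest.approx(raw_diff, abs=0.3)
        assert (rc.comparison.p_value < 0.05) == (raw.p_value < 0.05)


class TestWatsonWilliams:
    def test_identical_groups_f_near_zero(self):
        a = np.array([0.1, 0.2, 0.0, -0.1, 0.15, 0.05])
        res = watson_williams(a, a.copy())
        assert res.f_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.99

    def test_separated_von_mises_means_detected(self):
        rng = np.random.default_rng(10)
        hits = 0
        reps = 100
        for _ in range(reps):
            a = rng.vonmises(0.0, 5.0, 10)
            b = rng.vonmises(1.0, 5.0, 10)
            hits += watson_williams(a, b).p_value < 0.05
        assert hits / reps > 0.8

    def test_equal_means_rejection_near_alpha(self):
        rng = np.random.default_rng(11)
        hits = sum(watson_williams(rng.vonmises(0.5, 5.0, 10),
                                   rng.vonmises(0.5, 5.0, 10)).p_value < 0.05
                   for _ in range(300))
        assert 0.01 <= hits / 300 <= 0.09

    def test_uniform_angles_flagged_invalid(self):
        rng = np.random.default_rng(12)
        res = watson_williams(rng.uniform(-np.pi, np.pi, 20),
                              rng.uniform(-np.pi, np.pi, 20))
        assert not res.valid and res.flags

    def test_too_few_angles_rejected(self):
        with pytest.raises(ValueError):
            watson_williams(np.zeros(3), np.zeros(10))


class TestPairedRunContrast:
    def test_no_run_effect_when_equal(self):
        vals = {"wt": rng0.normal(size=10), "mut": rng0.normal(size=10)}
        out = tp.paired_run_contrast(vals, {g: v.copy() for g, v in vals.items()})
        for g in vals:
            assert out["run_effect"][g].p_value > 0.9
        assert out["interaction"].p_value > 0.9

    def test_one_group_boost_yields_interaction(self):
        rng = np.random.default_rng(13)
        sample = {"wt": rng.normal(1.0, 0.05, 10),
                  "mut": rng.normal(1.0, 0.05, 10)}
        choice = {"wt": sample["wt"] * 1.2 + rng.normal(0, 0.02, 10),
                  "mut": sample["mut"] + rng.normal(0, 0.02, 10)}
        out = tp.paired_run_contrast(sample, choice)
        assert out["run_effect"]["wt"].p_value < 0.05
        assert out["interaction"].p_value < 0.05

    def test_common_boost_main_effect_without_interaction(self):
        rng = np.random.default_rng(14)
        sample = {"wt": rng.normal(1.0, 0.05, 10),
                  "mut": rng.normal(1.0, 0.05, 10)}
        choice = {g: v * 1.2 + rng.normal(0, 0.02, 10)
                  for g, v in sample.items()}
        out = tp.paired_run_contrast(sample, choice)
        for g in sample:
            assert out["run_effect"][g].p_value < 0.05
        assert out["interaction"].p_value > 0.05
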