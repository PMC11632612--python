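import numpy as np
import pytest
from scipy.stats import hypergeom

from fragsite import simulate
from fragsite import stats as istats
from fragsite.stats import CountTable, FluctuationExperiment, SCESample


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by direct hypergeometric enumeration: sum the
    probabilities of all tables (same margins) no more probable than the
    observed one."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    kmin, kmax = max(0, row1 + col1 - n), min(row1, col1)
    ks = np.arange(kmin, kmax + 1)
    probs = hypergeom.pmf(ks, n, col1, row1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


class TestMnNbudTest:
    def test_identical_tables_give_p_one(self):
        t = CountTable(1000, {"MN": 20, "NBud": 10})
        res = istats.mn_nbud_test(t, t)
        assert res.p_value == pytest.approx(1.0)
        assert res.effect == pytest.approx(1.0)

    def test_no_events_anywhere_gives_p_one(self):
        t = CountTable(500, {"MN": 0, "NBud": 0})
        assert istats.mn_nbud_test(t, t).p_value == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        """Fisher p equals brute-force enumeration to 1e-12 on a grid of
        2x2 tables with margins up to 200."""
        cases = [(30, 970, 10, 990), (3, 97, 0, 100), (15, 85, 5, 95),
                 (50, 50, 30, 70), (1, 99, 1, 99), (8, 42, 2, 48)]
        for a, b, c, d in cases:
            case = CountTable(a + b, {"MN": a, "NBud": 0})
            control = CountTable(c + d, {"MN": c, "NBud": 0})
            res = istats.mn_nbud_test(case, control)
            assert res.p_value == pytest.approx(
                fisher_two_sided_oracle(a, b, c, d), abs=1e-12)

    def test_pooling_combines_categories(self):
        case = CountTable(100, {"MN": 5, "NBud": 5})
        control = CountTable(100, {"MN": 10, "NBud": 0})
        # pooled 10 vs 10 -> identical
        assert istats.mn_nbud_test(case, control).p_value == pytest.approx(1.0)
        assert istats.mn_nbud_test(case, control).per_category["MN"]["p_value"] < 1.0

    def test_missing_category_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            istats.mn_nbud_test(CountTable(10, {"MN": 1}), CountTable(10, {"MN": 1}))


class TestSceCompare:
    def test_identical_samples_p_one_fold_one(self):
        a = SCESample(np.array([7.0, 7.0, 7.0]))
        res = istats.sce_compare(a, a)
        assert res.p_value == pytest.approx(1.0)
        assert res.effect == pytest.approx(1.0)

    def test_two_values_per_group_matches_closed_form_t(self):
        a = SCESample(np.array([6.0, 8.0]))
        b = SCESample(np.array([10.0, 14.0]))
        res = istats.sce_compare(a, b, test="t")
        # pooled-variance t with 2 dof: t = (7-12)/sqrt(s2p*(1/2+1/2)), s2p=(2+8)/2
        t_hand = (7.0 - 12.0) / np.sqrt(5.0)
        assert res.statistic == pytest.approx(t_hand)

    def test_degenerate_within_group_variance_uses_permutation(self):
        a = SCESample(np.array([5.0, 5.0, 5.0]))
        b = SCESample(np.array([9.0, 9.0, 9.0]))
        with pytest.warns(UserWarning, match="permutation"):
            res = istats.sce_compare(a, b, test="t")
        assert res.test == "permutation"
        assert res.p_value <= 0.2  # exact two-sided p for 3|3 complete separation

    def test_twofold_shift_detected_with_high_power(self):
        """Poisson 7 vs 14 per metaphase, n=100 each: rejection in >99%
        of simulations."""
        rng = np.random.default_rng(0)
        rejections = 0
        n_sim = 300
        for _ in range(n_sim):
            a = SCESample(rng.poisson(7, 100).astype(float))
            b = SCESample(rng.poisson(14, 100).astype(float))
            if istats.sce_compare(a, b, test="t").p_value < 0.05:
                rejections += 1
        assert rejections / n_sim > 0.99


class TestArmEnrichment:
    def test_all_on_arm_closed_form(self):
        assert istats.arm_enrichment(10, 10, 0.3) == pytest.approx(0.3**10)

    def test_null_center(self):
        # at the expectation the upper tail sits near 0.5 (within the point mass)
        from scipy.stats import binom
        p = istats.arm_enrichment(15, 100, 0.15)
        assert abs(p - 0.5) <= binom.pmf(15, 100, 0.15) + 0.05

    def test_matches_direct_tail_oracle(self):
        from scipy.stats import binom
        direct = sum(binom.pmf(k, 100, 0.15) for k in range(30, 101))
        assert istats.arm_enrichment(30, 100, 0.15) == pytest.approx(direct, rel=1e-10)

    def test_null_rejection_rate_at_most_nominal_plus_margin(self):
        rng = np.random.default_rng(5)
        totals = rng.poisson(40, 2000) + 1
        arms = rng.binomial(totals, 0.15)
        rej = np.mean([istats.arm_enrichment(int(a), int(t), 0.15) < 0.05
                       for a, t in zip(arms, totals)])
        assert rej <= 0.06

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            istats.arm_enrichment(1, 10, 1.0)


class TestLeaCoulson:
    def test_median_four_root(self):
        """r=4: the median equation 4/m - ln m = 1.24 has its root near 2.05."""
        est = istats.lea_coulson_rate(
            FluctuationExperiment(np.array([4.0] * 5), 1e7))
        assert est.m == pytest.approx(2.05, abs=0.01)
        assert est.rate == pytest.approx(est.m / 1e7)

    def test_solver_residual_below_1e10(self):
        for r in (1, 3, 4, 10, 50, 300):
            est = istats.lea_coulson_rate(
                FluctuationExperiment(np.array([float(r)] * 5), 1e7))
            residual = r / est.m - np.log(est.m) - istats.LEA_COULSON_CONSTANT
            assert abs(residual) < 1e-10

    def test_zero_median_is_censored_ln2(self):
        est = istats.lea_coulson_rate(
            FluctuationExperiment(np.array([0.0, 0.0, 0.0, 0.0, 3.0]), 1e6))
        assert est.censored
        assert est.m == pytest.approx(np.log(2))

    def test_too_few_cultures_rejected(self):
        with pytest.raises(ValueError, match=">=5"):
            istats.lea_coulson_rate(FluctuationExperiment(np.array([1.0] * 4), 1e6))

    def test_rate_recovery_from_simulated_experiments(self):
        """Median recovered rate over 50 simulated experiments (30 cultures,
        rate 1e-6, N=1e7) lies within a factor 1.5 of truth."""
        rates = []
        for seed in range(50):
            exp = simulate.simulate_fluctuation_cultures(1e-6, 30, 10**7, seed=seed)
            rates.append(istats.lea_coulson_rate(exp).rate)
        med = np.median(rates)
        assert 1e-6 / 1.5 < med < 1e-6 * 1.5

    def test_mss_ml_agrees_with_median_method(self):
        exp = simulate.simulate_fluctuation_cultures(1e-6, 40, 10**6, seed=3)
        med = istats.lea_coulson_rate(exp, method="median")
        mss = istats.lea_coulson_rate(exp, method="mss")
        assert mss.m == pytest.approx(med.m, rel=0.5)

    def test_luria_delbruck_pmf_normalizes_up_to_heavy_tail(self):
        # the mutant-count tail decays like m/r, so truncation at n leaves
        # roughly m/n of mass beyond it
        m, n = 1.0, 500
        pmf = istats.luria_delbruck_pmf(m, n)
        assert np.all(pmf >= 0)
        assert 1.0 - 3 * m / n < pmf.sum() <= 1.0 + 1e-12
        assert pmf[0] == pytest.approx(np.exp(-m))


class TestRateFoldChange:
    def test_identical_experiments_fold_one_ci_contains_one(self):
        exp = simulate.simulate_fluctuation_cultures(1e-6, 30, 10**6, seed=1)
        fc = istats.rate_fold_change(exp, exp, n_boot=200, seed=0)
        assert fc.fold == pytest.approx(1.0)
        assert fc.ci_low <= 1.0 <= fc.ci_high

    def test_deterministic_cultures_zero_width_ci(self):
        exp = FluctuationExperiment(np.array([4.0] * 10), 1e6)
        fc = istats.rate_fold_change(exp, exp, n_boot=100, seed=0)
        assert fc.ci_low == pytest.approx(fc.ci_high) == pytest.approx(1.0)

    def test_planted_tenfold_difference_covered(self):
        """CI covers the planted 10-fold rate difference in >=90% of
        simulated experiment pairs."""
        covered = 0
        n_sim = 50
        for seed in range(n_sim):
            a = simulate.simulate_fluctuation_cultures(1e-6, 30, 10**7, seed=1000 + seed)
            b = simulate.simulate_fluctuation_cultures(1e-7, 30, 10**7, seed=2000 + seed)
            fc = istats.rate_fold_change(a, b, n_boot=200, seed=seed)
            if fc.ci_low <= 10.0 <= fc.ci_high:
                covered += 1
        assert covered >= int(0.9 * n_sim)
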