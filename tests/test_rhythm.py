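"""Umbrella patterns, permutation p-values, BH and peak assignment."""

import numpy as np
import pytest
from scipy import stats

from dieltx import (
    assign_peak,
    bh_adjust,
    enumerate_patterns,
    pattern_pvalue,
    rain_test,
    run_rhythmicity,
    umbrella_statistic,
)
from dieltx.rhythm import n_multiset_permutations


def pattern_with(patterns, peak, trough):
    return next(p for p in patterns if p.peak == peak and p.trough == trough)


class TestEnumeratePatterns:
    def test_counts(self):
        assert len(enumerate_patterns(6)) == 30
        assert len(enumerate_patterns(3)) == 6

    def test_no_peak_equals_trough(self):
        assert all(p.peak != p.trough for p in enumerate_patterns(6))

    def test_chains_cover_cycle(self):
        for p in enumerate_patterns(5):
            assert p.rising[0] == p.trough and p.rising[-1] == p.peak
            assert p.falling[0] == p.peak and p.falling[-1] == p.trough
            assert sorted(set(p.rising) | set(p.falling)) == list(range(5))

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            enumerate_patterns(2)


class TestUmbrellaStatistic:
    def test_hand_example_with_cyclic_pairs(self):
        """Groups {1,2},{3,4},{2,1}, rise 0->1 fall 1->2.

        The two open-chain pair sums contribute 8 concordances; the cyclic
        wrap-around (trough, peak) comparison (2, 1) adds 2 more for a
        statistic of 10 out of a maximum of 12 (frozen oracle value,
        verified by exhaustive pair listing).
        """
        groups = [np.array([1, 2]), np.array([3, 4]), np.array([2, 1])]
        pat = pattern_with(enumerate_patterns(3), peak=1, trough=2)
        stat, smax = umbrella_statistic(groups, pat)
        assert (stat, smax) == (10.0, 12.0)

    def test_all_equal_is_half_max(self):
        groups = [np.ones(4), np.ones(4), np.ones(4)]
        for pat in enumerate_patterns(3):
            stat, smax = umbrella_statistic(groups, pat)
            assert stat == smax / 2

    def test_sign_reversal_antisymmetry(self):
        rng = np.random.default_rng(906)
        groups = [rng.normal(size=4) for _ in range(5)]
        neg = [-g for g in groups]
        for pat in enumerate_patterns(5):
            s, m = umbrella_statistic(groups, pat)
            s2, m2 = umbrella_statistic(neg, pat)
            assert m2 == m
            assert s2 == pytest.approx(m - s)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            umbrella_statistic([np.array([1.0]), np.array([]), np.array([2.0])],
                               enumerate_patterns(3)[0])


class TestPatternPvalue:
    def test_exhaustive_one_sixth(self):
        """Groups {1},{2},{1.5}: the observed arrangement uniquely maximizes
        the peak-at-index-1 statistic over the 3! = 6 permutations."""
        groups = [np.array([1.0]), np.array([2.0]), np.array([1.5])]
        pat = pattern_with(enumerate_patterns(3), peak=1, trough=0)
        p = pattern_pvalue(groups, pat, null_engine="exhaustive")
        assert p == pytest.approx(1 / 6)

    def test_constant_series_p_one(self):
        groups = [np.ones(2), np.ones(2), np.ones(2)]
        pat = enumerate_patterns(3)[0]
        assert pattern_pvalue(groups, pat, null_engine="exhaustive") == 1.0

    def test_monte_carlo_matches_exhaustive(self):
        """<= 8 observations: MC within 3 binomial SE of the exhaustive p."""
        rng = np.random.default_rng(901)
        n_perm = 4000
        pats3 = enumerate_patterns(3)
        for trial in range(10):
            sizes = rng.integers(1, 4, size=3)
            if sizes.sum() > 8:
                continue
            groups = [rng.normal(size=s) for s in sizes]
            pat = pats3[int(rng.integers(0, len(pats3)))]
            p_ex = pattern_pvalue(groups, pat, null_engine="exhaustive")
            p_mc = pattern_pvalue(
                groups, pat, null_engine="monte_carlo", n_perm=n_perm,
                seed=int(rng.integers(2**31)),
            )
            se = np.sqrt(p_ex * (1 - p_ex) / n_perm)
            assert abs(p_mc - p_ex) <= 3 * se + 1 / (n_perm + 1), (sizes, p_ex, p_mc)

    def test_exhaustive_limit_enforced(self):
        rng = np.random.default_rng(907)
        groups = [rng.normal(size=8) for _ in range(6)]
        pat = enumerate_patterns(6)[0]
        with pytest.raises(ValueError, match="arrangements"):
            pattern_pvalue(groups, pat, null_engine="exhaustive")

    def test_multiset_count(self):
        assert n_multiset_permutations(np.array([1, 1, 2, 3])) == 12


class TestRainTest:
    def test_noiseless_cosine_detected(self, design48):
        hours = np.array(design48.times_of_day)
        wave = 1 + np.cos(2 * np.pi * (hours - 6.0) / 24.0)
        groups = [np.full(8, w) + np.arange(8) * 1e-9 for w in wave]
        res = rain_test(groups, design48, n_perm=10_000, seed=1)
        assert res.p_raw < 0.001
        assert res.best_pattern.peak == int(np.argmax(wave))

    def test_constant_series(self, design_small):
        res = rain_test([np.ones(4)] * 3, n_perm=100, seed=0)
        assert res.p_raw == 1.0
        assert res.best_pattern is None

    def test_shift_and_monotone_invariance(self):
        rng = np.random.default_rng(903)
        groups = [rng.normal(size=4) for _ in range(4)]
        base = rain_test(groups, n_perm=500, seed=7)
        shifted = rain_test([g + 100.0 for g in groups], n_perm=500, seed=7)
        cubed = rain_test([np.exp(g) for g in groups], n_perm=500, seed=7)
        assert base.p_raw == shifted.p_raw == cubed.p_raw
        assert base.statistic == shifted.statistic == cubed.statistic

    def test_engine_auto_matches_exhaustive(self):
        rng = np.random.default_rng(904)
        groups = [rng.normal(size=2) for _ in range(3)]
        auto = rain_test(groups, n_perm=200, seed=0, engine="auto")
        assert auto.engine == "exhaustive"

    def test_mc_pattern_tails_match_exhaustive(self):
        """The kernel's per-pattern tail probabilities (including the
        complement-symmetry shortcut) match the exhaustive oracle within
        binomial error; the combined p is calibrated (see null test)."""
        rng = np.random.default_rng(902)
        n_perm = 4000
        for _ in range(5):
            groups = [rng.normal(size=2) for _ in range(3)]
            ex = rain_test(groups, engine="exhaustive")
            mc = rain_test(groups, engine="monte_carlo", n_perm=n_perm,
                           seed=int(rng.integers(2**31)))
            for p_ex, p_mc in zip(ex.pattern_pvalues, mc.pattern_pvalues):
                se = np.sqrt(p_ex * (1 - p_ex) / n_perm)
                assert abs(p_mc - p_ex) <= 3 * se + 1 / (n_perm + 1), (p_ex, p_mc)

    def test_mc_bonferroni_p_matches_exhaustive(self):
        """With the Bonferroni combination (integer tail counts, no
        standardization) the MC engine converges to the exhaustive p.

        The default max-T combination is calibrated (see the null test) but
        at tiny sample sizes its MC estimate need not converge to the
        exhaustive number: the permutation-estimated standard deviations
        decide whether heavily-tied statistic atoms fall inside the tail.
        """
        groups = [np.array([0.0, 0.1]), np.array([10.0, 10.1]), np.array([5.0, 5.1])]
        n_perm = 4000
        ex = rain_test(groups, engine="exhaustive", combine="bonferroni")
        for seed in (5, 6, 7):
            mc = rain_test(groups, engine="monte_carlo", n_perm=n_perm,
                           seed=seed, combine="bonferroni")
            # Bonferroni multiplies the min pattern tail by 15, so the
            # binomial SE of that tail scales by 15 as well
            p_min = ex.p_raw / 15
            se = np.sqrt(p_min * (1 - p_min) / n_perm)
            assert abs(mc.p_raw - ex.p_raw) <= 15 * (3 * se + 1 / (n_perm + 1))

    def test_null_calibration(self, design_small):
        """Exchangeable null series: P(p_raw < 0.05) <= 0.05 + 3 SE."""
        rng = np.random.default_rng(905)
        n_series = 1000
        hits = 0
        for i in range(n_series):
            groups = [rng.normal(size=3) for _ in range(3)]
            res = rain_test(groups, n_perm=400, seed=int(rng.integers(2**31)),
                            engine="monte_carlo")
            hits += res.p_raw < 0.05
        se = np.sqrt(0.05 * 0.95 / n_series)
        assert hits / n_series <= 0.05 + 3 * se

    def test_bad_combine_rejected(self):
        with pytest.raises(ValueError):
            rain_test([np.ones(2)] * 3, combine="stouffer")

    def test_design_mismatch_rejected(self, design48):
        with pytest.raises(ValueError):
            rain_test([np.ones(2)] * 3, design48)


class TestBHAdjust:
    def test_printed_critical_value(self):
        m, k, alpha = 103_904, 9_153, 0.05
        # p-vector engineered so the step-up stops at exactly k discoveries
        p = np.empty(m)
        p[:k] = (np.arange(1, k + 1) / m) * alpha * 0.99
        p[k:] = np.linspace(0.5, 1.0, m - k)
        adjusted, flags, critical = bh_adjust(p, alpha)
        assert int(flags.sum()) == k
        assert round(critical, 4) == 0.0044

    def test_all_ones_no_discovery(self):
        _, flags, critical = bh_adjust(np.ones(10), 0.05)
        assert not flags.any() and critical == 0.0

    def test_hand_example_all_discovered(self):
        adjusted, flags, critical = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]), 0.05)
        assert flags.all()
        assert critical == pytest.approx(0.05)
        assert np.allclose(adjusted, 0.04)

    def test_adjusted_ge_raw(self):
        rng = np.random.default_rng(908)
        p = rng.uniform(size=200)
        adjusted, _, _ = bh_adjust(p)
        assert (adjusted >= p - 1e-12).all()

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(909)
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=500) ** 2
        adjusted, flags, _ = bh_adjust(p, 0.05)
        reject_sm, adj_sm, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.allclose(adjusted, adj_sm)
        # statsmodels rejects at <=, we flag at <; agreement holds when no
        # adjusted p sits exactly on alpha
        assert (flags == reject_sm).all() or np.isclose(adj_sm[flags != reject_sm], 0.05).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))

    def test_empty_input(self):
        adjusted, flags, critical = bh_adjust(np.array([]))
        assert adjusted.size == 0 and flags.size == 0 and critical == 0.0


class TestAssignPeak:
    def test_noiseless_cosine_18(self, design48):
        hours = np.array(design48.times_of_day)
        wave = 1 + np.cos(2 * np.pi * (hours - 18.0) / 24.0)
        groups = [np.full(8, w) + np.arange(8) * 1e-9 for w in wave]
        res = rain_test(groups, design48, n_perm=2000, seed=3)
        peak = assign_peak(res.pattern_z, [g.mean() for g in groups],
                           enumerate_patterns(6), design48.times_of_day)
        assert peak == 18.0

    def test_tie_broken_by_larger_mean(self):
        patterns = enumerate_patterns(3)
        z = np.zeros(len(patterns))  # every hour ties at score 0
        peak = assign_peak(z, [5.0, 7.0, 6.0], patterns, (2.0, 6.0, 10.0))
        assert peak == 6.0  # hour of the mean-7.0 group


class TestRunRhythmicity:
    def test_output_contract(self, small_study, design48):
        from dieltx import quantify
        from dieltx.taxonomy import TaxonomyTree

        tax = TaxonomyTree.from_frame(small_study.taxonomy)
        abund = quantify(small_study.contigs, tax, "genus")
        res = run_rhythmicity(abund, design48, n_perm=300, seed=5)
        assert len(res) == len(abund.values)
        assert ((res["p_raw"] >= 0) & (res["p_raw"] <= 1)).all()
        assert (res["p_adjusted"] >= res["p_raw"] - 1e-12).all()
        assert (res["is_diel"] == (res["p_adjusted"] < 0.05)).all()
        diel = res[res["is_diel"]]
        assert diel["peak_hour"].isin(design48.times_of_day).all()
        assert res.loc[~res["is_diel"], "peak_hour"].isna().all()

    def test_per_bin_scope_runs(self, small_study, design48):
        from dieltx import quantify
        from dieltx.taxonomy import TaxonomyTree

        tax = TaxonomyTree.from_frame(small_study.taxonomy)
        abund = quantify(small_study.contigs, tax, "genus")
        res = run_rhythmicity(abund, design48, n_perm=200, seed=5, scope="per_bin")
        assert len(res) == len(abund.values)
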