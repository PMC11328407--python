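"""Differential-editing statistics: GLM LRT, exact Fisher, BH, Tukey, and
the dual decision rule."""

import itertools
import math
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from rnaedit.dre import (
    DREConfig,
    SiteCountsByGroup,
    bh_adjust,
    decide_dre,
    fisher_rx2_test,
    flag_missense_diff,
    glm_lrt_statistic,
    glm_lrt_test,
    tukey_hsd,
)


def _site(alt_by_group, ref_by_group):
    groups = [f"g{i}" for i in range(len(alt_by_group))]
    return SiteCountsByGroup(
        groups,
        [np.asarray(a, dtype=float) for a in alt_by_group],
        [np.asarray(r, dtype=float) for r in ref_by_group],
    )


class TestGlmLrt:
    def test_identical_groups_give_p_one(self):
        site = _site([[5, 5, 5]] * 4, [[45, 45, 45]] * 4)
        p, stat, _ = glm_lrt_test(site)
        assert stat == 0.0
        assert p == 1.0

    def test_matches_statsmodels_glm_deviance(self):
        """Closed-form LRT equals an iteratively fitted binomial GLM."""
        import statsmodels.api as sm

        rng = np.random.default_rng(21)
        for _ in range(25):
            k = rng.integers(2, 5)
            depth = rng.integers(20, 200, size=(k, 3))
            levels = rng.uniform(0.05, 0.6, size=k)
            alt = rng.binomial(depth, levels[:, None])
            ref = depth - alt
            if (alt.sum(axis=1) == 0).any() or (ref.sum(axis=1) == 0).any():
                continue  # separation guard would change the counts
            site = _site(list(alt), list(ref))
            _, stat, _ = glm_lrt_test(site)

            endog = np.column_stack([alt.sum(axis=1), ref.sum(axis=1)])
            exog = pd.get_dummies(pd.Series([f"g{i}" for i in range(k)]), dtype=float)
            full = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
            null = sm.GLM(
                endog, np.ones((k, 1)), family=sm.families.Binomial()
            ).fit()
            assert stat == pytest.approx(null.deviance - full.deviance, abs=1e-6)

    def test_large_effect_and_permutation_agreement(self):
        rng = np.random.default_rng(3)
        depth = 200
        alt = [rng.binomial(depth, p, 3) for p in (0.05, 0.05, 0.05, 0.40)]
        ref = [depth - a for a in alt]
        site = _site(alt, ref)
        p_lrt, _, _ = glm_lrt_test(site)
        assert p_lrt < 1e-6
        p_perm, _, _ = glm_lrt_test(
            site, DREConfig(empirical_p_mode="permutation", n_perm=500, seed=9)
        )
        # the permutation null is granular: any shuffle that reunites the
        # three extreme samples in one group reproduces the statistic, so the
        # attainable floor is ~4/C(12,3) ~= 0.018; both modes call it extreme
        assert p_perm < 0.05

    def test_null_calibration(self):
        """Type-I error of the LRT at nominal 0.05 on binomial null sites."""
        rng = np.random.default_rng(11)
        hits = 0
        n_sites = 500
        for _ in range(n_sites):
            depth = rng.negative_binomial(5, 5 / 105, (4, 3))
            alt = rng.binomial(depth, 0.1)
            p, _, _ = glm_lrt_test(_site(list(alt), list(depth - alt)))
            hits += p < 0.05
        assert 0.02 <= hits / n_sites <= 0.09

    def test_separation_guard_flags_and_returns_finite_p(self):
        site = _site([[0, 0, 0], [10, 12, 9]], [[50, 50, 50], [40, 38, 41]])
        p, stat, adjusted = glm_lrt_test(site)
        assert adjusted
        assert 0 < p < 1 and math.isfinite(stat)

    def test_statistic_non_negative(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            alt = rng.integers(0, 30, 4) + 1
            ref = rng.integers(1, 100, 4)
            assert glm_lrt_statistic(alt, ref) >= 0

    def test_insufficient_groups_missing(self):
        site = _site([[5, 5]], [[45, 45]])
        p, stat, _ = glm_lrt_test(site)
        assert math.isnan(p) and math.isnan(stat)


def fisher_bruteforce(table):
    """Independent oracle: exhaustive product enumeration of margin-fixed
    tables via exact integer binomial coefficients."""
    t = np.asarray(table, dtype=int)
    rows = t.sum(axis=1)
    c1 = int(t[:, 0].sum())
    n = int(rows.sum())
    denom = comb(n, c1)

    def prob(a):
        num = 1
        for r, x in zip(rows, a):
            num *= comb(int(r), int(x))
        return num / denom

    obs = prob(t[:, 0])
    total = p_sum = 0.0
    for a in itertools.product(*[range(int(r) + 1) for r in rows]):
        if sum(a) != c1:
            continue
        pr = prob(a)
        total += pr
        if pr <= obs * (1 + 1e-7):
            p_sum += pr
    return p_sum, total


class TestFisherRx2:
    def test_proportional_rows_independent(self):
        p, method = fisher_rx2_test([[5, 10], [10, 20], [2, 4], [6, 12]])
        assert method == "exact"
        assert p == pytest.approx(1.0)

    def test_2x2_against_scipy_and_enumeration(self):
        table = [[10, 0], [0, 10]]
        p, _, total = fisher_rx2_test(table, return_total=True)
        assert total == pytest.approx(1.0, abs=1e-9)
        assert p == pytest.approx(fisher_exact(table).pvalue, rel=1e-9)
        p_brute, _ = fisher_bruteforce(table)
        assert p == pytest.approx(p_brute, abs=1e-9)

    def test_random_tables_match_bruteforce(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            R = rng.integers(2, 5)
            t = rng.integers(0, 11, (R, 2))
            if t.sum(axis=1).min() == 0 or t[:, 0].sum() == 0 or t[:, 1].sum() == 0:
                continue
            p, method, total = fisher_rx2_test(t, return_total=True)
            assert method == "exact"
            assert total == pytest.approx(1.0, abs=1e-9)
            p_brute, brute_total = fisher_bruteforce(t)
            assert brute_total == pytest.approx(1.0, abs=1e-9)
            assert abs(p - p_brute) < 1e-9

    def test_degenerate_column_warns_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            p, method = fisher_rx2_test([[0, 10], [0, 20]])
        assert p == 1.0

    def test_monte_carlo_fallback_close_to_exact(self):
        table = [[120, 380], [150, 350], [100, 400], [170, 330]]
        p_mc, method = fisher_rx2_test(
            table, enum_budget=10, n_mc=40_000, rng=np.random.default_rng(5)
        )
        assert method == "monte_carlo"
        p_exact, _ = fisher_rx2_test(table, enum_budget=10**9)
        assert p_mc == pytest.approx(p_exact, abs=0.02)


class TestBhAdjust:
    def test_forced_equal_adjustment(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_never_decreases_and_rank_preserving(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=1000)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert math.isnan(out[1]) and not math.isnan(out[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])


class TestTukeyHsd:
    def test_equal_means_p_near_one(self):
        levels = {g: np.array([0.10, 0.12, 0.11]) for g in "abcd"}
        pairs, degenerate = tukey_hsd(levels)
        assert not degenerate
        assert all(p > 0.99 for p in pairs.values())

    def test_shifted_group_has_smallest_pairs(self):
        rng = np.random.default_rng(4)
        levels = {g: 0.1 + rng.normal(0, 0.01, 3) for g in "abc"}
        levels["d"] = 0.4 + rng.normal(0, 0.01, 3)
        pairs, _ = tukey_hsd(levels)
        with_d = [p for k, p in pairs.items() if "d" in k]
        without_d = [p for k, p in pairs.items() if "d" not in k]
        assert max(with_d) < min(without_d)

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(12)
        for _ in range(5):
            levels = {g: rng.uniform(0, 1, 4) for g in "abcd"}
            pairs, _ = tukey_hsd(levels)
            flat = np.concatenate(list(levels.values()))
            labels = np.repeat(list(levels), 4)
            ref = pairwise_tukeyhsd(flat, labels)
            ref_pairs = {
                (a, b): p
                for (a, b), p in zip(
                    itertools.combinations(ref.groupsunique, 2), ref.pvalues
                )
            }
            for key, p in pairs.items():
                # statsmodels uses an interpolated studentized-range table
                assert p == pytest.approx(ref_pairs[key], abs=2e-3)

    def test_zero_variance_limit_convention(self):
        pairs, degenerate = tukey_hsd(
            {"a": np.array([0.1, 0.1]), "b": np.array([0.1, 0.1]), "c": np.array([0.3, 0.3])}
        )
        assert degenerate
        assert pairs[("a", "b")] == 1.0
        assert pairs[("a", "c")] == 0.0


class TestDecisionRule:
    @pytest.mark.parametrize(
        "glm_p, glm_fdr, fisher_fdr, expected",
        [
            (0.04, 0.20, 0.01, True),  # rescued by Fisher FDR
            (0.06, 0.001, None, False),  # gate 1 fails regardless of FDR
            (0.01, 0.10, 0.10, False),  # gate 2 fails on both FDRs
            (0.01, 0.01, None, True),  # GLM FDR alone suffices
        ],
    )
    def test_dual_criterion(self, glm_p, glm_fdr, fisher_fdr, expected):
        assert decide_dre(glm_p, glm_fdr, fisher_fdr) is expected

    @pytest.mark.parametrize(
        "is_dre, category, diff, expected",
        [
            (True, "missense", 0.125, True),  # 17.3/9/6.6/19.1% spread
            (True, "missense", 0.03, False),
            (True, "3UTR", 0.20, False),
            (False, "missense", 0.20, False),
        ],
    )
    def test_missense_spread_flag(self, is_dre, category, diff, expected):
        assert flag_missense_diff(is_dre, category, diff) is expected
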