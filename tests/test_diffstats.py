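from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ribomethyl.diffstats import (
    bh_adjust,
    impute_lower_tail,
    permutation_fdr,
    s0_statistic,
    significance_b,
)
from ribomethyl.synthdata import MissingSpec, simulate_intensity_table


def toy_table(seed=0, n_features=40, missing=False):
    table, _ = simulate_intensity_table(n_features, 3, None,
                                        MissingSpec() if missing else None, seed=seed)
    return table


GROUPS = {f"WT_{i}": "WT" for i in (1, 2, 3)} | {f"KO_{i}": "KO" for i in (1, 2, 3)}


class TestImpute:
    def test_complete_table_unchanged(self):
        table = toy_table()
        pd.testing.assert_frame_equal(impute_lower_tail(table, seed=1), table)

    def test_observed_cells_never_altered(self):
        table = toy_table(missing=True, n_features=400)
        done = impute_lower_tail(table, seed=1)
        observed = ~table.isna()
        assert (done[observed] == table[observed]).all().all() or \
            np.allclose(done.to_numpy()[observed.to_numpy()], table.to_numpy()[observed.to_numpy()])
        assert not done.isna().any().any()

    def test_imputed_values_sit_in_lower_tail(self):
        """Imputed draws concentrate far below the observed distribution:
        nearly all under the observed 25th percentile, most under the 5th."""
        table = toy_table(missing=True, n_features=5000)
        done = impute_lower_tail(table, seed=2)
        for col in table.columns:
            missing = table[col].isna()
            if missing.sum() < 20:
                continue
            imputed = done.loc[missing, col]
            assert (imputed < table[col].quantile(0.25)).mean() > 0.99
            assert (imputed < table[col].quantile(0.05)).mean() > 0.6
            assert imputed.median() < table[col].quantile(0.05)

    def test_same_seed_identical_completion(self):
        table = toy_table(missing=True, n_features=300)
        pd.testing.assert_frame_equal(impute_lower_tail(table, seed=9),
                                      impute_lower_tail(table, seed=9))

    def test_too_few_observed_values_error(self):
        table = toy_table(n_features=4)
        table.iloc[0:2, 0] = np.nan
        with pytest.raises(ValueError, match="observed"):
            impute_lower_tail(table, seed=0)


class TestS0Statistic:
    def test_identical_groups_give_zero(self):
        x = np.array([[1.0, 2.0, 3.0]])
        assert s0_statistic(x, x, 0.1)[0] == 0.0

    def test_s0_zero_equals_pooled_t(self):
        x = np.array([5.1, 4.8, 5.4])
        y = np.array([4.2, 4.0, 4.5])
        d = s0_statistic(x[None, :], y[None, :], 0.0)[0]
        t = stats.ttest_ind(x, y, equal_var=True).statistic
        assert d == pytest.approx(t, rel=1e-12)

    @given(s0a=st.floats(0.0, 1.0), s0b=st.floats(1.0, 5.0))
    @settings(max_examples=30, deadline=None)
    def test_larger_s0_shrinks_statistic(self, s0a, s0b):
        x = np.array([[5.1, 4.8, 5.4]])
        y = np.array([[4.2, 4.0, 4.5]])
        da = abs(s0_statistic(x, y, s0a)[0])
        db = abs(s0_statistic(x, y, s0b)[0])
        if s0b > s0a:
            assert db < da

    def test_single_sample_group_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            s0_statistic(np.array([[1.0]]), np.array([[1.0, 2.0]]), 0.1)


class TestPermutationFdr:
    def test_identical_groups_nothing_significant(self):
        half = toy_table(seed=3)[["WT_1", "WT_2", "WT_3"]]
        table = pd.concat([half, half.set_axis(["KO_1", "KO_2", "KO_3"], axis=1)], axis=1)
        res = permutation_fdr(table, GROUPS, s0=0.1, fdr_target=0.01, seed=0)
        assert not res.table.significant.any()

    def test_null_statistics_match_brute_force_enumeration(self):
        """Exact enumeration must agree with an independent loop over all
        label assignments (identity and mirror excluded), s0 = 0."""
        table = toy_table(seed=4, n_features=15)
        res = permutation_fdr(table, GROUPS, s0=0.0, fdr_target=0.05, n_perm=10_000, seed=1)
        data = table.to_numpy()
        null = []
        observed = (0, 1, 2)
        for idx in combinations(range(6), 3):
            if idx == observed or idx == (3, 4, 5):
                continue
            rest = [j for j in range(6) if j not in idx]
            for row in data:
                g1, g2 = row[list(idx)], row[rest]
                t = stats.ttest_ind(g1, g2, equal_var=True).statistic
                null.append(abs(t))
        assert res.n_permutations == 18
        np.testing.assert_allclose(res.null_abs, np.sort(null), rtol=1e-10)
        # FDR-hat at the largest observed |d| recomputed independently
        c = res.fdr_curve.threshold.iloc[0]
        n_null_ge = np.sum(np.array(null) >= c)
        assert res.fdr_curve.mean_null.iloc[0] == pytest.approx(n_null_ge / 18)

    def test_planted_effects_recovered(self):
        table, truth = simulate_intensity_table(400, 3, [(list(range(30)), 2.0)], None, seed=6)
        groups = {c: c.split("_")[0] for c in table.columns}
        res = permutation_fdr(table, groups, s0=0.1, fdr_target=0.01, seed=2)
        sig = res.table.significant
        assert (sig & truth).sum() / truth.sum() >= 0.9

    def test_too_few_assignments_error(self):
        table = toy_table(seed=5)[["WT_1", "WT_2", "KO_1", "KO_2"]]
        groups = {"WT_1": "WT", "WT_2": "WT", "KO_1": "KO", "KO_2": "KO"}
        with pytest.raises(ValueError, match="assignments"):
            permutation_fdr(table, groups)

    def test_missing_values_rejected(self):
        table = toy_table(seed=7)
        table.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            permutation_fdr(table, GROUPS)


class TestSignificanceB:
    def test_bin_median_ratio_has_p_one(self, rng):
        ratios = rng.normal(0, 1, 301)
        ratios[0] = np.median(ratios[1:301])
        inten = np.arange(301.0)
        # put feature 0 in the only bin; its ratio equals the bin median
        p = significance_b(ratios, inten, bin_size=300)
        med_idx = int(np.argsort(ratios)[len(ratios) // 2])
        assert p[med_idx] == pytest.approx(1.0, abs=0.02)

    def test_1p96_robust_sigma_gives_p05(self, rng):
        base = rng.normal(0, 1, 400)
        centre = np.median(base)
        lo, hi = np.percentile(base, [15.87, 84.13])
        scale = (hi - lo) / 2
        target = centre + 1.96 * scale
        ratios = np.concatenate([base, [target]])
        inten = np.arange(401.0)
        p = significance_b(ratios, inten, bin_size=401)
        # adding the probe point itself shifts the bin statistics slightly
        assert p[-1] == pytest.approx(0.05, abs=0.002)

    def test_standard_normal_calibration(self, rng):
        n = 3000
        ratios = rng.normal(0, 1, n)
        inten = rng.uniform(20, 30, n)
        frac = (significance_b(ratios, inten) < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) < 3 * se + 0.01  # robust-scale estimation adds slack

    def test_invariant_to_monotone_intensity_rescaling(self, rng):
        ratios = rng.normal(0, 1, 900)
        inten = rng.uniform(20, 30, 900)
        p1 = significance_b(ratios, inten)
        p2 = significance_b(ratios, np.exp(inten / 3))
        np.testing.assert_allclose(p1, p2)

    def test_zero_scale_bin_error(self):
        ratios = np.zeros(300)
        with pytest.raises(ValueError, match="bin"):
            significance_b(ratios, np.arange(300.0))


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_at_least_raw_and_monotone(self, pvals):
        adj = bh_adjust(pvals)
        assert (adj >= np.asarray(pvals) - 1e-12).all()
        order = np.argsort(pvals)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust([0.1, 1.5])
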