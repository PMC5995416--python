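import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from advafm import cohortstats
from advafm.cohortstats import (
    BinSpec,
    DIAMETER_BINS,
    DPERIOD_BINS,
    aggregate_per_patient,
    bh_adjust,
    bin_subgroups,
    compare_variables,
    ks_two_sample,
    mann_whitney,
    spearman,
    students_t,
)


def _brute_force_mw_p(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all group labelings."""
    pooled = np.concatenate([x, y])
    n = len(x)
    u_obs = cohortstats._u_statistic(np.asarray(x, float), np.asarray(y, float))
    us = []
    for idx in itertools.combinations(range(len(pooled)), n):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(idx)] = True
        us.append(cohortstats._u_statistic(pooled[sel], pooled[~sel]))
    us = np.asarray(us)
    lower = np.mean(us <= u_obs)
    upper = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(lower, upper))


class TestMannWhitney:
    def test_exact_matches_brute_force(self, rng):
        for _ in range(10):
            n, m = rng.integers(2, 7, size=2)
            x = rng.normal(size=n)
            y = rng.normal(rng.normal(), size=m)
            res = mann_whitney(x, y)
            assert res.p_value == pytest.approx(_brute_force_mw_p(x, y), abs=1e-12)

    def test_exact_matches_scipy(self, rng):
        for _ in range(10):
            x = rng.normal(size=8)
            y = rng.normal(0.5, size=9)
            res = mann_whitney(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_ties_fall_back_to_normal(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [2.0, 4.0, 5.0, 6.0]
        res = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_hodges_lehmann_shift(self, rng):
        x = rng.normal(10.0, 1.0, size=10)
        y = rng.normal(0.0, 1.0, size=10)
        res = mann_whitney(x, y)
        lo, hi = res.ci95
        diffs = np.sort(np.subtract.outer(x, y).ravel())
        assert lo in diffs and hi in diffs
        assert lo <= np.median(diffs) <= hi
        assert lo <= 10.0 <= hi

    def test_hl_ci_coverage_null_shift(self, rng):
        hits = 0
        for _ in range(200):
            x = rng.normal(3.0, 1.0, size=8)
            y = rng.normal(0.0, 1.0, size=9)
            lo, hi = mann_whitney(x, y).ci95
            hits += lo <= 3.0 <= hi
        assert hits / 200 > 0.88  # nominal 95%, small-sample conservative band

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError, match="at least 2"):
            mann_whitney([1.0], [2.0, 3.0])


class TestKS:
    def test_statistic_matches_ecdf_sweep(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(0.7, size=25)
        res = ks_two_sample(x, y)
        # independent oracle: sweep every pooled value
        pooled = np.concatenate([x, y])
        d = max(
            abs(np.mean(x <= v) - np.mean(y <= v)) for v in pooled
        )
        assert res.statistic == pytest.approx(d, abs=1e-12)

    def test_p_matches_scipy(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        res = ks_two_sample(x, y)
        ref = stats.ks_2samp(x, y, method="asymp")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError, match="at least 8"):
            ks_two_sample(np.arange(5.0), np.arange(8.0))


class TestSpearman:
    def test_matches_scipy(self, rng):
        x = rng.normal(size=17)
        y = x + rng.normal(size=17)
        rho, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_close_to_exact_permutation_at_n6(self, rng):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        rho, p = spearman(x, y)
        rhos = [
            stats.spearmanr(x, np.asarray(perm)).statistic
            for perm in itertools.permutations(y)
        ]
        p_exact = np.mean(np.abs(rhos) >= abs(rho) - 1e-12)
        assert abs(p - p_exact) < 0.01

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="undefined correlation"):
            spearman([1.0] * 6, [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])

    def test_minimum_pairs(self):
        with pytest.raises(ValueError, match="at least 5"):
            spearman([1.0, 2.0], [3.0, 4.0])


class TestStudentsT:
    def test_matches_scipy_pooled(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(1.0, size=9)
        res = students_t(x, y)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_degenerate_zero_variance(self):
        res = students_t([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.degenerate and res.p_value == 1.0
        res = students_t([3.0, 3.0], [2.0, 2.0])
        assert res.degenerate and res.p_value == 0.0 and math.isinf(res.statistic)


class TestBins:
    def test_default_bin_specs(self):
        assert DIAMETER_BINS.edges_nm == (70.0, 120.0, 150.0, 200.0)
        assert DPERIOD_BINS.edges_nm == (45.0, 59.0, 70.0, 80.0)

    def test_half_open_and_closed_last(self):
        tbl, n_out = bin_subgroups([70.0, 119.9, 120.0, 150.0, 200.0, 60.0, 201.0],
                                   DIAMETER_BINS)
        assert tbl["n"].tolist() == [2, 1, 2]
        assert n_out == 2
        assert tbl["percentage"].sum() == pytest.approx(100.0)

    def test_bin_summary_stats(self):
        tbl, _ = bin_subgroups([80.0, 100.0], DIAMETER_BINS)
        assert tbl.loc[0, "mean"] == pytest.approx(90.0)
        assert tbl.loc[0, "sd"] == pytest.approx(np.std([80.0, 100.0], ddof=1))

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            BinSpec("x", (10.0, 5.0))


class TestBH:
    def test_matches_hand_computed_step_up(self):
        p = [0.01, 0.04, 0.03, 0.005]
        np.testing.assert_allclose(bh_adjust(p), [0.02, 0.04, 0.04, 0.02])

    def test_monotone_and_bounded(self, rng):
        p = rng.random(20)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestAggregation:
    def test_per_patient_mean_with_validity(self):
        df = pd.DataFrame(
            {
                "patient_id": ["a", "a", "a", "b", "b"],
                "v": [1.0, 3.0, 100.0, 5.0, 7.0],
                "valid": [True, True, False, True, True],
            }
        )
        means = aggregate_per_patient(df, "v", valid_col="valid")
        assert means["a"] == pytest.approx(2.0)
        assert means["b"] == pytest.approx(6.0)

    def test_warns_on_empty_patient(self):
        df = pd.DataFrame(
            {"patient_id": ["a", "b"], "v": [1.0, 2.0], "valid": [True, False]}
        )
        with pytest.warns(UserWarning, match="zero valid"):
            means = aggregate_per_patient(df, "v", valid_col="valid")
        assert list(means.index) == ["a"]


class TestCompareVariables:
    def test_batch_layout_and_bh(self, rng):
        patients = pd.DataFrame(
            {
                "group": ["low"] * 8 + ["high"] * 9,
                "a": rng.normal(size=17),
                "b": rng.normal(2.0, size=17),
            }
        )
        tbl = compare_variables(patients, ["a", "b"])
        assert list(tbl["variable"]) == ["a", "b"]
        np.testing.assert_allclose(
            tbl["p_adjusted"], bh_adjust(tbl["p_value"]), atol=1e-12
        )
        assert {"n_low", "mean_low", "sd_high", "ci95_low", "statistic"} <= set(
            tbl.columns
        )

    def test_unknown_test(self):
        with pytest.raises(ValueError, match="unknown test"):
            compare_variables(pd.DataFrame({"group": []}), [], test="wilcoxon")
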