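import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mbfuse.univariate import (ANTI_GAD_SCHEME, PH_BINARY, PH_STRATA, Interval,
                               IntervalScheme, adjust_pvalues,
                               differential_features, kruskal_wallis,
                               mann_whitney, pearson, stratify_samples)
from _helpers import make_table


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def oracle_kw_h(groups):
    """Rank-sum brute force, no ties assumed."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = pd.Series(pooled).rank().to_numpy()
    offset = 0
    h = 0.0
    for g in groups:
        r = ranks[offset:offset + len(g)]
        h += r.sum() ** 2 / len(g)
        offset += len(g)
    return 12 / (n * (n + 1)) * h - 3 * (n + 1)


class TestKruskalWallis:
    def test_matches_rank_sum_oracle(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        values = np.concatenate(groups)
        labels = np.repeat(["a", "b", "c"], 3)
        h, p = kruskal_wallis(values, labels)
        assert h == pytest.approx(oracle_kw_h(groups))
        assert 0 < p < 1

    def test_identical_values_degenerate_to_null(self):
        h, p = kruskal_wallis([5.0] * 6, np.repeat(["a", "b"], 3))
        assert h == 0.0 and p == 1.0

    def test_two_group_h_equals_squared_standardized_u(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=6) + 0.5
        h, _ = kruskal_wallis(np.concatenate([x, y]),
                              np.array(["x"] * 8 + ["y"] * 6))
        u, _ = mann_whitney(x, y, mode="asymptotic")
        m, n = 8, 6
        z = (u - m * n / 2) / np.sqrt(m * n * (m + n + 1) / 12)
        assert h == pytest.approx(z ** 2, abs=1e-10)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def oracle_mw_exact_p(x, y):
    """Two-sided exact p by enumerating all rank assignments."""
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled)
    ranks = np.empty(nx + ny)
    ranks[order] = np.arange(1, nx + ny + 1)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    us = []
    for combo in itertools.combinations(range(1, nx + ny + 1), nx):
        us.append(sum(combo) - nx * (nx + 1) / 2)
    us = np.array(us)
    mn = nx * ny
    lo = min(u_obs, mn - u_obs)
    p = (np.sum(us <= lo) + np.sum(us >= mn - lo)) / len(us)
    return min(1.0, p)


class TestMannWhitney:
    def test_extreme_ordering_exact_p(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(2 / 6)

    def test_identical_samples_p_near_one(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p > 0.9

    def test_exact_and_asymptotic_agree_at_moderate_n(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        _, p_exact = mann_whitney(x, y, mode="exact")
        _, p_approx = mann_whitney(x, y, mode="asymptotic")
        assert abs(p_exact - p_approx) < 0.02

    @given(st.sets(st.integers(0, 100), min_size=4, max_size=9),
           st.integers(1, 8))
    def test_exact_p_matches_enumeration(self, values, cut):
        values = sorted(values)
        cut = min(cut, len(values) - 1)
        x = np.array(values[:cut], dtype=float)
        y = np.array(values[cut:], dtype=float)
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(oracle_mw_exact_p(x, y), abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


# ---------------------------------------------------------------------------
# p-value adjustment
# ---------------------------------------------------------------------------

def oracle_bh(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_i, idx in list(enumerate(order, start=1))[::-1]:
        prev = min(prev, p[idx] * m / rank_i)
        adj[idx] = prev
    return adj


class TestAdjustPvalues:
    def test_bonferroni_example(self):
        np.testing.assert_allclose(adjust_pvalues([0.01, 0.04], "bonferroni"),
                                   [0.02, 0.08])

    def test_bh_matches_step_up_definition(self, rng):
        for _ in range(10):
            p = rng.uniform(size=rng.integers(1, 12))
            np.testing.assert_allclose(adjust_pvalues(p, "bh_fdr"),
                                       oracle_bh(p), atol=1e-12)

    def test_single_test_unchanged(self):
        assert adjust_pvalues([0.3], "bh_fdr")[0] == pytest.approx(0.3)
        assert adjust_pvalues([0.3], "bonferroni")[0] == pytest.approx(0.3)

    def test_bonferroni_dominates_bh(self, rng):
        p = rng.uniform(size=10)
        assert (adjust_pvalues(p, "bonferroni")
                >= adjust_pvalues(p, "bh_fdr") - 1e-12).all()

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=10)
        for method in ("bonferroni", "bh_fdr"):
            assert (adjust_pvalues(p, method) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5])


# ---------------------------------------------------------------------------
# Pearson
# ---------------------------------------------------------------------------

class TestPearson:
    def test_perfect_linear_relationships(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_definitional_formula(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        r, _ = pearson(x, y)
        expected = (np.mean((x - x.mean()) * (y - y.mean()))
                    / (x.std() * y.std()))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_pairwise_complete_deletion(self):
        x = np.array([1.0, 2, 3, 4, np.nan])
        y = np.array([2.0, 4, 6, 8, 100.0])
        assert pearson(x, y)[0] == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def clinical_frame(**cols):
    n = len(next(iter(cols.values())))
    return pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])


class TestStratifySamples:
    def test_ph_severity_strata(self):
        df = clinical_frame(blood_pH=[7.40, 7.20, 7.05])
        out = stratify_samples(df, "blood_pH", PH_STRATA)
        assert list(out) == ["normal", "moderate", "severe"]

    def test_anti_gad_boundary_is_strictly_greater(self):
        df = clinical_frame(anti_GAD=[0.5, 1.0, 3.2])
        out = stratify_samples(df, "anti_GAD", ANTI_GAD_SCHEME)
        assert list(out) == ["low", "low", "high"]

    def test_binary_ph_boundary_belongs_to_upper_stratum(self):
        df = clinical_frame(blood_pH=[7.32])
        out = stratify_samples(df, "blood_pH", PH_BINARY)
        assert list(out) == ["pH>=7.32"]

    def test_missing_values_excluded(self):
        df = clinical_frame(blood_pH=[7.40, np.nan, 7.00])
        out = stratify_samples(df, "blood_pH", PH_STRATA)
        assert len(out) == 2 and "s1" not in out.index

    def test_partitions_without_overlap_or_gaps(self, rng):
        df = clinical_frame(blood_pH=rng.uniform(6.8, 7.6, 50))
        out = stratify_samples(df, "blood_pH", PH_STRATA)
        assert len(out) == 50  # every non-missing sample labeled exactly once

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            IntervalScheme((Interval("a", 0, 5), Interval("b", 4, 9)))

    def test_unknown_variable_rejected(self):
        with pytest.raises(KeyError):
            stratify_samples(clinical_frame(x=[1.0]), "missing", PH_STRATA)


# ---------------------------------------------------------------------------
# differential features
# ---------------------------------------------------------------------------

class TestDifferentialFeatures:
    def test_planted_shifts_recovered(self, rng):
        hits = 0
        n_rep = 10
        for _ in range(n_rep):
            X = rng.normal(size=(120, 200))
            X[:60, :10] += 1.0
            t = make_table(X - X.min() + 0.1)
            labels = np.repeat(["case", "ctrl"], 60)
            res = differential_features(t, labels, adjust="bh_fdr",
                                        alpha=0.05, alpha_adjusted=0.1)
            if res["flag"].to_numpy()[:10].sum() >= 8:
                hits += 1
        assert hits >= 0.8 * n_rep

    def test_null_data_flags_almost_nothing(self, rng):
        X = rng.normal(size=(60, 100))
        t = make_table(X - X.min() + 0.1)
        res = differential_features(t, np.repeat(["a", "b"], 30))
        assert res["flag"].mean() <= 0.05

    def test_single_feature_identical_groups_not_flagged(self):
        t = make_table([[1.0], [2.0], [1.0], [2.0]])
        res = differential_features(t, np.array(["a", "a", "b", "b"]))
        assert not res["flag"].any()

    def test_direction_reports_larger_median_group(self, rng):
        X = np.vstack([rng.normal(10, 1, size=(20, 1)),
                       rng.normal(0, 1, size=(20, 1))])
        t = make_table(X - X.min() + 0.1)
        res = differential_features(t, np.repeat(["hi", "lo"], 20))
        assert res["direction"].iloc[0] == "hi"
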