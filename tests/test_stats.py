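"""Differential statistics, Z stratification, Mahalanobis attribution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunomodules import (
    differential_counts,
    differential_distribution,
    flag_substantial_change,
    mahalanobis_attribution,
    zscore_stratify,
)
from immunomodules.stats import bh_adjust, significance_rule, zscore
from oracles import bh_stepup, fisher_p_enumeration, ranksum_p_enumeration


class TestRankSum:
    def test_fully_separated_groups_exact_p(self):
        """{1..5} vs {6..10}: the two most extreme of C(10,5) rank splits."""
        table = pd.DataFrame({"f": np.arange(1.0, 11.0)})
        groups = pd.Series([0] * 5 + [1] * 5, index=table.index)
        out = differential_distribution(table, groups)
        assert out.loc["f", "p"] == pytest.approx(2 / 252, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=4), rng.normal(size=5)
        table = pd.DataFrame({"f": np.concatenate([a, b])})
        groups = pd.Series([0] * 4 + [1] * 5, index=table.index)
        out = differential_distribution(table, groups)
        assert out.loc["f", "p"] == pytest.approx(
            ranksum_p_enumeration(a, b), abs=1e-12
        )

    def test_identical_groups_not_significant(self):
        table = pd.DataFrame({"f": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        groups = pd.Series([0, 0, 0, 1, 1, 1], index=table.index)
        out = differential_distribution(table, groups)
        assert out.loc["f", "effect_size"] == 0.0
        assert not out.loc["f", "significant"]

    def test_constant_feature_flagged(self):
        table = pd.DataFrame({"f": [2.0] * 8})
        groups = pd.Series([0] * 4 + [1] * 4, index=table.index)
        out = differential_distribution(table, groups)
        assert out.loc["f", "p"] == 1.0
        assert out.loc["f", "constant"]

    def test_cohens_d_value(self):
        a, b = np.array([0.0, 1.0, 2.0]), np.array([3.0, 4.0, 5.0])
        table = pd.DataFrame({"f": np.concatenate([a, b])})
        groups = pd.Series([0] * 3 + [1] * 3, index=table.index)
        out = differential_distribution(table, groups)
        assert out.loc["f", "effect_size"] == pytest.approx(-3.0)  # d = -3/1


class TestPaired:
    def test_signed_rank_on_differences(self):
        before = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        after = before + np.array([1.0, 2.0, 1.5, 2.5, 3.0, 2.75])
        table = pd.DataFrame({"f": np.concatenate([after, before])})
        groups = pd.Series([1] * 6 + [0] * 6, index=table.index)
        out = differential_distribution(table, groups, paired=True)
        # all six differences positive: exact two-sided p = 2 / 2^6
        assert out.loc["f", "p"] == pytest.approx(2 / 64, abs=1e-12)
        # group a is the 0-labeled (before) arm, so ES = mean(before - after) / SD
        d = before - after
        assert out.loc["f", "effect_size"] == pytest.approx(d.mean() / d.std(ddof=1))

    def test_zero_differences_give_p_one(self):
        table = pd.DataFrame({"f": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        groups = pd.Series([0, 0, 0, 1, 1, 1], index=table.index)
        out = differential_distribution(table, groups, paired=True)
        assert out.loc["f", "p"] == 1.0


class TestBH:
    def test_spec_vector(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_matches_stepup_formula(self, pvals):
        assert np.allclose(bh_adjust(pvals), bh_stepup(pvals), atol=1e-12)

    @given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_q_bounds_and_monotonicity(self, pvals):
        p = np.asarray(pvals)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1 + 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestSignificanceRule:
    @pytest.mark.parametrize(
        "p,q,es,expected",
        [
            (0.2, 0.05, 0.1, True),   # q < 0.1 alone suffices
            (0.04, 0.5, 1.5, True),   # p < 0.05 with |ES| > 1
            (0.04, 0.5, -1.5, True),  # sign-free effect size
            (0.04, 0.5, 0.9, False),  # small effect, q too large
            (0.06, 0.5, 2.0, False),  # p too large
        ],
    )
    def test_rule(self, p, q, es, expected):
        out = significance_rule(np.array([p]), np.array([q]), np.array([es]))
        assert bool(out[0]) is expected


class TestFisher:
    def test_identical_proportions_p_one(self):
        out = differential_counts([np.array([[5, 95], [5, 95]])])
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        table = np.array([[20, 80], [0, 100]])
        out = differential_counts([table])
        assert out["p"].iloc[0] == pytest.approx(fisher_p_enumeration(table), abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_small_tables_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            t = rng.integers(0, 10, size=(2, 2))
            if t.sum() > 0 and t.sum() <= 30:
                break
        out = differential_counts([t])
        assert out["p"].iloc[0] == pytest.approx(fisher_p_enumeration(t), abs=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            differential_counts([np.zeros((2, 2), dtype=int)])

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            differential_counts([np.array([[1, -1], [2, 3]])])


class TestZStratification:
    def test_constant_column_zeroed(self):
        table = pd.DataFrame({"c": [3.0] * 6, "x": np.arange(6.0)})
        labels = pd.Series([0, 0, 0, 1, 1, 1], index=table.index)
        zm = zscore_stratify(table, ["c", "x"], labels)
        assert (zm.z["c"] == 0.0).all()

    def test_zscore_idempotent(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(rng.normal(2.0, 5.0, size=(20, 4)))
        once = zscore(values)
        pd.testing.assert_frame_equal(zscore(once), once)

    def test_substantial_change_flag(self):
        before = pd.Series({"f1": -0.3, "f2": 0.0})
        after = pd.Series({"f1": 0.3, "f2": 0.4})
        out = flag_substantial_change(before, after)
        assert bool(out.loc["f1", "substantial"])   # |0.6| > 0.5
        assert not bool(out.loc["f2", "substantial"])  # 0.4 below threshold

    def test_opposite_profiles_split_cleanly(self):
        """Groups with mirrored Z profiles separate at the 2-cluster cut."""
        rng = np.random.default_rng(4)
        n, p = 10, 6
        base = np.ones(p)
        rows = np.vstack(
            [base + 0.05 * rng.standard_normal(p) for _ in range(n)]
            + [-base + 0.05 * rng.standard_normal(p) for _ in range(n)]
        )
        table = pd.DataFrame(rows, index=[f"s{i}" for i in range(2 * n)],
                             columns=[f"f{j}" for j in range(p)])
        labels = pd.Series([0] * n + [1] * n, index=table.index)
        zm = zscore_stratify(table, list(table.columns), labels)
        from scipy.cluster.hierarchy import fcluster

        cut = fcluster(zm.linkage, t=2, criterion="maxclust")
        assert pd.Series(cut).groupby(labels.values).nunique().max() == 1
        # per-group mean Z has opposite signs feature-wise
        assert (zm.group_mean_z.loc[0] * zm.group_mean_z.loc[1] < 0).all()

    def test_empty_feature_list_rejected(self):
        table = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(ValueError, match="empty"):
            zscore_stratify(table, [], pd.Series([0, 1], index=table.index))


class TestMahalanobisAttribution:
    @staticmethod
    def _table(seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)] + ["out"]
        return pd.DataFrame(
            {"f1": rng.normal(size=13), "f2": rng.normal(size=13)}, index=idx
        )

    def test_distance_units(self):
        """d = 0 at the group mean and 1 at one SD from it."""
        table = self._table()
        a = [f"a{i}" for i in range(6)]
        b = [f"b{i}" for i in range(6)]
        table.loc["out", "f1"] = table.loc[a, "f1"].mean()
        table.loc["out", "f2"] = table.loc[a, "f2"].mean() + table.loc[a, "f2"].std(ddof=1)
        out = mahalanobis_attribution(table, "out", a, b)
        assert out.loc["f1", "d_group_a"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["f2", "d_group_a"] == pytest.approx(1.0, abs=1e-12)

    def test_delta_rule_at_threshold(self):
        table = self._table(1)
        a = [f"a{i}" for i in range(6)]
        b = [f"b{i}" for i in range(6)]
        out = mahalanobis_attribution(table, "out", a, b, threshold=0.3)
        manual = out["d_group_a"] - out["d_group_b"]
        pd.testing.assert_series_equal(out["delta"], manual, check_names=False)
        assert ((out["delta"] > 0.3) == out["attributed"]).all()

    def test_swap_negates_delta(self):
        table = self._table(2)
        a = [f"a{i}" for i in range(6)]
        b = [f"b{i}" for i in range(6)]
        fwd = mahalanobis_attribution(table, "out", a, b)
        rev = mahalanobis_attribution(table, "out", b, a)
        assert np.allclose(fwd["delta"], -rev["delta"])

    def test_zero_sd_feature_skipped(self):
        table = self._table(3)
        a = [f"a{i}" for i in range(6)]
        b = [f"b{i}" for i in range(6)]
        table.loc[a, "f1"] = 5.0
        out = mahalanobis_attribution(table, "out", a, b)
        assert bool(out.loc["f1", "skipped_zero_sd"])
        assert not bool(out.loc["f1", "attributed"])

    def test_small_groups_rejected(self):
        table = self._table(4)
        with pytest.raises(ValueError, match="3 subjects"):
            mahalanobis_attribution(table, "out", ["a0", "a1"], ["b0", "b1", "b2"])


class TestNullCalibrationSmall:
    def test_allnull_bh_few_discoveries(self):
        """BH at q<0.1 yields almost no discoveries on pure-noise features."""
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.normal(size=(30, 200)))
        groups = pd.Series([0] * 15 + [1] * 15, index=table.index)
        out = differential_distribution(table, groups)
        assert (out["q"] < 0.1).mean() <= 0.1
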