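"""Statistics layer: U test with tie-corrected z, Welch t, correlations,
test selection, and control-referenced cognitive standardization."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from wristmic.stats import (
    SkewPolicy,
    choose_test,
    correlate,
    group_table,
    mann_whitney,
    mann_whitney_exact_p,
    standardize_cognition,
    welch_t,
)


class TestMannWhitney:
    def test_complete_separation_small(self):
        c = mann_whitney([1, 2, 3], [4, 5, 6])
        assert c.statistic == 0.0
        # enumeration oracle: all C(6,3) = 20 labelings, symmetric deviation
        assert c.p_exact == pytest.approx(0.1)

    def test_exact_p_matches_independent_enumeration(self, rng):
        for _ in range(10):
            a = rng.normal(size=4)
            b = rng.normal(size=5)
            got = mann_whitney_exact_p(a, b)
            # brute-force oracle written from the definition
            pooled = np.concatenate([a, b])
            ranks = sps.rankdata(pooled)
            mu = 4 * 5 / 2
            obs = abs(ranks[:4].sum() - 4 * 5 / 2 - mu)
            count = total = 0
            for idx in itertools.combinations(range(9), 4):
                u = ranks[list(idx)].sum() - 10
                count += abs(u - mu) >= obs - 1e-12
                total += 1
            assert got == pytest.approx(count / total)

    def test_two_groups_of_29_separation(self):
        a = np.arange(1.0, 30.0)
        b = np.arange(100.0, 129.0)
        c = mann_whitney(a, b, exact=False)
        assert c.statistic == 0.0
        # closed form, tie-free: z = -(n1 n2 / 2) / sqrt(n1 n2 (N+1) / 12)
        assert c.z == pytest.approx(-420.5 / np.sqrt(29 * 29 * 59 / 12))
        assert c.z == pytest.approx(-6.539, abs=0.001)
        assert c.p < 0.001

    def test_u_complement_identity(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=13)
        u_ab = mann_whitney(a, b, exact=False).statistic
        u_ba = mann_whitney(b, a, exact=False).statistic
        assert u_ab + u_ba == pytest.approx(8 * 13)

    @given(shift=st.floats(-3, 3))
    @settings(max_examples=20, deadline=None)
    def test_u_invariant_under_monotone_transform(self, shift):
        rng = np.random.default_rng(7)
        a = rng.normal(size=10) + shift
        b = rng.normal(size=12)
        u1 = mann_whitney(a, b, exact=False).statistic
        u2 = mann_whitney(np.exp(a), np.exp(b), exact=False).statistic
        assert u1 == u2

    def test_agreement_with_scipy_reference(self, rng):
        # tie-corrected asymptotic p without continuity correction
        for _ in range(100):
            n1, n2 = rng.integers(5, 30, size=2)
            a = np.round(rng.normal(size=n1), 1)  # rounding creates ties
            b = np.round(rng.normal(size=n2), 1)
            mine = mann_whitney(a, b, exact=False)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                                   use_continuity=False)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-8)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_exact_agrees_with_normal_on_tie_free_samples(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=6), rng.normal(size=6)
            c = mann_whitney(a, b)
            assert abs(c.p_exact - 2 * sps.norm.sf(abs(c.z))) < 0.1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestWelchT:
    def test_identical_groups(self):
        c = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert c.statistic == 0.0
        assert c.p == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=10), rng.normal(1.0, 2.0, size=15)
        c1, c2 = welch_t(a, b), welch_t(b, a)
        assert c1.statistic == pytest.approx(-c2.statistic)
        assert c1.p == pytest.approx(c2.p)
        assert c1.df == pytest.approx(c2.df)

    def test_hand_computed_five_plus_five(self):
        # textbook computation on a fixed table:
        # a: mean 3, var 2.5; b: mean 4.6, var 7.3
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [2.0, 3.0, 4.0, 5.0, 9.0]
        c = welch_t(a, b)
        se = np.sqrt(2.5 / 5 + 7.3 / 5)
        assert c.statistic == pytest.approx((3.0 - 4.6) / se)
        df = (2.5 / 5 + 7.3 / 5) ** 2 / ((2.5 / 5) ** 2 / 4 + (7.3 / 5) ** 2 / 4)
        assert c.df == pytest.approx(df)

    def test_agreement_with_scipy_reference(self, rng):
        for _ in range(100):
            n1, n2 = rng.integers(3, 40, size=2)
            a = rng.normal(0, 1, size=n1)
            b = rng.normal(0.5, 2.0, size=n2)
            mine = welch_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-8)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-8)
            assert mine.df == pytest.approx(ref.df, abs=1e-8)

    def test_zero_variance_cases(self):
        c = welch_t([2.0, 2.0], [2.0, 2.0])
        assert c.statistic == 0.0 and c.p == 1.0
        c = welch_t([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(c.statistic)


class TestChooseTest:
    def test_lognormal_triggers_rank_test(self, rng):
        assert choose_test(rng.lognormal(0, 1.5, 60), rng.normal(size=60)) == "mann_whitney"

    def test_two_normals_use_welch(self, rng):
        assert choose_test(rng.normal(size=60), rng.normal(size=60)) == "welch_t"

    def test_policy_override(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=10)
        assert choose_test(a, b, SkewPolicy(force="mann_whitney")) == "mann_whitney"


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r = correlate(x, 2 * x + 1, method="pearson")
        assert r.coefficient == pytest.approx(1.0)

    def test_monotone_transform_spearman_one(self, rng):
        x = rng.normal(size=20)
        r = correlate(x, np.exp(x), method="spearman")
        assert r.coefficient == pytest.approx(1.0)

    def test_spearman_matches_midrank_formula(self):
        # enumeration oracle on a fixed 10-pair table with ties
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 5.0, 6.0, 7.0, 8.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0, 8.0, 7.0, 9.0, 9.0])
        r = correlate(x, y, method="spearman")
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]  # Pearson on midranks
        assert r.coefficient == pytest.approx(expected, abs=1e-12)

    def test_agreement_with_scipy_reference(self, rng):
        for _ in range(100):
            n = rng.integers(5, 50)
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            mine_p = correlate(x, y, method="pearson")
            ref = sps.pearsonr(x, y)
            assert mine_p.coefficient == pytest.approx(ref.statistic, abs=1e-10)
            mine_s = correlate(x, y, method="spearman")
            refs = sps.spearmanr(x, y)
            assert mine_s.coefficient == pytest.approx(refs.statistic, abs=1e-10)

    def test_missing_data_dropped_pairwise(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, np.nan, 10.0])
        r = correlate(x, y, method="pearson")
        assert r.n == 3
        assert r.coefficient == pytest.approx(1.0)

    def test_constant_input_flagged(self):
        r = correlate(np.ones(5), np.arange(5.0))
        assert r.constant_input and np.isnan(r.coefficient)

    def test_auto_uses_skew_policy(self, rng):
        x = rng.lognormal(0, 2, 50)
        y = rng.normal(size=50)
        assert correlate(x, y, method="auto").method == "spearman"
        assert correlate(y, y + rng.normal(size=50), method="auto").method == "pearson"


class TestStandardizeCognition:
    DOMAIN_MAP = {"A": [("t1", +1), ("t2", -1)], "B": [("t3", +1)]}

    def _table(self):
        return pd.DataFrame(
            {
                "participant_id": ["c1", "c2", "c3", "p1"],
                "t1": [10.0, 12.0, 14.0, 12.0],
                "t2": [30.0, 20.0, 10.0, 20.0],
                "t3": [5.0, 6.0, 7.0, 6.0],
            }
        )

    def test_simple_control_zscores(self):
        out = standardize_cognition(self._table(), ["c1", "c2", "c3"], self.DOMAIN_MAP)
        assert np.allclose(out["z_t1"][:3], [-1.0, 0.0, 1.0])

    def test_control_mean_zero_sd_one_exactly(self):
        out = standardize_cognition(self._table(), ["c1", "c2", "c3"], self.DOMAIN_MAP)
        for col in ("A", "B", "Grand"):
            ctrl = out[col][:3]
            assert abs(ctrl.mean()) < 1e-10
        assert out["z_t3"][:3].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_participant_at_control_mean_scores_zero_grand(self):
        out = standardize_cognition(self._table(), ["c1", "c2", "c3"], self.DOMAIN_MAP)
        assert out.loc[3, "Grand"] == pytest.approx(0.0, abs=1e-12)

    def test_orientation_flips_sign(self):
        out = standardize_cognition(self._table(), ["c1", "c2", "c3"], self.DOMAIN_MAP)
        # t2 is a time: larger raw (c1 = 30) must standardize to worse (negative)
        assert out.loc[0, "z_t2"] < 0

    def test_zero_control_sd_task_excluded_with_warning(self):
        df = self._table()
        df["t3"] = 5.0
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):  # domain B loses its only task
                standardize_cognition(df, ["c1", "c2", "c3"], self.DOMAIN_MAP)


class TestGroupTable:
    def _profiles(self, rng):
        return pd.DataFrame(
            {
                "group": ["case"] * 8 + ["control"] * 8,
                "v1": np.r_[rng.normal(0, 1, 8), rng.normal(0, 1, 8)],
                "v2": np.r_[rng.normal(0, 1, 8), rng.normal(3, 1, 8)],
            }
        )

    def test_row_per_variable(self, rng):
        table = group_table(self._profiles(rng), ["v1", "v2"], groups=("case", "control"))
        assert len(table) == 2
        assert set(table["variable"]) == {"v1", "v2"}

    def test_identical_groups_large_p(self, rng):
        df = self._profiles(rng)
        df["v1"] = np.tile(np.arange(8.0), 2)
        table = group_table(df, ["v1"], groups=("case", "control"))
        assert table.loc[0, "p"] > 0.95

    def test_complete_separation_shows_u_zero(self, rng):
        df = self._profiles(rng)
        df["v2"] = np.r_[rng.lognormal(0, 0.2, 8), rng.lognormal(0, 0.2, 8) + 50]
        df.loc[df.index[:8], "v2"] = rng.lognormal(0, 2.0, 8)  # skewed case group
        df.loc[df.index[8:], "v2"] = 1e4 + rng.lognormal(0, 2.0, 8)
        table = group_table(df, ["v2"], groups=("case", "control"))
        assert table.loc[0, "test"] == "mann_whitney"
        assert table.loc[0, "statistic"] == 0.0

    def test_fdr_column_optional(self, rng):
        table = group_table(self._profiles(rng), ["v1", "v2"], groups=("case", "control"), fdr=True)
        assert "p_fdr" in table.columns
        assert (table["p_fdr"] >= table["p"] - 1e-12).all()
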