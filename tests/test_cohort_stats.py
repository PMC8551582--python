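"""Cohort statistics: test gate, post-hoc adjustment, stepwise selection."""

import numpy as np
import pandas as pd
import pytest

from octaquant.cohort_stats import (
    CohortTable,
    EyeRecord,
    adjusted_r2,
    chi_square_counts,
    describe_groups,
    group_compare,
    pearson_p_from_r,
    pearson_with_p,
    stepwise_regression,
)


def three_group_df(a, b, c):
    return pd.DataFrame(
        {
            "group": ["HC"] * len(a) + ["acute"] * len(b) + ["convalescent"] * len(c),
            "m": list(a) + list(b) + list(c),
        }
    )


class TestGroupCompare:
    def test_identical_groups_p_one(self):
        df = three_group_df([5.0] * 5, [5.0] * 5, [5.0] * 5)
        c = group_compare(df, "m")
        assert c.global_p == 1.0
        assert all(p == 1.0 for p in c.pairwise_p.values())

    def test_anova_matches_closed_form(self):
        # {1,2,3},{1,2,3},{10,11,12}: SSB=2*0+... hand F computation
        df = three_group_df([1, 2, 3], [1, 2, 3], [10, 11, 12])
        groups = [np.array([1, 2, 3.0]), np.array([1, 2, 3.0]), np.array([10, 11, 12.0])]
        grand = np.concatenate(groups).mean()
        ssb = sum(3 * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        F = (ssb / 2) / (ssw / 6)
        from scipy import stats

        p_hand = stats.f.sf(F, 2, 6)
        c = group_compare(df, "m")
        assert c.test_used == "anova"
        assert c.global_p == pytest.approx(p_hand, rel=1e-9)

    def test_gate_routes_skewed_data_to_kruskal(self, rng):
        skew = rng.lognormal(0, 1.5, 30)
        df = three_group_df(skew, rng.lognormal(0.2, 1.5, 30), rng.lognormal(0, 1.5, 30))
        c = group_compare(df, "m")
        assert c.test_used == "kruskal"

    def test_bonferroni_pairwise_at_least_raw(self):
        rng = np.random.default_rng(4)
        df = three_group_df(
            rng.normal(0, 1, 20), rng.normal(0.2, 1, 20), rng.normal(3, 1, 20)
        )
        c = group_compare(df, "m")
        assert all(0.0 <= p <= 1.0 for p in c.pairwise_p.values())
        # the separated group is detected, the close pair is not
        assert c.pairwise_p[("HC", "convalescent")] < 0.01
        assert c.pairwise_p[("HC", "acute")] > 0.05

    def test_insufficient_sizes_error(self):
        df = three_group_df([1, 2], [1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            group_compare(df, "m")


class TestPearson:
    @pytest.mark.parametrize(
        "r,n,expected",
        [
            (-0.500, 20, 0.025),  # macular deep-plexus VLD, acute arm
            (-0.445, 30, 0.014),  # macular superficial VPD, convalescent arm
            (-0.441, 30, 0.015),
            (-0.373, 30, 0.042),
            (0.414, 30, 0.023),
            (0.365, 30, 0.047),
        ],
    )
    def test_p_from_printed_r_n(self, r, n, expected):
        assert round(pearson_p_from_r(r, n), 3) == expected

    def test_r_zero_p_one(self):
        assert pearson_p_from_r(0.0, 25) == pytest.approx(1.0)

    def test_sign_symmetry_and_monotonicity(self):
        rs = np.linspace(0.05, 0.95, 10)
        ps = [pearson_p_from_r(r, 24) for r in rs]
        assert ps == sorted(ps, reverse=True)
        for r in rs:
            assert pearson_p_from_r(-r, 24) == pytest.approx(pearson_p_from_r(r, 24))

    def test_matches_sample_computation(self, rng):
        x = rng.normal(size=40)
        y = 0.4 * x + rng.normal(size=40)
        r, p = pearson_with_p(x, y)
        assert p == pytest.approx(pearson_p_from_r(r, 40), rel=1e-9)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pearson_with_p([1, 1, 1, 1], [1, 2, 3, 4])


class TestStepwise:
    def test_univariate_beta_equals_pearson_r(self, rng):
        x = rng.normal(size=50)
        y = 0.6 * x + rng.normal(size=50)
        X = pd.DataFrame({"x": x})
        res = stepwise_regression(y, X)
        r, _ = pearson_with_p(x, y)
        assert res.selected == ("x",)
        assert res.coef.loc["x", "beta"] == pytest.approx(r, rel=1e-9)
        assert res.r2 == pytest.approx(r**2, rel=1e-9)

    def test_adjusted_r2_formula(self):
        assert adjusted_r2(0.250, 20, 1) == pytest.approx(0.2083, abs=5e-4)
        assert adjusted_r2(0.425, 30, 3) == pytest.approx(0.3587, abs=5e-4)

    def test_alpha_one_is_forward_select_all(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = rng.normal(size=40)
        res = stepwise_regression(y, X, alpha_enter=1.01, alpha_remove=1.01)
        assert set(res.selected) == {"a", "b", "c"}

    def test_alpha_zero_returns_empty_model(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = X["a"] * 2 + rng.normal(size=40)
        res = stepwise_regression(y.to_numpy(), X, alpha_enter=0.0)
        assert res.selected == ()
        assert res.r2 == 0.0 and np.isnan(res.model_p)

    def test_collinear_candidate_skipped(self, rng):
        x = rng.normal(size=60)
        X = pd.DataFrame({"x": x, "x_copy": x * 2.0})
        y = x + rng.normal(scale=0.5, size=60)
        with pytest.warns(UserWarning, match="collinear"):
            res = stepwise_regression(y, X)
        assert len(res.selected) == 1

    def test_recovers_true_predictors(self, rng):
        X = pd.DataFrame(
            rng.standard_normal((200, 8)), columns=[f"x{i}" for i in range(1, 9)]
        )
        y = 0.5 * X["x1"] - 0.3 * X["x3"] + rng.standard_normal(200)
        res = stepwise_regression(y.to_numpy(), X)
        assert {"x1", "x3"} <= set(res.selected)
        assert res.adj_r2 == pytest.approx(
            adjusted_r2(res.r2, 200, len(res.selected)), rel=1e-9
        )


class TestDescribe:
    def test_mean_sd_basic(self):
        df = three_group_df([1, 2, 3], [1, 2, 3], [1, 2, 3])
        d = describe_groups(df, "m")
        assert d.loc["HC", "mean"] == 2.0
        assert d.loc["HC", "sd"] == pytest.approx(1.0)

    def test_outlier_switches_to_median_style(self, rng):
        vals = np.concatenate([rng.normal(10, 1, 29), [300.0]])
        df = pd.DataFrame({"group": ["acute"] * 30, "m": vals})
        d = describe_groups(df, "m")
        assert not d.loc["acute", "normal"]
        assert "(" in d.loc["acute", "summary"]

    def test_chi_square_closed_form(self):
        # 2x2 table: chi2 = N (ad - bc)^2 / (row/col margins product)
        a, b, c, d = 10, 5, 8, 17
        n = a + b + c + d
        chi_hand = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        chi2, p = chi_square_counts([[a, b], [c, d]])
        assert chi2 == pytest.approx(chi_hand, rel=1e-12)


def test_cohort_table_roundtrip():
    recs = [
        EyeRecord("e1", "HC", None, {"m": 1.0}),
        EyeRecord("e2", "acute", 0.5, {"m": 2.0}),
    ]
    table = CohortTable(recs)
    df = table.to_frame()
    assert table.n_per_group == {"HC": 1, "acute": 1}
    assert df.loc[1, "m"] == 2.0
    with pytest.raises(ValueError):
        EyeRecord("e3", "unknown", 0.1)
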