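"""Statistical battery: every F/p checked against independent oracles
(textbook formulas, nested-OLS projections, statsmodels, pingouin, grid
scans)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wmhh.harmonisation_stats import (
    AncovaResult,
    ancova_wmh_age,
    anova_oneway_posthoc,
    chi_square,
    elastic_net_variance,
    independent_ttest,
    johnson_neyman,
    johnson_neyman_all,
    mixed_anova,
    paired_ttest,
    significance_marker,
)


# --------------------------------------------------------------------------
# elementary tests
# --------------------------------------------------------------------------


class TestElementaryTests:
    def test_paired_identical_samples(self):
        res = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.statistic, res.p) == (0.0, 1.0)
        assert res.df == 2

    def test_paired_constant_nonzero_difference_errors(self):
        with pytest.raises(ValueError, match="constant"):
            paired_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_independent_matches_pooled_formula(self):
        x, y = np.array([0.0, 1.0, 2.0]), np.array([1.0, 2.0, 3.0])
        res = independent_ttest(x, y)
        sp2 = ((x.var(ddof=1) * 2) + (y.var(ddof=1) * 2)) / 4
        expected_t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert res.statistic == pytest.approx(expected_t)
        assert res.df == 4

    def test_independent_zero_variance_both_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            independent_ttest([1.0, 1.0], [2.0, 2.0])

    def test_chi_square_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            chi_square([[3, -1], [2, 2]])

    def test_chi_square_matches_scipy(self):
        table = [[20, 30], [35, 15]]
        res = chi_square(table)
        chi2, p, dof, _ = stats.chi2_contingency(np.array(table), correction=False)
        assert res.statistic == pytest.approx(chi2)
        assert res.p == pytest.approx(p)

    def test_significance_markers(self):
        assert significance_marker(0.04) == "*"
        assert significance_marker(0.004) == "**"
        assert significance_marker(0.0004) == "***"
        assert significance_marker(0.2) == ""


# --------------------------------------------------------------------------
# mixed ANOVA
# --------------------------------------------------------------------------


def _long_table(values, sites):
    """values: (n_subjects, n_options); sites: per-subject labels."""
    rows = []
    for s in range(values.shape[0]):
        for j in range(values.shape[1]):
            rows.append({"subject_id": f"s{s}", "site": sites[s],
                         "option": f"o{j}", "value": values[s, j]})
    return pd.DataFrame(rows)


def _nested_ols_oracle(values, sites):
    """Mixed-ANOVA F statistics from nested least-squares model comparisons."""
    n, p = values.shape
    y = values.ravel()
    subj = np.repeat(np.arange(n), p)
    opt = np.tile(np.arange(p), n)
    site = np.repeat([{"A": 0, "B": 1}[s] for s in sites], p)

    # sum-to-zero contrasts keep option and interaction orthogonal in the
    # balanced design, as the classical decomposition assumes
    contrasts = np.vstack([np.eye(p - 1), -np.ones((1, p - 1))])

    def design(cols):
        mats = [np.eye(n)[subj]]  # subject dummies absorb site
        if "option" in cols:
            mats.append(contrasts[opt])
        if "interaction" in cols:
            s_pm = np.where(site == 1, 1.0, -1.0)[:, None]
            mats.append(contrasts[opt] * s_pm)
        return np.hstack(mats)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_full = rss(design(["option", "interaction"]))
    df_resid = n * p - (n + (p - 1) + (p - 1))
    ms_resid = rss_full / df_resid
    F_opt = ((rss(design(["interaction"])) - rss_full) / (p - 1)) / ms_resid
    F_int = ((rss(design(["option"])) - rss_full) / (p - 1)) / ms_resid

    # between-subject effect: one-way ANOVA of subject means on site
    m = values.mean(axis=1)
    groups = [m[np.array(sites) == g] for g in ("A", "B")]
    F_site = stats.f_oneway(*groups).statistic
    return F_site, F_opt, F_int, df_resid


class TestMixedAnova:
    def test_all_equal_observations_flagged(self):
        table = _long_table(np.ones((6, 3)), ["A"] * 3 + ["B"] * 3)
        res = mixed_anova(table)
        assert "all_observations_equal" in res.flags
        assert res.ss["total"] == 0

    def test_pure_additivity_gives_zero_interaction(self):
        sites = ["A"] * 4 + ["B"] * 4
        site_eff = np.array([0.0] * 4 + [2.0] * 4)[:, None]
        opt_eff = np.array([0.0, 1.0, 3.0])[None, :]
        values = 5.0 + site_eff + opt_eff
        res = mixed_anova(_long_table(values, sites))
        assert res.ss["interaction"] == pytest.approx(0.0, abs=1e-12)
        assert res.ss["residual"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_nested_ols_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            values = rng.standard_normal((16, 3)) + rng.standard_normal((16, 1))
            sites = ["A"] * 8 + ["B"] * 8
            res = mixed_anova(_long_table(values, sites))
            F_site, F_opt, F_int, df_resid = _nested_ols_oracle(values, sites)
            assert res.between_F == pytest.approx(F_site, rel=1e-8)
            assert res.within_F == pytest.approx(F_opt, rel=1e-8)
            assert res.interaction_F == pytest.approx(F_int, rel=1e-8)
            assert res.df["residual"] == df_resid

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        values = rng.standard_normal((12, 3)) + 2 * rng.standard_normal((12, 1))
        sites = ["A"] * 6 + ["B"] * 6
        table = _long_table(values, sites)
        res = mixed_anova(table)
        pg = pingouin.mixed_anova(table, dv="value", within="option",
                                  between="site", subject="subject_id")
        assert res.between_F == pytest.approx(
            float(pg.loc[pg.Source == "site", "F"].iloc[0]), rel=1e-6)
        assert res.within_F == pytest.approx(
            float(pg.loc[pg.Source == "option", "F"].iloc[0]), rel=1e-6)
        assert res.interaction_F == pytest.approx(
            float(pg.loc[pg.Source == "Interaction", "F"].iloc[0]), rel=1e-6)

    def test_ss_conservation_balanced_and_unbalanced(self):
        rng = np.random.default_rng(11)
        for sites in (["A"] * 8 + ["B"] * 8, ["A"] * 9 + ["B"] * 7):
            values = rng.standard_normal((16, 4))
            res = mixed_anova(_long_table(values, sites))
            parts = sum(res.ss[k] for k in
                        ("site", "subjects", "option", "interaction", "residual"))
            assert parts == pytest.approx(res.ss["total"], rel=1e-8)

    def test_incomplete_subject_listed(self):
        table = _long_table(np.random.default_rng(0).standard_normal((6, 2)),
                            ["A"] * 3 + ["B"] * 3)
        table = table.drop(table[(table.subject_id == "s2")
                                 & (table.option == "o1")].index)
        with pytest.raises(ValueError, match="s2"):
            mixed_anova(table)


# --------------------------------------------------------------------------
# one-way ANOVA with post-hocs
# --------------------------------------------------------------------------


class TestOneWayAnova:
    def test_identical_groups_give_null_result(self):
        values = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        groups = np.repeat(["a", "b", "c"], 4)
        res = anova_oneway_posthoc(values, groups)
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.normal(0, 1, 10), rng.normal(1, 1, 10)])
        groups = np.repeat(["a", "b"], 10)
        res = anova_oneway_posthoc(values, groups)
        t = independent_ttest(values[:10], values[10:])
        assert res.F == pytest.approx(t.statistic ** 2, rel=1e-10)

    def test_large_shift_flagged_in_posthoc(self):
        rng = np.random.default_rng(4)
        values = np.concatenate([rng.normal(0, 1, 12), rng.normal(0, 1, 12),
                                 rng.normal(10, 1, 12)])
        groups = np.repeat(["a", "b", "c"], 12)
        res = anova_oneway_posthoc(values, groups)
        row = res.posthoc[(res.posthoc.a == "a") & (res.posthoc.b == "c")]
        assert float(row.p_bonferroni.iloc[0]) < 0.001
        assert row.marker.iloc[0] == "***"

    def test_repeated_measures_two_conditions_f_equals_paired_t_squared(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 2, 10)
        values = np.concatenate([base, base + rng.normal(0.5, 1, 10)])
        groups = np.repeat(["a", "b"], 10)
        subjects = np.tile([f"s{i}" for i in range(10)], 2)
        res = anova_oneway_posthoc(values, groups, paired_posthoc=True,
                                   subjects=subjects)
        t = paired_ttest(values[:10], values[10:])
        assert res.F == pytest.approx(t.statistic ** 2, rel=1e-10)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway_posthoc([1.0, 2.0, 3.0], ["a", "a", "b"])


# --------------------------------------------------------------------------
# ANCOVA
# --------------------------------------------------------------------------


def _simulate_two_sites(rng, n=200, slope=0.05, offsets=(0.0, 0.0),
                        slopes_delta=0.0, noise=0.3):
    age = np.concatenate([rng.uniform(50, 85, n), rng.uniform(50, 85, n)])
    site = np.array(["S1"] * n + ["S2"] * n)
    y = 1.0 + slope * (age - 65)
    y += np.where(site == "S2", offsets[1] - offsets[0]
                  + slopes_delta * (age - 65), 0.0)
    y += rng.normal(0, noise, 2 * n)
    return y, age, site


class TestAncova:
    def test_matches_statsmodels_wald_tests(self):
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(8)
        y, age, site = _simulate_two_sites(rng, n=80, offsets=(0, 0.4),
                                           slopes_delta=0.02)
        res = ancova_wmh_age(y, age, site)
        df = pd.DataFrame({"y": y, "age_c": age - age.mean(), "site": site})
        fit = smf.ols("y ~ C(site) * age_c", data=df).fit()
        sm_slope = fit.f_test("C(site)[T.S2]:age_c = 0")
        sm_int = fit.f_test("C(site)[T.S2] = 0")
        assert res.slope_F == pytest.approx(float(sm_slope.fvalue), rel=1e-8)
        assert res.slope_p == pytest.approx(float(sm_slope.pvalue), rel=1e-8)
        assert res.intercept_F == pytest.approx(float(sm_int.fvalue), rel=1e-8)
        assert res.intercept_p == pytest.approx(float(sm_int.pvalue), rel=1e-8)

    def test_two_site_slope_f_is_t_squared(self):
        rng = np.random.default_rng(9)
        y, age, site = _simulate_two_sites(rng, n=60)
        res = ancova_wmh_age(y, age, site)
        j = res.param_names.index("site[S2]:age_c")
        t = res.params[j] / np.sqrt(res.cov[j, j])
        assert res.slope_F == pytest.approx(t ** 2, rel=1e-10)

    def test_type_i_error_rate_under_equal_slopes(self):
        """Slope test rejects at about the nominal 5% under the null."""
        rng = np.random.default_rng(10)
        rejections = 0
        for _ in range(100)               :
            y, age, site = _simulate_two_sites(rng, n=150)
            if ancova_wmh_age(y, age, site).slope_p < 0.05:
                rejections += 1
        assert 2 <= rejections <= 8

    def test_power_for_intercept_shift(self):
        """A pure intercept shift is seen by the intercept test, not the
        slope test."""
        rng = np.random.default_rng(12)
        slope_ok = 0
        for _ in range(20):
            y, age, site = _simulate_two_sites(rng, n=200, offsets=(0.0, 1.0))
            res = ancova_wmh_age(y, age, site)
            assert res.intercept_p < 0.001
            slope_ok += res.slope_p > 0.05
        assert slope_ok >= 18

    def test_too_few_subjects_per_site_rejected(self):
        with pytest.raises(ValueError):
            ancova_wmh_age([1, 2, 3, 4], [60, 61, 62, 63],
                           ["a", "a", "a", "b"])

    def test_rank_deficient_design_rejected(self):
        y = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        age = [65.0] * 6  # constant age: interaction column collinear
        site = ["a"] * 3 + ["b"] * 3
        with pytest.raises(ValueError, match="rank"):
            ancova_wmh_age(y, age, site)


# --------------------------------------------------------------------------
# Johnson–Neyman
# --------------------------------------------------------------------------


def _grid_scan(result, pair, alpha, age_range, step=0.01):
    from wmhh.harmonisation_stats import _pair_contrast
    gamma, delta, v_g, v_d, c_gd = _pair_contrast(result, pair)
    t_crit = stats.t.ppf(1 - alpha / 2, result.df_resid)
    ages = np.arange(age_range[0], age_range[1] + step / 2, step)
    u = ages - result.age_mean
    tval = (gamma + delta * u) / np.sqrt(v_g + 2 * c_gd * u + v_d * u ** 2)
    return ages, np.abs(tval) < t_crit


class TestJohnsonNeyman:
    def test_boundaries_match_grid_scan(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            y, age, site = _simulate_two_sites(
                rng, n=60, offsets=(0.0, rng.uniform(-0.5, 0.5)),
                slopes_delta=rng.uniform(-0.05, 0.05))
            res = ancova_wmh_age(y, age, site)
            region = johnson_neyman(res, 0.05, (45.0, 95.0))
            ages, ns = _grid_scan(res, ("S1", "S2"), 0.05, (45.0, 95.0))
            member = np.zeros_like(ns)
            for lo, hi in region.intervals:
                member |= (ages >= lo - 0.011) & (ages <= hi + 0.011)
            # agreement except within one grid step of a boundary
            disagree = ages[member != ns]
            for a in disagree:
                assert any(min(abs(a - lo), abs(a - hi)) <= 0.011
                           for lo, hi in region.intervals) or not region.intervals

    def test_null_model_gives_entire_range(self):
        res = _synthetic_result(gamma=0.0, delta=0.0, v_g=0.04, v_d=0.0004,
                                c_gd=0.0)
        region = johnson_neyman(res, 0.05, (50.0, 90.0))
        assert region.intervals == [[50.0, 90.0]]

    def test_constant_significant_gap_gives_empty_region(self):
        res = _synthetic_result(gamma=5.0, delta=0.0, v_g=0.01, v_d=0.0,
                                c_gd=0.0)
        region = johnson_neyman(res, 0.05, (50.0, 90.0))
        assert region.is_empty

    def test_three_site_pairs_and_intersection(self):
        rng = np.random.default_rng(15)
        age = rng.uniform(50, 85, 300)
        site = np.repeat(["S1", "S2", "S3"], 100)
        y = 1 + 0.05 * (age - 65) + rng.normal(0, 0.3, 300)
        y[site == "S3"] += 0.02 * (age[site == "S3"] - 65)
        res = ancova_wmh_age(y, age, site)
        out = johnson_neyman_all(res, 0.05, (50.0, 85.0))
        assert set(out["pairs"]) == {("S1", "S2"), ("S1", "S3"), ("S2", "S3")}
        for iv in out["intersection"]:
            for reg in out["pairs"].values():
                assert any(lo <= iv[0] and iv[1] <= hi + 1e-9
                           for lo, hi in reg.intervals)


def _synthetic_result(gamma, delta, v_g, v_d, c_gd):
    params = np.array([1.0, 0.05, gamma, delta])
    cov = np.zeros((4, 4))
    cov[2, 2], cov[3, 3] = v_g, v_d
    cov[2, 3] = cov[3, 2] = c_gd
    return AncovaResult(
        slope_F=0.0, slope_df=(1, 96), slope_p=1.0, intercept_F=0.0,
        intercept_df=(1, 96), intercept_p=1.0, params=params, cov=cov,
        param_names=["intercept", "age_c", "site[S2]", "site[S2]:age_c"],
        df_resid=96, age_mean=65.0, sites=["S1", "S2"])


# --------------------------------------------------------------------------
# Elastic-Net variance attribution
# --------------------------------------------------------------------------


def _covariate_frame(rng, n):
    return pd.DataFrame({
        "age": rng.uniform(50, 85, n),
        "bmi": rng.normal(26, 4, n),
        "sex": rng.choice(["M", "F"], n),
        "site": rng.choice(["S1", "S2"], n),
    })


class TestElasticNetVariance:
    def test_null_outcome_attributes_nothing_to_site(self):
        rng = np.random.default_rng(16)
        ok = 0
        for _ in range(20):
            X = _covariate_frame(rng, 500)
            y = rng.normal(0, 1, 500)
            dec = elastic_net_variance(X, y, seed=0)
            ok += dec.site_feature_fraction < 0.01
        assert ok >= 19

    def test_known_signal_fraction_recovered(self):
        """y = 2 z(age) + noise(1): age explains 4/5 of the variance."""
        rng = np.random.default_rng(18)
        X = _covariate_frame(rng, 2000)
        z_age = (X.age - X.age.mean()) / X.age.std(ddof=0)
        y = 2.0 * z_age + rng.normal(0, 1, 2000)
        dec = elastic_net_variance(X, y, seed=1)
        assert dec.fractions["age"] == pytest.approx(0.8, abs=0.05)
        assert dec.model_r2 == pytest.approx(0.8, abs=0.05)

    def test_huge_penalty_shrinks_everything(self):
        rng = np.random.default_rng(19)
        X = _covariate_frame(rng, 200)
        y = X.age.to_numpy() + rng.normal(0, 1, 200)
        dec = elastic_net_variance(X, y, seed=2, alphas=[1e9])
        assert all(v == 0.0 for v in dec.fractions.values())
        assert dec.model_r2 == 0.0

    def test_constant_predictor_dropped(self):
        rng = np.random.default_rng(20)
        X = _covariate_frame(rng, 100)
        X["const"] = 1.0
        dec = elastic_net_variance(X, rng.normal(0, 1, 100), seed=3)
        assert "const" in dec.dropped
        assert "const" not in dec.fractions

    def test_drop_one_attribution_available(self):
        rng = np.random.default_rng(24)
        X = _covariate_frame(rng, 300)
        z_age = (X.age - X.age.mean()) / X.age.std(ddof=0)
        y = 2.0 * z_age + rng.normal(0, 1, 300)
        dec = elastic_net_variance(X, y, seed=4, attribution="drop_one")
        assert dec.method.endswith("drop_one")
        assert max(dec.fractions, key=dec.fractions.get) == "age"

    def test_ols_companion_ranks_same_top_feature(self):
        rng = np.random.default_rng(25)
        X = _covariate_frame(rng, 400)
        z_age = (X.age - X.age.mean()) / X.age.std(ddof=0)
        y = 1.5 * z_age + rng.normal(0, 1, 400)
        dec = elastic_net_variance(X, y, seed=5)
        assert dec.ols_fractions is not None
        assert max(dec.ols_fractions, key=dec.ols_fractions.get) == "age"
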