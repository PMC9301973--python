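import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from lvshape import lvas, stats
from lvshape.stats import (
    adjusted_association,
    cox_fit,
    expand_time_varying,
    group_compare,
    mice_impute,
    percentage,
    propensity_continuous,
    univariate_screen,
    yates_chi2_2x2,
)

from conftest import survival_toy
from test_coxlib import brute_force_partial_lik


def _survival_df(seed=0, n=200, beta=0.0, base_rate=0.05):
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, 0.5, n).astype(float)
    t_ev = rng.exponential(1.0 / (base_rate * np.exp(beta * x)))
    c = np.minimum(rng.exponential(8.0, n), 16.0)
    return pd.DataFrame(
        {
            "x": x,
            "follow_up_years": np.minimum(t_ev, c),
            "event": (t_ev <= c).astype(int),
        }
    )


class TestCoxFit:
    def test_binary_covariate_matches_grid_search(self):
        df = _survival_df(seed=1, n=40, beta=0.8)
        fit = cox_fit(df, ["x"])
        X = df[["x"]].to_numpy()
        t = df["follow_up_years"].to_numpy()
        e = df["event"].to_numpy()
        opt = minimize_scalar(
            lambda b: -brute_force_partial_lik(b, X, t, e),
            bounds=(-4, 4), method="bounded", options={"xatol": 1e-10},
        )
        assert fit.coef("x") == pytest.approx(opt.x, abs=1e-4)

    def test_constant_zero_covariate_hr_one(self):
        df = _survival_df(seed=2, n=50)
        df["z"] = 0.0
        fit = cox_fit(df, ["z"])
        assert fit.hr("z") == pytest.approx(1.0)

    def test_summary_invariants(self):
        df = _survival_df(seed=3, n=120, beta=0.5)
        s = cox_fit(df, ["x"]).summary
        assert s.loc["x", "hr"] == pytest.approx(np.exp(s.loc["x", "coef"]))
        assert s.loc["x", "ci_lower"] == pytest.approx(
            np.exp(s.loc["x", "coef"] - 1.96 * s.loc["x", "se"]), rel=1e-4
        )

    def test_planted_quartile_hr_recovered(self):
        rng = np.random.default_rng(4)
        n = 500
        score = rng.normal(size=n)
        q = lvas.quartile_code(score, np.quantile(score, [0.25, 0.5, 0.75]))
        t_ev = rng.exponential(1.0 / (0.04 * 2.0**q))
        c = np.minimum(rng.exponential(10.0, n), 16.0)
        df = pd.DataFrame(
            {
                "q": q.astype(float),
                "follow_up_years": np.minimum(t_ev, c),
                "event": (t_ev <= c).astype(int),
            }
        )
        assert cox_fit(df, ["q"]).hr("q") == pytest.approx(2.0, rel=0.2)


class TestTimeVarying:
    def _df(self, seed=5, n=150):
        rng = np.random.default_rng(seed + 10_000)  # devices: own stream
        df = _survival_df(seed=seed, n=n, beta=0.4)
        icd = np.where(
            rng.random(n) < 0.5,
            rng.uniform(0.05, 0.95, n) * df["follow_up_years"],
            np.nan,
        )
        df["icd_time_years"] = icd
        return df

    def test_follow_up_conserved(self):
        df = self._df()
        ep = expand_time_varying(df, [("icd", "icd_time_years")])
        per = ep.groupby("patient").apply(
            lambda g: (g["stop"] - g["start"]).sum(), include_groups=False
        )
        assert np.allclose(per.to_numpy(), df["follow_up_years"].to_numpy())

    def test_indicator_switches_and_absorbs(self):
        df = self._df()
        ep = expand_time_varying(df, [("icd", "icd_time_years")])
        for pid, g in ep.groupby("patient"):
            assert np.all(np.diff(g["icd"].to_numpy()) >= 0)  # absorbing

    def test_event_lands_on_last_episode(self):
        df = self._df()
        ep = expand_time_varying(df, [("icd", "icd_time_years")])
        total = ep.groupby("patient")["episode_event"].sum()
        assert np.array_equal(
            total.to_numpy(), df["event"].to_numpy()
        )

    def test_matches_lifelines_time_varying(self):
        from lifelines import CoxTimeVaryingFitter

        df = self._df(seed=16)
        fit = cox_fit(df, ["x"], time_varying=[("icd", "icd_time_years")])
        assert not fit.flagged
        ep = expand_time_varying(df, [("icd", "icd_time_years")])
        ctv = CoxTimeVaryingFitter().fit(
            ep[["patient", "start", "stop", "episode_event", "x", "icd"]],
            id_col="patient", start_col="start", stop_col="stop",
            event_col="episode_event",
        )
        assert np.allclose(
            fit.summary["coef"].to_numpy(), ctv.params_.to_numpy(), atol=1e-6
        )


class TestUnivariateScreen:
    def _cohort(self, seed=7, n=300):
        rng = np.random.default_rng(seed)
        df = _survival_df(seed=seed, n=n, beta=0.8)
        df = df.rename(columns={"x": "risk_var"})
        df["age"] = rng.normal(60, 10, n)
        df["sex"] = rng.binomial(1, 0.8, n)
        df["noise"] = rng.normal(size=n)
        df["with_missing"] = rng.normal(size=n)
        df.loc[0, "with_missing"] = np.nan
        return df

    def test_missing_excluded_regardless_of_p(self):
        df = self._cohort()
        sel = univariate_screen(df, ["risk_var", "noise", "with_missing"])
        assert "with_missing" not in sel

    def test_age_sex_forced(self):
        df = self._cohort()
        sel = univariate_screen(df, ["noise"])
        assert "age" in sel and "sex" in sel

    def test_strong_predictor_kept(self):
        df = self._cohort()
        sel = univariate_screen(df, ["risk_var", "noise"])
        assert "risk_var" in sel

    def test_null_variable_mostly_excluded(self):
        kept = 0
        for s in range(20):
            rng = np.random.default_rng(800 + s)
            df = _survival_df(seed=900 + s, n=500)
            df["pure_noise"] = rng.normal(size=500)
            sel = univariate_screen(df, ["pure_noise"], forced=())
            kept += "pure_noise" in sel
        assert kept <= 6  # null pass rate ~25%; >=70% excluded

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            univariate_screen(self._cohort(), ["noise"], p_threshold=1.5)


class TestPropensity:
    def test_independent_covariates_weights_near_one(self):
        rng = np.random.default_rng(300)
        n = 1000
        cov = pd.DataFrame(
            {"a": rng.normal(size=n), "b": rng.binomial(1, 0.5, n).astype(float)}
        )
        e = rng.normal(size=n)
        pr = propensity_continuous(e, cov)
        assert pr.weights.std() / pr.weights.mean() < 0.15

    def test_confounded_balance_restored(self):
        rng = np.random.default_rng(201)
        n = 2000
        conf = rng.uniform(-1.7, 1.7, n)
        e = 0.35 * conf + 0.8 * rng.normal(size=n)
        cov = pd.DataFrame({"conf": conf, "other": rng.normal(size=n)})
        pr = propensity_continuous(e, cov)
        assert abs(pr.balance.loc["conf", "unweighted_r"]) > 0.3
        assert abs(pr.balance.loc["conf", "weighted_r"]) < 0.05

    def test_balance_always_shrinks(self):
        # weighting reduces the exposure-confounder correlation in every
        # seeded confounded scenario
        for s in range(5):
            rng = np.random.default_rng(210 + s)
            n = 800
            conf = rng.uniform(-1.7, 1.7, n)
            e = 0.4 * conf + 0.8 * rng.normal(size=n)
            cov = pd.DataFrame({"conf": conf})
            pr = propensity_continuous(e, cov)
            assert abs(pr.balance.loc["conf", "weighted_r"]) < abs(
                pr.balance.loc["conf", "unweighted_r"]
            )

    def test_truncation_bounds_honoured(self):
        rng = np.random.default_rng(220)
        n = 600
        conf = rng.normal(size=n)
        e = 0.5 * conf + rng.normal(size=n)
        pr = propensity_continuous(e, pd.DataFrame({"conf": conf}))
        assert pr.weights.max() == pytest.approx(
            np.quantile(
                pr.weights, 0.99, method="linear"
            ),
            rel=0.05,
        )
        assert np.all(pr.weights > 0)

    def test_deterministic_exposure_rejected(self):
        # exposure a pure function of a binary covariate: the tree
        # ensemble fits it (out of fold) to numerical precision
        rng = np.random.default_rng(230)
        b = rng.binomial(1, 0.5, 400).astype(float)
        with pytest.raises(ValueError, match="determined"):
            propensity_continuous(2.0 * b, pd.DataFrame({"b": b}))

    def test_incomplete_covariates_rejected(self):
        cov = pd.DataFrame({"a": [1.0, np.nan, 3.0]})
        with pytest.raises(ValueError, match="complete"):
            propensity_continuous(np.ones(3), cov)


class TestAdjustedAssociation:
    def test_unit_weights_match_unweighted(self):
        df = _survival_df(seed=8, n=200, beta=0.6)
        fit_w = adjusted_association(df, df["x"].to_numpy(),
                                     weights=np.ones(len(df)))["ipw"]
        fit_u = adjusted_association(df, df["x"].to_numpy())["unadjusted"]
        assert fit_w.coef("lvas_quartile") == pytest.approx(
            fit_u.coef("lvas_quartile"), abs=1e-9
        )

    def test_nonpositive_weights_rejected(self):
        df = _survival_df(seed=8, n=50)
        with pytest.raises(ValueError, match="positive"):
            adjusted_association(df, df["x"].to_numpy(), weights=np.zeros(50))

    @staticmethod
    def _confounded_null(seed, n=600):
        rng = np.random.default_rng(seed)
        conf = rng.uniform(-1.7, 1.7, n)
        exposure = 0.5 * conf + 0.8 * rng.normal(size=n)
        t_ev = rng.exponential(1.0 / (0.05 * np.exp(0.8 * conf)))
        c = np.minimum(rng.exponential(8.0, n), 16.0)
        df = pd.DataFrame(
            {
                "conf": conf,
                "follow_up_years": np.minimum(t_ev, c),
                "event": (t_ev <= c).astype(int),
            }
        )
        return df, exposure

    def test_ipw_restores_null(self):
        # exposure affects nothing; the confounder drives both exposure
        # and hazard: unadjusted is biased, IPW covers the null
        covered = 0
        biased = 0
        for s in range(10):
            df, exposure = self._confounded_null(500 + s)
            pr = propensity_continuous(exposure, df[["conf"]])
            fits = adjusted_association(df, exposure, weights=pr.weights)
            un = adjusted_association(df, exposure)["unadjusted"]
            lo = fits["ipw"].summary.loc["lvas_quartile", "ci_lower"]
            hi = fits["ipw"].summary.loc["lvas_quartile", "ci_upper"]
            covered += lo <= 1.0 <= hi
            biased += un.summary.loc["lvas_quartile", "ci_lower"] > 1.0
        assert covered >= 8
        assert biased >= 8

    def test_ipw_closer_to_truth_with_real_effect(self):
        closer = 0
        true_log_hr = 0.5
        for s in range(10):
            rng = np.random.default_rng(600 + s)
            n = 600
            conf = rng.uniform(-1.7, 1.7, n)
            exposure = 0.5 * conf + 0.8 * rng.normal(size=n)
            eta = true_log_hr * exposure + 0.8 * conf
            t_ev = rng.exponential(1.0 / (0.05 * np.exp(eta)))
            c = np.minimum(rng.exponential(8.0, n), 16.0)
            df = pd.DataFrame(
                {
                    "conf": conf,
                    "follow_up_years": np.minimum(t_ev, c),
                    "event": (t_ev <= c).astype(int),
                }
            )
            pr = propensity_continuous(exposure, df[["conf"]])
            ipw = adjusted_association(df, exposure, weights=pr.weights)["ipw"]
            un = adjusted_association(df, exposure)["unadjusted"]
            err_ipw = abs(ipw.coef("lvas_quartile") - true_log_hr)
            err_un = abs(un.coef("lvas_quartile") - true_log_hr)
            closer += err_ipw < err_un
        assert closer >= 8

    def test_covariate_adjustment_route(self):
        df, exposure = self._confounded_null(42)
        pr = propensity_continuous(exposure, df[["conf"]])
        ps = pr.model.predict(df[["conf"]].to_numpy())
        fits = adjusted_association(df, exposure, propensity_score=ps)
        assert "covariate_adjusted" in fits


class TestMice:
    def _df(self, seed=9, n=400, missing=True):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "b": rng.binomial(1, 0.4, n).astype(float),
                "follow_up_years": rng.exponential(5, n) + 0.1,
                "event": rng.binomial(1, 0.3, n),
            }
        )
        df["z"] = 0.6 * df["x"] + rng.normal(size=n)
        if missing:
            mask = rng.random(n) < 0.15
            df.loc[mask, "z"] = np.nan
        return df

    def test_complete_data_identity(self):
        df = self._df(missing=False)
        completed, pooled = mice_impute(df, m=3, n_cycles=2, seed=0,
                                        cox_covariates=["x"])
        for c in completed:
            pd.testing.assert_frame_equal(c, df)
        single = cox_fit(df, ["x"])
        assert pooled.loc["x", "coef"] == pytest.approx(single.coef("x"))

    def test_mcar_mean_recovered(self):
        rng = np.random.default_rng(10)
        df = self._df(seed=10, n=500)
        true = self._df(seed=10, n=500, missing=False)
        completed, _ = mice_impute(df, m=5, n_cycles=5, seed=1)
        sd = true["z"].std()
        for c in completed:
            assert abs(c["z"].mean() - true["z"].mean()) < 0.5 * sd

    def test_rubin_variance_inequality(self):
        df = self._df(seed=11)
        completed, pooled = mice_impute(df, m=5, n_cycles=5, seed=2,
                                        cox_covariates=["x", "z"])
        fits = [cox_fit(c, ["x", "z"]) for c in completed]
        within = np.mean([f.summary["se"].to_numpy() ** 2 for f in fits], axis=0)
        assert np.all(pooled["se"].to_numpy() ** 2 >= within - 1e-12)

    def test_binary_column_stays_binary(self):
        df = self._df(seed=12)
        rng = np.random.default_rng(12)
        df.loc[rng.random(len(df)) < 0.1, "b"] = np.nan
        completed, _ = mice_impute(df, m=2, n_cycles=3, seed=3)
        for c in completed:
            assert set(np.unique(c["b"])) <= {0.0, 1.0}

    def test_m_validated(self):
        with pytest.raises(ValueError):
            mice_impute(self._df(), m=1)

    def test_fully_missing_column_rejected(self):
        df = self._df()
        df["z"] = np.nan
        with pytest.raises(ValueError, match="fully missing"):
            mice_impute(df, m=2)


class TestGroupCompare:
    def test_identical_distributions_p_near_one(self):
        half = pd.DataFrame({"v": np.arange(30.0), "c": [0, 1] * 15})
        df = pd.concat(
            [half.assign(g=0), half.assign(g=1)], ignore_index=True
        )
        table = group_compare(df, "g")
        assert table.loc["v", "p"] > 0.9
        assert table.loc["c", "p"] > 0.9

    def test_sex_table_from_printed_counts(self):
        # male/female x event/no-event counts as printed in the cohort
        # table reproduce the ~0.99 chi-square p-value with Yates
        stat, p = yates_chi2_2x2([[107, 21], [24, 4]])
        assert abs(p - 0.99) <= 0.015

    def test_u_statistic_matches_pairwise_count(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=6)
        b = rng.normal(size=6) + 0.5
        df = pd.DataFrame(
            {"v": np.concatenate([a, b]), "g": [0] * 6 + [1] * 6}
        )
        table = group_compare(df, "g")
        brute = sum(
            1.0 if x < y else (0.5 if x == y else 0.0) for x in a for y in b
        )
        u_for_g0 = 36 - brute  # U reported for the first group
        assert table.loc["v", "statistic"] in (brute, u_for_g0)

    def test_group_count_validated(self):
        df = pd.DataFrame({"v": [1.0, 2.0], "g": [0, 0]})
        with pytest.raises(ValueError, match="2 groups"):
            group_compare(df, "g")

    def test_uses_all_available_data(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame(
            {"v": rng.normal(size=50), "g": rng.binomial(1, 0.5, 50)}
        )
        df.loc[:4, "v"] = np.nan
        table = group_compare(df, "g")
        assert np.isfinite(table.loc["v", "p"])


class TestPercentage:
    def test_rounding(self):
        assert percentage(128, 156) == 82.1
        assert percentage(81, 156) == 51.9
        assert percentage(45, 156) == 28.8

    def test_total_validated(self):
        with pytest.raises(ValueError):
            percentage(1, 0)
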