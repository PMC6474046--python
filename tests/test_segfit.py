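"""Segmented-fit correctness: exact recovery, independent oracles, invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import expit

from rosterits.config import FitOptions
from rosterits.segfit import (
    SegmentedFit,
    adopter_class_effects,
    build_design,
    derive_effects,
    fit_adopter_interaction,
    fit_segmented_linear,
    fit_segmented_logistic,
    linearity_check,
    predict_trajectory,
)

TRUE = dict(intercept=60.0, time=-0.3, post=0.5, tst=-0.8)


def make_records(n_phys=6, per_year=30, noise=0.0, re_sd=0.0, seed=0,
                 early_offset=0.0, years=range(2000, 2014)):
    """Patient-year-like records generated directly from the linear model."""
    rng = np.random.default_rng(seed)
    transition = rng.choice([2004, 2005, 2006, 2008], n_phys)
    re = rng.normal(0, re_sd, n_phys)
    rows = []
    for j in range(n_phys):
        for year in years:
            t = float(year - 2000)
            post = 1.0 if year > transition[j] else 0.0
            tst = (year - transition[j]) * post
            early = 1.0 if transition[j] <= 2006 else 0.0
            mu = (TRUE["intercept"] + TRUE["time"] * t + TRUE["post"] * post
                  + TRUE["tst"] * tst + early_offset * early + re[j])
            y = mu + rng.normal(0, noise, per_year)
            rows.append(pd.DataFrame({
                "upc": y, "time": t, "post": post, "tst": tst,
                "fiscal_year": year, "transition_year": transition[j],
                "early_adopter": early, "physician_id": j,
            }))
    return pd.concat(rows, ignore_index=True)


class TestLinearFit:
    def test_noiseless_data_recovered_exactly(self):
        records = make_records(noise=0.0)
        design = build_design(records, "upc", covariates="none")
        fit = fit_segmented_linear(design, FitOptions(re_terms=()))
        assert fit.estimate("intercept") == pytest.approx(TRUE["intercept"],
                                                          abs=1e-8)
        assert fit.estimate("time") == pytest.approx(TRUE["time"], abs=1e-8)
        assert fit.estimate("post") == pytest.approx(TRUE["post"], abs=1e-8)
        assert fit.estimate("tst") == pytest.approx(TRUE["tst"], abs=1e-8)

    def test_ols_rung_matches_lstsq_oracle(self):
        records = make_records(noise=3.0, seed=1)
        design = build_design(records, "upc", covariates="none")
        fit = fit_segmented_linear(design, FitOptions(re_terms=()))
        X = np.column_stack([
            np.ones(len(design.frame)),
            design.frame[["time", "post", "tst"]].to_numpy(),
        ])
        beta = np.linalg.lstsq(X, design.frame["y"].to_numpy(), rcond=None)[0]
        got = [fit.estimate(t) for t in ("intercept", "time", "post", "tst")]
        np.testing.assert_allclose(got, beta, atol=1e-9)

    def test_random_intercept_fit_matches_reml_oracle(self):
        # brute-force REML for y = Xb + u_j + e on a 3-physician instance
        records = make_records(n_phys=3, per_year=5, noise=2.0, re_sd=3.0,
                               seed=2, years=range(2000, 2010))
        design = build_design(records, "upc", covariates="none")
        fit = fit_segmented_linear(design, FitOptions(re_terms=("intercept",)))

        frame = design.frame
        X = np.column_stack([np.ones(len(frame)),
                             frame[["time", "post", "tst"]].to_numpy()])
        y = frame["y"].to_numpy()
        groups = frame["physician_id"].to_numpy()

        def reml_neg(params):
            s2, t2 = np.exp(params)
            V_chunks, logdet = [], 0.0
            XtVX = np.zeros((4, 4))
            XtVy = np.zeros(4)
            for g in np.unique(groups):
                idx = groups == g
                n = idx.sum()
                V = s2 * np.eye(n) + t2 * np.ones((n, n))
                Vi = np.linalg.inv(V)
                sign, ld = np.linalg.slogdet(V)
                logdet += ld
                XtVX += X[idx].T @ Vi @ X[idx]
                XtVy += X[idx].T @ Vi @ y[idx]
            beta = np.linalg.solve(XtVX, XtVy)
            resid_term = 0.0
            for g in np.unique(groups):
                idx = groups == g
                n = idx.sum()
                V = s2 * np.eye(n) + t2 * np.ones((n, n))
                r = y[idx] - X[idx] @ beta
                resid_term += r @ np.linalg.solve(V, r)
            _, ld2 = np.linalg.slogdet(XtVX)
            return 0.5 * (logdet + resid_term + ld2)

        res = optimize.minimize(reml_neg, np.log([4.0, 9.0]),
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        s2, t2 = np.exp(res.x)
        XtVX = np.zeros((4, 4))
        XtVy = np.zeros(4)
        for g in np.unique(groups):
            idx = groups == g
            n = idx.sum()
            Vi = np.linalg.inv(s2 * np.eye(n) + t2 * np.ones((n, n)))
            XtVX += X[idx].T @ Vi @ X[idx]
            XtVy += X[idx].T @ Vi @ y[idx]
        beta_oracle = np.linalg.solve(XtVX, XtVy)

        got = [fit.estimate(t) for t in ("intercept", "time", "post", "tst")]
        np.testing.assert_allclose(got, beta_oracle, atol=1e-4)

    def test_time_origin_shift_changes_only_intercept(self):
        records = make_records(noise=2.0, re_sd=1.5, seed=3)
        fit0 = fit_segmented_linear(
            build_design(records, "upc", covariates="none"),
            FitOptions(re_terms=("intercept",)))
        shifted = records.assign(time=records["time"] + 5.0)
        fit1 = fit_segmented_linear(
            build_design(shifted, "upc", covariates="none"),
            FitOptions(re_terms=("intercept",)))
        for term in ("time", "post", "tst"):
            assert fit1.estimate(term) == pytest.approx(
                fit0.estimate(term), abs=1e-4)
        assert fit1.estimate("intercept") == pytest.approx(
            fit0.estimate("intercept") - 5.0 * fit0.estimate("time"), abs=1e-3)

    def test_fewer_than_two_clusters_rejected(self):
        records = make_records(n_phys=1)
        design = build_design(records, "upc", covariates="none")
        with pytest.raises(ValueError, match="clusters"):
            fit_segmented_linear(design)

    def test_constant_outcome_rejected(self):
        records = make_records(noise=0.0).assign(upc=50.0)
        with pytest.raises(ValueError, match="constant"):
            build_design(records, "upc", covariates="none")


class TestLogisticFit:
    def make_binary(self, n_phys=30, per_year=40, re_sd=0.0, seed=4):
        rng = np.random.default_rng(seed)
        records = make_records(n_phys=n_phys, per_year=per_year, seed=seed)
        eta = (-2.5 + 0.05 * records["time"] - 0.05 * records["post"]
               - 0.04 * records["tst"])
        if re_sd:
            re = rng.normal(0, re_sd, n_phys)
            eta = eta + re[records["physician_id"].to_numpy()]
        records["fpsc"] = rng.binomial(1, expit(eta))
        return records

    def test_glm_route_matches_hand_coded_likelihood(self):
        records = self.make_binary()
        design = build_design(records, "fpsc", scale="logit",
                              covariates="none")
        fit = fit_segmented_logistic(design, FitOptions(re_terms=()))
        X = np.column_stack([np.ones(len(design.frame)),
                             design.frame[["time", "post", "tst"]].to_numpy()])
        y = design.frame["y"].to_numpy()

        def nll(b):
            eta = X @ b
            return float(np.sum(np.logaddexp(0, eta) - y * eta))

        res = optimize.minimize(nll, np.zeros(4), method="BFGS")
        got = [fit.estimate(t) for t in ("intercept", "time", "post", "tst")]
        np.testing.assert_allclose(got, res.x, atol=2e-4)

    def test_mixed_fit_recovers_planted_slopes(self):
        records = self.make_binary(n_phys=40, per_year=120, re_sd=0.3, seed=5)
        design = build_design(records, "fpsc", scale="logit",
                              covariates="none")
        fit = fit_segmented_logistic(design)
        assert fit.re_terms == ("intercept",)
        assert fit.estimate("time") == pytest.approx(0.05, abs=0.04)
        assert fit.estimate("tst") == pytest.approx(-0.04, abs=0.04)
        assert fit.re_var["intercept"] > 0

    def test_no_events_is_descriptive_failure(self):
        records = self.make_binary().assign(fpsc=0)
        with pytest.raises(ValueError, match="constant"):
            build_design(records, "fpsc", scale="logit", covariates="none")

    def test_separation_is_flagged(self):
        records = self.make_binary()
        records["fpsc"] = (records["time"] > 6).astype(float)
        design = build_design(records, "fpsc", scale="logit",
                              covariates="none")
        fit = fit_segmented_logistic(design, FitOptions(re_terms=()))
        assert not fit.converged
        assert any("separation" in n for n in fit.notes)


class TestAdopterInteraction:
    def test_planted_baseline_offset_recovered(self):
        records = make_records(noise=1.0, seed=6, early_offset=7.02)
        design = build_design(records, "upc", covariates="none",
                              adopter_interaction=True)
        fit = fit_adopter_interaction(design, FitOptions(re_terms=()))
        assert fit.estimate("early_adopter") == pytest.approx(7.02, abs=0.3)
        for term in ("early_time", "early_post", "early_tst"):
            assert fit.estimate(term) == pytest.approx(0.0, abs=0.2)

    def test_class_effects_match_per_class_refits(self):
        records = make_records(noise=1.0, seed=7, early_offset=4.0)
        design = build_design(records, "upc", covariates="none",
                              adopter_interaction=True)
        fit = fit_adopter_interaction(design, FitOptions(re_terms=()))
        derived = adopter_class_effects(fit).set_index(
            ["adopter_class", "term"])
        for cls, flag in (("early", 1.0), ("late", 0.0)):
            subset = records[records["early_adopter"] == flag]
            sub_fit = fit_segmented_linear(
                build_design(subset, "upc", covariates="none"),
                FitOptions(re_terms=()))
            for term in ("time", "post", "tst"):
                assert derived.loc[(cls, term), "estimate"] == pytest.approx(
                    sub_fit.estimate(term), abs=1e-6)

    def test_single_class_rejected(self):
        records = make_records(seed=8)
        records["early_adopter"] = 1.0
        with pytest.raises(ValueError, match="early and late"):
            build_design(records, "upc", covariates="none",
                         adopter_interaction=True)


def stub_fit(estimates: dict, scale="linear") -> SegmentedFit:
    names = list(estimates)
    params = pd.DataFrame({
        "estimate": list(estimates.values()),
        "se": 0.05, "ci_low": np.nan, "ci_high": np.nan, "pvalue": np.nan,
    }, index=pd.Index(names, name="term"))
    cov = pd.DataFrame(np.eye(len(names)) * 0.05**2,
                       index=names, columns=names)
    return SegmentedFit(outcome="upc", scale=scale, params=params,
                        cov_params=cov, re_var={}, re_terms=(),
                        converged=True, n_obs=100, n_clusters=10,
                        method="stub")


class TestDerivedEffects:
    def test_ten_year_cumulative_change(self):
        fit = stub_fit({"intercept": 57.2, "time": -0.27, "post": 0.39,
                        "tst": -0.59})
        out = derive_effects(fit, horizon_years=10).set_index("quantity")
        assert out.loc["post_slope_per_year", "estimate"] \
            == pytest.approx(-0.86)
        assert out.loc["cumulative_10yr_post_change", "estimate"] \
            == pytest.approx(-8.6)

    def test_log_odds_fit_reports_per_year_odds_ratios(self):
        fit = stub_fit({"intercept": -3.28, "time": 0.018, "post": -0.010,
                        "tst": -0.011}, scale="logit")
        out = derive_effects(fit).set_index("quantity")
        assert out.loc["or_pre_per_year", "estimate"] \
            == pytest.approx(np.exp(0.018))
        assert out.loc["or_post_per_year", "estimate"] \
            == pytest.approx(np.exp(0.007))

    def test_zero_slope_change_means_parallel_segments(self):
        fit = stub_fit({"intercept": 60.0, "time": -0.2, "post": 1.0,
                        "tst": 0.0})
        out = derive_effects(fit).set_index("quantity")
        assert out.loc["post_slope_per_year", "estimate"] \
            == out.loc["pre_slope_per_year", "estimate"]

    def test_nonconverged_fit_rejected(self):
        fit = stub_fit({"intercept": 1.0, "time": 0.0, "post": 0.0,
                        "tst": 0.0})
        fit.converged = False
        with pytest.raises(ValueError, match="non-converged"):
            derive_effects(fit)


class TestTrajectories:
    def test_zero_level_change_gives_continuous_trajectory(self):
        fit = stub_fit({"intercept": 60.0, "time": -0.3, "post": 0.0,
                        "tst": -0.5})
        tr = predict_trajectory(fit, {}, np.arange(0, 14), 6.0)
        jumps = np.diff(tr["prediction"])
        # slope changes but no discontinuity beyond the slope change
        assert jumps.max() < 0
        assert jumps.min() >= -0.8 - 1e-9

    def test_negative_slopes_give_decreasing_trajectory(self):
        fit = stub_fit({"intercept": 60.0, "time": -0.3, "post": -0.2,
                        "tst": -0.5})
        tr = predict_trajectory(fit, {}, np.arange(0, 14), 6.0)
        assert (np.diff(tr["prediction"]) < 0).all()

    def test_cumulative_change_consistent_with_trajectory(self):
        fit = stub_fit({"intercept": 60.0, "time": -0.27, "post": 0.39,
                        "tst": -0.59})
        k = 10
        tr = predict_trajectory(fit, {}, [6.0, 6.0 + k], 5.0)
        out = derive_effects(fit, horizon_years=k).set_index("quantity")
        direct = tr["prediction"].iloc[1] - tr["prediction"].iloc[0]
        assert direct == pytest.approx(
            out.loc[f"cumulative_{k}yr_post_change", "estimate"])

    def test_missing_covariate_named_in_error(self):
        fit = stub_fit({"intercept": 60.0, "time": -0.3, "post": 0.0,
                        "tst": -0.5, "female": -1.0})
        with pytest.raises(ValueError, match="female"):
            predict_trajectory(fit, {}, np.arange(5), 2.0)


class TestLinearityCheck:
    def test_perfectly_linear_means_have_unit_r_squared(self):
        records = make_records(noise=0.0)
        records["upc"] = 80.0 - 0.5 * records["time"]
        means, fits = linearity_check(records, "upc")
        overall = fits.set_index("cohort").loc["overall"]
        assert overall["r_squared"] == pytest.approx(1.0)
        assert overall["slope"] == pytest.approx(-0.5)

    def test_short_cohort_skipped(self):
        records = make_records(noise=1.0, seed=9)
        single = records[records["fiscal_year"] == 2001].assign(
            transition_year=1999)
        mixed = pd.concat([records, single], ignore_index=True)
        means, fits = linearity_check(mixed, "upc")
        assert 1999 not in set(fits["cohort"])

    def test_needs_three_years(self):
        records = make_records(years=(2000, 2001))
        with pytest.raises(ValueError, match="3"):
            linearity_check(records, "upc")
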