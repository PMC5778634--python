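"""Hurdle GLMMs: oracle equivalence, invariances, screening, stepwise."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from posuse.models import (
    SeparationError,
    build_design,
    fit_glmm,
    fit_hurdle,
    screen_covariates,
    simulate_hurdle_data,
    stepwise_procedure,
)


@pytest.fixture(scope="module")
def hurdle_df():
    rng = np.random.default_rng(31)
    return simulate_hurdle_data(
        1200, 6, {"girl": 0.5}, {"girl": 0.47}, sigma_school=0.3, rng=rng
    )


@pytest.fixture(scope="module")
def flat_df():
    """No school clustering: the single-level GLM is the truth."""
    rng = np.random.default_rng(32)
    return simulate_hurdle_data(
        1000, 6, {"girl": 0.5}, {"girl": 0.47}, sigma_school=0.0, rng=rng
    )


class TestGlmOracle:
    def test_logistic_matches_glm_with_variance_fixed_at_zero(self, flat_df):
        X, terms = build_design(flat_df, ["girl"])
        y = (flat_df["pos_min_day"] > 0).to_numpy(dtype=float)
        ours = fit_glmm(X, y, flat_df["school_id"], "binomial", terms=terms, fix_sigma=0.0)
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(ours.estimate, glm.params, atol=1e-3)

    def test_gamma_matches_glm_with_variance_fixed_at_zero(self, flat_df):
        sub = flat_df[flat_df["pos_min_day"] > 0]
        X, terms = build_design(sub, ["girl"])
        ours = fit_glmm(
            X, sub["pos_min_day"].to_numpy(), sub["school_id"], "gamma",
            terms=terms, fix_sigma=0.0,
        )
        glm = sm.GLM(
            sub["pos_min_day"], X, family=sm.families.Gamma(sm.families.links.Log())
        ).fit()
        np.testing.assert_allclose(ours.estimate, np.asarray(glm.params), atol=1e-3)


class TestInvariances:
    def test_gamma_scale_equivariance(self, hurdle_df):
        sub = hurdle_df[hurdle_df["pos_min_day"] > 0]
        X, terms = build_design(sub, ["girl"])
        y = sub["pos_min_day"].to_numpy()
        f1 = fit_glmm(X, y, sub["school_id"], "gamma", terms=terms)
        f2 = fit_glmm(X, 7.0 * y, sub["school_id"], "gamma", terms=terms)
        assert abs(f2.estimate[1] - f1.estimate[1]) < 1e-6
        assert abs(f2.estimate[0] - f1.estimate[0] - np.log(7.0)) < 1e-6

    def test_exponentiation_preserves_ordering(self, hurdle_df):
        fit = fit_hurdle(hurdle_df, "pos_min_day", ["girl", "age_c"])
        tab = fit.occurrence.table()
        order_link = np.argsort(tab["estimate"].to_numpy())
        order_exp = np.argsort(tab["exp_estimate"].to_numpy())
        np.testing.assert_array_equal(order_link, order_exp)

    def test_ci_brackets_exponentiated_estimate(self, hurdle_df):
        tab = fit_hurdle(hurdle_df, "pos_min_day", ["girl"]).table()
        assert (tab["ci_low"] <= tab["exp_estimate"]).all()
        assert (tab["exp_estimate"] <= tab["ci_high"]).all()


class TestHurdleBookkeeping:
    def test_part_sample_sizes(self, hurdle_df):
        fit = fit_hurdle(hurdle_df, "pos_min_day", ["girl"])
        n_pos = int((hurdle_df["pos_min_day"] > 0).sum())
        assert fit.occurrence.n == len(hurdle_df)
        assert fit.amount.n == n_pos
        assert fit.occurrence.n >= fit.amount.n

    def test_degenerate_all_positive_skips_occurrence(self, hurdle_df):
        sub = hurdle_df[hurdle_df["pos_min_day"] > 0]
        fit = fit_hurdle(sub, "pos_min_day", ["girl"])
        assert fit.occurrence is None
        assert fit.amount is not None
        assert "occurrence part skipped" in fit.notes[0]

    def test_joint_loglik_decomposes(self, flat_df):
        """The hurdle log likelihood is the sum of the two part
        likelihoods: density (1-pi) at zero, pi * gamma(y) above it."""
        from scipy import special

        fit = fit_hurdle(flat_df, "pos_min_day", ["girl"], fix_sigma=0.0)
        X, _ = build_design(flat_df, ["girl"])
        y = flat_df["pos_min_day"].to_numpy()
        pi = special.expit(X @ fit.occurrence.estimate)
        mu = np.exp(X @ fit.amount.estimate)
        k = fit.amount.shape
        pos = y > 0
        direct = np.sum(np.log(1 - pi[~pos]))
        direct += np.sum(np.log(pi[pos]))
        direct += np.sum(
            k * np.log(k / mu[pos])
            + (k - 1) * np.log(y[pos])
            - k * y[pos] / mu[pos]
            - special.gammaln(k)
        )
        assert direct == pytest.approx(fit.loglik, rel=1e-10)

    def test_gamma_part_rejects_zeros(self, hurdle_df):
        X, _ = build_design(hurdle_df, ["girl"])
        with pytest.raises(ValueError):
            fit_glmm(X, hurdle_df["pos_min_day"].to_numpy(), hurdle_df["school_id"], "gamma")

    def test_complete_separation_raised(self):
        rng = np.random.default_rng(2)
        n = 200
        x = rng.integers(0, 2, n).astype(float)
        df = pd.DataFrame(
            {
                "school_id": [f"S{i % 4}" for i in range(n)],
                "girl": x,
                "pos_min_day": np.where(x > 0, 30.0, 0.0),
            }
        )
        with pytest.raises(SeparationError):
            fit_hurdle(df, "pos_min_day", ["girl"])


class TestScreening:
    def test_forced_covariate_survives_any_p(self, hurdle_df):
        df = hurdle_df.copy()
        rng = np.random.default_rng(8)
        df["noise"] = rng.normal(size=len(df))
        retained = screen_covariates(
            df, "pos_min_day", candidates=["noise"], forced=["girl"]
        )
        assert "girl" in retained

    def test_strong_retained_noise_usually_dropped(self):
        """The screen keeps a strong covariate always and a pure-noise
        covariate only at roughly its false-positive rate."""
        rng = np.random.default_rng(12)
        kept_strong = kept_noise = 0
        reps = 10
        for _ in range(reps):
            df = simulate_hurdle_data(800, 6, {}, {"girl": 0.8}, sigma_school=0.1, rng=rng)
            df["noise"] = rng.normal(size=len(df))
            retained = screen_covariates(df, "pos_min_day", candidates=["girl", "noise"])
            kept_strong += "girl" in retained
            kept_noise += "noise" in retained
        assert kept_strong == reps
        assert kept_noise <= 2

    def test_empty_candidates_empty_set(self, hurdle_df):
        assert screen_covariates(hurdle_df, "pos_min_day", candidates=[], forced=[]) == []


class TestStepwise:
    def test_only_true_factor_reaches_step3(self):
        rng = np.random.default_rng(13)
        df = simulate_hurdle_data(
            1500, 6, {"girl": 0.9}, {"girl": 0.6}, sigma_school=0.1, rng=rng
        )
        report = stepwise_procedure(
            df,
            "pos_min_day",
            individual_factors=("girl", "age_c"),
            social_factors=(),
            covariates=[],
        )
        assert report.step3_factors == ["girl"]
        assert report.step3 is not None

    def test_social_factor_recovery(self):
        """A social variable with a true amount effect recovers the
        generating multiplier in step 4."""
        rng = np.random.default_rng(14)
        df = simulate_hurdle_data(2000, 6, {}, {}, sigma_school=0.1, rng=rng)
        # add a sibling-accompaniment rate that multiplies positive time
        sib = rng.poisson(0.5, len(df)).astype(float)
        pos = df["pos_min_day"] > 0
        df["visits_siblings_day"] = np.where(pos, sib, 0.0)
        df.loc[pos, "pos_min_day"] *= np.exp(0.47 * sib[pos.to_numpy()])
        report = stepwise_procedure(
            df,
            "pos_min_day",
            individual_factors=(),
            social_factors=("visits_siblings_day",),
            covariates=[],
        )
        tab = report.step4["visits_siblings_day"].amount.table().set_index("term")
        got = tab.loc["visits_siblings_day", "exp_estimate"]
        assert got == pytest.approx(np.exp(0.47), rel=0.1)

    def test_no_significant_factors_noted(self):
        rng = np.random.default_rng(15)
        df = simulate_hurdle_data(300, 6, {}, {}, sigma_school=0.1, rng=rng)
        df["visits_siblings_day"] = 0.0
        report = stepwise_procedure(
            df,
            "pos_min_day",
            individual_factors=(),
            social_factors=(),
            covariates=[],
        )
        assert report.step3 is None
        assert any("covariates only" in n for n in report.notes)
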