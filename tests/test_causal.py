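"""Propensity, trimming, weighting, MSM and matching: identities and oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holctract.causal import (
    IPWPrevalenceDifference,
    MatchedSets,
    PropensityFit,
    PropensityScoreModel,
    WeightedSample,
    compute_ipw_weights,
    covariate_balance,
    estimate_msm,
    fit_propensity,
    full_matching,
    matched_estimate,
    run_pair_analysis,
    trim_by_propensity,
    weighted_difference,
)
from holctract.synthetic import make_scenarios
from holctract.types import COVARIATE_COLUMNS, DataError


class TestPropensityModel:
    def test_null_covariates_give_flat_scores(self, rng):
        X = rng.normal(size=(2000, 4))
        z = rng.integers(0, 2, size=2000).astype(float)
        m = PropensityScoreModel().fit(X, z)
        assert np.abs(m.coef_).max() < 0.15
        assert m.scores_.mean() == pytest.approx(z.mean(), abs=0.01)

    def test_matches_sklearn_unpenalized(self, confounded_df):
        from sklearn.linear_model import LogisticRegression

        fit = fit_propensity(confounded_df, ("C", "B"))
        sub = confounded_df[confounded_df["grade"].isin(["B", "C"])]
        from holctract.causal import propensity_design

        X = propensity_design(sub).to_numpy()
        z = (sub["grade"] == "C").to_numpy(float)
        sk = LogisticRegression(C=np.inf, max_iter=10000, tol=1e-10).fit(
            (X - X.mean(0)) / X.std(0), z
        )
        # back-transform sklearn's standardized coefficients
        sk_coef = sk.coef_[0] / X.std(0)
        np.testing.assert_allclose(
            fit.coefficients.to_numpy()[1:], sk_coef, rtol=1e-4, atol=1e-6
        )

    def test_recovers_known_assignment_coefficients(self):
        """At n=5000 the IRLS estimates lie within 3 oracle SEs of the truth
        (SEs from an independent statsmodels Logit fit)."""
        import statsmodels.api as sm

        sc = make_scenarios(n=5000)["confounded"]
        df = sc.generate(seed=77)
        fit = fit_propensity(df, ("C", "B"))
        sub = df[df["grade"].isin(["B", "C"])]
        from holctract.causal import propensity_design

        X = propensity_design(sub)
        xstd = (X - X.mean()) / X.std(ddof=0)
        z = (sub["grade"] == "C").to_numpy(float)
        sm_fit = sm.Logit(z, sm.add_constant(xstd.to_numpy())).fit(disp=0)
        truth = sc.truth.assignment_coefficients
        # generator coefficients are on within-sample standardized covariates
        my_std_coefs = fit.coefficients.to_numpy()[1:] * X.std(ddof=0).to_numpy()
        for j, name in enumerate(X.columns):
            true_b = truth.get(name, 0.0)
            assert abs(my_std_coefs[j] - true_b) < 3 * sm_fit.bse[j + 1]

    def test_perfect_separator_raises(self):
        X = np.linspace(-1, 1, 200).reshape(-1, 1)
        z = (X[:, 0] > 0).astype(float)
        with pytest.raises(DataError, match="separat"):
            PropensityScoreModel().fit(X, z)

    def test_coefficient_count_is_twelve(self, confounded_df):
        fit = fit_propensity(confounded_df, ("C", "B"))
        assert len(fit.coefficients) == 12  # intercept + 8 socio + 3 region

    def test_small_arm_is_error(self, confounded_df):
        sub = pd.concat(
            [
                confounded_df[confounded_df["grade"] == "C"].head(10),
                confounded_df[confounded_df["grade"] == "B"].head(100),
            ]
        )
        with pytest.raises(DataError, match="arm sizes"):
            fit_propensity(sub, ("C", "B"))


def _manual_fit(scores, treatment, pair=("C", "B")):
    scores = np.asarray(scores, dtype=float)
    treatment = np.asarray(treatment, dtype=float)
    ids = np.array([f"t{i}" for i in range(len(scores))])
    return PropensityFit(
        pair=pair,
        tract_ids=ids,
        coefficients=pd.Series(dtype=float),
        scores=scores,
        treatment=treatment,
        converged=True,
        iterations=1,
    )


class TestTrimming:
    def test_interpolated_quantile_bounds(self):
        scores = np.arange(1, 101) / 101.0
        fit = _manual_fit(scores, np.tile([0, 1], 50))
        out = trim_by_propensity(fit, alpha=0.025)
        lo, hi = np.quantile(scores, [0.025, 0.975], method="linear")
        assert out.trim_lo == pytest.approx(lo) and out.trim_hi == pytest.approx(hi)
        kept = scores[(scores >= lo) & (scores <= hi)]
        # interpolated bounds fall strictly between order statistics, so 94
        # of the 100 equally spaced scores survive (roughly the central 95%)
        assert len(out.tract_ids) == len(kept) == 94
        assert out.n_original == 100

    def test_alpha_zero_retains_all(self):
        scores = np.linspace(0.05, 0.95, 40)
        fit = _manual_fit(scores, np.tile([0, 1], 20))
        out = trim_by_propensity(fit, alpha=0.0)
        assert len(out.tract_ids) == 40
        assert out.trim_lo == pytest.approx(0.05)
        assert out.trim_hi == pytest.approx(0.95)

    @given(alpha=st.floats(min_value=0.0, max_value=0.24))
    @settings(max_examples=30, deadline=None)
    def test_retention_matches_quantile_rule(self, alpha):
        rng = np.random.default_rng(7)
        scores = rng.uniform(0.01, 0.99, 500)
        fit = _manual_fit(scores, rng.integers(0, 2, 500))
        out = trim_by_propensity(fit, alpha=alpha)
        if alpha == 0:
            lo, hi = scores.min(), scores.max()
        else:
            lo, hi = np.quantile(scores, [alpha, 1 - alpha], method="linear")
        expected = {f"t{i}" for i in np.flatnonzero((scores >= lo) & (scores <= hi))}
        assert set(out.tract_ids) == expected

    def test_pathological_retention_is_error(self):
        # spread-out scores with an extreme alpha retain under half the
        # sample, which signals pathological overlap
        scores = np.linspace(0.01, 0.99, 100)
        fit = _manual_fit(scores, np.tile([0, 1], 50))
        with pytest.raises(DataError, match="retained"):
            trim_by_propensity(fit, alpha=0.45)


class TestWeights:
    def test_constant_half_scores(self):
        fit = _manual_fit(np.full(40, 0.5), np.tile([0.0, 1.0], 20))
        sample = trim_by_propensity(fit, alpha=0.0)
        uns = compute_ipw_weights(fit, sample, "unstabilized")
        np.testing.assert_allclose(uns.weights, 2.0)
        stab = compute_ipw_weights(fit, sample, "stabilized")
        np.testing.assert_allclose(stab.weights, 1.0)

    def test_treated_weight_is_inverse_score(self):
        fit = _manual_fit([0.8, 0.4, 0.5, 0.5], [1.0, 0.0, 1.0, 0.0])
        sample = trim_by_propensity(fit, alpha=0.0)
        out = compute_ipw_weights(fit, sample, "unstabilized")
        assert out.weights[0] == pytest.approx(1 / 0.8)
        assert out.weights[1] == pytest.approx(1 / 0.6)

    def test_stabilized_mean_is_one_before_trimming(self, confounded_df):
        fit = fit_propensity(confounded_df, ("C", "B"))
        sample = trim_by_propensity(fit, alpha=0.0)  # no trimming
        out = compute_ipw_weights(fit, sample, "stabilized")
        assert out.weights.mean() == pytest.approx(1.0, abs=1e-6)

    def test_effective_sample_size_reported(self, confounded_df):
        fit = fit_propensity(confounded_df, ("C", "B"))
        sample = trim_by_propensity(fit)
        out = compute_ipw_weights(fit, sample)
        n_t = int(fit.treatment[np.isin(fit.tract_ids, sample.tract_ids)].sum())
        assert 0 < out.ess_treated <= len(sample.tract_ids)
        assert 0 < out.ess_control <= len(sample.tract_ids)


def _pair_frame(y, z):
    n = len(y)
    return pd.DataFrame(
        {
            "tract_id": [f"t{i}" for i in range(n)],
            "grade": np.where(np.asarray(z) == 1, "C", "B"),
            "diabetes": y,
        }
    )


class TestMSM:
    def test_constant_scores_reduce_to_crude_difference(self, rng):
        z = rng.integers(0, 2, 300).astype(float)
        y = rng.normal(10, 2, 300) + 1.5 * z
        fit = _manual_fit(np.full(300, z.mean()), z)
        sample = trim_by_propensity(fit, alpha=0.0)
        weighted = compute_ipw_weights(fit, sample)
        res = estimate_msm(_pair_frame(y, z), fit, weighted, "diabetes")
        crude = y[z == 1].mean() - y[z == 0].mean()
        assert res.estimate == pytest.approx(crude, abs=1e-10)

    def test_estimate_is_weighted_mean_difference(self, confounded_df):
        fit = fit_propensity(confounded_df, ("C", "B"))
        sample = trim_by_propensity(fit)
        weighted = compute_ipw_weights(fit, sample)
        res = estimate_msm(confounded_df, fit, weighted, "diabetes")
        sub = confounded_df.set_index("tract_id")
        y = sub["diabetes"].reindex(weighted.tract_ids).to_numpy()
        z = fit.treatment[np.isin(fit.tract_ids, weighted.tract_ids)]
        w = weighted.weights
        manual = (w[z == 1] * y[z == 1]).sum() / w[z == 1].sum() - (
            w[z == 0] * y[z == 0]
        ).sum() / w[z == 0].sum()
        assert res.estimate == pytest.approx(manual, abs=1e-10)

    def test_sandwich_se_matches_closed_form(self, rng):
        """HC0 for the two-arm weighted design has an independent closed
        form: sum_T w^2 e^2 / (sum_T w)^2 + same for controls."""
        z = rng.integers(0, 2, 200).astype(float)
        y = rng.normal(10, 2, 200) + z
        w = rng.uniform(0.5, 3.0, 200)
        est, se = weighted_difference(y, z, w)
        mt = (w[z == 1] * y[z == 1]).sum() / w[z == 1].sum()
        mc = (w[z == 0] * y[z == 0]).sum() / w[z == 0].sum()
        var = (w[z == 1] ** 2 * (y[z == 1] - mt) ** 2).sum() / w[z == 1].sum() ** 2
        var += (w[z == 0] ** 2 * (y[z == 0] - mc) ** 2).sum() / w[z == 0].sum() ** 2
        assert est == pytest.approx(mt - mc, abs=1e-12)
        assert se == pytest.approx(np.sqrt(var), rel=1e-10)

    def test_single_arm_after_trim_is_error(self, rng):
        y = rng.normal(10, 1, 60)
        z = np.ones(60)
        z[:2] = 0.0
        fit = _manual_fit(np.linspace(0.3, 0.7, 60), z)
        sample = trim_by_propensity(fit, alpha=0.0)
        weighted = compute_ipw_weights(fit, sample)
        df = _pair_frame(y, z)
        df.loc[df["grade"] == "B", "diabetes"] = np.nan  # kill the control arm
        with pytest.raises(DataError, match="arm"):
            estimate_msm(df, fit, weighted, "diabetes")

    def test_trimmed_and_original_counts(self, confounded_df):
        fit = fit_propensity(confounded_df, ("C", "B"))
        sample = trim_by_propensity(fit, alpha=0.025)
        weighted = compute_ipw_weights(fit, sample)
        res = estimate_msm(confounded_df, fit, weighted, "diabetes")
        assert res.n_original == len(fit.scores)
        assert res.n_trimmed == len(sample.tract_ids)
        assert res.n_trimmed < res.n_original

    def test_bootstrap_ci_brackets_estimate(self, confounded_df):
        fit = fit_propensity(confounded_df, ("C", "B"))
        sample = trim_by_propensity(fit)
        weighted = compute_ipw_weights(fit, sample)
        res = estimate_msm(
            confounded_df, fit, weighted, "diabetes", n_bootstrap=60, seed=5
        )
        lo, hi = res.bootstrap_ci
        assert lo < res.estimate < hi
        # sandwich and bootstrap CIs should be broadly comparable
        assert (hi - lo) == pytest.approx(res.ci_high - res.ci_low, rel=0.6)


class TestFullMatching:
    def test_identical_scores_make_pairs(self):
        z = np.tile([1.0, 0.0], 10)
        scores = np.repeat(np.linspace(0.2, 0.8, 10), 2)
        fit = _manual_fit(scores, z)
        sample = trim_by_propensity(fit, alpha=0.0)
        sets = full_matching(fit, sample)
        assert sets.n_sets == 10
        np.testing.assert_allclose(sets.match_weights, 1.0)
        counts = pd.Series(sets.set_ids).value_counts()
        assert (counts == 2).all()

    def test_one_to_two_sets_weight_majority_half(self):
        # 2 treated at scores .3/.7, controls clustered pairwise around them
        z = np.array([1.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        scores = np.array([0.3, 0.7, 0.29, 0.31, 0.69, 0.71])
        fit = _manual_fit(scores, z)
        sample = trim_by_propensity(fit, alpha=0.0)
        sets = full_matching(fit, sample)
        assert sets.n_sets == 2
        # raw within-set majority weight is 1/2; arm rescale (4 units, raw
        # sum 2) doubles it back to 1
        maj = sets.match_weights[z == 0]
        np.testing.assert_allclose(maj, 1.0)
        assert sets.match_weights[z == 1].sum() == pytest.approx(2.0)
        assert maj.sum() == pytest.approx(4.0)

    def test_every_set_contains_both_arms(self, confounded_df):
        fit = fit_propensity(confounded_df, ("C", "B"))
        sample = trim_by_propensity(fit)
        sets = full_matching(fit, sample)
        df = pd.DataFrame(
            {"set": sets.set_ids,
             "z": fit.treatment[np.isin(fit.tract_ids, sample.tract_ids)]}
        )
        grouped = df.groupby("set")["z"]
        nonempty = grouped.count() > 0
        assert (grouped.max()[nonempty] == 1).all()
        assert (grouped.min()[nonempty] == 0).all()

    def test_arm_weight_sums_equal_arm_sizes(self, confounded_df):
        fit = fit_propensity(confounded_df, ("C", "B"))
        sample = trim_by_propensity(fit)
        sets = full_matching(fit, sample)
        z = fit.treatment[np.isin(fit.tract_ids, sample.tract_ids)]
        w = sets.match_weights
        assert w[z == 1].sum() == pytest.approx((z == 1).sum())
        assert w[z == 0].sum() == pytest.approx((z == 0).sum())

    def test_matched_estimate_agrees_with_ipw(self):
        """Across replicates of the confounded design the matched and IPW
        estimates agree on average within 0.2 percentage points."""
        sc = make_scenarios(n=4000)["confounded"]
        gaps = []
        for s in range(30):
            df = sc.generate(seed=6000 + s)
            fit = fit_propensity(df, ("C", "B"))
            sample = trim_by_propensity(fit)
            weighted = compute_ipw_weights(fit, sample)
            ipw = estimate_msm(df, fit, weighted, "diabetes")
            matched = matched_estimate(
                df, fit, full_matching(fit, sample), "diabetes"
            )
            gaps.append(matched.estimate - ipw.estimate)
        assert abs(np.mean(gaps)) < 0.2


class TestBalance:
    def test_identical_arms_give_zero_smd(self):
        x = np.linspace(0, 1, 50)
        df = pd.DataFrame({c: np.tile(x, 2) for c in COVARIATE_COLUMNS})
        z = np.repeat([1, 0], 50)
        bal = covariate_balance(df, z)
        np.testing.assert_allclose(bal["smd_unweighted"], 0.0, atol=1e-12)

    def test_one_sd_shift_gives_unit_smd(self, rng):
        base = rng.normal(10, 2, 500)
        sd = base.std(ddof=1)
        df = pd.DataFrame(
            {c: np.concatenate([base + sd, base]) for c in COVARIATE_COLUMNS}
        )
        z = np.repeat([1, 0], 500)
        bal = covariate_balance(df, z)
        np.testing.assert_allclose(bal["smd_unweighted"], 1.0, atol=1e-12)

    def test_zero_sd_flagged(self):
        df = pd.DataFrame({c: np.ones(20) for c in COVARIATE_COLUMNS})
        z = np.repeat([1, 0], 10)
        with pytest.warns(UserWarning, match="zero pooled SD"):
            bal = covariate_balance(df, z)
        assert bal["zero_sd"].all()
        assert (bal["smd_unweighted"] == 0).all()

    def test_weighting_shrinks_confounded_imbalance(self, confounded_df):
        ipw, _, bal = run_pair_analysis(
            confounded_df, ("C", "B"), outcomes=["diabetes"], with_matching=False
        )
        assert bal["smd_weighted"].abs().max() < bal["smd_unweighted"].abs().max()
        assert bal["smd_unweighted"].abs().max() > 0.3


class TestSklearnFrontend:
    def test_estimator_protocol_and_recovery(self, rng):
        X = rng.normal(size=(3000, 3))
        logits = 0.8 * X[:, 0] - 0.5 * X[:, 1]
        z = (rng.uniform(size=3000) < 1 / (1 + np.exp(-logits))).astype(float)
        y = 5.0 + 1.2 * X[:, 0] + 1.0 * z + rng.normal(0, 1, 3000)
        est = IPWPrevalenceDifference().fit(X, z, y)
        assert est.get_params()["trim_alpha"] == 0.025
        crude = y[z == 1].mean() - y[z == 0].mean()
        assert abs(crude - 1.0) > 0.3  # confounded by construction
        assert est.estimate_ == pytest.approx(1.0, abs=0.25)
        assert est.ci_low_ < est.estimate_ < est.ci_high_
        assert est.n_retained_ <= est.n_original_

    def test_clone_compatible(self):
        from sklearn.base import clone

        est = IPWPrevalenceDifference(trim_alpha=0.05, weight_type="stabilized")
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_bootstrap_ci_available_on_raw_matrices(self, rng):
        X = rng.normal(size=(800, 2))
        z = (rng.uniform(size=800) < 1 / (1 + np.exp(-X[:, 0]))).astype(float)
        y = 3.0 + X[:, 0] + z + rng.normal(0, 1, 800)
        est = IPWPrevalenceDifference(n_bootstrap=40, seed=9).fit(X, z, y)
        lo, hi = est.bootstrap_ci_
        assert lo < est.estimate_ < hi
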