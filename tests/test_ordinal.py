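"""Proportional-odds MLE, diagnostics, deviance LRT, effect interpretation, LDA."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from ssnod.cohort import CLASS_LABELS, PoSimConfig, generate_po_cohort
from ssnod.lda import fit_lda, predict_lda
from ssnod.ordinal import (
    OrdinalFit,
    SeparationError,
    deviance_test,
    fit_nonproportional,
    fit_proportional_odds,
    odds_ratios,
    po_diagnostics,
    predict_class_probs,
    quartile_probability_change,
    proportional_odds_lrt,
)


def nonpo_cohort(n, seed, slopes=(1.0, 3.0), intercepts=(-2.2, 0.2)):
    """Cumulative-logit data with cutoff-specific slopes (violates PO).

    x ~ U(-1, 1) keeps the two cumulative curves ordered on the whole support.
    """
    rng = np.random.default_rng(seed)
    x = rng.uniform(-1, 1, n)
    g1 = expit(intercepts[0] - slopes[0] * x)
    g2 = expit(intercepts[1] - slopes[1] * x)
    assert np.all(g1 <= g2)
    u = rng.uniform(size=n)
    codes = (u > g1).astype(int) + (u > g2)
    return pd.DataFrame({"x": x}), np.array([CLASS_LABELS[c] for c in codes])


class TestFit:
    def test_intercept_only_fit_matches_closed_form_mle(self):
        """Null cumulative intercepts are the empirical cumulative logits."""
        y = np.repeat(["H1", "H2", "H3"], [31, 64, 132])
        fit = fit_proportional_odds(np.empty((227, 0)), y)
        assert fit.intercepts[0] == pytest.approx(float(logit(31 / 227)), abs=1e-8)
        assert fit.intercepts[1] == pytest.approx(float(logit(95 / 227)), abs=1e-8)

    def test_two_class_fit_equals_binary_logistic(self, rng):
        """Collapsing H2 into H3 reduces the model to logistic regression."""
        import statsmodels.api as sm

        X = rng.standard_normal((300, 2))
        y = (rng.uniform(size=300) < expit(0.5 + X @ [1.0, -0.7])).astype(int)
        fit = fit_proportional_odds(X, y)
        sm_fit = sm.Logit(y, sm.add_constant(X - X.mean(0))).fit(disp=False)
        # P(Y=1) = expit(x beta - alpha): slopes match, intercept flips sign
        assert np.allclose(fit.beta, sm_fit.params[1:], atol=1e-6)
        assert fit.intercepts[0] == pytest.approx(-sm_fit.params[0], abs=1e-6)

    def test_parameter_recovery_with_wald_coverage(self):
        """95% Wald CIs cover the generating slopes in >= 90% of seeds."""
        beta_true = np.array([1.4, 3.6])
        covered = 0
        estimates = []
        for seed in range(50):
            table = generate_po_cohort(
                PoSimConfig(n=5000, beta=tuple(beta_true), seed=seed)
            )
            fit = fit_proportional_odds(
                table[["volume_log", "attenuation"]], table["class"].to_numpy()
            )
            se = fit.se[2:]
            lo, hi = fit.beta - 1.96 * se, fit.beta + 1.96 * se
            covered += bool(np.all((lo <= beta_true) & (beta_true <= hi)))
            estimates.append(fit.beta)
        assert covered >= 45
        bias = np.mean(estimates, axis=0) - beta_true
        assert np.all(np.abs(bias) < 0.05 * beta_true)

    def test_gradient_converged_and_covariance_sane(self, rng):
        table = generate_po_cohort(PoSimConfig(n=800, seed=3))
        fit = fit_proportional_odds(
            table[["volume_log", "attenuation"]], table["class"].to_numpy()
        )
        cov = fit.covariance
        assert np.allclose(cov, cov.T, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(cov) > 0)
        assert fit.intercepts[0] < fit.intercepts[1]

    def test_centering_invariance_of_predictions(self, rng):
        X = rng.standard_normal((400, 2)) + [3.0, -5.0]
        codes = rng.integers(0, 3, 400)
        codes[:3] = [0, 1, 2]
        y = np.array([CLASS_LABELS[c] for c in codes])
        fit_raw = fit_proportional_odds(X, y)
        shift = X.mean(0)
        fit_cent = fit_proportional_odds(X - shift, y)
        x0 = X[:5]
        assert np.allclose(
            predict_class_probs(fit_raw, x0),
            predict_class_probs(fit_cent, x0 - shift),
            atol=1e-9,
        )

    def test_complete_separation_raises(self):
        x = np.arange(30, dtype=float)[:, None]
        y = np.repeat(["H1", "H2", "H3"], 10)
        with pytest.raises(SeparationError):
            fit_proportional_odds(x, y)

    def test_non_ordinal_labels_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_proportional_odds(rng.standard_normal((10, 1)), np.repeat("H1", 10))


class TestPredict:
    def _null_fit(self, p1=0.2, p12=0.6):
        return OrdinalFit(
            feature_names=["x"],
            class_labels=list(CLASS_LABELS),
            centers=np.zeros(1),
            beta=np.zeros(1),
            intercepts=np.array([float(logit(p1)), float(logit(p12))]),
            covariance=np.eye(3) * 1e-4,
            deviance=0.0,
            loglik=0.0,
            wald_z=np.zeros(3),
            wald_p=np.ones(3),
            n_obs=100,
            n_iter=1,
        )

    def test_zero_slope_closed_form_probabilities(self):
        probs = predict_class_probs(self._null_fit(), np.array([1.7]))
        assert np.allclose(probs, [0.2, 0.4, 0.4], atol=1e-12)

    def test_positive_slope_limit_saturates_to_h3(self):
        fit = self._null_fit()
        fit.beta = np.array([2.0])
        probs = predict_class_probs(fit, np.array([1e4]))
        assert np.allclose(probs, [0.0, 0.0, 1.0], atol=1e-12)

    def test_simplex_contract_and_monotone_ordinality(self, rng):
        table = generate_po_cohort(PoSimConfig(n=300, seed=1))
        fit = fit_proportional_odds(
            table[["volume_log", "attenuation"]], table["class"].to_numpy()
        )
        X = rng.standard_normal((200, 2)) * 3
        probs = predict_class_probs(fit, X)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        # along a positive-slope feature, P(H3) is non-decreasing
        j = int(np.argmax(fit.beta > 0))
        grid = np.zeros((50, 2))
        grid[:, j] = np.linspace(-5, 5, 50)
        p3 = predict_class_probs(fit, grid)[:, 2]
        assert np.all(np.diff(p3) >= -1e-12)

    def test_missing_feature_raises(self):
        fit = self._null_fit()
        with pytest.raises(ValueError, match="missing"):
            predict_class_probs(fit, {"y": 1.0})


class TestOddsRatios:
    @pytest.mark.parametrize(
        "coef,printed_or,tol",
        [
            (1.251, 3.493, 5e-4),
            (0.00695, 1.0070, 5e-5),
            (1.362, 3.91, 0.005),
            (3.644, 38.23, 0.005),
            (0.0, 1.0, 1e-12),
        ],
    )
    def test_exponentiation_identity(self, coef, printed_or, tol):
        """exp(coefficient) reproduces the odds ratio to printed precision."""
        assert np.exp(coef) == pytest.approx(printed_or, rel=tol)

    def test_odds_ratio_table_consistency(self):
        table = generate_po_cohort(PoSimConfig(n=1000, seed=6))
        fit = fit_proportional_odds(
            table[["volume_log", "attenuation"]], table["class"].to_numpy()
        )
        ors = odds_ratios(fit)
        assert np.allclose(ors["odds_ratio"], np.exp(ors["coefficient"]))
        assert np.allclose(
            ors["or_ci_low"], np.exp(ors["coef_ci_low"]), rtol=1e-12
        )
        assert (ors["or_ci_low"] <= ors["odds_ratio"]).all()
        assert (ors["odds_ratio"] <= ors["or_ci_high"]).all()


class TestDevianceTest:
    def test_identical_models_give_chi2_zero_p_one(self):
        table = generate_po_cohort(PoSimConfig(n=300, seed=0))
        fit = fit_proportional_odds(
            table[["volume_log", "attenuation"]], table["class"].to_numpy()
        )
        res = deviance_test(fit, fit)
        assert res.chi2 == 0.0
        assert res.p_value == 1.0

    def test_nonpo_fit_never_has_higher_deviance(self):
        for seed in range(5):
            table = generate_po_cohort(PoSimConfig(n=400, seed=seed))
            X = table[["volume_log", "attenuation"]]
            y = table["class"].to_numpy()
            simple = fit_proportional_odds(X, y)
            complex_ = fit_nonproportional(X, y, start=simple)
            assert simple.deviance >= complex_.deviance - 1e-8

    def test_detects_nonproportional_slopes(self):
        """Cutoff-specific generating slopes (1 vs 3) are rejected at n=5000."""
        rejections = 0
        for seed in range(10):
            X, y = nonpo_cohort(5000, seed)
            rejections += proportional_odds_lrt(X, y).p_value < 0.05
        assert rejections >= 9


class TestDiagnostics:
    def test_po_data_slope_agreement(self):
        """Per-cutoff binary slopes agree within 2 pooled SEs under PO truth."""
        ok = 0
        n_seeds = 30
        for seed in range(n_seeds):
            table = generate_po_cohort(PoSimConfig(n=600, beta=(1.2,), seed=seed,
                                                   predictor_dists=((0.0, 1.0),),
                                                   predictor_names=("x",)))
            diag = po_diagnostics(table[["x"]], table["class"].to_numpy())
            ok += not diag["po_flag"]
        assert ok >= 0.9 * n_seeds

    def test_nonpo_data_raises_flag(self):
        flagged = 0
        for seed in range(10):
            X, y = nonpo_cohort(5000, seed + 100)
            flagged += po_diagnostics(X, y)["po_flag"]
        assert flagged >= 9

    def test_ordinality_table_tracks_observed_means(self):
        table = generate_po_cohort(PoSimConfig(n=2000, seed=5))
        diag = po_diagnostics(
            table[["volume_log", "attenuation"]], table["class"].to_numpy()
        )
        ords = diag["ordinality"]
        for _, row in ords.iterrows():
            assert row["implied_mean"] == pytest.approx(
                row["observed_mean"], abs=0.35
            )

    def test_degenerate_separation_reported_not_raised(self):
        x = np.arange(30, dtype=float)[:, None]
        y = np.repeat(["H1", "H2", "H3"], 10)
        with pytest.raises(SeparationError):
            # the PO fit itself separates; diagnostics cannot proceed
            po_diagnostics(x, y)
        # separation at one cutoff only: diagnostics still return a report
        rng = np.random.default_rng(0)
        x2 = np.concatenate([rng.normal(0, 1, 20), rng.normal(0.5, 1, 20),
                             np.linspace(5.0, 7.0, 20)])[:, None]
        y2 = np.repeat(["H1", "H2", "H3"], 20)
        diag = po_diagnostics(x2, y2)
        assert diag["degenerate_cutoffs"] or not diag["cutoff_slopes"].empty


class TestQuartileChange:
    def _fit_and_table(self, beta=(1.4, 3.6), n=1500, seed=11):
        table = generate_po_cohort(PoSimConfig(n=n, beta=beta, seed=seed))
        fit = fit_proportional_odds(
            table[["volume_log", "attenuation"]], table["class"].to_numpy()
        )
        return fit, table

    def test_null_predictor_has_no_effect(self):
        fit, table = self._fit_and_table(beta=(0.0, 3.6), n=4000, seed=2)
        prof = quartile_probability_change(
            fit, table, "volume_log", n_draws=2000, seed=1
        )
        assert np.all(np.abs(prof.delta) < 0.05)
        assert np.all(prof.p_values > 0.05)

    def test_positive_attenuation_effect_signs(self):
        """Raising the attenuation feature moves mass from H1 to H3."""
        fit, table = self._fit_and_table()
        prof = quartile_probability_change(
            fit, table, "attenuation", n_draws=1000, seed=3
        )
        assert prof.delta[2] > 0 and prof.p_values[2] < 0.05
        assert prof.delta[0] < 0 and prof.p_values[0] < 0.05
        assert np.allclose(
            prof.class_probs_at_q1.sum(), 1.0, atol=1e-9
        )
        assert np.allclose(prof.delta, prof.class_probs_at_q3 - prof.class_probs_at_q1)

    def test_seed_determinism(self):
        fit, table = self._fit_and_table(n=500, seed=4)
        a = quartile_probability_change(fit, table, "attenuation", seed=9)
        b = quartile_probability_change(fit, table, "attenuation", seed=9)
        assert np.array_equal(a.delta, b.delta)
        assert np.array_equal(a.p_values, b.p_values)

    def test_invalid_inputs(self):
        fit, table = self._fit_and_table(n=300, seed=5)
        with pytest.raises(ValueError):
            quartile_probability_change(fit, table, "nope")
        with pytest.raises(ValueError):
            quartile_probability_change(fit, table, "attenuation", n_draws=10)


class TestLda:
    def test_identical_classes_return_priors(self, rng):
        X = rng.standard_normal((300, 2))
        y = np.array([CLASS_LABELS[c] for c in rng.integers(0, 3, 300)])
        y[:3] = CLASS_LABELS
        fit = fit_lda(X, y)
        post = predict_lda(fit, X)
        assert np.allclose(post.mean(axis=0), fit.priors, atol=0.06)

    def test_separated_gaussians_near_perfect_accuracy(self, rng):
        means = np.array([[0, 0], [8, 0], [0, 8]])
        codes = rng.integers(0, 3, 300)
        X = rng.standard_normal((300, 2)) + means[codes]
        y = np.array([CLASS_LABELS[c] for c in codes])
        fit = fit_lda(X, y)
        post = predict_lda(fit, X)
        assert (post.argmax(axis=1) == codes).mean() > 0.99
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_sklearn_posteriors(self, rng):
        """The Gaussian discriminant rule agrees with sklearn's on shared moments.

        sklearn pools the within-class covariance with an ML denominator
        rather than n - J, so its covariance is substituted into the fit to
        compare the posterior rules themselves.
        """
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        codes = rng.integers(0, 3, 200)
        X = rng.standard_normal((200, 3)) + codes[:, None]
        sk = LinearDiscriminantAnalysis(solver="lsqr", store_covariance=True).fit(
            X, codes
        )
        fit = fit_lda(X, codes)
        assert np.allclose(fit.class_means, sk.means_)
        assert np.allclose(fit.priors, sk.priors_)
        fit.pooled_covariance = sk.covariance_
        assert np.allclose(predict_lda(fit, X), sk.predict_proba(X), atol=1e-8)

    def test_too_few_samples_per_class_rejected(self, rng):
        X = rng.standard_normal((7, 3))
        y = ["H1", "H1", "H1", "H2", "H2", "H3", "H3"]
        with pytest.raises(ValueError, match="at least"):
            fit_lda(X, y)
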