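"""Cumulative-logit ordinal regression with proportional odds.

Model: P(Y <= j | x) = expit(alpha_j - x.beta), j = 1..J-1, with a single
slope vector shared across cutoffs — so a positive beta raises the odds of
the more invasive classes, and exponentiated slopes are the cutoff-free
odds ratios. Features are centred at their training means before fitting
(centres are stored and folded back in at prediction time), matching how
the printed intercepts of such models are conventionally reported.

Fitting is Newton-Raphson on the exact log-likelihood with analytic
gradient and Hessian and step-halving; the covariance is the inverse
observed information. The unconstrained (non-proportional) cumulative-logit
MLE — separate slopes per cutoff — provides the complex model of the
nested deviance test of the proportional-odds assumption.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

MAX_ABS_SLOPE = 30.0
GRAD_TOL = 1e-8
MAX_ITER = 200


class SeparationError(RuntimeError):
    """Slopes diverge: the classes are (quasi-)completely separated."""


class ConvergenceError(RuntimeError):
    pass


def _encode_labels(y):
    y = np.asarray(y)
    labels = np.unique(y)
    if labels.size < 2:
        raise ValueError("need at least two ordered classes")
    codes = np.searchsorted(labels, y)
    return codes, [str(lab) for lab in labels]


@dataclass
class OrdinalFit:
    feature_names: list[str]
    class_labels: list[str]
    centers: np.ndarray
    beta: np.ndarray
    intercepts: np.ndarray  # alpha_j for P(Y <= j), increasing
    covariance: np.ndarray  # (J-1+p) x (J-1+p), intercepts first
    deviance: float
    loglik: float
    wald_z: np.ndarray
    wald_p: np.ndarray
    n_obs: int
    n_iter: int

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.intercepts, self.beta])

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


def _as_matrix(X, feature_names=None):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns) if feature_names is None else list(feature_names)
        return X[names].to_numpy(dtype=float), names
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and feature_names and len(feature_names) == 1:
        X = X.T
    names = feature_names or [f"x{i}" for i in range(X.shape[1])]
    return X, list(names)


def _po_ll_grad_hess(theta, Xc, codes, J, want_derivs=True):
    """Log-likelihood (and optionally gradient/Hessian) of the PO model."""
    n, p = Xc.shape
    alpha = theta[: J - 1]
    beta = theta[J - 1 :]
    eta = Xc @ beta
    z = alpha[None, :] - eta[:, None]  # n x (J-1)
    gam = expit(z)
    full = np.hstack([np.zeros((n, 1)), gam, np.ones((n, 1))])
    prob = full[np.arange(n), codes + 1] - full[np.arange(n), codes]
    if np.any(prob <= 0):
        return -np.inf, None, None
    ll = float(np.log(prob).sum())
    if not want_derivs:
        return ll, None, None

    phi = gam * (1.0 - gam)
    rho = phi * (1.0 - 2.0 * gam)
    A = np.zeros((n, J - 1))
    B = np.zeros((n, J - 1))
    rows = np.arange(n)
    up = codes <= J - 2  # upper cumulative gamma_{c+1} exists
    A[rows[up], codes[up]] += phi[rows[up], codes[up]] / prob[up]
    B[rows[up], codes[up]] += rho[rows[up], codes[up]] / prob[up]
    lo = codes >= 1  # lower cumulative gamma_c exists
    A[rows[lo], codes[lo] - 1] -= phi[rows[lo], codes[lo] - 1] / prob[lo]
    B[rows[lo], codes[lo] - 1] -= rho[rows[lo], codes[lo] - 1] / prob[lo]

    a = A.sum(axis=1)
    b = B.sum(axis=1)
    grad = np.concatenate([A.sum(axis=0), -Xc.T @ a])
    H_aa = np.diag(B.sum(axis=0)) - A.T @ A
    H_ab = (-B + A * a[:, None]).T @ Xc
    H_bb = Xc.T @ (Xc * (b - a * a)[:, None])
    H = np.block([[H_aa, H_ab], [H_ab.T, H_bb]])
    return ll, grad, H


def _newton_decrement(grad, H):
    """Expected remaining log-likelihood gain 0.5 * g' (-H)^-1 g."""
    try:
        return 0.5 * float(grad @ np.linalg.solve(-H, grad))
    except np.linalg.LinAlgError:
        return np.inf


def _newton(theta, objective, n_params):
    """Maximise ``objective`` by Newton steps with step-halving.

    Convergence is max |score| < 1e-8; when the line search stalls at the
    resolution of the log-likelihood (near-separated folds), a Newton
    decrement below 1e-8 — the remaining attainable gain — also counts as
    converged, which is scale-invariant where the raw gradient is not.
    """
    ll, grad, H = objective(theta)
    if not np.isfinite(ll):
        raise ConvergenceError("invalid starting point")
    for it in range(1, MAX_ITER + 1):
        if np.max(np.abs(grad)) < GRAD_TOL:
            return theta, ll, grad, H, it
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, -grad, rcond=None)[0]
        t = 1.0
        for _ in range(60):
            cand = theta + t * step
            ll_new, g_new, H_new = objective(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            t *= 0.5
        else:
            if _newton_decrement(grad, H) < 1e-8:
                return theta, ll, grad, H, it
            raise ConvergenceError("step-halving failed to improve the likelihood")
        theta, ll, grad, H = cand, ll_new, g_new, H_new
    if np.max(np.abs(grad)) >= GRAD_TOL and _newton_decrement(grad, H) >= 1e-8:
        raise ConvergenceError("Newton iterations did not converge")
    return theta, ll, grad, H, MAX_ITER


def fit_proportional_odds(X, y, feature_names=None) -> OrdinalFit:
    """Maximum-likelihood proportional-odds fit on centred predictors."""
    Xraw, names = _as_matrix(X, feature_names)
    codes, labels = _encode_labels(y)
    J = len(labels)
    n, p = Xraw.shape
    if n != codes.size:
        raise ValueError("X and y lengths differ")
    if np.isnan(Xraw).any():
        raise ValueError("missing values in X")
    counts = np.bincount(codes, minlength=J)
    if np.any(counts == 0):
        raise ValueError("every ordered class must be non-empty")

    centers = Xraw.mean(axis=0)
    Xc = Xraw - centers
    # optimise on unit-variance predictors: keeps the Newton system well
    # conditioned when feature scales differ by orders of magnitude (HU vs
    # log-volume); estimates and covariance are mapped back afterwards
    scales = Xc.std(axis=0)
    scales[scales == 0] = 1.0
    Xs = Xc / scales
    alpha0 = logit(np.cumsum(counts)[:-1] / n)
    theta0 = np.concatenate([alpha0, np.zeros(p)])

    def objective(theta):
        if p and np.max(np.abs(theta[J - 1 :])) > MAX_ABS_SLOPE:
            raise SeparationError(
                "slope magnitude exceeds 30; classes appear separated"
            )
        return _po_ll_grad_hess(theta, Xs, codes, J)

    theta, ll, grad, H, n_iter = _newton(theta0, objective, J - 1 + p)
    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise SeparationError("observed information is singular") from exc
    back = np.concatenate([np.ones(J - 1), 1.0 / scales])
    theta = theta * back
    cov = cov * np.outer(back, back)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        wz = np.where(se > 0, theta / se, np.inf * np.sign(theta))
    return OrdinalFit(
        feature_names=names,
        class_labels=labels,
        centers=centers,
        beta=theta[J - 1 :],
        intercepts=theta[: J - 1],
        covariance=cov,
        deviance=-2.0 * ll,
        loglik=ll,
        wald_z=wz,
        wald_p=2.0 * norm.sf(np.abs(wz)),
        n_obs=n,
        n_iter=n_iter,
    )


def predict_class_probs(fit: OrdinalFit, X) -> np.ndarray:
    """Class probabilities for raw (uncentred) feature rows; rows sum to 1."""
    single = False
    if isinstance(X, dict):
        missing = [f for f in fit.feature_names if f not in X]
        if missing:
            raise ValueError(f"missing features: {missing}")
        X = np.array([[X[f] for f in fit.feature_names]])
        single = True
    elif isinstance(X, pd.DataFrame):
        missing = [f for f in fit.feature_names if f not in X.columns]
        if missing:
            raise ValueError(f"missing features: {missing}")
        X = X[fit.feature_names].to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
            single = True
        if X.shape[1] != len(fit.feature_names):
            raise ValueError("feature count mismatch")
    probs = _class_probs(fit.params, X - fit.centers, len(fit.class_labels))
    return probs[0] if single else probs


def _class_probs(theta, Xc, J) -> np.ndarray:
    alpha = theta[: J - 1]
    beta = theta[J - 1 :]
    z = alpha[None, :] - (Xc @ beta)[:, None]
    gam = expit(z)
    full = np.hstack([np.zeros((len(Xc), 1)), gam, np.ones((len(Xc), 1))])
    return np.diff(full, axis=1)


def odds_ratios(fit: OrdinalFit, z_mult: float = 1.96) -> pd.DataFrame:
    """Per-feature odds ratios exp(beta) with Wald 95% CIs."""
    J = len(fit.class_labels)
    se = fit.se[J - 1 :]
    return pd.DataFrame(
        {
            "feature": fit.feature_names,
            "coefficient": fit.beta,
            "coef_ci_low": fit.beta - z_mult * se,
            "coef_ci_high": fit.beta + z_mult * se,
            "odds_ratio": np.exp(fit.beta),
            "or_ci_low": np.exp(fit.beta - z_mult * se),
            "or_ci_high": np.exp(fit.beta + z_mult * se),
            "wald_p": fit.wald_p[J - 1 :],
        }
    )


# ---------------------------------------------------------------------------
# Unconstrained (non-proportional) cumulative-logit model, 3 classes


@dataclass
class NonPoFit:
    feature_names: list[str]
    centers: np.ndarray
    intercepts: np.ndarray
    beta: np.ndarray  # 2 x p, one slope vector per cutoff
    loglik: float
    deviance: float
    n_obs: int


def _nonpo_ll_grad_hess(theta, Xc, codes):
    n, p = Xc.shape
    alpha = theta[:2]
    b1 = theta[2 : 2 + p]
    b2 = theta[2 + p :]
    z = np.column_stack([alpha[0] - Xc @ b1, alpha[1] - Xc @ b2])
    gam = expit(z)
    full = np.hstack([np.zeros((n, 1)), gam, np.ones((n, 1))])
    prob = full[np.arange(n), codes + 1] - full[np.arange(n), codes]
    if np.any(prob <= 0):
        return -np.inf, None, None
    ll = float(np.log(prob).sum())

    phi = gam * (1.0 - gam)
    rho = phi * (1.0 - 2.0 * gam)
    A = np.zeros((n, 2))
    B = np.zeros((n, 2))
    rows = np.arange(n)
    up = codes <= 1
    A[rows[up], codes[up]] += phi[rows[up], codes[up]] / prob[up]
    B[rows[up], codes[up]] += rho[rows[up], codes[up]] / prob[up]
    lo = codes >= 1
    A[rows[lo], codes[lo] - 1] -= phi[rows[lo], codes[lo] - 1] / prob[lo]
    B[rows[lo], codes[lo] - 1] -= rho[rows[lo], codes[lo] - 1] / prob[lo]

    grad = np.concatenate(
        [A.sum(axis=0), -Xc.T @ A[:, 0], -Xc.T @ A[:, 1]]
    )
    # Hessian blocks; parameter order (a1, a2, b1, b2)
    H = np.zeros((2 + 2 * p, 2 + 2 * p))
    H[:2, :2] = np.diag(B.sum(axis=0)) - A.T @ A
    for k in range(2):
        sl_k = slice(2 + k * p, 2 + (k + 1) * p)
        for m in range(2):
            sl_m = slice(2 + m * p, 2 + (m + 1) * p)
            diag_term = B[:, k] if k == m else np.zeros(n)
            H[sl_k, sl_m] = Xc.T @ (Xc * (diag_term - A[:, k] * A[:, m])[:, None])
            cross = ((A[:, k] * A[:, m] - diag_term)[:, None] * Xc).sum(axis=0)
            H[k, sl_m] = cross
            H[sl_m, k] = cross
    return ll, grad, H


def fit_nonproportional(X, y, feature_names=None, start: OrdinalFit | None = None):
    """Unconstrained cumulative-logit MLE (3 classes, one slope set per cutoff)."""
    Xraw, names = _as_matrix(X, feature_names)
    codes, labels = _encode_labels(y)
    if len(labels) != 3:
        raise ValueError("the non-proportional comparator requires 3 classes")
    n, p = Xraw.shape
    centers = Xraw.mean(axis=0)
    Xc = Xraw - centers
    scales = Xc.std(axis=0)
    scales[scales == 0] = 1.0
    Xs = Xc / scales
    if start is None:
        start = fit_proportional_odds(Xraw, y, feature_names=names)
    beta_s = start.beta * scales
    theta0 = np.concatenate([start.intercepts, beta_s, beta_s])

    def objective(theta):
        if np.max(np.abs(theta[2:])) > MAX_ABS_SLOPE:
            raise SeparationError("slope magnitude exceeds 30")
        return _nonpo_ll_grad_hess(theta, Xs, codes)

    theta, ll, _, _, _ = _newton(theta0, objective, 2 + 2 * p)
    return NonPoFit(
        feature_names=names,
        centers=centers,
        intercepts=theta[:2],
        beta=theta[2:].reshape(2, p) / scales,
        loglik=ll,
        deviance=-2.0 * ll,
        n_obs=n,
    )


@dataclass(frozen=True)
class DevianceTest:
    chi2: float
    df: int
    p_value: float


def deviance_test(fit_simple, fit_complex) -> DevianceTest:
    """Chi-squared test on the deviance gap between nested fits.

    ``fit_simple`` is the proportional-odds fit; ``fit_complex`` any richer
    nested model exposing ``deviance`` (by default the unconstrained
    cumulative-logit fit; df = number of extra slope parameters).
    """
    chi2 = fit_simple.deviance - fit_complex.deviance
    if chi2 < -1e-6:
        raise ValueError(
            "complex model has higher deviance; models are not nested or a fit failed"
        )
    chi2 = max(chi2, 0.0)
    df = len(fit_simple.feature_names)
    return DevianceTest(
        chi2=float(chi2), df=df, p_value=float(chi2_dist.sf(chi2, df))
    )


def proportional_odds_lrt(X, y, feature_names=None) -> DevianceTest:
    """Convenience wrapper: PO fit vs unconstrained cumulative-logit fit."""
    simple = fit_proportional_odds(X, y, feature_names=feature_names)
    complex_ = fit_nonproportional(X, y, feature_names=feature_names, start=simple)
    return deviance_test(simple, complex_)


# ---------------------------------------------------------------------------
# Diagnostics


def po_diagnostics(X, y, feature_names=None) -> dict:
    """Numeric proportional-odds / ordinality diagnostics.

    Returns per-cutoff binary-logit slopes with a pooled-SE z for their
    difference (Brant-style), and per-feature observed vs PO-implied
    class-conditional means. Degenerate (separated) cutoffs are reported,
    not raised.
    """
    Xraw, names = _as_matrix(X, feature_names)
    codes, labels = _encode_labels(y)
    J = len(labels)
    fit = fit_proportional_odds(Xraw, y, feature_names=names)

    slope_rows = []
    degenerate = []
    per_cutoff = []
    for j in range(1, J):
        yj = (codes >= j).astype(int)
        try:
            # a 2-class PO fit IS binary logistic regression on the indicator
            bfit = fit_proportional_odds(Xraw, yj, feature_names=names)
            per_cutoff.append(bfit)
            for i, name in enumerate(names):
                slope_rows.append(
                    {
                        "feature": name,
                        "cutoff": j,
                        "slope": bfit.beta[i],
                        "se": bfit.se[1 + i],
                    }
                )
        except (SeparationError, ConvergenceError) as exc:
            degenerate.append({"cutoff": j, "reason": str(exc)})
    slopes = pd.DataFrame(slope_rows)

    diff_rows = []
    if not slopes.empty and slopes["cutoff"].nunique() == J - 1 and J == 3:
        for name in names:
            sub = slopes[slopes["feature"] == name].sort_values("cutoff")
            d = sub["slope"].iloc[0] - sub["slope"].iloc[1]
            se = float(np.hypot(*sub["se"]))
            z = d / se if se > 0 else np.inf
            diff_rows.append(
                {
                    "feature": name,
                    "slope_cut1": sub["slope"].iloc[0],
                    "slope_cut2": sub["slope"].iloc[1],
                    "diff_z": z,
                    "flag": bool(abs(z) > 2.0),
                }
            )
    slope_diff = pd.DataFrame(diff_rows)

    probs = predict_class_probs(fit, Xraw)
    ord_rows = []
    for j, lab in enumerate(labels):
        obs_mask = codes == j
        wj = probs[:, j]
        for i, name in enumerate(names):
            ord_rows.append(
                {
                    "feature": name,
                    "class": lab,
                    "observed_mean": float(Xraw[obs_mask, i].mean()),
                    "implied_mean": float(
                        np.sum(wj * Xraw[:, i]) / np.sum(wj)
                    ),
                }
            )
    return {
        "fit": fit,
        "cutoff_slopes": slopes,
        "slope_difference": slope_diff,
        "ordinality": pd.DataFrame(ord_rows),
        "degenerate_cutoffs": degenerate,
        "po_flag": bool(slope_diff["flag"].any()) if not slope_diff.empty else False,
    }


# ---------------------------------------------------------------------------
# Simulation-based quartile probability changes


@dataclass
class ClassProbabilityProfile:
    predictor: str
    class_labels: list[str]
    class_probs_at_q1: np.ndarray
    class_probs_at_q3: np.ndarray
    delta: np.ndarray
    delta_ci_low: np.ndarray
    delta_ci_high: np.ndarray
    p_values: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.class_labels,
                "prob_at_q1": self.class_probs_at_q1,
                "prob_at_q3": self.class_probs_at_q3,
                "delta": self.delta,
                "ci_low": self.delta_ci_low,
                "ci_high": self.delta_ci_high,
                "p_value": self.p_values,
            }
        )


def quartile_probability_change(
    fit: OrdinalFit,
    table: pd.DataFrame,
    predictor: str,
    n_draws: int = 1000,
    seed: int = 0,
) -> ClassProbabilityProfile:
    """Monte-Carlo change in class probabilities between predictor quartiles.

    Parameter vectors are drawn from N(estimates, covariance); per draw the
    class probabilities are evaluated with the predictor at its cohort Q3 vs
    Q1, the other predictors held at their cohort means. Reports mean delta,
    2.5/97.5 percentile interval, and two-sided simulation p-values.
    """
    if predictor not in fit.feature_names:
        raise ValueError(f"{predictor!r} is not a model feature")
    if n_draws < 100:
        raise ValueError("n_draws must be at least 100")
    J = len(fit.class_labels)
    try:
        chol = np.linalg.cholesky(fit.covariance)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular covariance matrix") from exc

    x_lo = np.array([table[f].mean() for f in fit.feature_names])
    x_hi = x_lo.copy()
    k = fit.feature_names.index(predictor)
    q1, q3 = np.quantile(table[predictor].to_numpy(dtype=float), [0.25, 0.75])
    x_lo[k], x_hi[k] = q1, q3

    rng = np.random.default_rng(seed)
    draws = fit.params + rng.standard_normal((n_draws, len(fit.params))) @ chol.T
    xc_lo = (x_lo - fit.centers)[None, :]
    xc_hi = (x_hi - fit.centers)[None, :]
    alpha = draws[:, : J - 1]
    beta = draws[:, J - 1 :]

    def probs(xc):
        z = alpha - (beta @ xc.T)  # n_draws x (J-1)
        gam = expit(z)
        full = np.hstack(
            [np.zeros((n_draws, 1)), gam, np.ones((n_draws, 1))]
        )
        return np.diff(full, axis=1)

    p_lo = probs(xc_lo)
    p_hi = probs(xc_hi)
    delta = p_hi - p_lo
    frac_pos = (delta > 0).mean(axis=0)
    frac_neg = (delta < 0).mean(axis=0)
    pvals = np.minimum(1.0, 2.0 * np.minimum(frac_pos, frac_neg))
    return ClassProbabilityProfile(
        predictor=predictor,
        class_labels=list(fit.class_labels),
        class_probs_at_q1=p_lo.mean(axis=0),
        class_probs_at_q3=p_hi.mean(axis=0),
        delta=delta.mean(axis=0),
        delta_ci_low=np.percentile(delta, 2.5, axis=0),
        delta_ci_high=np.percentile(delta, 97.5, axis=0),
        p_values=pvals,
    )


# ---------------------------------------------------------------------------
# Model (de)serialisation for the CLI


def fit_to_json(fit: OrdinalFit, path) -> None:
    payload = {
        "feature_names": fit.feature_names,
        "class_labels": fit.class_labels,
        "centers": fit.centers.tolist(),
        "beta": fit.beta.tolist(),
        "intercepts": fit.intercepts.tolist(),
        "covariance": fit.covariance.tolist(),
        "deviance": fit.deviance,
        "loglik": fit.loglik,
        "wald_z": fit.wald_z.tolist(),
        "wald_p": fit.wald_p.tolist(),
        "n_obs": fit.n_obs,
        "n_iter": fit.n_iter,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)


def fit_from_json(path) -> OrdinalFit:
    with open(path) as fh:
        d = json.load(fh)
    return OrdinalFit(
        feature_names=d["feature_names"],
        class_labels=d["class_labels"],
        centers=np.asarray(d["centers"]),
        beta=np.asarray(d["beta"]),
        intercepts=np.asarray(d["intercepts"]),
        covariance=np.asarray(d["covariance"]),
        deviance=d["deviance"],
        loglik=d["loglik"],
        wald_z=np.asarray(d["wald_z"]),
        wald_p=np.asarray(d["wald_p"]),
        n_obs=d["n_obs"],
        n_iter=d["n_iter"],
    )
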