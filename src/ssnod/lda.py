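"""Three-class linear discriminant analysis comparator.

Gaussian class-conditional model with a pooled within-class covariance and
empirical priors; posteriors follow from the linear discriminant rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ordinal import _as_matrix, _encode_labels


class SingularCovarianceError(np.linalg.LinAlgError):
    pass


@dataclass
class LdaFit:
    feature_names: list[str]
    class_labels: list[str]
    class_means: np.ndarray  # J x p
    pooled_covariance: np.ndarray  # p x p
    priors: np.ndarray  # J, sums to 1


def fit_lda(X, y, feature_names=None) -> LdaFit:
    Xm, names = _as_matrix(X, feature_names)
    codes, labels = _encode_labels(y)
    J = len(labels)
    n, p = Xm.shape
    counts = np.bincount(codes, minlength=J)
    if np.any(counts < p + 1):
        raise ValueError(f"each class needs at least {p + 1} samples")
    means = np.vstack([Xm[codes == j].mean(axis=0) for j in range(J)])
    resid = Xm - means[codes]
    pooled = resid.T @ resid / (n - J)
    try:
        np.linalg.cholesky(pooled)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError("pooled covariance is singular") from exc
    return LdaFit(
        feature_names=names,
        class_labels=labels,
        class_means=means,
        pooled_covariance=pooled,
        priors=counts / n,
    )


def predict_lda(fit: LdaFit, X) -> np.ndarray:
    """Posterior class probabilities; rows sum to 1."""
    single = False
    if isinstance(X, pd.DataFrame):
        X = X[fit.feature_names].to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
            single = True
    inv_m = np.linalg.solve(fit.pooled_covariance, fit.class_means.T)  # p x J
    disc = (
        X @ inv_m
        - 0.5 * np.einsum("jp,pj->j", fit.class_means, inv_m)[None, :]
        + np.log(fit.priors)[None, :]
    )
    disc -= disc.max(axis=1, keepdims=True)
    post = np.exp(disc)
    post /= post.sum(axis=1, keepdims=True)
    return post[0] if single else post
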