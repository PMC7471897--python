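"""Univariate feature screening by binary ROC-AUC, plus confounder-plot data.

The AUC is the tie-corrected Mann-Whitney statistic U/(n1*n0); its variance
and the test against AUC = 0.5 use DeLong's placement method. The Youden-
optimal operating point is searched over all midpoints between consecutive
distinct scores (higher sensitivity wins ties). A feature whose AUC is below
0.5 is reported in the flipped orientation (direction "less_or_equal").

Confounder-plot coordinates are absolute Spearman correlations: similarity
to the ordinal response (class rank H1=1 < H2=2 < H3=3) on one axis,
similarity to a reference predictor on the other — rank-based, hence
invariant to monotone feature transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, spearmanr

from .cohort import CLASS_LABELS


@dataclass(frozen=True)
class AucResult:
    feature: str
    auc: float
    ci_low: float
    ci_high: float
    sensitivity_pct: float
    specificity_pct: float
    best_threshold: float
    direction: str  # "greater" or "less_or_equal"
    p_value: float
    auc_variance: float


def _mw_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected Mann-Whitney AUC (probability score_pos > score_neg)."""
    r = rankdata(scores)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    return (r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance of the AUC via midrank placements."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_r = rankdata(np.concatenate([pos, neg]))
    v10 = (all_r[:m] - rankdata(pos)) / n  # placements of positives
    v01 = 1.0 - (all_r[m:] - rankdata(neg)) / m  # placements of negatives
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def _youden(scores: np.ndarray, labels: np.ndarray):
    """Best (sens, spec, threshold) for the rule `score > t`, maximising J.

    Candidate thresholds are midpoints between consecutive distinct scores
    (plus one below the minimum); ties in J resolve to the threshold with
    higher sensitivity, i.e. the smallest t.
    """
    uniq = np.unique(scores)
    cand = np.concatenate([[uniq[0] - 1.0], 0.5 * (uniq[:-1] + uniq[1:])])
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    sens = 1.0 - np.searchsorted(pos, cand, side="right") / pos.size
    spec = np.searchsorted(neg, cand, side="right") / neg.size
    j = sens + spec - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)[0]  # smallest t = highest sens
    return float(sens[best]), float(spec[best]), float(cand[best])


def roc_auc(scores, labels, feature: str = "") -> AucResult:
    """AUC with DeLong CI/test and the Youden-optimal operating point."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.size != labels.size:
        raise ValueError("scores and labels must have the same length")
    auc0 = _mw_auc(scores, labels)
    var = _delong_variance(scores, labels)
    if auc0 >= 0.5:
        direction, s, auc = "greater", scores, auc0
    else:
        direction, s, auc = "less_or_equal", -scores, 1.0 - auc0
    sens, spec, thr = _youden(s, labels)
    if direction == "less_or_equal":
        thr = -thr  # rule becomes `score <= t` on the original scale
    se = np.sqrt(var)
    if se > 0:
        z = (auc0 - 0.5) / se
        p = 2.0 * norm.sf(abs(z))
    else:
        p = 0.0 if auc != 0.5 else 1.0
    return AucResult(
        feature=feature,
        auc=float(auc),
        ci_low=float(max(0.0, auc - 1.96 * se)),
        ci_high=float(min(1.0, auc + 1.96 * se)),
        sensitivity_pct=100.0 * sens,
        specificity_pct=100.0 * spec,
        best_threshold=thr,
        direction=direction,
        p_value=float(p),
        auc_variance=float(var),
    )


def _binary_labels(classes: pd.Series, cutoff: int) -> np.ndarray:
    """Cutoff 1: H1 vs (H2 or H3); cutoff 2: (H1 or H2) vs H3. 1 = more invasive."""
    rank = classes.map({lab: i for i, lab in enumerate(CLASS_LABELS)})
    if rank.isna().any():
        raise ValueError("class labels must be H1/H2/H3")
    if cutoff == 1:
        return (rank >= 1).to_numpy().astype(int)
    if cutoff == 2:
        return (rank == 2).to_numpy().astype(int)
    raise ValueError("cutoff must be 1 or 2")


def screen_features(
    table: pd.DataFrame,
    cutoff: int,
    features=None,
    response: str = "class",
    alpha: float = 1e-3,
) -> pd.DataFrame:
    """Per-feature AUC screening at one ordinal cutoff, sorted by AUC descending.

    Features whose DeLong test against AUC = 0.5 fails P < ``alpha`` are
    flagged ``excluded``. Missing feature values raise with the offending rows.
    """
    if features is None:
        features = [
            c
            for c in table.columns
            if c != response and pd.api.types.is_numeric_dtype(table[c])
        ]
    bad = table.index[table[features].isna().any(axis=1)].tolist()
    if bad:
        raise ValueError(f"missing feature values in rows {bad}")
    y = _binary_labels(table[response], cutoff)
    rows = []
    for feat in features:
        res = roc_auc(table[feat].to_numpy(), y, feature=feat)
        rows.append(
            {
                "parameter": feat,
                "auc": res.auc,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "sensitivity_pct": res.sensitivity_pct,
                "specificity_pct": res.specificity_pct,
                "threshold": res.best_threshold,
                "direction": res.direction,
                "p_value": res.p_value,
                "excluded": res.p_value >= alpha,
            }
        )
    out = pd.DataFrame(rows).sort_values("auc", ascending=False, kind="stable")
    return out.reset_index(drop=True)


def _abs_spearman(a: np.ndarray, b: np.ndarray, name: str) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn(f"constant input for {name}; similarity set to 0")
        return 0.0
    return float(abs(spearmanr(a, b).statistic))


def confounder_plot_data(
    table: pd.DataFrame,
    response: str = "class",
    reference: str = "volume_log",
    features=None,
) -> pd.DataFrame:
    """Similarity-to-response vs similarity-to-reference per candidate feature.

    The recommended set collects features above the median response
    similarity and below the median reference similarity (the top-left
    corner of the confounder plot).
    """
    if reference not in table.columns:
        raise ValueError(f"reference feature {reference!r} not in table")
    if features is None:
        features = [
            c
            for c in table.columns
            if c not in (response, reference)
            and pd.api.types.is_numeric_dtype(table[c])
        ]
    y = table[response].map({lab: i + 1 for i, lab in enumerate(CLASS_LABELS)})
    ref = table[reference].to_numpy()
    rows = []
    for feat in features:
        x = table[feat].to_numpy()
        rows.append(
            {
                "feature_name": feat,
                "sim_response": _abs_spearman(x, y.to_numpy(), feat),
                "sim_reference": (
                    1.0 if feat == reference else _abs_spearman(x, ref, feat)
                ),
            }
        )
    out = pd.DataFrame(rows)
    med_resp = out["sim_response"].median()
    med_ref = out["sim_reference"].median()
    out["recommended"] = (out["sim_response"] > med_resp) & (
        out["sim_reference"] < med_ref
    )
    return out
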