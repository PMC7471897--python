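"""Monte-Carlo cross-validated discrimination and calibration assessment.

Repeated stratified 80/20 holdout (default 200 repeats): per repeat the
model is refit on the training split (feature centring recomputed on train
only) and evaluated on the held-out split at the two ordinal cutoffs —
cutoff 1 scores P(H2)+P(H3) against the indicator Y >= H2, cutoff 2 scores
P(H3) against Y = H3. Metrics per cutoff: Mann-Whitney AUC, the scaled
(normalised) Brier score in percent, and the average absolute calibration
error EAVG against a lowess-smoothed observed-frequency curve. Repeats with
a single-class test outcome at a cutoff are excluded from that metric's
summary and counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from statsmodels.nonparametric.smoothers_lowess import lowess

from .cohort import CLASS_LABELS
from .lda import fit_lda, predict_lda
from .ordinal import (
    SeparationError,
    fit_proportional_odds,
    predict_class_probs,
)
from .screening import _mw_auc, _youden


@dataclass(frozen=True)
class CvConfig:
    model_spec: str = "class ~ volume_log + FPC1"
    classifier: str = "ordinal"  # ordinal | binary_logit_pair | lda
    n_repeats: int = 200
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")
        if self.classifier not in ("ordinal", "binary_logit_pair", "lda"):
            raise ValueError(f"unknown classifier {self.classifier!r}")


def load_cv_config(path) -> CvConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return CvConfig(**raw)


def parse_formula(spec: str) -> tuple[str, list[str]]:
    """'class ~ volume_log + FPC1' -> ('class', ['volume_log', 'FPC1'])."""
    lhs, _, rhs = spec.partition("~")
    features = [f.strip() for f in rhs.split("+") if f.strip()]
    if not lhs.strip() or not features:
        raise ValueError(f"cannot parse model spec {spec!r}")
    return lhs.strip(), features


def stratified_split(labels, train_fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Per-class round-half-up 80/20 partition with >= 1 test sample per class."""
    labels = np.asarray(labels)
    train_idx, test_idx = [], []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 members")
        n_test = max(1, int(np.floor(idx.size * (1.0 - train_fraction) + 0.5)))
        perm = rng.permutation(idx)
        test_idx.append(perm[:n_test])
        train_idx.append(perm[n_test:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def brier_score(probs, outcomes) -> float:
    """Mean squared difference between predicted probabilities and outcomes."""
    p = np.asarray(probs, dtype=float)
    o = np.asarray(outcomes, dtype=float)
    if p.size != o.size or p.size == 0:
        raise ValueError("probs and outcomes must be equal-length, non-empty")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - o) ** 2))


def scaled_brier_pct(probs, outcomes) -> float:
    """100 * (1 - Brier/Brier_max); Brier_max is the prevalence predictor's score."""
    o = np.asarray(outcomes, dtype=float)
    prev = o.mean()
    bmax = prev * (1.0 - prev)
    if bmax == 0:
        raise ValueError("outcomes are single-level; the scaled score is undefined")
    return 100.0 * (1.0 - brier_score(probs, o) / bmax)


def calibration_error_eavg(probs, outcomes, frac: float = 2.0 / 3.0) -> float:
    """Mean |predicted - smoothed observed frequency| over the predictions.

    The observed-frequency curve is a lowess fit (span ``frac``, 0
    robustifying iterations) of the binary outcomes on the predicted
    probabilities, evaluated back at each prediction.
    """
    p = np.asarray(probs, dtype=float)
    o = np.asarray(outcomes, dtype=float)
    if p.size < 20:
        raise ValueError("EAVG needs at least 20 observations")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if np.ptp(p) == 0:
        warnings.warn("degenerate constant predictions; EAVG is |prevalence - prob|")
        return float(abs(o.mean() - p[0]))
    sm = lowess(o, p, frac=frac, it=0, return_sorted=True)
    cal = np.interp(p, sm[:, 0], np.clip(sm[:, 1], 0.0, 1.0))
    return float(np.mean(np.abs(p - cal)))


# ---------------------------------------------------------------------------


def _fit_predict(classifier, table_train, table_test, response, features):
    """Train one classifier and return test-set 3-class probabilities."""
    Xtr = table_train[features]
    ytr = table_train[response].to_numpy()
    Xte = table_test[features]
    if classifier == "ordinal":
        fit = fit_proportional_odds(Xtr, ytr)
        return predict_class_probs(fit, Xte)
    if classifier == "lda":
        fit = fit_lda(Xtr, ytr)
        return predict_lda(fit, Xte)
    if classifier == "binary_logit_pair":
        rank = pd.Series(ytr).map(
            {lab: i for i, lab in enumerate(CLASS_LABELS)}
        ).to_numpy()
        # two binary logistic fits (a 2-class PO fit is logistic regression)
        f1 = fit_proportional_odds(Xtr, (rank >= 1).astype(int))
        f2 = fit_proportional_odds(Xtr, (rank == 2).astype(int))
        q1 = predict_class_probs(f1, Xte)[:, 1]  # P(Y >= H2)
        q2 = predict_class_probs(f2, Xte)[:, 1]  # P(Y = H3)
        p2 = np.clip(q1 - q2, 0.0, None)
        probs = np.column_stack([1.0 - q1, p2, q2])
        return probs / probs.sum(axis=1, keepdims=True)
    raise ValueError(classifier)


METRIC_COLUMNS = [
    "auc1",
    "auc2",
    "brier1_scaled_pct",
    "brier2_scaled_pct",
    "eavg1",
    "eavg2",
]


@dataclass
class CvResult:
    config: CvConfig
    per_repeat: pd.DataFrame
    summary: pd.DataFrame
    n_excluded: dict = field(default_factory=dict)


def _cutoff_metrics(probs, rank_test):
    out = {}
    for cut, (score, outcome) in enumerate(
        [
            (probs[:, 1] + probs[:, 2], (rank_test >= 1).astype(int)),
            (probs[:, 2], (rank_test == 2).astype(int)),
        ],
        start=1,
    ):
        score = np.clip(score, 0.0, 1.0)
        if outcome.min() == outcome.max():
            out[f"auc{cut}"] = np.nan
            out[f"brier{cut}_scaled_pct"] = np.nan
            out[f"eavg{cut}"] = np.nan
            continue
        out[f"auc{cut}"] = _mw_auc(score, outcome)
        out[f"brier{cut}_scaled_pct"] = scaled_brier_pct(score, outcome)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[f"eavg{cut}"] = calibration_error_eavg(score, outcome)
        except ValueError:
            out[f"eavg{cut}"] = np.nan
    return out


def monte_carlo_cv(
    table: pd.DataFrame, config: CvConfig, response: str | None = None
) -> CvResult:
    """Repeated stratified holdout evaluation of one model/classifier."""
    resp, features = parse_formula(config.model_spec)
    if response is not None:
        resp = response
    missing = [f for f in features + [resp] if f not in table.columns]
    if missing:
        raise ValueError(f"table lacks columns {missing}")
    labels = table[resp].to_numpy()
    rank = pd.Series(labels).map(
        {lab: i for i, lab in enumerate(CLASS_LABELS)}
    ).to_numpy()
    rng = np.random.default_rng(config.seed)
    rows = []
    for rep in range(config.n_repeats):
        if config.stratified:
            tr, te = stratified_split(labels, config.train_fraction, rng)
        else:
            perm = rng.permutation(len(labels))
            n_test = max(1, int(np.floor(len(labels) * (1 - config.train_fraction) + 0.5)))
            te, tr = np.sort(perm[:n_test]), np.sort(perm[n_test:])
        try:
            probs = _fit_predict(
                config.classifier, table.iloc[tr], table.iloc[te], resp, features
            )
            metrics = _cutoff_metrics(probs, rank[te])
        except SeparationError:
            metrics = {c: np.nan for c in METRIC_COLUMNS}
        rows.append({"repeat": rep, **metrics})
    per_repeat = pd.DataFrame(rows)

    def _sum_col(col):
        vals = per_repeat[col].dropna().to_numpy()
        if vals.size == 0:
            return {"mean": np.nan, "p2.5": np.nan, "p97.5": np.nan}
        return {
            "mean": float(vals.mean()),
            "p2.5": float(np.percentile(vals, 2.5)),
            "p97.5": float(np.percentile(vals, 97.5)),
        }

    summary = pd.DataFrame({col: _sum_col(col) for col in METRIC_COLUMNS})
    n_excluded = {
        col: int(per_repeat[col].isna().sum()) for col in METRIC_COLUMNS
    }
    return CvResult(
        config=config, per_repeat=per_repeat, summary=summary, n_excluded=n_excluded
    )


def multiclass_report(
    table: pd.DataFrame,
    config: CvConfig,
    classifiers=("ordinal", "lda"),
    response: str | None = None,
) -> pd.DataFrame:
    """Cross-validated one-vs-rest AUC/sens/spec per class for each classifier."""
    resp, features = parse_formula(config.model_spec)
    if response is not None:
        resp = response
    labels = table[resp].to_numpy()
    rank = pd.Series(labels).map(
        {lab: i for i, lab in enumerate(CLASS_LABELS)}
    ).to_numpy()
    results = {
        clf: {lab: {"auc": [], "sens": [], "spec": []} for lab in CLASS_LABELS}
        for clf in classifiers
    }
    rng = np.random.default_rng(config.seed)
    for _ in range(config.n_repeats):
        tr, te = stratified_split(labels, config.train_fraction, rng)
        for clf in classifiers:
            try:
                probs = _fit_predict(
                    clf, table.iloc[tr], table.iloc[te], resp, features
                )
            except SeparationError:
                continue
            for j, lab in enumerate(CLASS_LABELS):
                yj = (rank[te] == j).astype(int)
                if yj.min() == yj.max():
                    continue
                results[clf][lab]["auc"].append(_mw_auc(probs[:, j], yj))
                sens, spec, _ = _youden(probs[:, j], yj)
                results[clf][lab]["sens"].append(sens)
                results[clf][lab]["spec"].append(spec)
    rows = []
    for clf in classifiers:
        for lab in CLASS_LABELS:
            r = results[clf][lab]
            rows.append(
                {
                    "classifier": clf,
                    "class": lab,
                    "auc_ovr": float(np.mean(r["auc"])) if r["auc"] else np.nan,
                    "sensitivity_pct": (
                        100.0 * float(np.mean(r["sens"])) if r["sens"] else np.nan
                    ),
                    "specificity_pct": (
                        100.0 * float(np.mean(r["spec"])) if r["spec"] else np.nan
                    ),
                    "n_repeats_used": len(r["auc"]),
                }
            )
    return pd.DataFrame(rows)
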