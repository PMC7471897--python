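"""Numeric report tables mirroring the published table layouts.

All CSV output is deterministic (fixed float formatting, LF line endings)
so identical seeds produce byte-identical reports.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ordinal import ClassProbabilityProfile, OrdinalFit, odds_ratios
from .validation import CvResult

PRINT_LABELS = {
    "min_diameter_mm": "Min. diameter (mm)",
    "max_diameter_mm": "Max. diameter (mm)",
    "average_diameter_mm": "Average diameter (mm)",
    "maxmin_ratio": "Max./min. diam ratio",
    "consolidation_ratio": "Consolidation ratio",
    "volume_mm3": "Volume (mm^3)",
    "volume_log": "Volume (log)",
    "mean_hu": "Mean (HU)",
    "sd_hu": "SD (HU)",
    "skewness": "Skewness",
    "kurtosis": "Kurtosis",
    "iqr_hu": "IQR (HU)",
    "q50_hu": "Q.50 (HU)",
    "q75_hu": "Q.75 (HU)",
    "q875_hu": "Q.875 (HU)",
    "FPC1": "FPC1",
    "FPC2": "FPC2",
}


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")


def screening_report(screened: pd.DataFrame) -> pd.DataFrame:
    """AUC-screening table with printed labels and integer percents."""
    out = screened.copy()
    out["parameter"] = out["parameter"].map(lambda c: PRINT_LABELS.get(c, c))
    out["sensitivity_pct"] = out["sensitivity_pct"].round().astype(int)
    out["specificity_pct"] = out["specificity_pct"].round().astype(int)
    out["threshold_rule"] = [
        ("> " if d == "greater" else "<= ") + f"{t:.4g}"
        for d, t in zip(out["direction"], out["threshold"])
    ]
    cols = [
        "parameter",
        "auc",
        "ci_low",
        "ci_high",
        "sensitivity_pct",
        "specificity_pct",
        "threshold_rule",
        "p_value",
        "excluded",
    ]
    return out[cols]


def fit_report(fit: OrdinalFit) -> pd.DataFrame:
    """Coefficient/OR/intercept rows in the style of the model-estimate table."""
    ors = odds_ratios(fit)
    rows = []
    for _, r in ors.iterrows():
        rows.append(
            {
                "term": PRINT_LABELS.get(r["feature"], r["feature"]),
                "kind": "coefficient",
                "estimate": r["coefficient"],
                "ci_low": r["coef_ci_low"],
                "ci_high": r["coef_ci_high"],
                "odds_ratio": r["odds_ratio"],
                "or_ci_low": r["or_ci_low"],
                "or_ci_high": r["or_ci_high"],
                "wald_p": r["wald_p"],
            }
        )
    J = len(fit.class_labels)
    se = fit.se[: J - 1]
    cut_names = [
        "H1 vs H2 or H3 (Y <= H1)",
        "H1 or H2 vs H3 (Y <= H2)",
    ]
    for j, (a, s) in enumerate(zip(fit.intercepts, se)):
        rows.append(
            {
                "term": cut_names[j] if j < len(cut_names) else f"intercept {j + 1}",
                "kind": "intercept",
                "estimate": a,
                "ci_low": a - 1.96 * s,
                "ci_high": a + 1.96 * s,
                "odds_ratio": np.nan,
                "or_ci_low": np.nan,
                "or_ci_high": np.nan,
                "wald_p": fit.wald_p[j],
            }
        )
    return pd.DataFrame(rows)


def probability_change_report(profiles: list[ClassProbabilityProfile]) -> pd.DataFrame:
    """Quartile class-probability changes, one block per predictor."""
    frames = []
    for prof in profiles:
        df = prof.as_frame()
        df.insert(0, "predictor", PRINT_LABELS.get(prof.predictor, prof.predictor))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def cv_report(result: CvResult) -> pd.DataFrame:
    """Cross-validation summary shaped like the predictive-performance table."""
    s = result.summary
    out = s.rename(
        columns={
            "auc1": "AUC1",
            "auc2": "AUC2",
            "brier1_scaled_pct": "Brier1 (%)",
            "brier2_scaled_pct": "Brier2 (%)",
            "eavg1": "EAVG1",
            "eavg2": "EAVG2",
        }
    )
    out.insert(0, "statistic", ["Mean", "2.5%", "97.5%"])
    return out.reset_index(drop=True)
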