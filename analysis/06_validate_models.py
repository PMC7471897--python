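#!/usr/bin/env python
"""Monte-Carlo cross-validated performance of both final models.

200-repeat stratified 80/20 holdout: per-cutoff AUC, scaled Brier score and
calibration EAVG for the ordinal models, plus a one-vs-rest multiclass
comparison of the ordinal classifier against 3-class LDA. Writes the
summary tables under results/validation/.
"""

from pathlib import Path

import pandas as pd

from ssnod.reports import cv_report, write_csv
from ssnod.validation import CvConfig, monte_carlo_cv, multiclass_report

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 20260920
SPECS = {
    "model1": "class ~ volume_log + FPC1",
    "model2": "class ~ volume_log + q875_hu",
}


def main() -> None:
    table = pd.read_csv(ROOT / "features.csv")
    out = ROOT / "validation"
    out.mkdir(parents=True, exist_ok=True)
    for name, spec in SPECS.items():
        cfg = CvConfig(model_spec=spec, n_repeats=200, seed=SEED)
        res = monte_carlo_cv(table, cfg)
        write_csv(cv_report(res), out / f"{name}_cv_summary.csv")
        s = res.summary
        print(f"{name} ({spec}), 200-repeat MC-CV:")
        print(f"  AUC1 {s.loc['mean', 'auc1']:.3f}  AUC2 {s.loc['mean', 'auc2']:.3f}"
              f"  Brier1 {s.loc['mean', 'brier1_scaled_pct']:.1f}%"
              f"  Brier2 {s.loc['mean', 'brier2_scaled_pct']:.1f}%"
              f"  EAVG1 {s.loc['mean', 'eavg1']:.3f}  EAVG2 {s.loc['mean', 'eavg2']:.3f}")
        if any(res.n_excluded.values()):
            print("  excluded degenerate repeats:", res.n_excluded)
    cfg = CvConfig(model_spec=SPECS["model2"], n_repeats=200, seed=SEED)
    mc = multiclass_report(table, cfg, classifiers=("ordinal", "lda"))
    write_csv(mc, out / "multiclass_report.csv")
    print("one-vs-rest AUCs (model 2 predictors):")
    for _, r in mc.iterrows():
        print(f"  {r['classifier']:>7} {r['class']}: AUC {r['auc_ovr']:.2f}")


if __name__ == "__main__":
    main()
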