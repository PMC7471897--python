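#!/usr/bin/env python
"""Univariate ROC-AUC screening at both ordinal cutoffs + confounder plot.

Writes the two screening tables and the similarity coordinates under
results/screening/, and prints the features recommended for model building
(high similarity to the class response, low similarity to volume(log)).
"""

from pathlib import Path

import pandas as pd

from ssnod.reports import screening_report, write_csv
from ssnod.screening import confounder_plot_data, screen_features

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = pd.read_csv(ROOT / "features.csv")
    out = ROOT / "screening"
    out.mkdir(parents=True, exist_ok=True)
    feats = [c for c in table.columns if c not in ("nodule_id", "class", "solid_diameter_mm")]
    for cutoff, name, desc in (
        (2, "screen_h12_vs_h3.csv", "H1 or H2 vs H3"),
        (1, "screen_h1_vs_h23.csv", "H1 vs H2 or H3"),
    ):
        res = screen_features(table, cutoff, features=feats)
        write_csv(screening_report(res), out / name)
        top = res.iloc[0]
        print(f"{desc}: best feature {top['parameter']} "
              f"(AUC {top['auc']:.2f}), {int(res['excluded'].sum())} excluded")
    conf = confounder_plot_data(table, reference="volume_log", features=feats)
    write_csv(conf, out / "confounder_plot.csv")
    rec = conf.loc[conf["recommended"], "feature_name"].tolist()
    print("confounder-plot recommended set:", rec)


if __name__ == "__main__":
    main()
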