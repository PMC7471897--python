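#!/usr/bin/env python
"""Recompute first-order attenuation features from the stored histograms.

Reads results/cohort/, merges the geometric sidecar, and writes the cohort
feature table results/features.csv (one row per nodule).
"""

from pathlib import Path

import pandas as pd

from ssnod.features import attenuation_features_from_histogram
from ssnod.pipeline import ATTENUATION_COLUMNS, GEOMETRIC_COLUMNS
from ssnod.reports import write_csv

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    sidecar = pd.read_csv(ROOT / "cohort" / "nodules.csv")
    hists = pd.read_csv(ROOT / "cohort" / "histograms.csv")
    rows = []
    for nid, grp in hists.groupby("nodule_id", sort=False):
        a = attenuation_features_from_histogram(
            grp["hu_bin_left"].to_numpy(), grp["count"].to_numpy()
        )
        rows.append({"nodule_id": nid, **{c: getattr(a, c) for c in ATTENUATION_COLUMNS}})
    keep = ["nodule_id", "class", "solid_diameter_mm"] + GEOMETRIC_COLUMNS
    table = sidecar[keep].merge(pd.DataFrame(rows), on="nodule_id", how="inner")
    write_csv(table, ROOT / "features.csv")
    print(f"extracted {len(ATTENUATION_COLUMNS)} attenuation + "
          f"{len(GEOMETRIC_COLUMNS)} geometric features for {len(table)} nodules")
    by_class = table.groupby("class")[["mean_hu", "q875_hu", "volume_log"]].mean()
    print("class means:\n", by_class.round(1))


if __name__ == "__main__":
    main()
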