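"""Cohort-level plumbing: nodules -> feature table -> FPC scores.

Glues the per-nodule extractors into the cohort feature CSV the modelling
stages consume. Column names are the machine-readable counterparts of the
printed feature labels (see ``reports.PRINT_LABELS``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import features as feat
from . import fpca
from .cohort import NoduleSample

GEOMETRIC_COLUMNS = [
    "min_diameter_mm",
    "max_diameter_mm",
    "average_diameter_mm",
    "maxmin_ratio",
    "consolidation_ratio",
    "volume_mm3",
    "volume_log",
]
ATTENUATION_COLUMNS = [
    "mean_hu",
    "sd_hu",
    "skewness",
    "kurtosis",
    "iqr_hu",
    "q50_hu",
    "q75_hu",
    "q875_hu",
]


def extract_feature_table(samples: list[NoduleSample]) -> pd.DataFrame:
    """One row per nodule: geometric + first-order attenuation features."""
    rows = []
    for i, s in enumerate(samples):
        if s.mask is None:
            raise ValueError("voxel masks are required; use the histogram pathway")
        g = feat.compute_geometric_features(s.mask, s.spacing_mm, s.solid_diameter_mm)
        a = feat.compute_attenuation_features(s.hu_values)
        rows.append(
            {
                "nodule_id": s.nodule_id or f"n{i:03d}",
                "class": s.class_label,
                "solid_diameter_mm": s.solid_diameter_mm,
                **{c: getattr(g, c) for c in GEOMETRIC_COLUMNS},
                **{c: getattr(a, c) for c in ATTENUATION_COLUMNS},
            }
        )
    return pd.DataFrame(rows)


def histograms_from_samples(samples: list[NoduleSample]) -> pd.DataFrame:
    """Long-format 1-HU histograms (nodule_id, hu_bin_left, count)."""
    rows = []
    for i, s in enumerate(samples):
        nid = s.nodule_id or f"n{i:03d}"
        left = np.floor(s.hu_values).astype(int)
        vals, counts = np.unique(left, return_counts=True)
        for v, c in zip(vals, counts):
            rows.append({"nodule_id": nid, "hu_bin_left": int(v), "count": int(c)})
    return pd.DataFrame(rows)


def curves_from_histograms(histograms: pd.DataFrame) -> dict[str, np.ndarray]:
    """Smoothed density -> LQD curve per nodule, keyed by nodule_id."""
    out = {}
    for nid, grp in histograms.groupby("nodule_id", sort=False):
        curve = fpca.histogram_to_density(
            histogram=(grp["hu_bin_left"].to_numpy(), grp["count"].to_numpy())
        )
        out[str(nid)] = fpca.lqd_transform(curve)
    return out


def add_fpca_scores(
    table: pd.DataFrame,
    lqd_by_id: dict[str, np.ndarray],
    K: int = 2,
) -> tuple[pd.DataFrame, fpca.FpcaModel]:
    """Fit cohort-wide FPCA (anchored on Q.875) and append FPC columns."""
    ids = table["nodule_id"].astype(str).tolist()
    missing = [i for i in ids if i not in lqd_by_id]
    if missing:
        raise ValueError(f"no attenuation curve for nodules {missing[:5]}")
    curves = np.vstack([lqd_by_id[i] for i in ids])
    anchor = table["q875_hu"].to_numpy() if "q875_hu" in table.columns else None
    model = fpca.fit_fpca(curves, K=K, anchor=anchor)
    out = table.copy()
    for k in range(K):
        out[f"FPC{k + 1}"] = model.scores[:, k]
    return out, model


def build_cohort_table(
    samples: list[NoduleSample], K: int = 2
) -> tuple[pd.DataFrame, fpca.FpcaModel]:
    """Full extraction pipeline for an in-memory cohort."""
    table = extract_feature_table(samples)
    hists = histograms_from_samples(samples)
    lqd = curves_from_histograms(hists)
    return add_fpca_scores(table, lqd, K=K)
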