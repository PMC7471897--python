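"""First-order CT features of a segmented nodule.

Geometric features come from the binary mask (physical voxel spacing in mm);
attenuation features are order statistics and sample moments of the in-mask
HU values. Conventions, since workstation rules are vendor-specific:

* ``max_diameter_mm`` — largest pairwise 3-D distance between in-mask voxel
  centers (convex-hull accelerated).
* ``min_diameter_mm`` — smallest extent of the PCA-aligned bounding box of
  the voxel centers, floored at one voxel spacing.
* quantiles — linear interpolation between order statistics at
  p(k) = (k-1)/(n-1) (numpy's default rule).
* kurtosis — non-excess (a normal distribution scores 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew


@dataclass(frozen=True)
class GeometricFeatures:
    min_diameter_mm: float
    max_diameter_mm: float
    average_diameter_mm: float
    volume_mm3: float
    volume_log: float
    maxmin_ratio: float
    consolidation_ratio: float


@dataclass(frozen=True)
class AttenuationFeatures:
    mean_hu: float
    sd_hu: float
    skewness: float
    kurtosis: float
    q50_hu: float
    q75_hu: float
    q875_hu: float
    iqr_hu: float


def _max_pairwise_distance(points: np.ndarray) -> float:
    if len(points) > 16:
        try:
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear) masks: brute force below
    return float(pdist(points).max())


def compute_geometric_features(
    mask: np.ndarray,
    spacing_mm,
    solid_diameter_mm: float,
) -> GeometricFeatures:
    """Geometric feature set from a binary mask and the measured solid diameter."""
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing_mm, dtype=float)
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise ValueError("mask is empty")
    if np.any(spacing <= 0):
        raise ValueError("voxel spacing must be positive")
    if solid_diameter_mm < 0:
        raise ValueError("solid_diameter_mm must be non-negative")

    coords = np.argwhere(mask).astype(float) * spacing
    max_d = _max_pairwise_distance(coords) if n_vox > 1 else float(spacing.max())
    centered = coords - coords.mean(axis=0)
    # PCA-aligned bounding box; extents measured between voxel centers
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt.T
    extents = proj.max(axis=0) - proj.min(axis=0)
    min_d = float(max(extents.min(), spacing.max()))

    if solid_diameter_mm > max_d * (1.0 + 1e-9):
        raise ValueError(
            f"solid diameter {solid_diameter_mm:.2f} mm exceeds nodule "
            f"maximum diameter {max_d:.2f} mm"
        )
    volume = n_vox * float(np.prod(spacing))
    return GeometricFeatures(
        min_diameter_mm=min_d,
        max_diameter_mm=max_d,
        average_diameter_mm=0.5 * (min_d + max_d),
        volume_mm3=volume,
        volume_log=float(np.log10(volume)),
        maxmin_ratio=max_d / min_d,
        consolidation_ratio=solid_diameter_mm / max_d,
    )


def compute_attenuation_features(hu_values) -> AttenuationFeatures:
    """First-order histogram features of the in-mask HU sample (n >= 4)."""
    x = np.asarray(hu_values, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("at least 4 HU values are required (kurtosis contract)")
    q25, q50, q75, q875 = np.quantile(x, [0.25, 0.50, 0.75, 0.875])
    return AttenuationFeatures(
        mean_hu=float(x.mean()),
        sd_hu=float(x.std(ddof=1)),
        skewness=float(_skew(x)),
        kurtosis=float(_kurtosis(x, fisher=False)),
        q50_hu=float(q50),
        q75_hu=float(q75),
        q875_hu=float(q875),
        iqr_hu=float(q75 - q25),
    )


def attenuation_features_from_histogram(
    bin_left, counts, bin_width: float = 1.0
) -> AttenuationFeatures:
    """Attenuation features from (bin_left, count) pairs using bin midpoints.

    Counts are expanded at the midpoints, so the result matches
    :func:`compute_attenuation_features` applied to midpoint-quantised data.
    """
    bin_left = np.asarray(bin_left, dtype=float)
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("histogram counts must be non-negative")
    mids = bin_left + 0.5 * bin_width
    x = np.repeat(mids, counts.astype(int))
    return compute_attenuation_features(x)
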