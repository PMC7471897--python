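"""Attenuation density curves, log-quantile-density transform, functional PCA.

Each nodule's HU histogram is smoothed into a density f on a 1-HU grid over
its support. Densities are mapped into the unconstrained log-quantile-density
(LQD) space psi(t) = -log f(Q(t)), t in [0, 1], where Q is the quantile
function; functional PCA is then an eigendecomposition of the sample
covariance operator of the LQD curves, discretised with trapezoid quadrature
on a common 101-point t-grid. FPC scores are quadrature inner products of
the centred curves with the eigenfunctions.

Sign conventions in FPCA are arbitrary; eigenfunctions are flipped so their
score vector correlates positively with a per-curve anchor (Q.875 in the
pipeline), falling back to a positive integral over t in [0.75, 1]. This
pins FPC1's clinical direction: high FPC1 = heterogeneous, high-attenuation
curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter1d

from .cohort import HU_MAX, HU_MIN

T_GRID = np.linspace(0.0, 1.0, 101)
DENSITY_FLOOR = 1e-6


class ZeroVarianceError(ValueError):
    """All HU values identical: a zero-variance density has no LQD image."""


@dataclass
class AttenuationCurve:
    """Smoothed HU density on its support grid, plus (optionally) its LQD."""

    hu_grid: np.ndarray
    density: np.ndarray
    t_grid: np.ndarray = field(default_factory=lambda: T_GRID.copy())
    lqd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hu_grid = np.asarray(self.hu_grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.hu_grid.ndim != 1 or self.hu_grid.size < 2:
            raise ValueError("hu_grid must be a 1-D array with >= 2 points")
        if np.any(np.diff(self.hu_grid) <= 0):
            raise ValueError("hu_grid must be strictly increasing")
        if self.density.shape != self.hu_grid.shape:
            raise ValueError("density and hu_grid must have the same shape")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")


def silverman_bandwidth(x, weights=None) -> float:
    """Silverman's rule 0.9 * min(sd, IQR/1.34) * n^(-1/5) (weighted variant)."""
    x = np.asarray(x, dtype=float)
    if weights is None:
        n = x.size
        sd = x.std(ddof=1)
        q25, q75 = np.quantile(x, [0.25, 0.75])
    else:
        w = np.asarray(weights, dtype=float)
        n = w.sum()
        mu = np.average(x, weights=w)
        sd = np.sqrt(np.average((x - mu) ** 2, weights=w) * n / max(n - 1, 1))
        order = np.argsort(x)
        cw = np.cumsum(w[order]) / n
        q25, q75 = np.interp([0.25, 0.75], cw, x[order])
    spread = min(sd, (q75 - q25) / 1.34) if q75 > q25 else sd
    if spread <= 0:
        raise ZeroVarianceError(
            "zero-variance HU sample; add +/-0.5 HU jitter before smoothing"
        )
    return 0.9 * spread * n ** (-0.2)


def histogram_to_density(
    hu_values=None,
    histogram=None,
    bandwidth="auto",
    grid_step: float = 1.0,
    pad_bandwidths: float = 4.0,
) -> AttenuationCurve:
    """Gaussian-kernel smoothed density from raw HU values or a histogram.

    ``histogram`` is a (bin_left, count) pair with 1-HU bins. The grid spans
    the data range padded by ``pad_bandwidths`` kernel widths, clipped to
    [-1024, 400]; the density is floored at 1e-6 per HU then renormalised so
    its trapezoid integral is exactly 1.
    """
    if (hu_values is None) == (histogram is None):
        raise ValueError("provide exactly one of hu_values or histogram")
    if hu_values is not None:
        x = np.asarray(hu_values, dtype=float).ravel()
        if x.size < 10:
            raise ValueError("at least 10 voxels are required for smoothing")
        if x.min() < HU_MIN or x.max() > HU_MAX:
            raise ValueError("HU values outside [-1024, 400]")
        weights = None
        lo_data, hi_data = x.min(), x.max()
    else:
        bin_left, counts = histogram
        bin_left = np.asarray(bin_left, dtype=float)
        counts = np.asarray(counts, dtype=float)
        keep = counts > 0
        x = bin_left[keep] + 0.5  # 1-HU bin midpoints
        weights = counts[keep]
        if weights.sum() < 10:
            raise ValueError("at least 10 voxels are required for smoothing")
        lo_data, hi_data = x.min(), x.max()

    h = silverman_bandwidth(x, weights) if bandwidth == "auto" else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")

    lo = max(HU_MIN, np.floor(lo_data - pad_bandwidths * h))
    hi = min(HU_MAX, np.ceil(hi_data + pad_bandwidths * h))
    grid = np.arange(lo, hi + 0.5 * grid_step, grid_step)
    edges = np.concatenate([grid - 0.5 * grid_step, [grid[-1] + 0.5 * grid_step]])
    counts_on_grid, _ = np.histogram(x, bins=edges, weights=weights)
    n = counts_on_grid.sum()
    dens = gaussian_filter1d(
        counts_on_grid.astype(float), sigma=h / grid_step, mode="constant"
    ) / (n * grid_step)
    dens = np.maximum(dens, DENSITY_FLOOR)
    dens /= np.trapezoid(dens, grid)
    return AttenuationCurve(hu_grid=grid, density=dens)


def lqd_transform(curve: AttenuationCurve, t_grid=None) -> np.ndarray:
    """psi(t) = -log f(Q(t)) on the curve's t-grid; stores it on the curve."""
    t = np.asarray(t_grid, dtype=float) if t_grid is not None else curve.t_grid
    cdf = cumulative_trapezoid(curve.density, curve.hu_grid, initial=0.0)
    total = cdf[-1]
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"density integrates to {total:.8f}, not 1")
    cdf = cdf / total
    if np.any(np.diff(cdf) <= 0):
        raise ValueError("CDF is not strictly increasing; floor the density first")
    quantile = np.interp(t, cdf, curve.hu_grid)
    f_at_q = np.interp(quantile, curve.hu_grid, curve.density)
    psi = -np.log(f_at_q)
    if t_grid is None:
        curve.lqd = psi
    return psi


def lqd_to_density(lqd, q0: float, t_grid=None):
    """Invert the LQD map: returns (hu points Q(t), density f(Q(t))).

    Q(t) = q0 + int_0^t exp(psi) ds since Q'(t) = 1/f(Q(t)) = exp(psi(t)).
    """
    psi = np.asarray(lqd, dtype=float)
    t = np.asarray(t_grid, dtype=float) if t_grid is not None else T_GRID
    hu = q0 + cumulative_trapezoid(np.exp(psi), t, initial=0.0)
    return hu, np.exp(-psi)


def trapezoid_weights(t: np.ndarray) -> np.ndarray:
    w = np.empty_like(t)
    w[1:-1] = 0.5 * (t[2:] - t[:-2])
    w[0] = 0.5 * (t[1] - t[0])
    w[-1] = 0.5 * (t[-1] - t[-2])
    return w


@dataclass
class FpcaModel:
    """Mean LQD curve plus the leading eigenstructure of the LQD ensemble."""

    t_grid: np.ndarray
    mean_lqd: np.ndarray
    eigenfunctions: np.ndarray  # K x len(t_grid)
    eigenvalues: np.ndarray  # K, non-increasing
    variance_fraction: np.ndarray  # K, eigenvalue / total variance
    scores: np.ndarray  # n x K training scores (centred)
    n_curves: int


def fit_fpca(curves, K: int = 2, anchor=None) -> FpcaModel:
    """Functional PCA of LQD curves sharing the common t-grid.

    ``anchor`` (optional, one scalar per curve, e.g. Q.875) orients each
    eigenfunction so its scores correlate positively with the anchor;
    without it the sign is fixed by a positive integral on t in [0.75, 1].
    """
    Psi = np.asarray(curves, dtype=float)
    if Psi.ndim != 2:
        raise ValueError("curves must be a 2-D array (n_curves x grid)")
    n, m = Psi.shape
    if m != T_GRID.size:
        raise ValueError(f"curves must sit on the {T_GRID.size}-point t-grid")
    if K < 1 or K > min(n - 1, m):
        raise ValueError(f"K={K} exceeds the available rank min(n-1, m)")

    t = T_GRID
    w = trapezoid_weights(t)
    sqw = np.sqrt(w)
    mu = Psi.mean(axis=0)
    R = Psi - mu
    cov = R.T @ R / max(n - 1, 1)
    B = sqw[:, None] * cov * sqw[None, :]
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()

    phi = (evecs[:, :K] / sqw[:, None]).T  # K x m, orthonormal under w
    scores = R @ (phi * w[None, :]).T  # n x K

    anchor_arr = None if anchor is None else np.asarray(anchor, dtype=float)
    for k in range(K):
        flip = False
        if anchor_arr is not None and np.std(scores[:, k]) > 0 and np.std(anchor_arr) > 0:
            flip = np.corrcoef(scores[:, k], anchor_arr)[0, 1] < 0
        else:
            tail = t >= 0.75
            flip = float(np.sum(w[tail] * phi[k, tail])) < 0
        if flip:
            phi[k] = -phi[k]
            scores[:, k] = -scores[:, k]

    # guard the zero-covariance case (identical curves): numerical eigenvalues
    # of order eps**2 must not be promoted into variance fractions
    tiny = 1e-10 * max(1.0, float(np.mean(Psi**2)))
    frac = evals[:K] / total if total > tiny else np.zeros(K)
    return FpcaModel(
        t_grid=t.copy(),
        mean_lqd=mu,
        eigenfunctions=phi,
        eigenvalues=evals[:K],
        variance_fraction=frac,
        scores=scores,
        n_curves=n,
    )


def project(model: FpcaModel, lqd) -> np.ndarray:
    """FPC scores of one LQD curve on the model grid."""
    psi = np.asarray(lqd, dtype=float)
    if psi.shape != model.t_grid.shape:
        raise ValueError("curve grid does not match the model t-grid")
    w = trapezoid_weights(model.t_grid)
    return (model.eigenfunctions * (w * (psi - model.mean_lqd))[None, :]).sum(axis=1)


def save_model(model: FpcaModel, path) -> None:
    payload = {
        "t_grid": model.t_grid.tolist(),
        "mean_lqd": model.mean_lqd.tolist(),
        "eigenfunctions": model.eigenfunctions.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
        "variance_fraction": model.variance_fraction.tolist(),
        "n_curves": model.n_curves,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)


def load_model(path) -> FpcaModel:
    with open(path) as fh:
        payload = json.load(fh)
    return FpcaModel(
        t_grid=np.asarray(payload["t_grid"]),
        mean_lqd=np.asarray(payload["mean_lqd"]),
        eigenfunctions=np.asarray(payload["eigenfunctions"]),
        eigenvalues=np.asarray(payload["eigenvalues"]),
        variance_fraction=np.asarray(payload["variance_fraction"]),
        scores=np.zeros((0, len(payload["eigenvalues"]))),
        n_curves=payload["n_curves"],
    )
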