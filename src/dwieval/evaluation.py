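"""Cross-validated model accuracy: RMSE, relative RMSE, SNR, and the
number-of-directions subsampling experiment.

Model accuracy is scored against test-retest reliability.  With two
repeated scans D1 and D2 and model predictions M1 (fit on D1) and M2
(fit on D2), the relative RMSE is

    rRMSE = (RMSE(M1, D2) + RMSE(M2, D1)) / (2 * RMSE(D1, D2))

A model that simply memorizes its training data scores exactly 1; a
model that perfectly predicts the noiseless signal has expectation
1/sqrt(2) ~= 0.707 under IID Gaussian noise, because the numerator sees
one noise sample per comparison while the denominator sees two.
The statistic is scale-invariant, so raw scanner units and
S0-normalized signals give the same value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import (
    GradientTable,
    VoxelSignal,
    electrostatic_sphere,
    pairwise_axial_angles,
)
from . import dtm as _dtm
from . import sfm as _sfm

__all__ = [
    "rmse",
    "rrmse_pair",
    "snr",
    "c4",
    "subsample_directions",
    "rrmse_map",
    "directions_curve",
    "bootstrap_median_ci",
]


def rmse(x: np.ndarray, y: np.ndarray) -> float:
    """Root mean square difference sqrt(mean((x - y)^2))."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size == 0:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def rrmse_pair(d1, d2, m1, m2) -> float:
    """Cross-validated relative RMSE for one voxel.

    ``m1`` must be the prediction of the model fit on ``d1`` (scored
    against ``d2``) and vice versa.  Returns NaN when the test-retest
    RMSE is zero (identical repeats).
    """
    denom = rmse(d1, d2)
    if denom == 0:
        return float("nan")
    return (rmse(m1, d2) + rmse(m2, d1)) / (2.0 * denom)


def c4(n: int) -> float:
    """Gaussian small-sample bias factor of the sample standard deviation:
    E[s] = c4(n) * sigma for n IID normal samples."""
    if n < 2:
        raise ValueError("c4 requires n >= 2")
    return float(
        np.sqrt(2.0 / (n - 1)) * np.exp(gammaln(n / 2.0) - gammaln((n - 1) / 2.0))
    )


def snr(voxel: VoxelSignal) -> float:
    """Per-voxel SNR = mean(DWI signal) / sigma.

    sigma is the sample standard deviation of the b0 measurements
    divided by c4(n) to remove small-sample bias.  Returns +inf when the
    b0 values are constant.
    """
    s0 = voxel.s0_measurements
    if s0.size < 2:
        raise ValueError("SNR needs at least 2 b0 measurements")
    mu = float(np.mean(voxel.sb))
    sigma = float(np.std(s0, ddof=1)) / c4(s0.size)
    if sigma == 0:
        return float("inf")
    return mu / sigma


def _align_first_point(points: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Minimal rotation taking points[0] onto target (axially)."""
    a = points[0] / np.linalg.norm(points[0])
    b = np.asarray(target, dtype=float)
    b = b / np.linalg.norm(b)
    if a @ b < 0:
        a = -a  # axial: rotate the nearer antipode
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        return points.copy()
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    return points @ rot.T


def _greedy_match(ideal: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    available = np.ones(dirs.shape[0], dtype=bool)
    chosen = []
    for p in ideal:
        ang = pairwise_axial_angles(p[None, :], dirs).ravel()
        ang[~available] = np.inf
        k = int(np.argmin(ang))
        chosen.append(k)
        available[k] = False
    return np.array(chosen)


def subsample_directions(
    gtab: GradientTable, n: int, origin_index: int = 0, seed: int = 0,
    n_spins: int = 36,
) -> np.ndarray:
    """Pick ``n`` maximally separated measured directions.

    The ideal n-point electrostatic set is rotated so its first point
    lands on the measured direction at ``origin_index`` (an index into
    the non-b0 rows); each ideal point is then greedily matched to the
    nearest unused measured direction (antipodal-aware).  The residual
    spin about the origin axis is free, so ``n_spins`` evenly spaced
    spins are tried and the subset with the largest minimum pairwise
    angle kept.  Deterministic given the origin; returns full
    gradient-table indices.
    """
    dwi_idx = np.flatnonzero(gtab.dwi_mask)
    dirs = gtab.bvecs[dwi_idx]
    t = dirs.shape[0]
    if not (1 <= n <= t):
        raise ValueError(f"n must be in [1, {t}], got {n}")
    if n == t:
        return dwi_idx
    if n == 1:
        return dwi_idx[[origin_index]]
    ideal = _align_first_point(electrostatic_sphere(n, seed=seed), dirs[origin_index])
    axis = dirs[origin_index] / np.linalg.norm(dirs[origin_index])
    kx = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    best_chosen, best_sep = None, -1.0
    for spin in np.linspace(0.0, np.pi, n_spins, endpoint=False):
        rot = np.eye(3) + np.sin(spin) * kx + (1 - np.cos(spin)) * (kx @ kx)
        chosen = _greedy_match(ideal @ rot.T, dirs)
        sub = dirs[chosen]
        a = pairwise_axial_angles(sub, sub)
        np.fill_diagonal(a, np.inf)
        sep = float(a.min())
        if sep > best_sep:
            best_sep, best_chosen = sep, chosen
    return dwi_idx[best_chosen]


def _fit_predict(model: str, signal, gtab_fit, gtab_predict, basis=None, **kw):
    if model == "dtm":
        fit = _dtm.fit_dtm(signal, gtab_fit, method=kw.get("method", "wls"))
        return _dtm.predict_dtm(fit, gtab_predict)
    if model == "sfm":
        if basis is None:
            raise ValueError("sfm evaluation requires a fascicle basis")
        fit = _sfm.fit_sfm(
            signal,
            gtab_fit,
            basis,
            lam=kw.get("lam", _sfm.DEFAULT_LAMBDA),
            alpha=kw.get("alpha", _sfm.DEFAULT_ALPHA),
            nonneg=kw.get("nonneg", True),
        )
        return _sfm.predict_sfm(fit, gtab_predict)
    raise ValueError(f"unknown model {model!r}")


def rrmse_map(
    d1: np.ndarray,
    d2: np.ndarray,
    gtab1: GradientTable,
    gtab2: GradientTable | None = None,
    model: str = "dtm",
    basis=None,
    fit_indices: np.ndarray | None = None,
    **model_kwargs,
) -> np.ndarray:
    """Per-voxel cross-validated rRMSE for a (V, T) two-repeat data set.

    Each repeat is fit with its own gradient table (motion-corrected
    directions may differ); the test-retest denominator pairs D1 and D2
    index-wise.  ``fit_indices`` restricts the *fitting* to a gradient
    subset while predictions and the denominator still use the full
    tables (the number-of-directions pathway).
    """
    if gtab2 is None:
        gtab2 = gtab1
    d1 = np.atleast_2d(np.asarray(d1, dtype=float))
    d2 = np.atleast_2d(np.asarray(d2, dtype=float))
    if d1.shape != d2.shape:
        raise ValueError("repeats must have identical shapes")
    g1_fit, g2_fit = gtab1, gtab2
    take1 = take2 = slice(None)
    if fit_indices is not None:
        g1_fit = gtab1.take(fit_indices)
        g2_fit = gtab2.take(fit_indices)
        # positions of the subset within the non-b0 rows
        dwi_idx = np.flatnonzero(gtab1.dwi_mask)
        pos = np.searchsorted(dwi_idx, np.asarray(fit_indices))
        take1 = take2 = pos

    out = np.empty(d1.shape[0])
    for v in range(d1.shape[0]):
        s1 = d1[v] if d1[v].size == gtab1.n_dwi else d1[v][gtab1.dwi_mask]
        s2 = d2[v] if d2[v].size == gtab2.n_dwi else d2[v][gtab2.dwi_mask]
        m1 = _fit_predict(model, s1[take1], g1_fit, gtab2, basis, **model_kwargs)
        m2 = _fit_predict(model, s2[take2], g2_fit, gtab1, basis, **model_kwargs)
        out[v] = rrmse_pair(s1, s2, m1[gtab2.dwi_mask], m2[gtab1.dwi_mask])
    return out


def bootstrap_median_ci(
    values: np.ndarray, n_boot: int = 1000, seed: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the median."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    rng = np.random.default_rng(seed)
    meds = np.median(
        rng.choice(values, size=(n_boot, values.size), replace=True), axis=1
    )
    lo = float(np.percentile(meds, 100 * (1 - level) / 2))
    hi = float(np.percentile(meds, 100 * (1 + level) / 2))
    return lo, hi


def directions_curve(
    d1: np.ndarray,
    d2: np.ndarray,
    gtab: GradientTable,
    n_values,
    models=("dtm", "sfm"),
    basis=None,
    origin_index: int = 0,
    n_boot: int = 1000,
    seed: int = 0,
    **model_kwargs,
) -> pd.DataFrame:
    """Median rRMSE as a function of the number of measurement directions.

    For each n, both models are refit per voxel on the n-direction
    subsample of each repeat and score the *full* other repeat; the
    table has columns model, n, median_rrmse, ci_lo, ci_hi.
    """
    rows = []
    for n in n_values:
        idx = subsample_directions(gtab, int(n), origin_index=origin_index)
        for model in models:
            vals = rrmse_map(
                d1, d2, gtab, gtab, model=model, basis=basis,
                fit_indices=idx, **model_kwargs,
            )
            lo, hi = bootstrap_median_ci(vals, n_boot=n_boot, seed=seed)
            rows.append(
                {
                    "model": model,
                    "n": int(n),
                    "median_rrmse": float(np.nanmedian(vals)),
                    "ci_lo": lo,
                    "ci_hi": hi,
                }
            )
    return pd.DataFrame(rows)
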