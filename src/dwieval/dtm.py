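"""Diffusion tensor model (DTM) fitting and tensor-derived scalars.

The DTM approximates within-voxel diffusion as a single 3D Gaussian:
the ADC along gradient direction theta is the quadratic form
``A(theta) = theta^T Q theta`` with Q symmetric positive-definite, so
the relative signal is ``exp(-b * theta^T Q theta)``.  Q has 6 free
parameters and is estimated per voxel by one of three classical
estimators:

``ols``
    ordinary least squares on log(S) against the linear model
    ``-b * theta^T Q theta``;
``wls``
    weighted least squares on log(S), weights equal to the squared
    predicted signals from a first-pass OLS fit (one reweighting pass);
``nlls``
    nonlinear least squares on S itself (trust-region LM on the
    Cholesky-parameterized tensor, which keeps Q positive
    semi-definite), initialized from the WLS solution.

Fits whose log-linear solution is not positive-definite are flagged,
not silently clamped; derived scalar maps carry NaN for flagged voxels
unless eigenvalue clipping is explicitly requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core import GradientTable, canonical_hemisphere, predict_relative_signal

__all__ = ["TensorFit", "fit_dtm", "predict_dtm", "westin_linearity"]

# qc flag values
NON_POSITIVE_DEFINITE = "non_positive_definite"
FIT_FAILED = "fit_failed"
EIGENVALUE_TIE = "eigenvalue_tie"

_TIE_RTOL = 1e-6


@dataclass(frozen=True)
class TensorFit:
    """A fitted tensor with its eigen-derived scalar summaries.

    eigenvalues are sorted descending (mm^2/s); ``pdd`` is the principal
    eigenvector canonicalized to the z >= 0 hemisphere; ``fa``/``md``/
    ``linearity`` are NaN when the fit is flagged non-positive-definite
    and clipping was not requested.
    """

    tensor: np.ndarray
    eigenvalues: np.ndarray
    pdd: np.ndarray
    fa: float
    md: float
    linearity: float
    qc_flags: frozenset = field(default_factory=frozenset)
    method: str = "wls"

    @property
    def ok(self) -> bool:
        return FIT_FAILED not in self.qc_flags


def _design_matrix(bvecs: np.ndarray, bvals: np.ndarray) -> np.ndarray:
    x, y, z = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    cols = np.stack([x * x, y * y, z * z, 2 * x * y, 2 * x * z, 2 * y * z], axis=1)
    return -bvals[:, None] * cols


def _q_from_params(p: np.ndarray) -> np.ndarray:
    return np.array(
        [
            [p[0], p[3], p[4]],
            [p[3], p[1], p[5]],
            [p[4], p[5], p[2]],
        ]
    )


def fractional_anisotropy(evals: np.ndarray) -> float:
    evals = np.asarray(evals, dtype=float)
    norm = np.linalg.norm(evals)
    if norm == 0:
        return float("nan")
    return float(np.sqrt(1.5) * np.linalg.norm(evals - evals.mean()) / norm)


def westin_linearity(fit_or_evals, formula: str = "westin") -> float:
    """Linearity of the diffusion ellipsoid: 1 for a stick, 0 for a sphere.

    ``westin``: c_l = (l1 - l2) / (l1 + l2 + l3) (default).
    ``normalized``: (l1 - l2) / l1.
    """
    evals = (
        fit_or_evals.eigenvalues
        if isinstance(fit_or_evals, TensorFit)
        else np.sort(np.asarray(fit_or_evals, dtype=float))[::-1]
    )
    if np.any(evals < 0):
        return float("nan")
    total = float(evals.sum())
    if total == 0:
        raise ValueError("all-zero eigenvalues have no defined linearity")
    if formula == "westin":
        return float((evals[0] - evals[1]) / total)
    if formula == "normalized":
        return float((evals[0] - evals[1]) / evals[0])
    raise ValueError(f"unknown linearity formula {formula!r}")


def _dwi_signal(signal: np.ndarray, gtab: GradientTable) -> np.ndarray:
    """Accept a signal vector aligned either to the full table or to its
    non-b0 rows; return the diffusion-weighted part."""
    s = np.asarray(signal, dtype=float).ravel()
    if s.size == len(gtab):
        return s[gtab.dwi_mask]
    if s.size == gtab.n_dwi:
        return s
    raise ValueError(
        f"signal length {s.size} matches neither table length {len(gtab)} "
        f"nor its {gtab.n_dwi} non-b0 rows"
    )


def _finalize(q: np.ndarray, method: str, extra_flags=()) -> TensorFit:
    q = 0.5 * (q + q.T)
    evals, evecs = np.linalg.eigh(q)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    flags = set(extra_flags)
    if evals[-1] <= 0:
        flags.add(NON_POSITIVE_DEFINITE)
    if np.isclose(evals[0], evals[1], rtol=_TIE_RTOL, atol=1e-18):
        flags.add(EIGENVALUE_TIE)
    pdd = canonical_hemisphere(evecs[:, 0])
    if NON_POSITIVE_DEFINITE in flags:
        fa = md = lin = float("nan")
    else:
        fa = fractional_anisotropy(evals)
        md = float(evals.mean())
        lin = westin_linearity(evals)
    return TensorFit(
        tensor=q,
        eigenvalues=evals,
        pdd=pdd,
        fa=fa,
        md=md,
        linearity=lin,
        qc_flags=frozenset(flags),
        method=method,
    )


def _fit_loglinear(
    s: np.ndarray, design: np.ndarray, weights: np.ndarray | None
) -> np.ndarray:
    if weights is None:
        p, *_ = np.linalg.lstsq(design, np.log(s), rcond=None)
    else:
        w = np.sqrt(weights)
        p, *_ = np.linalg.lstsq(design * w[:, None], np.log(s) * w, rcond=None)
    return p


def _clip_spd(q: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    evals, evecs = np.linalg.eigh(0.5 * (q + q.T))
    evals = np.maximum(evals, floor)
    return evecs @ np.diag(evals) @ evecs.T


def fit_dtm(
    signal: np.ndarray,
    gtab: GradientTable,
    method: str = "wls",
    n_wls_passes: int = 1,
    log_floor: float | None = None,
) -> TensorFit:
    """Fit the 6-parameter tensor to a relative-signal vector.

    Parameters
    ----------
    signal : array
        Relative signal, aligned either to the full gradient table or to
        its non-b0 rows.
    method : {"ols", "wls", "nlls"}
    n_wls_passes : int
        Reweighting passes for WLS (weights = squared predicted signal
        from the previous pass).
    log_floor : float, optional
        If given, non-positive signal samples are floored at this value
        for the log-domain fits instead of being dropped.
    """
    if method not in ("ols", "wls", "nlls"):
        raise ValueError(f"unknown method {method!r}")
    s = _dwi_signal(signal, gtab)
    bvecs = gtab.bvecs[gtab.dwi_mask]
    bvals = gtab.bvals[gtab.dwi_mask]
    if s.size < 6:
        raise ValueError("tensor fitting needs at least 6 non-b0 measurements")

    pos = s > 0
    if log_floor is not None:
        s_log = np.maximum(s, log_floor)
        pos = np.ones_like(pos)
    else:
        s_log = s
        if not np.all(pos):
            warnings.warn(
                f"dropping {np.count_nonzero(~pos)} non-positive samples "
                "from the log-domain fit",
                stacklevel=2,
            )
    design = _design_matrix(bvecs[pos], bvals[pos])
    if np.count_nonzero(pos) < 6 or np.linalg.matrix_rank(design) < 6:
        return TensorFit(
            tensor=np.full((3, 3), np.nan),
            eigenvalues=np.full(3, np.nan),
            pdd=np.full(3, np.nan),
            fa=float("nan"),
            md=float("nan"),
            linearity=float("nan"),
            qc_flags=frozenset({FIT_FAILED}),
            method=method,
        )

    p_ols = _fit_loglinear(s_log[pos], design, None)
    if method == "ols":
        return _finalize(_q_from_params(p_ols), method)

    p = p_ols
    for _ in range(max(n_wls_passes, 1)):
        w = np.exp(design @ p) ** 2
        p = _fit_loglinear(s_log[pos], design, w)
    if method == "wls":
        return _finalize(_q_from_params(p), method)

    # NLLS on the signal itself, Cholesky parameterization Q = L L^T
    q0 = _clip_spd(_q_from_params(p))
    L0 = np.linalg.cholesky(q0)
    x0 = np.array([L0[0, 0], L0[1, 1], L0[2, 2], L0[1, 0], L0[2, 0], L0[2, 1]])
    # scale free parameters to order unity for the trust-region solver
    scale = max(np.abs(x0).max(), 1e-8)

    def q_of(x):
        L = np.zeros((3, 3))
        L[0, 0], L[1, 1], L[2, 2] = x[0], x[1], x[2]
        L[1, 0], L[2, 0], L[2, 1] = x[3], x[4], x[5]
        return (L @ L.T) * scale**2

    def resid(x):
        q = q_of(x)
        a = np.einsum("ij,jk,ik->i", bvecs, q, bvecs)
        return np.exp(-bvals * a) - s

    res = least_squares(
        resid, x0 / scale, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-10,
        max_nfev=1000 * 6,
    )
    flags = () if res.success else (FIT_FAILED,)
    return _finalize(q_of(res.x), method, flags)


def predict_dtm(fit: TensorFit, gtab: GradientTable) -> np.ndarray:
    """Relative signal predicted by a fitted tensor on ``gtab``."""
    if FIT_FAILED in fit.qc_flags:
        raise ValueError("cannot predict from a failed tensor fit")
    return predict_relative_signal(fit.tensor, gtab)
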