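"""Volume I/O, white-matter mask refinement, corpus-callosum ROI
selection and canonical-kernel estimation.

NIfTI volumes are read and written through nibabel; gradient tables use
the FSL bvals/bvecs text dialect (see :mod:`dwieval.core`).  All
preprocessing (motion correction, unwarping, segmentation) is assumed
done upstream: this module consumes aligned volumes and masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy.stats import iqr

from .core import CanonicalKernel, GradientTable, read_bvals_bvecs, relative_signal, VoxelSignal
from . import dtm as _dtm

__all__ = [
    "VolumeSet",
    "load_volume_set",
    "save_scalar_map",
    "load_mask",
    "save_mask",
    "DtmVolumeFit",
    "fit_dtm_volume",
    "refine_wm_mask",
    "select_cc_roi",
    "estimate_kernel",
]

# integer-coded QC bitmask for on-disk maps
QC_CODES = {
    _dtm.NON_POSITIVE_DEFINITE: 1,
    _dtm.FIT_FAILED: 2,
    _dtm.EIGENVALUE_TIE: 4,
}


@dataclass(frozen=True)
class VolumeSet:
    """A 4D acquisition: (x, y, z, volumes) data, affine, gradient table."""

    data: np.ndarray
    affine: np.ndarray
    gtab: GradientTable

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, volumes)")
        if data.shape[3] != len(self.gtab):
            raise ValueError(
                f"{data.shape[3]} volumes but gradient table has {len(self.gtab)} rows"
            )
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4) or abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple:
        return self.data.shape[:3]

    def voxel_signal(self, i: int, j: int, k: int) -> VoxelSignal:
        v = self.data[i, j, k]
        return VoxelSignal(v[self.gtab.b0_mask], v[self.gtab.dwi_mask])

    def relative_signal(self, i: int, j: int, k: int) -> np.ndarray:
        return relative_signal(self.voxel_signal(i, j, k), self.gtab)


def load_volume_set(dwi_path, bvals_path, bvecs_path) -> VolumeSet:
    img = nib.load(str(dwi_path))
    gtab = read_bvals_bvecs(bvals_path, bvecs_path)
    return VolumeSet(np.asarray(img.dataobj, dtype=float), img.affine, gtab)


def save_scalar_map(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine)), str(path))


def load_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0


def save_mask(mask: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(
        nib.Nifti1Image(mask.astype(np.uint8), np.asarray(affine)), str(path)
    )


@dataclass(frozen=True)
class DtmVolumeFit:
    """Per-voxel tensor-fit maps over a masked volume.

    Unfitted voxels carry NaN; ``qc`` is an integer bitmask (1 = not
    positive-definite, 2 = fit failed, 4 = eigenvalue tie).
    """

    fa: np.ndarray
    md: np.ndarray
    linearity: np.ndarray
    pdd: np.ndarray  # (..., 3)
    eigenvalues: np.ndarray  # (..., 3) sorted descending
    qc: np.ndarray
    mask: np.ndarray


def fit_dtm_volume(
    volumes: VolumeSet, mask: np.ndarray, method: str = "wls"
) -> DtmVolumeFit:
    """Fit the tensor model in every masked voxel of a 4D acquisition."""
    shape = volumes.shape
    if mask.shape != shape:
        raise ValueError("mask shape does not match the volume")
    fa = np.full(shape, np.nan)
    md = np.full(shape, np.nan)
    lin = np.full(shape, np.nan)
    pdd = np.full(shape + (3,), np.nan)
    evals = np.full(shape + (3,), np.nan)
    qc = np.zeros(shape, dtype=np.int16)
    for i, j, k in zip(*np.nonzero(mask)):
        try:
            fit = _dtm.fit_dtm(volumes.relative_signal(i, j, k), volumes.gtab, method)
        except ValueError:
            qc[i, j, k] = QC_CODES[_dtm.FIT_FAILED]
            continue
        fa[i, j, k] = fit.fa
        md[i, j, k] = fit.md
        lin[i, j, k] = fit.linearity
        pdd[i, j, k] = fit.pdd
        evals[i, j, k] = fit.eigenvalues
        qc[i, j, k] = sum(QC_CODES[f] for f in fit.qc_flags)
    return DtmVolumeFit(fa, md, lin, pdd, evals, qc, mask.copy())


def refine_wm_mask(mask: np.ndarray, md_map: np.ndarray) -> np.ndarray:
    """Drop high-MD voxels from a white-matter mask.

    Voxels whose mean diffusivity exceeds the in-mask median by more
    than two inter-quartile ranges are excluded; the criterion is
    one-sided because the target is CSF/grey-matter partial volume.
    """
    if mask.shape != md_map.shape:
        raise ValueError("mask and MD map must be aligned")
    if not mask.any():
        raise ValueError("empty mask")
    vals = md_map[mask]
    vals = vals[np.isfinite(vals)]
    cutoff = np.median(vals) + 2.0 * iqr(vals)
    out = mask.copy()
    out[mask] &= ~(md_map[mask] > cutoff)
    return out


def select_cc_roi(
    fits: DtmVolumeFit,
    mask: np.ndarray | None = None,
    max_voxels: int = 250,
    fa_threshold: float = 0.4,
    md_range: tuple[float, float] = (0.7e-3, 1.1e-3),
    b0_means: np.ndarray | None = None,
    b0_uniformity: bool = False,
) -> np.ndarray:
    """Automated corpus-callosum ROI: the most linear left-right voxels.

    Filters (strict inequalities): dominant left-right PDD
    (|PDD_x| > max(|PDD_y|, |PDD_z|)), FA > 0.4, MD within
    0.7-1.1 x 10^-3 mm^2/s.  Survivors are ranked by Westin linearity
    and the top ``max_voxels`` returned as an (N, 3) voxel-index array.
    An optional b0-uniformity filter (off by default) drops voxels whose
    mean b0 signal deviates more than 2 IQR from the ROI median.
    """
    mask = fits.mask if mask is None else mask
    px, py, pz = np.abs(fits.pdd[..., 0]), np.abs(fits.pdd[..., 1]), np.abs(fits.pdd[..., 2])
    lr = (px > py) & (px > pz)
    fa_ok = fits.fa > fa_threshold
    md_ok = (fits.md > md_range[0]) & (fits.md < md_range[1])
    with np.errstate(invalid="ignore"):
        selected = mask & lr & fa_ok & md_ok
    if b0_uniformity:
        if b0_means is None:
            raise ValueError("b0_uniformity filter requires b0_means")
        vals = b0_means[selected]
        cutoff = 2.0 * iqr(vals)
        dev = np.abs(b0_means - np.median(vals))
        selected &= dev <= cutoff
    if not selected.any():
        raise ValueError(
            "no voxels survive the CC ROI filters "
            f"(in-mask: {int(mask.sum())}, left-right PDD: {int((mask & lr).sum())}, "
            f"FA > {fa_threshold}: {int((mask & fa_ok).sum())}, "
            f"MD in range: {int((mask & md_ok).sum())})"
        )
    idx = np.argwhere(selected)
    lin = fits.linearity[selected]
    order = np.argsort(lin)[::-1]
    return idx[order[:max_voxels]]


def estimate_kernel(fits: DtmVolumeFit, roi_indices: np.ndarray) -> CanonicalKernel:
    """Canonical kernel from an ROI: median axial and radial diffusivity.

    Per voxel the axial diffusivity is the largest eigenvalue and the
    radial diffusivity the mean of the two minor eigenvalues; the ROI
    medians of each define the kernel.
    """
    roi_indices = np.atleast_2d(np.asarray(roi_indices))
    if roi_indices.size == 0:
        raise ValueError("empty ROI")
    evals = fits.eigenvalues[tuple(roi_indices.T)]
    axial = float(np.median(evals[:, 0]))
    radial = float(np.median((evals[:, 1] + evals[:, 2]) / 2.0))
    return CanonicalKernel(axial, radial)
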