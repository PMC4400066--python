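"""Core diffusion-signal machinery shared by every model.

The diffusion-weighted signal in a voxel follows the Stejskal-Tanner
relation ``S(theta, b) = exp(-b * A(theta))`` where ``A(theta)`` is the
apparent diffusion coefficient (ADC) along the gradient direction
``theta`` and ``b`` (s/mm^2) summarizes the diffusion weighting.  This
module provides the gradient-table container, tensor/ADC arithmetic,
axially symmetric kernel rotation, angular utilities under antipodal
symmetry, and deterministic electrostatic-repulsion point sets on the
sphere.

Directions are treated as *axial* throughout: a diffusion measurement
cannot distinguish ``theta`` from ``-theta``, so every angular
comparison folds into [0, 90] degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "GradientTable",
    "VoxelSignal",
    "CanonicalKernel",
    "relative_signal",
    "adc",
    "predict_relative_signal",
    "rotate_kernel",
    "angular_difference",
    "canonical_hemisphere",
    "electrostatic_sphere",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
]

_UNIT_TOL = 1e-6


def _as_unit(v: np.ndarray, name: str = "direction") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError(f"{name} is the zero vector")
    if abs(n - 1.0) > _UNIT_TOL:
        raise ValueError(f"{name} is not unit-norm (|v| = {n:.8f})")
    return v / n


@dataclass(frozen=True)
class GradientTable:
    """Measurement geometry: per-volume gradient directions and b-values.

    Parameters
    ----------
    bvecs : (T, 3) array
        Gradient directions.  Non-b0 rows must be unit vectors (within
        1e-6); b0 rows may be zero.
    bvals : (T,) array
        Diffusion weighting in s/mm^2.  Zero marks a non-diffusion-
        weighted (b0) volume.
    coordinate_frame : str
        ``"image"`` or ``"world"``; documents the frame of the stored
        directions.  No reorientation is performed.
    """

    bvecs: np.ndarray
    bvals: np.ndarray
    coordinate_frame: str = "image"

    def __post_init__(self):
        bvecs = np.atleast_2d(np.asarray(self.bvecs, dtype=float))
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        if bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"bvecs shape {bvecs.shape} does not match {bvals.size} bvals"
            )
        if self.coordinate_frame not in ("image", "world"):
            raise ValueError("coordinate_frame must be 'image' or 'world'")
        b0 = bvals == 0
        norms = np.linalg.norm(bvecs[~b0], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("non-b0 gradient directions must be unit-norm")
        object.__setattr__(self, "bvecs", bvecs)
        object.__setattr__(self, "bvals", bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return ~self.b0_mask

    @property
    def n_dwi(self) -> int:
        return int(np.count_nonzero(self.dwi_mask))

    def __len__(self) -> int:
        return self.bvals.size

    def dwi_subset(self) -> "GradientTable":
        """Gradient table restricted to the diffusion-weighted volumes."""
        m = self.dwi_mask
        return GradientTable(self.bvecs[m], self.bvals[m], self.coordinate_frame)

    def take(self, indices) -> "GradientTable":
        idx = np.asarray(indices)
        return GradientTable(self.bvecs[idx], self.bvals[idx], self.coordinate_frame)

    @property
    def unique_dwi_bvalue(self) -> float:
        """The single shared non-zero b-value; error on multi-shell tables."""
        bv = np.unique(self.bvals[self.dwi_mask])
        if bv.size != 1:
            raise ValueError(
                f"expected a single non-zero b-value, found {bv.tolist()}"
            )
        return float(bv[0])


@dataclass(frozen=True)
class VoxelSignal:
    """Raw scanner-unit signal in one voxel: b0 measurements plus DWI values."""

    s0_measurements: np.ndarray
    sb: np.ndarray

    def __post_init__(self):
        s0 = np.atleast_1d(np.asarray(self.s0_measurements, dtype=float))
        sb = np.atleast_1d(np.asarray(self.sb, dtype=float))
        if s0.size < 1:
            raise ValueError("at least one b0 measurement is required")
        if np.any(s0 < 0) or np.any(sb < 0):
            raise ValueError("signal values must be non-negative (rectified)")
        object.__setattr__(self, "s0_measurements", s0)
        object.__setattr__(self, "sb", sb)


def relative_signal(voxel: VoxelSignal, gtab: GradientTable) -> np.ndarray:
    """S(theta, b) = S_b(theta) / mean(S0), aligned to the non-b0 table rows.

    The b0 volumes are aggregated by their mean; the returned vector has
    one entry per diffusion-weighted gradient-table row.
    """
    if voxel.sb.size != gtab.n_dwi:
        raise ValueError(
            f"{voxel.sb.size} DWI values for {gtab.n_dwi} non-b0 directions"
        )
    s0 = float(np.mean(voxel.s0_measurements))
    if s0 <= 0:
        raise ValueError("mean b0 signal must be positive")
    return voxel.sb / s0


def _check_tensor(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape != (3, 3):
        raise ValueError("tensor must be a 3x3 matrix")
    if not np.allclose(q, q.T, atol=1e-10):
        raise ValueError("tensor must be symmetric within 1e-10")
    return q


def adc(tensor: np.ndarray, direction: np.ndarray) -> float:
    """Apparent diffusion coefficient along ``direction``: theta^T Q theta."""
    q = _check_tensor(tensor)
    d = _as_unit(direction)
    return float(d @ q @ d)


def predict_relative_signal(tensor: np.ndarray, gtab: GradientTable) -> np.ndarray:
    """Tensor-predicted relative signal exp(-b * theta^T Q theta) per row.

    Rows with b = 0 predict exactly 1 (no diffusion weighting).
    """
    q = _check_tensor(tensor)
    a = np.einsum("ij,jk,ik->i", gtab.bvecs, q, gtab.bvecs)
    out = np.exp(-gtab.bvals * a)
    out[gtab.b0_mask] = 1.0
    return out


@dataclass(frozen=True)
class CanonicalKernel:
    """Axially symmetric tensor response shared by all fascicle compartments.

    Diffusivities in mm^2/s; axial >= radial > 0.
    """

    axial_diffusivity: float
    radial_diffusivity: float

    def __post_init__(self):
        if not (self.axial_diffusivity >= self.radial_diffusivity > 0):
            raise ValueError("kernel requires axial >= radial > 0")


def rotate_kernel(kernel: CanonicalKernel, fascicle_direction: np.ndarray) -> np.ndarray:
    """Tensor with eigenvalues {axial, radial, radial}, principal axis along
    ``fascicle_direction``: Q = radial*I + (axial - radial) * d d^T."""
    d = _as_unit(fascicle_direction, "fascicle_direction")
    ad, rd = kernel.axial_diffusivity, kernel.radial_diffusivity
    return rd * np.eye(3) + (ad - rd) * np.outer(d, d)


def angular_difference(u: np.ndarray, v: np.ndarray) -> float:
    """Axial angle between two directions, in degrees within [0, 90]."""
    uu = _as_unit(u, "u")
    vv = _as_unit(v, "v")
    c = abs(float(uu @ vv))
    return float(np.degrees(np.arccos(min(c, 1.0))))


def pairwise_axial_angles(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Axial angles (degrees) between each row of ``u`` and each row of ``v``."""
    c = np.abs(np.asarray(u) @ np.asarray(v).T)
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def canonical_hemisphere(v: np.ndarray) -> np.ndarray:
    """Flip an axial direction into the canonical hemisphere.

    Sign chosen so z >= 0; on the z = 0 circle so y >= 0; at y = z = 0
    so x >= 0.  Makes principal diffusion directions reproducible.
    """
    v = np.asarray(v, dtype=float)
    sign_keys = (v[..., 2], v[..., 1], v[..., 0])
    s = np.ones(v.shape[:-1])
    undecided = np.ones(v.shape[:-1], dtype=bool)
    for k in sign_keys:
        s = np.where(undecided & (k < 0), -1.0, s)
        undecided = undecided & (k == 0)
    return v * s[..., None]


# --- electrostatic repulsion point sets -------------------------------------

def _coulomb_energy_grad(x: np.ndarray, n: int):
    x = x.reshape(n, 3)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    u = x / norms
    diff = u[:, None, :] - u[None, :, :]
    summ = u[:, None, :] + u[None, :, :]
    dm = np.linalg.norm(diff, axis=2)
    dp = np.linalg.norm(summ, axis=2)
    iu = np.triu_indices(n, 1)
    energy = np.sum(1.0 / dm[iu]) + np.sum(1.0 / dp[iu])
    # dE/du_k, antipodally symmetric pair potential
    np.fill_diagonal(dm, np.inf)
    np.fill_diagonal(dp, np.inf)
    g = -(diff / dm[:, :, None] ** 3).sum(axis=1) - (summ / dp[:, :, None] ** 3).sum(
        axis=1
    )
    # chain rule through the normalization u = x/|x|
    g = (g - (g * u).sum(axis=1, keepdims=True) * u) / norms
    return energy, g.ravel()


def _sphere_energy(u: np.ndarray) -> float:
    n = u.shape[0]
    iu = np.triu_indices(n, 1)
    dm = np.linalg.norm(u[:, None, :] - u[None, :, :], axis=2)[iu]
    dp = np.linalg.norm(u[:, None, :] + u[None, :, :], axis=2)[iu]
    return float(np.sum(1.0 / dm) + np.sum(1.0 / dp))


@lru_cache(maxsize=32)
def _electrostatic_cached(n: int, seed: int) -> tuple:
    rng = np.random.default_rng(seed)
    n_restarts = 8 if n <= 64 else 1
    best_u, best_e = None, np.inf
    for _ in range(n_restarts):
        x0 = rng.standard_normal((n, 3))
        x0 /= np.linalg.norm(x0, axis=1, keepdims=True)
        res = minimize(
            _coulomb_energy_grad,
            x0.ravel(),
            args=(n,),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
        )
        u = res.x.reshape(n, 3)
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        e = _sphere_energy(u)
        if e < best_e:
            best_e, best_u = e, u
    u = canonical_hemisphere(best_u)
    order = np.lexsort((u[:, 0], u[:, 1], u[:, 2]))
    return tuple(map(tuple, u[order]))


def electrostatic_sphere(n: int, seed: int = 0) -> np.ndarray:
    """``n`` unit vectors minimizing antipodally symmetric Coulomb energy.

    Minimizes ``sum_{i<j} 1/|u_i - u_j| + 1/|u_i + u_j|`` by L-BFGS from
    seeded random starts (best of a few restarts), so the axial point set
    is near-uniform on the hemisphere and bit-reproducible for a given
    ``(n, seed)``.
    """
    if n < 3:
        raise ValueError("at least 3 points are required")
    return np.array(_electrostatic_cached(int(n), int(seed)))


# --- FSL-style bvals/bvecs text files ---------------------------------------

def read_bvals_bvecs(bvals_path, bvecs_path, coordinate_frame: str = "image") -> GradientTable:
    """Read an FSL-dialect gradient table.

    bvals: whitespace-separated scalars, one row.  bvecs: 3 rows of T
    columns in the image coordinate frame.
    """
    bvals = np.loadtxt(bvals_path).ravel()
    bvecs = np.loadtxt(bvecs_path)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous 3x3: FSL convention stores 3 rows x T columns
        bvecs = bvecs.T
    return GradientTable(bvecs, bvals, coordinate_frame)


def write_bvals_bvecs(gtab: GradientTable, bvals_path, bvecs_path) -> None:
    """Write a gradient table in the FSL dialect (bvecs as 3 rows x T cols)."""
    np.savetxt(bvals_path, gtab.bvals[None, :], fmt="%.8g")
    np.savetxt(bvecs_path, gtab.bvecs.T, fmt="%.10g")
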