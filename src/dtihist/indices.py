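"""Eigen-decomposition of the tensor field and the five derived index maps.

Indices (per voxel, from eigenvalues l1 >= l2 >= l3):

* MD = (l1 + l2 + l3) / 3
* AD = l1
* RD = (l2 + l3) / 2
* FA = sqrt(3/2) * ||l - mean(l)|| / ||l||
* MO = 3*sqrt(6) * det(A~ / ||A~||_F) with A~ = D - MD*I (deviatoric tensor)

FA ranges 0 (isotropic) to 1 (single nonzero eigenvalue); MO ranges -1
(planar anisotropy) to +1 (linear anisotropy).  Negative eigenvalues from
noisy fits are used as-is; voxels with l1 <= 0 or an all-zero tensor are
marked invalid rather than clamped.  For numerically isotropic voxels
(deviatoric norm < 1e-12 * MD) MO is set to 0 and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EigenSystem",
    "IndexMaps",
    "eigendecompose",
    "compute_indices",
    "indices_from_eigenvalues",
    "INDEX_NAMES",
]

INDEX_NAMES = ("md", "fa", "ad", "rd", "mo")

_ISO_TOL = 1e-12


@dataclass(frozen=True)
class EigenSystem:
    """Per-voxel eigenvalues (descending, mm^2/s) and orthonormal eigenvectors."""

    eigenvalues: np.ndarray  # (..., 3), l1 >= l2 >= l3
    eigenvectors: np.ndarray  # (..., 3, 3), columns are eigenvectors


@dataclass(frozen=True)
class IndexMaps:
    """The five index maps plus validity / isotropic-MO flags."""

    md: np.ndarray
    fa: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    mo: np.ndarray
    valid: np.ndarray
    isotropic_mo: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"md": self.md, "fa": self.fa, "ad": self.ad,
                "rd": self.rd, "mo": self.mo}


def tensor6_to_matrix(tensor6: np.ndarray) -> np.ndarray:
    """(..., 6) [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] -> (..., 3, 3) symmetric."""
    t = np.asarray(tensor6, dtype=float)
    if t.shape[-1] != 6:
        raise ValueError(f"expected trailing dimension 6, got {t.shape}")
    m = np.empty(t.shape[:-1] + (3, 3), dtype=float)
    m[..., 0, 0] = t[..., 0]
    m[..., 1, 1] = t[..., 1]
    m[..., 2, 2] = t[..., 2]
    m[..., 0, 1] = m[..., 1, 0] = t[..., 3]
    m[..., 0, 2] = m[..., 2, 0] = t[..., 4]
    m[..., 1, 2] = m[..., 2, 1] = t[..., 5]
    return m


def eigendecompose(tensor6: np.ndarray) -> EigenSystem:
    """Eigen-decompose symmetric tensors, eigenvalues sorted descending."""
    t = np.asarray(tensor6, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("tensor field contains non-finite entries")
    mats = tensor6_to_matrix(t)
    evals, evecs = np.linalg.eigh(mats)  # ascending
    evals = evals[..., ::-1]
    evecs = evecs[..., :, ::-1]
    return EigenSystem(eigenvalues=evals, eigenvectors=evecs)


def indices_from_eigenvalues(evals: np.ndarray) -> dict[str, np.ndarray]:
    """Index values from (..., 3) descending eigenvalues (no validity logic)."""
    lam = np.asarray(evals, dtype=float)
    md = lam.mean(axis=-1)
    ad = lam[..., 0]
    rd = 0.5 * (lam[..., 1] + lam[..., 2])
    dev = lam - md[..., None]
    sumsq = np.sum(lam * lam, axis=-1)
    devnorm = np.sqrt(np.sum(dev * dev, axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5) * devnorm / np.sqrt(sumsq)
        mo = 3.0 * np.sqrt(6.0) * np.prod(dev, axis=-1) / devnorm ** 3
    iso = devnorm < _ISO_TOL * np.abs(md)
    mo = np.where(iso | (devnorm == 0), 0.0, mo)
    return {"md": md, "fa": fa, "ad": ad, "rd": rd, "mo": mo}


def compute_indices(eigensystem: EigenSystem) -> IndexMaps:
    """Compute the five index maps and the validity mask.

    A voxel is invalid when the tensor is all-zero (FA/MO undefined) or the
    largest eigenvalue is non-positive.  FA/MO for invalid voxels are NaN.
    """
    lam = eigensystem.eigenvalues
    raw = indices_from_eigenvalues(lam)
    sumsq = np.sum(lam * lam, axis=-1)
    valid = (sumsq > 0) & (lam[..., 0] > 0)

    dev = lam - raw["md"][..., None]
    devnorm = np.sqrt(np.sum(dev * dev, axis=-1))
    isotropic_mo = valid & (devnorm < _ISO_TOL * np.abs(raw["md"]))

    fa = np.where(valid, raw["fa"], np.nan)
    mo = np.where(valid, raw["mo"], np.nan)
    return IndexMaps(md=raw["md"], fa=fa, ad=raw["ad"], rd=raw["rd"], mo=mo,
                     valid=valid, isotropic_mo=isotropic_mo)
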