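"""Per-voxel diffusion-tensor estimation.

Provides b-matrix construction (with rotation by the rotational part of an
affine), log-linear (LLS) and weighted (WLLS) fits, and a robust
iteratively-reweighted fit with outlier rejection.

Conventions fixed here and unit-tested:

* design row per measurement: b * (gx^2, gy^2, gz^2, 2*gx*gy, 2*gx*gz,
  2*gy*gz) plus an intercept column for ln(S0);
* the rotational part of an affine is extracted by polar decomposition of
  its 3x3 block, so pure scaling/shear leaves gradients untouched;
* non-positive signals are clamped to half the voxel's smallest positive
  measurement before the log transform and the voxel is flagged;
* robust fit constants: 3*sigma residual threshold, Geman-McClure weights
  w = 1/(r^2 + C^2)^2 with C = 1.4826 * median(|r|), at most 50 reweighting
  iterations, relative weight-change tolerance 1e-6.  A voxel that would
  lose so many measurements that fewer than 7 remain falls back to the
  full-data weighted fit and is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import DWIDataset, GradientScheme, RegionMask

__all__ = [
    "BMatrix",
    "TensorField",
    "METHOD_CODES",
    "build_bmatrix",
    "rotate_bmatrix",
    "fit_tensor_lls",
    "fit_tensor_wlls",
    "fit_tensor_restore",
    "estimate_noise_sigma",
]

METHOD_CODES = {"none": 0, "lls": 1, "wlls": 2, "restore": 3, "restore_fallback": 4}


@dataclass(frozen=True)
class BMatrix:
    """Design rows b*(gx^2, gy^2, gz^2, 2gxgy, 2gxgz, 2gygz) + intercept."""

    bvals: np.ndarray
    bvecs: np.ndarray

    @property
    def n_measurements(self) -> int:
        return len(self.bvals)

    @property
    def design(self) -> np.ndarray:
        """(N, 7) matrix; last column is the ln(S0) intercept (all ones)."""
        g = self.bvecs
        b = self.bvals
        rows = np.column_stack([
            g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
        ]) * b[:, None]
        return np.column_stack([rows, np.ones(len(b))])

    @property
    def regression_design(self) -> np.ndarray:
        """Design for the regression ln(S) = X @ (D6, lnS0): negated b-rows."""
        x = self.design.copy()
        x[:, :6] *= -1.0
        return x


def build_bmatrix(scheme: GradientScheme) -> BMatrix:
    bm = BMatrix(bvals=scheme.bvals.copy(), bvecs=scheme.bvecs.copy())
    if bm.n_measurements >= 7 and np.linalg.matrix_rank(bm.design, tol=1e-10) < 7:
        raise ValueError("rank-deficient gradient scheme (collinear/coplanar directions)")
    return bm


def rotation_from_affine(affine: np.ndarray) -> np.ndarray:
    """Rotational part of a 4x4 (or 3x3) affine via polar decomposition."""
    a = np.asarray(affine, dtype=float)
    block = a[:3, :3]
    if np.abs(np.linalg.det(block)) < 1e-12:
        raise ValueError("affine 3x3 block is singular; no rotational part")
    u, _, vt = np.linalg.svd(block)
    return u @ vt


def rotate_bmatrix(bmatrix: BMatrix, affine: np.ndarray) -> BMatrix:
    """Apply the rotational part of an affine to the gradient directions.

    b-values are unchanged; scaling/shear components of the affine (as left
    by eddy-current correction) do not move the gradients.
    """
    r = rotation_from_affine(affine)
    return BMatrix(bvals=bmatrix.bvals.copy(), bvecs=bmatrix.bvecs @ r.T)


@dataclass
class TensorField:
    """Per-voxel tensor fit over a 3-D grid.

    ``tensor`` holds (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) in mm^2/s; voxels outside
    the mask (or with <7 usable measurements) are zero and ``valid`` False.
    """

    tensor: np.ndarray        # (x, y, z, 6)
    ln_s0: np.ndarray         # (x, y, z)
    outlier_count: np.ndarray  # (x, y, z) int
    method: np.ndarray        # (x, y, z) int, see METHOD_CODES
    valid: np.ndarray         # (x, y, z) bool
    clamped: np.ndarray       # (x, y, z) bool: had non-positive signals

    @property
    def s0(self) -> np.ndarray:
        return np.exp(self.ln_s0)


def _resolve_mask(dwi: DWIDataset, mask) -> np.ndarray:
    if mask is None:
        return np.ones(dwi.shape3d, dtype=bool)
    if isinstance(mask, RegionMask):
        mask = mask.mask
    mask = np.asarray(mask).astype(bool)
    if mask.shape != dwi.shape3d:
        raise ValueError(f"mask grid {mask.shape} != DWI grid {dwi.shape3d}")
    return mask


def _prepare_log_signals(signals: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Clamp non-positive signals, return (log signals, clamped flag, usable flag)."""
    positive = signals > 0
    n_positive = positive.sum(axis=1)
    usable = n_positive >= 7
    clamped = (~positive).any(axis=1) & usable
    safe = signals.copy()
    with np.errstate(invalid="ignore"):
        minpos = np.where(positive, signals, np.inf).min(axis=1)
    minpos = np.where(np.isfinite(minpos), minpos, 1.0)
    floor = 0.5 * minpos
    safe = np.where(positive, safe, floor[:, None])
    return np.log(safe), clamped, usable


def _check_fit_inputs(dwi: DWIDataset, bmatrix: BMatrix) -> None:
    if bmatrix.n_measurements != dwi.scheme.n_measurements:
        raise ValueError("b-matrix and DWI measurement counts differ")
    if bmatrix.n_measurements < 7:
        raise ValueError("tensor fit needs at least 7 measurements")
    if np.linalg.matrix_rank(bmatrix.design, tol=1e-10) < 7:
        raise ValueError("rank-deficient b-matrix")


def _lls_beta(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS coefficients for every voxel: y (V, N), X (N, 7) -> (V, 7)."""
    pinv = np.linalg.pinv(x)
    return y @ pinv.T


def _wlls_beta(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Batched weighted LS: per-voxel weights w (V, N) -> (V, 7)."""
    a = np.einsum("vn,np,nq->vpq", w, x, x)
    b = np.einsum("vn,np,vn->vp", w, x, y)
    return np.linalg.solve(a, b[..., None])[..., 0]


def _assemble_field(shape3d, mask_idx, beta, outliers, method_code, valid_flat,
                    clamped_flat, method_flat=None) -> TensorField:
    tensor = np.zeros(shape3d + (6,))
    ln_s0 = np.zeros(shape3d)
    outlier_count = np.zeros(shape3d, dtype=int)
    method = np.zeros(shape3d, dtype=int)
    valid = np.zeros(shape3d, dtype=bool)
    clamped = np.zeros(shape3d, dtype=bool)

    tensor[mask_idx] = np.where(valid_flat[:, None], beta[:, :6], 0.0)
    ln_s0[mask_idx] = np.where(valid_flat, beta[:, 6], 0.0)
    outlier_count[mask_idx] = outliers
    if method_flat is None:
        method_flat = np.where(valid_flat, method_code, METHOD_CODES["none"])
    method[mask_idx] = method_flat
    valid[mask_idx] = valid_flat
    clamped[mask_idx] = clamped_flat
    return TensorField(tensor=tensor, ln_s0=ln_s0, outlier_count=outlier_count,
                       method=method, valid=valid, clamped=clamped)


def fit_tensor_lls(dwi: DWIDataset, bmatrix: BMatrix, mask=None) -> TensorField:
    """Ordinary least squares on ln(S) against the design."""
    _check_fit_inputs(dwi, bmatrix)
    m = _resolve_mask(dwi, mask)
    signals = dwi.signal[m]
    x = bmatrix.regression_design
    y, clamped, usable = _prepare_log_signals(signals)
    beta = _lls_beta(x, y)
    beta[~usable] = 0.0
    return _assemble_field(dwi.shape3d, m, beta, np.zeros(len(beta), dtype=int),
                           METHOD_CODES["lls"], usable, clamped)


def _wlls_core(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """LLS followed by one reweighting pass with w = predicted signal squared."""
    beta0 = _lls_beta(x, y)
    w = np.exp(2.0 * (beta0 @ x.T))
    return _wlls_beta(x, y, w)


def fit_tensor_wlls(dwi: DWIDataset, bmatrix: BMatrix, mask=None) -> TensorField:
    """Weighted LLS, weights = squared predicted signals from an LLS pass."""
    _check_fit_inputs(dwi, bmatrix)
    m = _resolve_mask(dwi, mask)
    signals = dwi.signal[m]
    x = bmatrix.regression_design
    y, clamped, usable = _prepare_log_signals(signals)
    beta = _wlls_core(x, y)
    beta[~usable] = 0.0
    return _assemble_field(dwi.shape3d, m, beta, np.zeros(len(beta), dtype=int),
                           METHOD_CODES["wlls"], usable, clamped)


def _robust_refit_voxel(x: np.ndarray, y: np.ndarray, s: np.ndarray,
                        beta_init: np.ndarray, sigma: float,
                        max_iter: int = 50, tol: float = 1e-6):
    """Geman-McClure IRLS for one voxel; returns (beta, outlier_mask, fallback)."""
    n = len(y)
    beta = beta_init.copy()
    w_prev = None
    for _ in range(max_iter):
        resid = s - np.exp(x @ beta)
        c = 1.4826 * np.median(np.abs(resid))
        if c <= 0:
            c = max(sigma, 1e-12)
        w = 1.0 / (resid ** 2 + c ** 2) ** 2
        beta = np.linalg.lstsq(x * np.sqrt(w)[:, None], y * np.sqrt(w), rcond=None)[0]
        if w_prev is not None:
            denom = np.maximum(np.abs(w_prev), 1e-300)
            if np.max(np.abs(w - w_prev) / denom) < tol:
                w_prev = w
                break
        w_prev = w
    resid = s - np.exp(x @ beta)
    outliers = np.abs(resid) > 3.0 * sigma
    n_keep = n - int(outliers.sum())
    if n_keep < 7:
        return None, outliers, True
    keep = ~outliers
    xk, yk = x[keep], y[keep]
    if np.linalg.matrix_rank(xk, tol=1e-10) < 7:
        return None, outliers, True
    beta0 = np.linalg.lstsq(xk, yk, rcond=None)[0]
    wk = np.exp(2.0 * (xk @ beta0))
    beta = np.linalg.lstsq(xk * np.sqrt(wk)[:, None], yk * np.sqrt(wk), rcond=None)[0]
    return beta, outliers, False


def fit_tensor_restore(dwi: DWIDataset, bmatrix: BMatrix, mask=None,
                       noise_sigma: float = None) -> TensorField:
    """Robust tensor fit with iterative reweighting and outlier rejection.

    Per voxel: a WLLS fit is accepted outright when all signal-space
    residuals lie within 3*noise_sigma; otherwise the voxel is refit with
    Geman-McClure IRLS, measurements with |residual| > 3*noise_sigma are
    excluded and the tensor re-estimated by WLLS on the remainder.  Voxels
    left with fewer than 7 measurements keep the full-data WLLS fit and are
    flagged ``restore_fallback``.
    """
    if noise_sigma is None or not noise_sigma > 0:
        raise ValueError("fit_tensor_restore requires noise_sigma > 0")
    _check_fit_inputs(dwi, bmatrix)
    m = _resolve_mask(dwi, mask)
    signals = dwi.signal[m]
    x = bmatrix.regression_design
    y, clamped, usable = _prepare_log_signals(signals)
    beta = _wlls_core(x, y)
    beta[~usable] = 0.0

    pred = np.exp(beta @ x.T)
    resid = signals - pred
    needs_robust = usable & (np.abs(resid) > 3.0 * noise_sigma).any(axis=1)

    n_vox = len(beta)
    outliers = np.zeros(n_vox, dtype=int)
    method_flat = np.where(usable, METHOD_CODES["restore"], METHOD_CODES["none"])
    for v in np.flatnonzero(needs_robust):
        beta_v, out_v, fallback = _robust_refit_voxel(
            x, y[v], signals[v], beta[v], noise_sigma)
        outliers[v] = int(out_v.sum())
        if fallback:
            method_flat[v] = METHOD_CODES["restore_fallback"]  # keep WLLS beta
        else:
            beta[v] = beta_v
    return _assemble_field(dwi.shape3d, m, beta, outliers,
                           METHOD_CODES["restore"], usable, clamped,
                           method_flat=method_flat)


def estimate_noise_sigma(dwi, background_mask) -> float:
    """Rayleigh moment estimator sigma = sqrt(mean(background^2) / 2).

    The mask must select at least 100 voxels of signal-free background.
    """
    if isinstance(dwi, DWIDataset):
        data = dwi.signal
        bg = _resolve_mask(dwi, background_mask)
    else:
        data = np.asarray(dwi, dtype=float)
        bg = np.asarray(background_mask).astype(bool)
    n = int(bg.sum())
    if n == 0:
        raise ValueError("background mask is empty")
    if n < 100:
        raise ValueError(f"background mask has {n} voxels; need >= 100")
    values = data[bg].ravel()
    return float(np.sqrt(np.mean(values ** 2) / 2.0))
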