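"""Dataset model and readers/writers for the standard on-disk formats.

Images are NIfTI-1, gradient tables use the FSL bval/bvec text dialect
(whitespace separated; bvec is 3 rows by N columns, expressed in the image
coordinate frame), and subject manifests are CSV.  Diffusivities are carried
in mm^2/s everywhere; reporting layers rescale to 1e-3 mm^2/s for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GradientScheme",
    "DWIDataset",
    "RegionMask",
    "SubjectRecord",
    "REGION_LABELS",
    "read_dwi",
    "write_dwi",
    "read_mask",
    "write_mask",
    "write_index_map",
    "read_manifest",
    "write_manifest",
]

REGION_LABELS = ("cerebrum", "brainstem_cerebellum")

_BVEC_NORM_TOL = 1e-3


@dataclass(frozen=True)
class GradientScheme:
    """Diffusion-weighting scheme: b-values (s/mm^2) plus unit directions.

    Directions with b > 0 must be unit norm (within 1e-3 on input; they are
    renormalized exactly).  A zero vector is the convention for b = 0.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (N, 3), got {bvecs.shape}")
        if len(bvals) != len(bvecs):
            raise ValueError(
                f"bvals ({len(bvals)}) and bvecs ({len(bvecs)}) length mismatch"
            )
        if not np.all(np.isfinite(bvals)) or not np.all(np.isfinite(bvecs)):
            raise ValueError("gradient table contains non-finite values")
        if np.any(bvals < 0):
            raise ValueError("negative b-value in gradient table")
        if not np.any(bvals == 0):
            raise ValueError("scheme must contain at least one b=0 measurement")
        norms = np.linalg.norm(bvecs, axis=1)
        weighted = bvals > 0
        bad = weighted & (np.abs(norms - 1.0) > _BVEC_NORM_TOL)
        if np.any(bad):
            raise ValueError(
                f"bvec norm deviates >{_BVEC_NORM_TOL} from 1 for b>0 rows "
                f"{np.flatnonzero(bad).tolist()}"
            )
        bvecs = bvecs.copy()
        bvecs[weighted] /= norms[weighted, None]
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def n_measurements(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0


@dataclass(frozen=True)
class DWIDataset:
    """A 4-D diffusion-weighted volume with its gradient scheme."""

    signal: np.ndarray  # (x, y, z, measurement)
    affine: np.ndarray  # 4x4 voxel-to-world
    scheme: GradientScheme

    def __post_init__(self) -> None:
        signal = np.asarray(self.signal, dtype=float)
        affine = np.asarray(self.affine, dtype=float)
        if signal.ndim != 4:
            raise ValueError(f"signal must be 4-D, got shape {signal.shape}")
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        if signal.shape[3] != self.scheme.n_measurements:
            raise ValueError(
                f"signal has {signal.shape[3]} volumes but scheme has "
                f"{self.scheme.n_measurements} measurements"
            )
        if not np.all(np.isfinite(signal)):
            raise ValueError("DWI signal contains non-finite values")
        object.__setattr__(self, "signal", signal)
        object.__setattr__(self, "affine", affine)

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass(frozen=True)
class RegionMask:
    """Boolean region mask on the DWI grid."""

    mask: np.ndarray
    label: str
    voxel_volume: float = 1.0  # mm^3

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask).astype(bool)
        if mask.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {mask.shape}")
        if not mask.any():
            raise ValueError(f"region mask '{self.label}' is empty")
        if self.label not in REGION_LABELS:
            raise ValueError(
                f"unknown region label '{self.label}'; expected one of {REGION_LABELS}"
            )
        object.__setattr__(self, "mask", mask)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class SubjectRecord:
    """Per-subject study metadata: group, interval and clinical scores.

    IACRS is scored 0-38, ICARS 0-100 (higher = worse).  ``cag_repeats`` and
    ``disease_duration_years`` apply to patients only and may be absent.
    """

    subject_id: str
    group: str  # "patient" | "control"
    interval_years: float
    iacrs_baseline: int
    iacrs_followup: int
    icars_baseline: int
    icars_followup: int
    cag_repeats: Optional[int] = None
    disease_duration_years: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"group must be 'patient' or 'control', got {self.group!r}")
        if not self.interval_years > 0:
            raise ValueError("interval_years must be > 0")
        for name, hi in (("iacrs_baseline", 38), ("iacrs_followup", 38),
                         ("icars_baseline", 100), ("icars_followup", 100)):
            v = getattr(self, name)
            if not (0 <= v <= hi):
                raise ValueError(f"{name}={v} outside legal range 0-{hi}")

    @property
    def iacrs_rate(self) -> float:
        return (self.iacrs_followup - self.iacrs_baseline) / self.interval_years

    @property
    def icars_rate(self) -> float:
        return (self.icars_followup - self.icars_baseline) / self.interval_years


# ---------------------------------------------------------------------------
# readers / writers


def read_dwi(image_path, bval_path, bvec_path) -> DWIDataset:
    """Load a 4-D NIfTI with its FSL-dialect bval/bvec gradient table."""
    img = nib.load(str(image_path))
    signal = np.asarray(img.dataobj, dtype=float)
    bvals = np.loadtxt(str(bval_path), ndmin=1).ravel()
    bvecs = np.loadtxt(str(bvec_path), ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous 3x3: FSL stores 3 rows x N columns
        bvecs = bvecs.T
    scheme = GradientScheme(bvals=bvals, bvecs=bvecs)
    return DWIDataset(signal=signal, affine=np.asarray(img.affine), scheme=scheme)


def write_dwi(dataset: DWIDataset, image_path, bval_path, bvec_path) -> None:
    img = nib.Nifti1Image(dataset.signal.astype(np.float32), dataset.affine)
    nib.save(img, str(image_path))
    np.savetxt(str(bval_path), dataset.scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(str(bvec_path), dataset.scheme.bvecs.T, fmt="%.10g")


def read_mask(path, label: str, companion_shape: Optional[tuple] = None) -> RegionMask:
    """Load a region mask; any nonzero voxel becomes True."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if companion_shape is not None and data.shape != tuple(companion_shape):
        raise ValueError(
            f"mask grid {data.shape} does not match companion DWI grid {companion_shape}"
        )
    voxel_volume = float(abs(np.linalg.det(np.asarray(img.affine)[:3, :3])))
    return RegionMask(mask=data != 0, label=label, voxel_volume=voxel_volume)


def write_mask(mask: RegionMask, affine: np.ndarray, path) -> None:
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), affine)
    nib.save(img, str(path))


def write_index_map(map3d: np.ndarray, affine: np.ndarray, path,
                    masked_fill: Optional[float] = None) -> None:
    """Write a 3-D index map as float32 NIfTI.

    Non-finite values are rejected unless ``masked_fill`` is given, in which
    case they are replaced (typical for NaN background outside the brain).
    Diffusivities are stored as-is in mm^2/s, never rescaled.
    """
    map3d = np.asarray(map3d, dtype=float)
    if map3d.ndim != 3:
        raise ValueError(f"index map must be 3-D, got shape {map3d.shape}")
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    bad = ~np.isfinite(map3d)
    if bad.any():
        if masked_fill is None:
            raise ValueError(
                f"{int(bad.sum())} non-finite voxels and no masked_fill specified"
            )
        map3d = np.where(bad, masked_fill, map3d)
    nib.save(nib.Nifti1Image(map3d.astype(np.float32), affine), str(path))


_MANIFEST_COLUMNS = [
    "subject_id", "group", "interval_years",
    "iacrs_baseline", "iacrs_followup", "icars_baseline", "icars_followup",
    "cag_repeats", "disease_duration_years",
]


def write_manifest(records: list[SubjectRecord], path) -> None:
    rows = []
    for r in records:
        rows.append({
            "subject_id": r.subject_id,
            "group": r.group,
            "interval_years": r.interval_years,
            "iacrs_baseline": r.iacrs_baseline,
            "iacrs_followup": r.iacrs_followup,
            "icars_baseline": r.icars_baseline,
            "icars_followup": r.icars_followup,
            "cag_repeats": r.cag_repeats if r.cag_repeats is not None else "",
            "disease_duration_years": (
                r.disease_duration_years if r.disease_duration_years is not None else ""
            ),
        })
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    missing = set(_MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        cag = row["cag_repeats"]
        dur = row["disease_duration_years"]
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            interval_years=float(row["interval_years"]),
            iacrs_baseline=int(row["iacrs_baseline"]),
            iacrs_followup=int(row["iacrs_followup"]),
            icars_baseline=int(row["icars_baseline"]),
            icars_followup=int(row["icars_followup"]),
            cag_repeats=None if pd.isna(cag) or cag == "" else int(cag),
            disease_duration_years=None if pd.isna(dur) or dur == "" else float(dur),
        ))
    return records
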