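"""Two-compartment, two-group, two-timepoint synthetic DWI studies.

The phantom places two axis-aligned boxes ("cerebrum" and
"brainstem_cerebellum") on a small grid, assigns each group/compartment a
mean eigenvalue triple with per-voxel multiplicative jitter, simulates the
monoexponential tensor signal S = s0 * exp(-b g'Dg), and corrupts it with
Rician noise.  Follow-up scans uniformly scale eigenvalues so that each
patient's brainstem-cerebellum true MD grows at a configured rate per year.
Everything is reproducible from a single seed via spawned substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core_io import (
    DWIDataset,
    GradientScheme,
    RegionMask,
    SubjectRecord,
    write_dwi,
    write_manifest,
    write_mask,
)
from .indices import indices_from_eigenvalues

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "SubjectStudy",
    "Study",
    "make_gradient_scheme",
    "simulate_signal",
    "add_rician_noise",
    "make_study",
    "write_study",
]

MS = 1e-3  # 1e-3 mm^2/s, the natural diffusivity scale

#: group/compartment mean eigenvalue triples (mm^2/s), calibrated so that
#: recovered AD/RD/FA medians land near the study's reported control/patient
#: brainstem-cerebellum values.
DEFAULT_EIGENVALUES = {
    ("control", "brainstem_cerebellum"): (1.00 * MS, 0.70 * MS, 0.70 * MS),
    ("patient", "brainstem_cerebellum"): (1.30 * MS, 1.03 * MS, 1.03 * MS),
    ("control", "cerebrum"): (1.05 * MS, 0.69 * MS, 0.69 * MS),
    ("patient", "cerebrum"): (1.05 * MS, 0.69 * MS, 0.69 * MS),
}


def _default_eigenvalues():
    return dict(DEFAULT_EIGENVALUES)


@dataclass
class PhantomSpec:
    """Full parameterization of a synthetic two-group longitudinal study."""

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    eigenvalues: dict = field(default_factory=_default_eigenvalues)
    jitter: float = 0.10  # per-voxel multiplicative eigenvalue jitter fraction
    direction_model: str = "fixed"  # {"fixed", "random"}
    s0: float = 100.0
    noise_sigma: float = 5.0  # SNR s0/sigma = 20 by default
    md_rate_patient_bc: float = 0.010 * MS  # mm^2/s per year
    md_rate_control: float = -0.003 * MS
    fa_drift_rate: float = 0.0  # fractional deviatoric scaling per year, patients BC
    n_patients: int = 9
    n_controls: int = 16
    interval_years: tuple[float, float] = (1.9, 4.7)  # uniform(low, high)
    n_directions: int = 15
    b_value: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for key, triple in self.eigenvalues.items():
            lam = np.asarray(triple, dtype=float)
            if lam.shape != (3,):
                raise ValueError(f"eigenvalue triple for {key} must have 3 entries")
            if np.any(lam <= 0):
                raise ValueError(f"eigenvalue means for {key} must be > 0")
            if not (lam[0] >= lam[1] >= lam[2]):
                raise ValueError(f"eigenvalue means for {key} must be sorted descending")
        if not 0 <= self.jitter <= 0.5:
            raise ValueError("jitter fraction must be in [0, 0.5]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.direction_model not in ("fixed", "random"):
            raise ValueError("direction_model must be 'fixed' or 'random'")
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("need at least one subject per group")
        lo, hi = self.interval_years
        if not (0 < lo <= hi):
            raise ValueError("interval_years bounds must satisfy 0 < low <= high")
        for label, msk in self.geometry().items():
            n = int(msk.sum())
            if n < 200:
                raise ValueError(
                    f"compartment '{label}' has {n} voxels; needs >= 200 "
                    f"(grid {self.grid_shape} too small)"
                )

    def geometry(self) -> dict[str, np.ndarray]:
        """Two non-overlapping boxes stacked along z, 1-voxel margins."""
        nx, ny, nz = self.grid_shape
        half = nz // 2
        cerebrum = np.zeros(self.grid_shape, dtype=bool)
        bc = np.zeros(self.grid_shape, dtype=bool)
        cerebrum[1:nx - 1, 1:ny - 1, 1:half - 1] = True
        bc[1:nx - 1, 1:ny - 1, half + 1:nz - 1] = True
        return {"cerebrum": cerebrum, "brainstem_cerebellum": bc}


@dataclass
class GroundTruth:
    """Noise-free truth behind a study: per-voxel eigenvalues and medians.

    ``eigenvalues[(subject_id, timepoint, region)]`` is a (n_voxels, 3) array
    of descending true eigenvalues; ``true_medians`` is a tidy table of the
    per-subject per-region median of each index computed from them.
    """

    eigenvalues: dict[tuple[str, str, str], np.ndarray]
    true_medians: pd.DataFrame
    md_rates: dict[str, float]  # per-group true BC MD rate (mm^2/s / year)


@dataclass
class SubjectStudy:
    record: SubjectRecord
    baseline: DWIDataset
    followup: DWIDataset


@dataclass
class Study:
    subjects: list[SubjectStudy]
    masks: dict[str, RegionMask]
    scheme: GradientScheme
    ground_truth: GroundTruth
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# gradient scheme


def make_gradient_scheme(n_directions: int, b_value: float, seed: int) -> GradientScheme:
    """One b=0 measurement plus electrostatically spread unit directions.

    Directions repel each other (and their antipodes) on the sphere until the
    layout settles; the result is deterministic given the seed, pairwise
    separated by at least 10 degrees and of rank 3 (non-coplanar).
    """
    if n_directions < 6:
        raise ValueError("need at least 6 diffusion directions for a tensor fit")
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n_directions, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    step = 0.05
    for _ in range(400):
        force = np.zeros_like(pts)
        for sign in (1.0, -1.0):
            diff = pts[:, None, :] - sign * pts[None, :, :]  # (n, n, 3)
            dist2 = np.sum(diff * diff, axis=2)
            # self terms excluded: the self-antipode force is purely radial
            # and vanishes after tangent-plane projection anyway
            np.fill_diagonal(dist2, np.inf)
            force += np.sum(diff / (dist2 ** 1.5)[:, :, None], axis=1)
        # project onto tangent plane and take a small step
        force -= np.sum(force * pts, axis=1, keepdims=True) * pts
        pts += step * force / n_directions
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    cosang = np.abs(pts @ pts.T)
    np.fill_diagonal(cosang, 0.0)
    min_angle = np.degrees(np.arccos(np.clip(cosang.max(), -1, 1)))
    if min_angle < 10.0:
        raise RuntimeError(
            f"direction placement failed: minimum pairwise angle {min_angle:.2f} deg"
        )
    if np.linalg.matrix_rank(pts, tol=1e-6) < 3:
        raise RuntimeError("direction placement failed: coplanar set")
    bvals = np.concatenate([[0.0], np.full(n_directions, float(b_value))])
    bvecs = np.vstack([np.zeros(3), pts])
    return GradientScheme(bvals=bvals, bvecs=bvecs)


# ---------------------------------------------------------------------------
# signal model


def _as_tensor3x3(tensor) -> np.ndarray:
    t = np.asarray(tensor, dtype=float)
    if t.shape == (6,):
        dxx, dyy, dzz, dxy, dxz, dyz = t
        t = np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
    if t.shape != (3, 3):
        raise ValueError(f"tensor must be 3x3 or a 6-vector, got shape {t.shape}")
    if not np.allclose(t, t.T, atol=1e-12):
        raise ValueError("tensor must be symmetric")
    return t


def simulate_signal(tensor, scheme: GradientScheme, s0: float) -> np.ndarray:
    """Noise-free monoexponential signal S = s0 * exp(-b g'Dg) per measurement."""
    t = _as_tensor3x3(tensor)
    quad = scheme.bvals * np.einsum("ni,ij,nj->n", scheme.bvecs, t, scheme.bvecs)
    if np.any(quad < -1e-12):
        raise ValueError("tensor is not positive semi-definite along a gradient")
    signal = s0 * np.exp(-np.clip(quad, 0.0, None))
    signal[scheme.b0_mask] = s0  # exact at b=0
    return signal


def _simulate_signals_batch(evals: np.ndarray, evecs: Optional[np.ndarray],
                            scheme: GradientScheme, s0: float) -> np.ndarray:
    """Vectorized signal for (V, 3) eigenvalues and optional (V, 3, 3) frames."""
    g = scheme.bvecs  # (N, 3)
    if evecs is None:
        quad = (g ** 2) @ evals.T  # (N, V) for axis-aligned tensors
        quad = quad.T
    else:
        ge = np.einsum("nk,vkj->vnj", g, evecs)  # gradient in eigenframe
        quad = np.einsum("vnj,vj->vn", ge ** 2, evals)
    quad = quad * scheme.bvals[None, :]
    signal = s0 * np.exp(-np.clip(quad, 0.0, None))
    signal[:, scheme.b0_mask] = s0
    return signal


def add_rician_noise(signals: np.ndarray, noise_sigma: float, rng) -> np.ndarray:
    """Rician-corrupt magnitudes: sqrt((S + e1)^2 + e2^2), e ~ N(0, sigma)."""
    signals = np.asarray(signals, dtype=float)
    if np.any(signals < 0):
        raise ValueError("signals must be non-negative")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if noise_sigma == 0:
        return signals.copy()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    e1 = rng.normal(0.0, noise_sigma, signals.shape)
    e2 = rng.normal(0.0, noise_sigma, signals.shape)
    return np.sqrt((signals + e1) ** 2 + e2 ** 2)


# ---------------------------------------------------------------------------
# study assembly


def _random_rotations(n: int, rng) -> np.ndarray:
    """Uniform random rotation matrices via QR of Gaussian matrices."""
    a = rng.standard_normal((n, 3, 3))
    q, r = np.linalg.qr(a)
    d = np.sign(np.einsum("vii->vi", r))
    q = q * d[:, None, :]
    det = np.linalg.det(q)
    q[det < 0, :, 0] *= -1.0
    return q


def _sample_eigenvalues(mean_triple, n_voxels, jitter, rng) -> np.ndarray:
    lam = np.asarray(mean_triple, dtype=float)[None, :] * (
        1.0 + jitter * rng.uniform(-1.0, 1.0, (n_voxels, 3))
    )
    return -np.sort(-lam, axis=1)


def _apply_followup_change(evals: np.ndarray, md_rate: float, fa_drift_rate: float,
                           interval_years: float) -> np.ndarray:
    """Uniformly scale each voxel's eigenvalues so true MD moves by rate * dt."""
    md = evals.mean(axis=1, keepdims=True)
    factor = 1.0 + md_rate * interval_years / md
    if np.any(factor <= 0):
        raise ValueError("follow-up MD change would produce non-positive eigenvalues")
    out = evals * factor
    if fa_drift_rate != 0.0:
        md_new = out.mean(axis=1, keepdims=True)
        out = md_new + (out - md_new) * (1.0 + fa_drift_rate * interval_years)
        out = -np.sort(-out, axis=1)
    return out


def _clinical_scores(rng, interval: float) -> dict:
    """Patient clinical scores shaped like the study population."""
    iacrs_b = int(np.clip(round(rng.normal(17.2, 4.3)), 0, 38))
    icars_b = int(np.clip(round(rng.normal(39.7, 14.3)), 0, 100))
    iacrs_fu = int(np.clip(iacrs_b + max(0, round(rng.normal(1.15, 0.8) * interval)), 0, 38))
    icars_fu = int(np.clip(icars_b + max(0, round(rng.normal(1.40, 1.2) * interval)), 0, 100))
    return {
        "iacrs_baseline": iacrs_b, "iacrs_followup": iacrs_fu,
        "icars_baseline": icars_b, "icars_followup": icars_fu,
        "cag_repeats": int(np.clip(round(rng.normal(40.6, 1.4)), 34, 60)),
        "disease_duration_years": float(np.round(rng.uniform(2.0, 23.0), 1)),
    }


def make_study(spec: PhantomSpec) -> Study:
    """Build the full in-memory study: DWIs, masks, records, ground truth."""
    geometry = spec.geometry()
    masks = {label: RegionMask(mask=m, label=label) for label, m in geometry.items()}
    scheme = make_gradient_scheme(spec.n_directions, spec.b_value, seed=spec.seed)
    affine = np.eye(4)

    root = np.random.SeedSequence(spec.seed)
    n_subjects = spec.n_patients + spec.n_controls
    subject_seeds = root.spawn(n_subjects)

    groups = ["patient"] * spec.n_patients + ["control"] * spec.n_controls
    subjects: list[SubjectStudy] = []
    gt_evals: dict[tuple[str, str, str], np.ndarray] = {}
    median_rows = []

    for i, (group, sseq) in enumerate(zip(groups, subject_seeds)):
        subject_id = f"{'P' if group == 'patient' else 'C'}{i + 1:02d}"
        tissue_rng, clin_rng, noise0_rng, noise1_rng = (
            np.random.default_rng(s) for s in sseq.spawn(4)
        )

        interval = float(np.round(clin_rng.uniform(*spec.interval_years), 2))
        if group == "patient":
            clinical = _clinical_scores(clin_rng, interval)
        else:
            clinical = {
                "iacrs_baseline": 0, "iacrs_followup": 0,
                "icars_baseline": 0, "icars_followup": 0,
                "cag_repeats": None, "disease_duration_years": None,
            }
        record = SubjectRecord(subject_id=subject_id, group=group,
                               interval_years=interval, **clinical)

        volumes = {"baseline": None, "followup": None}
        for tp in volumes:
            volumes[tp] = np.zeros(spec.grid_shape + (scheme.n_measurements,))

        for label, compartment in geometry.items():
            n_vox = int(compartment.sum())
            evals0 = _sample_eigenvalues(spec.eigenvalues[(group, label)],
                                         n_vox, spec.jitter, tissue_rng)
            if label == "brainstem_cerebellum":
                rate = (spec.md_rate_patient_bc if group == "patient"
                        else spec.md_rate_control)
                drift = spec.fa_drift_rate if group == "patient" else 0.0
            else:
                rate, drift = 0.0, 0.0
            evals1 = _apply_followup_change(evals0, rate, drift, interval)

            if spec.direction_model == "random":
                evecs = _random_rotations(n_vox, tissue_rng)
            else:
                evecs = None

            for tp, evals in (("baseline", evals0), ("followup", evals1)):
                volumes[tp][compartment] = _simulate_signals_batch(
                    evals, evecs, scheme, spec.s0)
                gt_evals[(subject_id, tp, label)] = evals
                idx = indices_from_eigenvalues(evals)
                for name, vals in idx.items():
                    median_rows.append({
                        "subject_id": subject_id, "group": group, "timepoint": tp,
                        "region": label, "index": name,
                        "true_median": float(np.median(vals)),
                    })

        noisy = {}
        for tp, rng in (("baseline", noise0_rng), ("followup", noise1_rng)):
            noisy[tp] = add_rician_noise(volumes[tp], spec.noise_sigma, rng)
        subjects.append(SubjectStudy(
            record=record,
            baseline=DWIDataset(signal=noisy["baseline"], affine=affine, scheme=scheme),
            followup=DWIDataset(signal=noisy["followup"], affine=affine, scheme=scheme),
        ))

    ground_truth = GroundTruth(
        eigenvalues=gt_evals,
        true_medians=pd.DataFrame(median_rows),
        md_rates={"patient": spec.md_rate_patient_bc,
                  "control": spec.md_rate_control},
    )
    return Study(subjects=subjects, masks=masks, scheme=scheme,
                 ground_truth=ground_truth, spec=spec)


def write_study(study: Study, outdir) -> Path:
    """Write a study to disk: NIfTI DWIs + bval/bvec, masks, manifest, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    for label, mask in study.masks.items():
        write_mask(mask, affine, outdir / f"mask_{label}.nii.gz")
    for subj in study.subjects:
        for tp, ds in (("baseline", subj.baseline), ("followup", subj.followup)):
            stem = outdir / f"{subj.record.subject_id}_{tp}"
            write_dwi(ds, f"{stem}_dwi.nii.gz", f"{stem}.bval", f"{stem}.bvec")
    write_manifest([s.record for s in study.subjects], outdir / "manifest.csv")
    truth = {
        "md_rates": study.ground_truth.md_rates,
        "true_medians": study.ground_truth.true_medians.to_dict(orient="records"),
        "seed": study.spec.seed,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return outdir
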