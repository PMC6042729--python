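# dtihist

Histogram analysis of DTI-derived index maps for detecting and tracking
regional neurodegeneration, built as a tested, reusable pipeline:

* **robust tensor fitting** — b-matrix construction and rotation (polar
  decomposition of the eddy-correction affine), log-linear (LLS) and
  weighted (WLLS) fits, and an iteratively-reweighted robust fit with
  Geman–McClure weights and 3σ outlier rejection;
* **five index maps** — MD, FA, AD, RD and the mode of anisotropy MO
  (deviatoric-determinant definition, −1 planar … +1 linear);
* **per-region normalized histograms** — median (from raw voxel values),
  peak location and peak height, with study bin widths (0.05×10⁻³ mm²/s for
  MD/AD/RD, 0.03 for FA, 0.08 for MO);
* **longitudinal statistics** — per-year rates of change, exact
  Mann–Whitney group comparisons with Holm–Bonferroni correction, Pearson
  correlations against clinical variables, and the standardised response
  mean (SRM);
* **synthetic phantom** — a two-compartment ("cerebrum" /
  "brainstem-cerebellum"), two-group, two-timepoint DWI study with known
  ground-truth tensors, Rician noise, and a configurable patient-only MD
  rate of change, so every stage has a parameter-recovery surface.

## CLI

```sh
dtihist simulate --preset paper_like --seed 1 --out study/     # write a study
dtihist fit --dwi study/P01_baseline_dwi.nii.gz \
            --bval study/P01_baseline.bval --bvec study/P01_baseline.bvec \
            --method restore --sigma 5 --out fit/
dtihist indices --tensor fit/tensor.nii.gz --out maps/
dtihist histo --maps maps/ --mask-cerebrum study/mask_cerebrum.nii.gz \
              --mask-bc study/mask_brainstem_cerebellum.nii.gz --out metrics.csv
dtihist stats --metrics run/metrics.csv --manifest run/manifest.csv --out stats/
dtihist run-all --preset paper_like --seed 1 --out run/        # whole chain
```

`run-all` also accepts a YAML config (`--config run.yaml`) with `fit_method`,
`alpha` and a `phantom:` block mirroring `PhantomSpec` fields. Every run is
deterministic given `--seed`; the seed and configuration are echoed to
`run_log.json` in the output directory.

Presets: `paper_like` (9 patients / 16 controls, calibrated group effects),
`null` (identical groups, zero rates — for calibration), `tiny` (3/4
subjects — fast smoke runs).

## Conventions

* diffusivities are mm²/s internally; tables print ×10⁻³ mm²/s for display;
* bvecs use the FSL image-frame dialect (3 rows × N columns on disk);
* design rows are `b·(gx², gy², gz², 2gxgy, 2gxgz, 2gygz)` plus an
  ln(S0) intercept;
* non-positive signals are clamped to half the voxel's smallest positive
  measurement before the log transform (and flagged); negative eigenvalues
  from noisy fits are kept, not clamped — voxels are instead marked invalid
  when λ₁ ≤ 0.
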