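# alffkit

A toolkit for resting-state fMRI ALFF (amplitude of low-frequency
fluctuation) analysis:

- **Synthetic cohorts** (`alffkit.synth`): 4D runs built from in-band
  sinusoids at exact FFT bins, nuisance frequencies and spatially smoothed
  noise, with planted group effects in spherical ROIs, grey-matter
  probability maps, motion traces, and a clinical table optionally coupled
  to the true ROI amplitude — every downstream stage has a recoverable
  ground truth.
- **Preprocessing** (`alffkit.preprocess`): initial-volume discard, motion
  QC (< 2 mm displacement range, < 1° rotation range), Gaussian smoothing
  (FWHM in mm), and an ideal frequency-domain band-pass (0.01–0.08 Hz by
  default).
- **ALFF** (`alffkit.alff`): per-voxel mean of the one-sided amplitude
  spectrum over the in-band bins, standardized by the global (in-mask)
  mean (mALFF).
- **Group inference** (`alffkit.inference`): pooled-variance voxel-wise
  t-maps, suprathreshold cluster extraction (6/18/26-connectivity),
  cluster-level FWE by permutation of group labels (max-cluster-size
  null), and covariate-adjusted models — a voxel-wise image covariate
  (GM probability) or a scalar covariate (e.g. TIV). Also the scalar
  helpers: summary-data t-test, 2×2 chi-square, Student-t quantiles.
- **Clinical statistics** (`alffkit.clinical`): progression rate
  `(40 − ALSFRS) / duration`, VOI mean extraction, Pearson correlations
  with two-tailed p-values.
- **I/O and reporting** (`alffkit.io`, `alffkit.coords`,
  `alffkit.pipeline`): NIfTI-1 round-trips via nibabel, MNI→Talairach
  conversion (Brett piecewise-affine constants), and an end-to-end driver
  that writes mALFF maps, t-maps, cluster tables with both coordinate
  spaces, and VOI–clinical correlation tables.

## CLI

```bash
alffkit simulate   --config synth.yaml --out cohort/ --seed 7
alffkit preprocess --in run.nii.gz --out filtered.nii.gz --discard 10 --fwhm 8 --band 0.01 0.08
alffkit alff       --in filtered.nii.gz --mask mask.nii.gz --out alff.nii.gz --standardized malff.nii.gz
alffkit group      --design design.csv --mask mask.nii.gz --cluster-t 3.32 --alpha 0.05 --perms 5000 --seed 7 --out clusters.csv
alffkit correlate  --clinical clinical.csv --design design.csv --voi roi=voi.nii.gz --out corr.csv
alffkit report     --config pipeline.yaml --out report/ --seed 7
```

`design.csv` needs columns `subject_id`, `group` (`patient`/`control`) and
`malff_path`; add `gm_path` for `--gm-covariate` or a named numeric column
for `--scalar-covariate`. The `simulate`/`report` YAML files mirror the
`SynthConfig` / pipeline fields (see `tests/test_cli.py` for worked
examples).

## Conventions

- A frequency bin is in-band iff `f_lo ≤ k/(N·TR) ≤ f_hi` (edges
  inclusive); the FFT length equals the number of retained time points.
- One-sided amplitude normalization is `2/N` (`1/N` at DC/Nyquist), so an
  exact-bin sinusoid of amplitude A reads back as A; the constant cancels
  in mALFF.
- Motion QC uses the peak-to-peak range per axis with strict inequality.
- Corrected cluster p-values use the add-one estimator
  `(1 + #{null ≥ obs}) / (1 + B)`; when the label arrangements number at
  most B the null is enumerated exhaustively.
- Voxel indices are 0-based; world coordinates come from the image affine.
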