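"""Synthetic resting-state cohorts with planted, recoverable effects.

Each subject's voxel time series is a sum of in-band sinusoids placed at
exact FFT bin frequencies (so closed-form spectra are available to tests),
out-of-band nuisance sinusoids, and spatially smoothed white noise.  Group
differences are planted as amplitude multipliers inside spherical ROIs for
the patient group; a clinical covariate can be coupled to the true ROI
amplitude at a target Pearson correlation.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .preprocess import smooth_gaussian
from .types import BrainMask, ConfigError, Fmri4D, MotionTrace, ScalarMap

__all__ = [
    "EffectROI",
    "SynthConfig",
    "GroundTruth",
    "SubjectData",
    "Cohort",
    "sphere_mask",
    "signal_bin_freqs",
    "generate_subject",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class EffectROI:
    """A spherical region where patients get a planted amplitude change.

    ``multiplier`` scales the patient group's in-band amplitude inside the
    sphere (> 1 increase, < 1 decrease, 1 null).
    """

    center_vox: Tuple[int, int, int]
    radius_mm: float
    multiplier: float = 1.0


@dataclass(frozen=True)
class SynthConfig:
    grid_dims: Tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: Tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr_s: float = 2.0
    n_volumes: int = 200
    n_per_group: int = 20
    baseline_amp: float = 1.0
    effect_rois: Tuple[EffectROI, ...] = ()
    nuisance_freqs_hz: Tuple[Tuple[float, float], ...] = ()  # (freq, amplitude)
    white_noise_sd: float = 0.0
    smoothness_fwhm_mm: float = 6.0
    band_lo_hz: float = 0.01
    band_hi_hz: float = 0.08
    n_sinusoids: int = 8
    # frequencies sit on exact FFT bins of (n_volumes - n_discard) samples,
    # so they remain exact bins after the pipeline's initial-volume discard
    n_discard: int = 0
    # per-subject lognormal jitter of the effect-ROI amplitude; 0 = none.
    # ROI-local (not global) so it survives global-mean standardization
    subject_amp_sd: float = 0.0
    clinical_coupling_r: Optional[float] = None
    coupled_variable: str = "duration_months"
    coupled_roi: int = 0
    gm_roi_coupling: float = 0.0
    motion_violators: Tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_dims) != 3 or any(d <= 0 for d in self.grid_dims):
            raise ConfigError(f"grid_dims must be 3 positive ints: {self.grid_dims}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ConfigError("voxel sizes must be positive")
        if self.tr_s <= 0:
            raise ConfigError("tr_s must be positive")
        if self.n_volumes <= 20:
            raise ConfigError(f"n_volumes must be > 20, got {self.n_volumes}")
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be >= 1")
        if self.baseline_amp < 0 or self.white_noise_sd < 0:
            raise ConfigError("amplitudes must be >= 0")
        if not 0 <= self.n_discard < self.n_volumes - 1:
            raise ConfigError("n_discard out of range")
        if self.clinical_coupling_r is not None and not (
            0 < abs(self.clinical_coupling_r) < 1
        ):
            raise ConfigError("clinical_coupling_r magnitude must be in (0, 1)")
        for roi in self.effect_rois:
            for c, d, v in zip(roi.center_vox, self.grid_dims, self.voxel_size_mm):
                if not 0 <= c < d:
                    raise ConfigError(f"ROI center {roi.center_vox} outside grid")
                if c * v - roi.radius_mm < -v / 2 or c * v + roi.radius_mm > (d - 0.5) * v:
                    raise ConfigError(
                        f"ROI sphere at {roi.center_vox} r={roi.radius_mm}mm exceeds grid"
                    )
            if roi.multiplier < 0:
                raise ConfigError("ROI multiplier must be >= 0")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([*self.voxel_size_mm, 1.0])
        # center the grid on the world origin, RAS-ish
        aff[:3, 3] = -(np.array(self.grid_dims) - 1) / 2.0 * self.voxel_size_mm
        return aff

    @property
    def n_kept(self) -> int:
        return self.n_volumes - self.n_discard


def sphere_mask(grid_dims, voxel_size_mm, center_vox, radius_mm) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within radius_mm of center."""
    grids = np.indices(grid_dims).astype(float)
    d2 = np.zeros(grid_dims)
    for ax in range(3):
        d2 += ((grids[ax] - center_vox[ax]) * voxel_size_mm[ax]) ** 2
    return d2 <= radius_mm**2


def signal_bin_freqs(config: SynthConfig) -> np.ndarray:
    """In-band signal frequencies: distinct exact FFT bins of the kept-length
    series, drawn deterministically from the cohort seed."""
    n = config.n_kept
    freqs = np.fft.rfftfreq(n, d=config.tr_s)
    inband = np.nonzero(
        (freqs >= config.band_lo_hz) & (freqs <= config.band_hi_hz)
    )[0]
    if inband.size < config.n_sinusoids:
        raise ConfigError(
            f"only {inband.size} in-band bins for n={n}, tr={config.tr_s}; "
            f"need {config.n_sinusoids}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xF0]))
    chosen = rng.choice(inband, size=config.n_sinusoids, replace=False)
    return freqs[np.sort(chosen)]


@dataclass
class SubjectData:
    subject_id: str
    group: str
    run: Fmri4D
    gm_map: ScalarMap
    motion: MotionTrace


@dataclass
class GroundTruth:
    """Everything a recovery oracle needs about the planted effects."""

    amplitude_maps: np.ndarray        # (n_subjects, x, y, z) true per-sinusoid amp
    roi_masks: List[np.ndarray]       # boolean, one per effect ROI
    subject_ids: List[str]
    subject_scales: np.ndarray        # per-subject ROI amplitude factor
    planted_r: Optional[float]
    coupled_variable: Optional[str]

    def __post_init__(self) -> None:
        if (self.amplitude_maps < 0).any():
            raise ConfigError("true amplitude map must be nonnegative")


@dataclass
class Cohort:
    config: SynthConfig
    subjects: List[SubjectData]
    clinical: pd.DataFrame
    truth: GroundTruth

    @property
    def mask(self) -> BrainMask:
        return BrainMask(np.ones(self.config.grid_dims, dtype=bool),
                         self.config.affine)


def _amplitude_map(config: SynthConfig, group: str, roi_scale: float) -> np.ndarray:
    amp = np.full(config.grid_dims, config.baseline_amp)
    for roi in config.effect_rois:
        m = sphere_mask(config.grid_dims, config.voxel_size_mm,
                        roi.center_vox, roi.radius_mm)
        mult = roi.multiplier if group == "patient" else 1.0
        amp[m] *= mult * roi_scale
    return amp


def _motion_trace(rng: np.random.Generator, n_vols: int, violate: bool) -> MotionTrace:
    # small random walk, rescaled well inside the 2 mm / 1 deg QC limits
    steps = rng.normal(size=(n_vols, 6))
    walk = np.cumsum(steps, axis=0)
    walk -= walk[0]
    ptp = np.ptp(walk, axis=0)
    ptp[ptp == 0] = 1.0
    walk[:, :3] *= 0.5 / ptp[:3]   # max 0.5 mm range
    walk[:, 3:] *= 0.2 / ptp[3:]   # max 0.2 deg range
    if violate:
        walk[n_vols // 2:, 0] += 3.0  # 3 mm jump in x
    return MotionTrace(walk)


def generate_subject(
    config: SynthConfig,
    group: str,
    subject_seed: int,
    subject_id: str = "",
    roi_amp_scale: float = 1.0,
    violate_motion: bool = False,
):
    """Generate one subject's 4D run, GM probability map and motion trace.

    Deterministic given (config, group, subject_seed).  Returns
    ``(Fmri4D, ScalarMap, MotionTrace, amplitude_map)`` where the last item
    is the true per-sinusoid in-band amplitude at every voxel.
    """
    if group not in ("patient", "control"):
        raise ConfigError(f"group must be patient/control, got {group!r}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, subject_seed]))
    dims = config.grid_dims
    n_t = config.n_volumes
    t = np.arange(n_t) * config.tr_s

    amp = _amplitude_map(config, group, roi_amp_scale)
    freqs = signal_bin_freqs(config)

    # sin(wt + phi) = cos(phi) sin(wt) + sin(phi) cos(wt): evaluate the
    # transcendentals per voxel (phases) and per timepoint (carriers) only
    data = np.zeros((*dims, n_t))
    for f in freqs:
        phase = rng.uniform(0, 2 * np.pi, size=dims)
        wt = 2 * np.pi * f * t
        data += (amp * np.cos(phase))[..., None] * np.sin(wt)
        data += (amp * np.sin(phase))[..., None] * np.cos(wt)
    for f, a in config.nuisance_freqs_hz:
        phase = rng.uniform(0, 2 * np.pi, size=dims)
        wt = 2 * np.pi * f * t
        data += (a * np.cos(phase))[..., None] * np.sin(wt)
        data += (a * np.sin(phase))[..., None] * np.cos(wt)
    if config.white_noise_sd > 0:
        noise = rng.normal(0, config.white_noise_sd, size=(*dims, n_t))
        if config.smoothness_fwhm_mm > 0:
            noise = smooth_gaussian(noise, config.smoothness_fwhm_mm,
                                    config.voxel_size_mm)
        data += noise

    gm = rng.normal(size=dims)
    gm = smooth_gaussian(gm, 4 * max(config.voxel_size_mm), config.voxel_size_mm)
    gm = (gm - gm.min()) / max(gm.max() - gm.min(), 1e-12)
    if config.gm_roi_coupling != 0 and group == "patient":
        for roi in config.effect_rois:
            m = sphere_mask(dims, config.voxel_size_mm, roi.center_vox, roi.radius_mm)
            gm[m] += config.gm_roi_coupling
        gm = np.clip(gm, 0.0, 1.0)

    run = Fmri4D(data, config.tr_s, config.affine, subject_id=subject_id)
    gm_map = ScalarMap(gm, config.affine, kind="gm_prob")
    motion = _motion_trace(rng, n_t, violate_motion)
    return run, gm_map, motion, amp


def _coupled_covariate(rng, anchor: np.ndarray, r: float) -> np.ndarray:
    """Standardized covariate with sample Pearson correlation exactly r to
    ``anchor`` (noise orthogonalized against the standardized anchor)."""
    z = (anchor - anchor.mean()) / anchor.std()
    e = rng.normal(size=anchor.size)
    e = e - e.mean()
    e = e - (e @ z) / (z @ z) * z
    norm = np.sqrt((e @ e) / e.size)
    if norm < 1e-12:  # pathological draw; fall back to raw noise
        e = rng.normal(size=anchor.size)
        e = (e - e.mean()) / e.std()
    else:
        e = e / norm
    return r * z + np.sqrt(1 - r * r) * e


def generate_cohort(config: SynthConfig) -> Cohort:
    """Generate 2 x n_per_group subjects plus clinical table and ground truth.

    Patients come first (``sub-p01`` ...), controls second (``sub-c01`` ...).
    When ``clinical_coupling_r`` is set, the designated clinical variable is
    constructed to correlate with the patients' true amplitude in the
    designated effect ROI.
    """
    if config.n_per_group < 2:
        raise ConfigError("n_per_group must be >= 2 for a cohort")
    n = config.n_per_group
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0]))

    groups = ["patient"] * n + ["control"] * n
    ids = [f"sub-p{i + 1:02d}" for i in range(n)] + \
          [f"sub-c{i + 1:02d}" for i in range(n)]
    scales = (
        np.exp(rng.normal(0, config.subject_amp_sd, size=2 * n))
        if config.subject_amp_sd > 0 else np.ones(2 * n)
    )
    violators = set(config.motion_violators)

    subjects: List[SubjectData] = []
    amp_maps = np.empty((2 * n, *config.grid_dims))
    for i, (sid, grp) in enumerate(zip(ids, groups)):
        run, gm, motion, amp = generate_subject(
            config, grp, subject_seed=i + 1, subject_id=sid,
            roi_amp_scale=scales[i], violate_motion=(i in violators),
        )
        subjects.append(SubjectData(sid, grp, run, gm, motion))
        amp_maps[i] = amp

    roi_masks = [
        sphere_mask(config.grid_dims, config.voxel_size_mm,
                    roi.center_vox, roi.radius_mm)
        for roi in config.effect_rois
    ]

    # clinical table
    age = rng.normal(46, 10, size=2 * n)
    sex = rng.choice(["M", "F"], size=2 * n, p=[0.65, 0.35])
    alsfrs = np.clip(rng.normal(32, 5, size=n), 0, 40)
    duration = np.clip(rng.lognormal(np.log(24), 0.5, size=n), 1.0, None)

    if config.clinical_coupling_r is not None:
        if not config.effect_rois:
            raise ConfigError("clinical coupling requires at least one effect ROI")
        roi = roi_masks[config.coupled_roi]
        anchor = np.array([amp_maps[i][roi].mean() for i in range(n)])  # patients
        if anchor.std() == 0:
            raise ConfigError(
                "clinical coupling needs between-subject amplitude variance; "
                "set subject_amp_sd > 0"
            )
        c = _coupled_covariate(rng, anchor, config.clinical_coupling_r)
        if config.coupled_variable == "duration_months":
            duration = np.clip(24.0 + 6.0 * c, 0.5, None)
        elif config.coupled_variable == "alsfrs":
            alsfrs = np.clip(31.0 + 4.0 * c, 0.0, 40.0)
        else:
            raise ConfigError(
                f"cannot couple to {config.coupled_variable!r}; "
                "use duration_months or alsfrs"
            )

    rate = (40.0 - alsfrs) / duration
    clinical = pd.DataFrame({
        "subject_id": ids,
        "group": groups,
        "age_years": np.round(age, 1),
        "sex": sex,
        "alsfrs": np.concatenate([alsfrs, np.full(n, np.nan)]),
        "duration_months": np.concatenate([duration, np.full(n, np.nan)]),
        "progression_rate": np.concatenate([rate, np.full(n, np.nan)]),
    })

    truth = GroundTruth(
        amplitude_maps=amp_maps,
        roi_masks=roi_masks,
        subject_ids=ids,
        subject_scales=scales,
        planted_r=config.clinical_coupling_r,
        coupled_variable=(
            config.coupled_variable if config.clinical_coupling_r is not None else None
        ),
    )
    return Cohort(config=config, subjects=subjects, clinical=clinical, truth=truth)


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write runs, GM maps and motion traces per subject, the clinical table,
    and ground-truth ROI masks with a plain-text manifest."""
    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sub in cohort.subjects:
        _io.write_nifti(out / f"{sub.subject_id}_bold.nii.gz", sub.run)
        _io.write_nifti(out / f"{sub.subject_id}_gm.nii.gz", sub.gm_map)
        np.savetxt(out / f"{sub.subject_id}_motion.txt", sub.motion.params,
                   fmt="%.6f")
    cohort.clinical.to_csv(out / "clinical.csv", index=False)
    truth_dir = out / "ground_truth"
    truth_dir.mkdir(exist_ok=True)
    lines = [f"seed: {cohort.config.seed}",
             f"n_subjects: {len(cohort.subjects)}",
             f"planted_r: {cohort.truth.planted_r}"]
    for i, m in enumerate(cohort.truth.roi_masks):
        roi = cohort.config.effect_rois[i]
        mask = BrainMask(m, cohort.config.affine) if m.any() else None
        if mask is not None:
            _io.write_nifti(truth_dir / f"roi_{i:02d}.nii.gz", mask)
        lines.append(
            f"roi_{i:02d}: center={roi.center_vox} radius_mm={roi.radius_mm} "
            f"multiplier={roi.multiplier} n_voxels={int(m.sum())}"
        )
    (truth_dir / "manifest.txt").write_text("\n".join(lines) + "\n")
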