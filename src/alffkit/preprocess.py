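"""Minimal preprocessing before ALFF: volume discard, motion QC, spatial
smoothing, and ideal band-pass filtering.

Slice timing, realignment and spatial normalization are out of scope:
synthetic runs are generated already aligned on a common grid, and motion
QC consumes externally supplied parameter traces.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import BandSpec, Fmri4D, InputError, MotionTrace

__all__ = [
    "discard_initial",
    "motion_qc",
    "QCResult",
    "bandpass_ideal",
    "bandpass_run",
    "smooth_gaussian",
    "smooth_run",
    "detrend_linear",
    "fwhm_to_sigma_voxels",
    "DEFAULT_MAX_TRANS_MM",
    "DEFAULT_MAX_ROT_DEG",
]

DEFAULT_MAX_TRANS_MM = 2.0
DEFAULT_MAX_ROT_DEG = 1.0

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


def discard_initial(run: Fmri4D, k: int) -> Fmri4D:
    """Drop the first ``k`` volumes; TR and affine are unchanged."""
    if k < 0:
        raise InputError(f"k must be >= 0, got {k}")
    if k >= run.n_volumes:
        raise InputError(f"cannot discard {k} of {run.n_volumes} volumes")
    if k == 0:
        return run
    return Fmri4D(
        data=run.data[..., k:],
        tr_s=run.tr_s,
        affine=run.affine,
        subject_id=run.subject_id,
    )


@dataclass(frozen=True)
class QCResult:
    passed: bool
    failing_axes: tuple  # e.g. ("trans_x", "rot_z")

    def __bool__(self) -> bool:
        return self.passed


def motion_qc(
    trace: MotionTrace,
    max_trans_mm: float = DEFAULT_MAX_TRANS_MM,
    max_rot_deg: float = DEFAULT_MAX_ROT_DEG,
) -> QCResult:
    """Pass iff every axis' displacement range is strictly below the limits.

    Displacement is the peak-to-peak range of each parameter over the run;
    a range exactly equal to the limit fails (strict "less than" passes).
    """
    axes = ("x", "y", "z")
    failing = []
    trans_range = np.ptp(trace.translations_mm, axis=0)
    rot_range = np.ptp(trace.rotations_deg, axis=0)
    for i, ax in enumerate(axes):
        if trans_range[i] >= max_trans_mm:
            failing.append(f"trans_{ax}")
    for i, ax in enumerate(axes):
        if rot_range[i] >= max_rot_deg:
            failing.append(f"rot_{ax}")
    return QCResult(passed=not failing, failing_axes=tuple(failing))


def _inband_mask(n: int, tr_s: float, band: BandSpec) -> np.ndarray:
    """Boolean mask over rfft bins: in-band iff f_lo <= k/(n*tr) <= f_hi."""
    freqs = np.fft.rfftfreq(n, d=tr_s)
    return (freqs >= band.f_lo_hz) & (freqs <= band.f_hi_hz)


def bandpass_ideal(series: np.ndarray, tr_s: float, band: BandSpec) -> np.ndarray:
    """Frequency-domain ideal (rectangular) band-pass of a 1D series.

    FFT, zero every bin whose frequency lies outside [f_lo, f_hi]
    (inclusive edges), inverse FFT.  No tapering.  Linear and idempotent.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 1 or series.size < 2:
        raise InputError("series must be 1D with length >= 2")
    band.validate_for_tr(tr_s)
    spec = np.fft.rfft(series)
    spec[~_inband_mask(series.size, tr_s, band)] = 0.0
    return np.fft.irfft(spec, n=series.size)


def bandpass_run(run: Fmri4D, band: BandSpec) -> Fmri4D:
    """Apply the ideal band-pass along the time axis of a whole run."""
    band.validate_for_tr(run.tr_s)
    spec = np.fft.rfft(run.data, axis=3)
    keep = _inband_mask(run.n_volumes, run.tr_s, band)
    spec[..., ~keep] = 0.0
    filtered = np.fft.irfft(spec, n=run.n_volumes, axis=3)
    return Fmri4D(filtered, run.tr_s, run.affine, run.subject_id)


def detrend_linear(series: np.ndarray) -> np.ndarray:
    """Remove the least-squares linear trend (optional pre-filter step).

    OFF by default in the pipeline: the band-pass already excludes the DC
    and drift bins.  Provided to match other ALFF conventions.
    """
    series = np.asarray(series, dtype=np.float64)
    t = np.arange(series.shape[-1], dtype=float)
    t = t - t.mean()
    denom = (t * t).sum()
    slope = (series * t).sum(axis=-1, keepdims=True) / denom
    mean = series.mean(axis=-1, keepdims=True)
    return series - mean - slope * t


def fwhm_to_sigma_voxels(fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Per-axis Gaussian sigma in voxels: fwhm / (2*sqrt(2*ln 2)) / voxel size."""
    voxel_size_mm = np.asarray(voxel_size_mm, dtype=float)
    return fwhm_mm / _FWHM_TO_SIGMA / voxel_size_mm


def smooth_gaussian(
    data: np.ndarray, fwhm_mm: float, voxel_size_mm
) -> np.ndarray:
    """Gaussian-smooth a 3D map or a 4D run (volume by volume).

    Reflective boundary handling, which preserves the grid mean of
    constant images.  ``fwhm_mm == 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise InputError(f"fwhm must be >= 0, got {fwhm_mm}")
    data = np.asarray(data, dtype=np.float64)
    if data.ndim not in (3, 4):
        raise InputError(f"expected 3D or 4D data, got ndim={data.ndim}")
    if fwhm_mm == 0:
        return data.copy()
    sigma = list(fwhm_to_sigma_voxels(fwhm_mm, voxel_size_mm))
    if data.ndim == 4:
        sigma = sigma + [0.0]  # never smooth across time
    return ndimage.gaussian_filter(data, sigma=sigma, mode="reflect")


def smooth_run(run: Fmri4D, fwhm_mm: float, voxel_size_mm) -> Fmri4D:
    return Fmri4D(
        smooth_gaussian(run.data, fwhm_mm, voxel_size_mm),
        run.tr_s,
        run.affine,
        run.subject_id,
    )
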