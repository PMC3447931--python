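"""ALFF: mean amplitude of the one-sided spectrum over a low-frequency band,
optionally standardized by the global (in-mask) mean.

Conventions
-----------
* FFT length equals the number of time points (no zero padding).
* One-sided amplitude normalization: amplitude(k) = (2/N)|X(k)| for
  0 < k < N/2, (1/N)|X(0)| at DC and (1/N)|X(N/2)| at Nyquist for even N,
  so a pure sinusoid of amplitude A at an exact bin reads back as A.
  The constant is immaterial after standardization.
* A bin is in-band iff f_lo <= k/(N*tr) <= f_hi (inclusive edges).
"""
from __future__ import annotations

import numpy as np

from .types import BandSpec, BrainMask, Fmri4D, InputError, ScalarMap

__all__ = [
    "amplitude_spectrum",
    "inband_bins",
    "compute_alff",
    "standardize_alff",
]


def _onesided_scale(n: int) -> np.ndarray:
    """Normalization per rfft bin so exact-bin sinusoids have unit gain."""
    n_bins = n // 2 + 1
    scale = np.full(n_bins, 2.0 / n)
    scale[0] = 1.0 / n
    if n % 2 == 0:
        scale[-1] = 1.0 / n
    return scale


def amplitude_spectrum(series: np.ndarray, tr_s: float):
    """One-sided amplitude spectrum of a 1D series.

    Returns ``(frequencies, amplitudes)`` with frequencies k/(N*tr).
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 1 or series.size < 2:
        raise InputError("series must be 1D with length >= 2")
    n = series.size
    freqs = np.fft.rfftfreq(n, d=tr_s)
    amps = np.abs(np.fft.rfft(series)) * _onesided_scale(n)
    return freqs, amps


def inband_bins(n: int, tr_s: float, band: BandSpec) -> np.ndarray:
    """Indices k of rfft bins with f_lo <= k/(n*tr) <= f_hi."""
    freqs = np.fft.rfftfreq(n, d=tr_s)
    return np.nonzero((freqs >= band.f_lo_hz) & (freqs <= band.f_hi_hz))[0]


def compute_alff(run: Fmri4D, mask: BrainMask, band: BandSpec) -> ScalarMap:
    """Per-voxel ALFF: mean one-sided amplitude over the in-band bins.

    Voxels outside the mask are set to 0.  Raises if the (N, TR, band)
    combination yields no in-band bins.
    """
    if mask.shape != run.shape[:3]:
        raise InputError(
            f"mask grid {mask.shape} != run grid {run.shape[:3]}"
        )
    band.validate_for_tr(run.tr_s)
    n = run.n_volumes
    bins = inband_bins(n, run.tr_s, band)
    if bins.size == 0:
        raise InputError(
            f"no in-band bins for N={n}, tr={run.tr_s}, "
            f"band=[{band.f_lo_hz}, {band.f_hi_hz}] (of {n // 2 + 1} one-sided bins)"
        )
    ts = run.data[mask.data]  # (n_in_mask, t)
    spec = np.abs(np.fft.rfft(ts, axis=1))[:, bins]
    spec *= _onesided_scale(n)[bins]
    alff_vals = spec.mean(axis=1)
    out = np.zeros(run.shape[:3])
    out[mask.data] = alff_vals
    return ScalarMap(out, run.affine, kind="alff")


def standardize_alff(alff: ScalarMap, mask: BrainMask) -> ScalarMap:
    """Divide each in-mask voxel by the in-mask mean (mALFF).

    The resulting in-mask mean is 1 by construction, making maps
    comparable across subjects.
    """
    if mask.shape != alff.shape:
        raise InputError(f"mask grid {mask.shape} != map grid {alff.shape}")
    gmean = alff.data[mask.data].mean()
    if not np.isfinite(gmean) or gmean <= 0:
        raise InputError(f"degenerate global mean ALFF: {gmean}")
    out = np.zeros_like(alff.data)
    out[mask.data] = alff.data[mask.data] / gmean
    return ScalarMap(out, alff.affine, kind="malff")
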