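"""Shared domain types for the ALFF analysis pipeline.

Lightweight dataclass containers around numpy grids.  All images carry a
4x4 voxel-to-world affine (mm); 4D runs additionally carry the repetition
time.  Validation happens at construction so downstream code can assume
well-formed inputs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "Fmri4D",
    "ScalarMap",
    "BrainMask",
    "MotionTrace",
    "BandSpec",
    "InputError",
    "ConfigError",
]


class InputError(ValueError):
    """Raised when an operation's input violates its precondition."""


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise InputError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise InputError("affine is singular")
    return affine


@dataclass
class Fmri4D:
    """A subject's 4D (x, y, z, t) time-series grid."""

    data: np.ndarray
    tr_s: float
    affine: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise InputError(f"expected 4D data, got ndim={self.data.ndim}")
        if self.data.shape[3] < 2:
            raise InputError("need at least 2 time points")
        if self.tr_s <= 0:
            raise InputError(f"tr_s must be positive, got {self.tr_s}")
        if np.isnan(self.data).any():
            raise InputError("NaN voxels in 4D run")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class ScalarMap:
    """A 3D per-voxel scalar map (ALFF, mALFF, GM probability, t-statistic)."""

    data: np.ndarray
    affine: np.ndarray
    kind: str = "alff"
    df: Optional[int] = None

    _KINDS = ("alff", "malff", "gm_prob", "tstat")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise InputError(f"expected 3D data, got ndim={self.data.ndim}")
        if self.kind not in self._KINDS:
            raise InputError(f"kind must be one of {self._KINDS}, got {self.kind!r}")
        if np.isnan(self.data).any():
            raise InputError("NaN voxels in scalar map")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class BrainMask:
    """Boolean 3D grid delimiting the analysis domain."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise InputError(f"expected 3D mask, got ndim={self.data.ndim}")
        if not self.data.any():
            raise InputError("mask is empty")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion parameters.

    Columns: translations x, y, z in mm, then rotations about each axis in
    degrees (6 columns total, one row per volume).
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.params.size == 0:
            raise InputError("empty motion trace")
        if self.params.shape[1] != 6:
            raise InputError(
                f"motion trace needs 6 columns (3 trans mm, 3 rot deg), got {self.params.shape[1]}"
            )

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations_deg(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass(frozen=True)
class BandSpec:
    """A pass band [f_lo_hz, f_hi_hz], inclusive at both edges."""

    f_lo_hz: float = 0.01
    f_hi_hz: float = 0.08

    def __post_init__(self) -> None:
        if not (0 < self.f_lo_hz < self.f_hi_hz):
            raise InputError(
                f"need 0 < f_lo < f_hi, got [{self.f_lo_hz}, {self.f_hi_hz}]"
            )

    def validate_for_tr(self, tr_s: float) -> None:
        nyquist = 1.0 / (2.0 * tr_s)
        if self.f_hi_hz >= nyquist:
            raise InputError(
                f"f_hi={self.f_hi_hz} Hz >= Nyquist {nyquist} Hz for TR={tr_s}s"
            )
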