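"""NIfTI-1 and table I/O built on nibabel.

4D images carry the repetition time in the header (pixdim[4]); loaders
reject NaN voxels with a clear error rather than propagating them.
"""
from __future__ import annotations

from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np

from .types import BrainMask, Fmri4D, InputError, MotionTrace, ScalarMap

__all__ = [
    "read_fmri",
    "read_scalar_map",
    "read_mask",
    "write_nifti",
    "read_motion_trace",
    "write_motion_trace",
]

Image = Union[Fmri4D, ScalarMap, BrainMask]


def _load(path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    img = nib.load(str(path))
    return img


def _get_data(img: nib.Nifti1Image, what: str) -> np.ndarray:
    data = np.asarray(img.dataobj, dtype=np.float64)
    if np.isnan(data).any():
        raise InputError(f"NaN voxels in {what}")
    return data


def read_fmri(path, tr_s: float | None = None, subject_id: str = "") -> Fmri4D:
    """Load a 4D run; TR comes from the header unless overridden."""
    img = _load(path)
    if img.ndim != 4:
        raise InputError(f"expected a 4D image, got {img.ndim}D: {path}")
    if tr_s is None:
        tr_s = float(img.header.get_zooms()[3])
        if tr_s <= 0:
            raise InputError(
                f"header TR is {tr_s}; pass tr_s explicitly for {path}"
            )
    return Fmri4D(_get_data(img, str(path)), tr_s, img.affine,
                  subject_id=subject_id or Path(path).name.split(".")[0])


def read_scalar_map(path, kind: str = "alff") -> ScalarMap:
    img = _load(path)
    if img.ndim != 3:
        raise InputError(f"expected a 3D image, got {img.ndim}D: {path}")
    return ScalarMap(_get_data(img, str(path)), img.affine, kind=kind)


def read_mask(path) -> BrainMask:
    img = _load(path)
    if img.ndim != 3:
        raise InputError(f"expected a 3D mask, got {img.ndim}D: {path}")
    return BrainMask(_get_data(img, str(path)) > 0.5, img.affine)


def write_nifti(path, image: Image) -> None:
    """Write any image container as 32-bit float NIfTI-1 (mask as uint8)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(image, Fmri4D):
        out = nib.Nifti1Image(image.data.astype(np.float32), image.affine)
        zooms = list(out.header.get_zooms())
        zooms[3] = image.tr_s
        out.header.set_zooms(zooms)
        out.header.set_xyzt_units("mm", "sec")
    elif isinstance(image, BrainMask):
        out = nib.Nifti1Image(image.data.astype(np.uint8), image.affine)
    elif isinstance(image, ScalarMap):
        out = nib.Nifti1Image(image.data.astype(np.float32), image.affine)
    else:
        raise InputError(f"cannot write object of type {type(image)}")
    nib.save(out, str(path))


def read_motion_trace(path) -> MotionTrace:
    arr = np.loadtxt(path, ndmin=2)
    return MotionTrace(arr)


def write_motion_trace(path, trace: MotionTrace) -> None:
    np.savetxt(path, trace.params, fmt="%.6f")
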