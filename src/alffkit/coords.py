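"""Stereotactic coordinate handling: MNI -> Talairach (Brett mni2tal).

The piecewise-affine constants are Matthew Brett's published mni2tal
mapping (http://imaging.mrc-cbu.cam.ac.uk/imaging/MniTalairach): a small
pitch rotation combined with one scaling above the AC plane and another
below it.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import InputError

__all__ = ["WorldCoordinate", "mni_to_talairach", "MNI2TAL_UP", "MNI2TAL_DOWN"]

# Brett constants: rotation by 0.05 rad about x composed with
# diag(0.99, 0.97, 0.92) for z >= 0 and diag(0.99, 0.97, 0.84) for z < 0.
MNI2TAL_UP = np.array([
    [0.9900, 0.0000, 0.0000],
    [0.0000, 0.9688, 0.0460],
    [0.0000, -0.0485, 0.9189],
])
MNI2TAL_DOWN = np.array([
    [0.9900, 0.0000, 0.0000],
    [0.0000, 0.9688, 0.0420],
    [0.0000, -0.0485, 0.8390],
])


@dataclass(frozen=True)
class WorldCoordinate:
    """A point in mm with an explicit space tag."""

    x: float
    y: float
    z: float
    space: str = "MNI"  # "MNI" | "Talairach"

    def __post_init__(self) -> None:
        if self.space not in ("MNI", "Talairach"):
            raise InputError(f"unknown space {self.space!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


def mni_to_talairach(c: WorldCoordinate) -> WorldCoordinate:
    """Brett piecewise-affine MNI -> Talairach conversion.

    Uses the z >= 0 matrix above the AC plane and the z < 0 matrix below;
    the origin is a fixed point of both.
    """
    if c.space != "MNI":
        raise InputError(f"expected an MNI coordinate, got space={c.space!r}")
    mat = MNI2TAL_UP if c.z >= 0 else MNI2TAL_DOWN
    out = mat @ c.as_array()
    return WorldCoordinate(float(out[0]), float(out[1]), float(out[2]),
                           space="Talairach")
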