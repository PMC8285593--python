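"""Minimal 3-D volume container used throughout the pipeline.

A :class:`Volume` couples a scalar grid with its voxel-to-world affine, the
two pieces of information every stage (feature extraction, resampling,
volumetry) needs.  I/O goes through nibabel so volumes round-trip as
standard NIfTI-1 files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Volume"]


@dataclass
class Volume:
    """A 3-D scalar grid with voxel spacing and a voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths (mm) from the affine column norms."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def copy_with(self, data: np.ndarray) -> "Volume":
        return Volume(np.asarray(data), self.affine.copy())

    def save(self, path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data), self.affine)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path) -> "Volume":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj), img.affine)
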