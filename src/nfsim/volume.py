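"""4D BOLD volume series container with NIfTI-1 round trip."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeSeries"]


@dataclass
class VolumeSeries:
    """A 4D BOLD sample grid: (x, y, z, time) plus acquisition geometry.

    Attributes
    ----------
    data
        Array of shape (nx, ny, nz, n_volumes), raw signal in arbitrary
        scanner units.
    voxel_size_mm
        Isotropic voxel edge length in millimetres.
    tr_s
        Repetition time (volume spacing) in seconds.
    """

    data: np.ndarray
    voxel_size_mm: float
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got shape {self.data.shape}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def roi_timecourse(self, mask: np.ndarray) -> np.ndarray:
        """Mean signal over a boolean voxel mask, one value per volume."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape does not match grid")
        if not mask.any():
            raise ValueError("empty mask")
        return self.data[mask].mean(axis=0)

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag([self.voxel_size_mm] * 3 + [1.0])
        img = nib.Nifti1Image(self.data.astype(np.float32), affine)
        img.header.set_zooms((self.voxel_size_mm,) * 3 + (self.tr_s,))
        img.header.set_xyzt_units("mm", "sec")
        return img

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image) -> "VolumeSeries":
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 else 1.0
        return cls(
            data=np.asarray(img.dataobj, dtype=np.float64),
            voxel_size_mm=float(zooms[0]),
            tr_s=tr,
        )

    @classmethod
    def load(cls, path: str | Path) -> "VolumeSeries":
        return cls.from_nifti(nib.load(str(path)))
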