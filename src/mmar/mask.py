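"""Voxelized binary left-ventricular myocardium masks (NIfTI-backed).

Voxel-to-world follows the voxel-center convention with 0-based indices:
world = affine @ (i, j, k, 1).  Volumes are reported in ml; the myocardium
can optionally be converted to grams with density 1.05 g/ml.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

MYOCARDIUM_DENSITY_G_PER_ML = 1.05


@dataclass
class MyocardiumMask:
    grid: np.ndarray       # 3D bool
    affine: np.ndarray     # 4x4 voxel-to-world (mm)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("mask grid must be 3D")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacings must be > 0")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_ml(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3]))) / 1000.0

    @property
    def n_foreground(self) -> int:
        return int(self.grid.sum())

    def total_volume_ml(self) -> float:
        return self.n_foreground * self.voxel_volume_ml

    def foreground_world_coords(self) -> np.ndarray:
        """World-mm centers of all foreground voxels, shape (n, 3)."""
        ijk = np.argwhere(self.grid)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    @classmethod
    def from_nifti(cls, path) -> "MyocardiumMask":
        img = nib.load(str(path))
        return cls(grid=np.asanyarray(img.dataobj) != 0, affine=img.affine)

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(self.grid.astype(np.uint8), self.affine)
        nib.save(img, str(path))


def mass_g(volume_ml: float, density: float = MYOCARDIUM_DENSITY_G_PER_ML) -> float:
    """Convert a myocardial volume in ml to mass in grams."""
    return volume_ml * density
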