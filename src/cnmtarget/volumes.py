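"""Volume grids, binary brain masks, and MNI↔voxel coordinate handling.

All spatial data in this package lives on a :class:`VolumeGrid`: a 3-D voxel
array together with a NIfTI-style 4×4 affine that maps 0-based voxel indices
to MNI millimetre coordinates.  Conversions always go through the affine —
there are no hard-coded assumptions about orientation, origin or voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "BrainMask",
    "load_mask",
    "save_mask",
    "load_volume_grid",
]


@dataclass
class VolumeGrid:
    """A 3-D voxel grid with an affine mapping voxel indices to MNI mm.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along each of the three spatial axes.
    affine : (4, 4) ndarray
        Invertible voxel-to-mm affine (NIfTI convention, 0-based indices).
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge length in mm per axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def same_grid(self, other: "VolumeGrid", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)

    # ------------------------------------------------------------------
    # coordinate transforms
    # ------------------------------------------------------------------
    def voxel_to_mni(self, ijk) -> np.ndarray:
        """Map voxel indices (single triple or (N, 3) array) to MNI mm."""
        arr = np.asarray(ijk, dtype=float)
        single = arr.ndim == 1
        xyz = np.atleast_2d(arr) @ self.affine[:3, :3].T + self.affine[:3, 3]
        return xyz[0] if single else xyz

    def mni_to_voxel(self, coord) -> tuple[int, int, int]:
        """Map one MNI mm coordinate to the nearest 0-based voxel index.

        Raises
        ------
        ValueError
            If the coordinate falls outside the grid bounds.
        """
        coord = np.asarray(coord, dtype=float)
        if coord.shape != (3,):
            raise ValueError("coordinate must be an (x, y, z) triple in mm")
        frac = np.linalg.inv(self.affine) @ np.append(coord, 1.0)
        ijk = np.round(frac[:3]).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= np.array(self.shape)):
            raise ValueError(
                f"MNI coordinate {tuple(coord)} maps outside the grid "
                f"(voxel {tuple(ijk)} not in shape {self.shape})"
            )
        return tuple(int(i) for i in ijk)

    def contains_mni(self, coord) -> bool:
        try:
            self.mni_to_voxel(coord)
        except ValueError:
            return False
        return True

    def mm_coordinates(self) -> np.ndarray:
        """MNI mm coordinate of every voxel centre, shape ``shape + (3,)``."""
        ii, jj, kk = np.meshgrid(*(np.arange(s) for s in self.shape), indexing="ij")
        ijk = np.stack([ii, jj, kk], axis=-1).astype(float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class BrainMask:
    """A boolean voxel mask on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    voxels: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.voxels.shape} does not match grid shape {self.grid.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        return not self.voxels.any()

    def indices(self) -> np.ndarray:
        """(N, 3) array of voxel indices inside the mask, C-order."""
        return np.argwhere(self.voxels)

    def mm_coordinates(self) -> np.ndarray:
        """(N, 3) MNI mm coordinates of the mask voxel centres."""
        return np.atleast_2d(self.grid.voxel_to_mni(self.indices()))

    def require_nonempty(self, what: str = "mask") -> "BrainMask":
        if self.is_empty:
            raise ValueError(f"{what} is empty")
        return self

    def intersect(self, other: "BrainMask") -> "BrainMask":
        if not self.grid.same_grid(other.grid):
            raise ValueError("cannot intersect masks on different grids")
        return BrainMask(self.grid, self.voxels & other.voxels,
                         name=f"{self.name}&{other.name}" if self.name or other.name else "")


# ----------------------------------------------------------------------
# NIfTI I/O
# ----------------------------------------------------------------------

def load_volume_grid(path) -> VolumeGrid:
    """Read only the grid (shape + affine) of a NIfTI volume."""
    img = nib.load(str(path))
    return VolumeGrid(tuple(img.shape[:3]), img.affine)


def load_mask(path, name: str = "") -> BrainMask:
    """Load a binary mask from a NIfTI file (non-zero voxels are True)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"mask file {path} is not a 3-D volume (shape {data.shape})")
    return BrainMask(VolumeGrid(tuple(data.shape), img.affine), data != 0, name=name)


def save_mask(mask: BrainMask, path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))
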