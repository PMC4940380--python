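"""Voxel grids and voxel/world coordinate transforms.

All volumes in the package live on a :class:`VolumeGrid`: a 3D voxel lattice
with a 4x4 voxel->world affine (RAS-ordered world axes, millimetre units,
0-based voxel indices).  Streamlines and centres of gravity are always
expressed in world mm; label and probability arrays are indexed by voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGrid", "centered_grid"]


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D voxel lattice with a voxel-to-world affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # (4, 4) voxel -> world (mm)
    _inv: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        if len(shape) != 3 or any(n < 1 for n in shape):
            raise ValueError(f"shape must be three positive ints, got {self.shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", aff)
        object.__setattr__(self, "_inv", np.linalg.inv(aff))

    # -- transforms -------------------------------------------------------
    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm coordinates (..., 3)."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm (..., 3) to continuous voxel coordinates (..., 3)."""
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self._inv[:3, :3].T + self._inv[:3, 3]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Nearest-voxel integer indices for world coordinates."""
        return np.rint(self.world_to_voxel(xyz)).astype(np.int64)

    # -- properties -------------------------------------------------------
    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def inside(self, ijk: np.ndarray) -> np.ndarray:
        """Boolean mask: which integer index triples lie on the grid."""
        ijk = np.asarray(ijk)
        ok = np.ones(ijk.shape[:-1], dtype=bool)
        for ax in range(3):
            ok &= (ijk[..., ax] >= 0) & (ijk[..., ax] < self.shape[ax])
        return ok

    def coordinate_volume(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``shape + (3,)``."""
        ii, jj, kk = np.meshgrid(
            np.arange(self.shape[0]),
            np.arange(self.shape[1]),
            np.arange(self.shape[2]),
            indexing="ij",
        )
        ijk = np.stack([ii, jj, kk], axis=-1).astype(float)
        return self.voxel_to_world(ijk)

    def world_z_volume(self) -> np.ndarray:
        """World z coordinate of every voxel centre (for AC-PC slab cuts)."""
        return self.coordinate_volume()[..., 2]

    def same_as(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    @property
    def half_extent_mm(self) -> np.ndarray:
        """Half the physical extent of the grid per world axis."""
        return np.asarray(self.shape) * self.spacing / 2.0


def centered_grid(shape, voxel_size_mm) -> VolumeGrid:
    """Axis-aligned RAS grid whose physical centre is the world origin."""
    shape = tuple(int(n) for n in shape)
    vox = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,)).copy()
    if np.any(vox <= 0):
        raise ValueError("voxel sizes must be positive")
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = vox
    # voxel centre i=0 sits at -extent/2 + vox/2
    affine[:3, 3] = -np.asarray(shape) * vox / 2.0 + vox / 2.0
    return VolumeGrid(shape=shape, affine=affine)
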