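"""Voxel-grid geometry and boolean ROI masks.

A :class:`VolumeGrid` pins down the mapping between voxel indices and
millimetre coordinates (a plain scaled-translation affine, no shears or
rotations -- simulated data live in a common grid by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass(frozen=True)
class VolumeGrid:
    """3D voxel grid with isotropic-by-default voxel size.

    The affine maps voxel index ``(i, j, k)`` to mm coordinates; by default
    the grid is centred on the origin.
    """

    shape: tuple[int, int, int]
    voxel_size: float = 3.0
    origin_mm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"invalid grid shape {self.shape!r}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if self.origin_mm is None:
            # centre the grid on 0 mm
            off = tuple(-(s - 1) / 2.0 * self.voxel_size for s in self.shape)
            object.__setattr__(self, "origin_mm", off)
        else:
            object.__setattr__(self, "origin_mm", tuple(float(v) for v in self.origin_mm))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk * self.voxel_size + np.asarray(self.origin_mm)

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Nearest voxel index for mm coordinates."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        return np.rint((xyz - np.asarray(self.origin_mm)) / self.voxel_size).astype(int)

    def contains_mm(self, xyz) -> bool:
        ijk = self.mm_to_voxel(xyz)[0]
        return bool(np.all(ijk >= 0) and np.all(ijk < np.asarray(self.shape)))

    def voxel_centers_mm(self) -> np.ndarray:
        """(n_voxels, 3) array of voxel-centre coordinates in C order."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.voxel_to_mm(idx)


@dataclass
class ROIMask:
    """Boolean mask on a :class:`VolumeGrid` with provenance metadata."""

    grid: VolumeGrid
    data: np.ndarray
    name: str = ""
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.data.shape} does not match grid {self.grid.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def flat_indices(self) -> np.ndarray:
        return np.flatnonzero(self.data.ravel())

    def __and__(self, other: "ROIMask") -> "ROIMask":
        if other.grid.shape != self.grid.shape:
            raise ValueError("masks live on different grids")
        return ROIMask(self.grid, self.data & other.data, name=f"{self.name}&{other.name}")

    def __or__(self, other: "ROIMask") -> "ROIMask":
        if other.grid.shape != self.grid.shape:
            raise ValueError("masks live on different grids")
        return ROIMask(self.grid, self.data | other.data, name=f"{self.name}|{other.name}")
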