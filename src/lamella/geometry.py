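"""Voxel-grid containers shared by every module.

World coordinates follow the voxel-center convention: the center of voxel
``(i, j, k)`` sits at ``origin + (index + 0.5) * spacing``; ``origin`` is the
corner of the first voxel. All lengths are millimetres, volumes are reported
in cubic centimetres (1 cc = 1000 mm^3), doses in gray.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Grid3D", "DoseGrid", "StructureMask"]


@dataclass(frozen=True)
class Grid3D:
    """Axis-aligned regular 3-D lattice geometry."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]  # mm per voxel edge, per axis
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm, corner of voxel (0,0,0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be three positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats (mm), got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def axis_centers(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Meshgrid (ij-indexed) of voxel-center world coordinates."""
        return np.meshgrid(*(self.axis_centers(a) for a in range(3)), indexing="ij")

    def isclose(self, other: "Grid3D", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


def _check_geometry(a, b) -> None:
    if not a.grid.isclose(b.grid):
        raise ValueError(
            f"geometry mismatch: {a.grid.shape}/{a.grid.spacing} vs {b.grid.shape}/{b.grid.spacing}"
        )


@dataclass
class DoseGrid:
    """Absorbed-dose scalar field (Gy) on a :class:`Grid3D`."""

    values: np.ndarray
    grid: Grid3D

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"dose array shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    def scaled(self, factor: float) -> "DoseGrid":
        return DoseGrid(self.values * float(factor), self.grid)

    def require_same_geometry(self, other) -> None:
        _check_geometry(self, other)


@dataclass
class StructureMask:
    """Binary structure on a :class:`Grid3D` (GTV, margin shells, evaluation region)."""

    voxels: np.ndarray
    grid: Grid3D
    label: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.grid.shape:
            raise ValueError(
                f"mask array shape {self.voxels.shape} != grid shape {self.grid.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_cc(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_cc

    def is_empty(self) -> bool:
        return not self.voxels.any()

    def relabeled(self, label: str) -> "StructureMask":
        return StructureMask(self.voxels, self.grid, label)

    def require_same_geometry(self, other) -> None:
        _check_geometry(self, other)
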