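"""NIfTI I/O for dose grids and structure masks.

The affine maps voxel index to the world position of the voxel center
(``origin + (index + 0.5) * spacing``), axis-aligned with no rotation.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import DoseGrid, Grid3D, StructureMask

__all__ = ["write_dose_nifti", "write_mask_nifti", "read_dose_nifti", "read_mask_nifti"]


def _affine(grid: Grid3D) -> np.ndarray:
    aff = np.eye(4)
    for a in range(3):
        aff[a, a] = grid.spacing[a]
        aff[a, 3] = grid.origin[a] + 0.5 * grid.spacing[a]
    return aff


def _grid_from(img: nib.Nifti1Image) -> Grid3D:
    aff = img.affine
    spacing = tuple(float(aff[a, a]) for a in range(3))
    origin = tuple(float(aff[a, 3]) - 0.5 * spacing[a] for a in range(3))
    return Grid3D(shape=tuple(img.shape[:3]), spacing=spacing, origin=origin)


def write_dose_nifti(dose: DoseGrid, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(dose.values.astype(np.float32), _affine(dose.grid)),
             str(path))


def write_mask_nifti(mask: StructureMask, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(mask.grid)),
             str(path))


def read_dose_nifti(path: str | Path) -> DoseGrid:
    img = nib.load(str(path))
    return DoseGrid(np.asarray(img.dataobj, dtype=np.float64), _grid_from(img))


def read_mask_nifti(path: str | Path, label: str = "") -> StructureMask:
    img = nib.load(str(path))
    return StructureMask(np.asarray(img.dataobj) > 0, _grid_from(img), label)
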