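"""Cumulative dose-volume histograms and dose/volume inverse lookups.

The curve is kept as the exact sorted multiset of voxel doses — no binning.
Every metric downstream is a near-extreme quantile (minimum dose covering
"volume minus 0.01 cc", dose covering 0.01 cc) and binning would distort
exactly those tails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DoseGrid, StructureMask

__all__ = ["DVHCurve", "build_dvh", "dose_at_volume", "dose_at_relative_volume",
           "volume_at_dose"]


@dataclass
class DVHCurve:
    """Empirical cumulative DVH: absolute volume (cc) receiving >= each dose.

    ``doses_desc`` holds each voxel's dose sorted descending, so the volume
    receiving at least ``doses_desc[k-1]`` is ``k * voxel_volume_cc``.
    """

    doses_desc: np.ndarray
    voxel_volume_cc: float
    label: str = ""

    def __post_init__(self) -> None:
        self.doses_desc = np.asarray(self.doses_desc, dtype=np.float64)
        if self.doses_desc.ndim != 1 or self.doses_desc.size == 0:
            raise ValueError("DVH needs a non-empty 1-D dose multiset")
        if np.any(np.diff(self.doses_desc) > 0):
            raise ValueError("doses_desc must be sorted descending")
        if self.voxel_volume_cc <= 0:
            raise ValueError("voxel volume must be positive")

    @property
    def total_volume_cc(self) -> float:
        return self.doses_desc.size * self.voxel_volume_cc

    @property
    def cum_volume_cc(self) -> np.ndarray:
        """Cumulative volume at each step point of the curve."""
        return (np.arange(self.doses_desc.size) + 1) * self.voxel_volume_cc

    def as_table(self) -> np.ndarray:
        """Two-column (dose Gy, cumulative volume cc) representation."""
        return np.column_stack([self.doses_desc, self.cum_volume_cc])


def build_dvh(dose: DoseGrid, mask: StructureMask) -> DVHCurve:
    """Exact-multiset cumulative DVH of the dose within a structure."""
    dose.require_same_geometry(mask)
    if mask.is_empty():
        raise ValueError(f"cannot build a DVH on the empty mask {mask.label!r}")
    values = dose.values[mask.voxels]
    return DVHCurve(np.sort(values)[::-1], mask.grid.voxel_volume_cc,
                    label=mask.label)


def dose_at_volume(curve: DVHCurve, volume_cc: float) -> float:
    """Minimum dose (Gy) covering at least ``volume_cc`` (the D_Vcc lookup).

    Linearly interpolated between adjacent step points of the cumulative
    curve; a volume below one voxel returns the maximum voxel dose (the
    limiting behaviour of the curve).
    """
    total = curve.total_volume_cc
    if not 0 < volume_cc <= total * (1 + 1e-12):
        raise ValueError(f"volume {volume_cc:g} cc outside (0, {total:g}]")
    # np.interp needs ascending x; cum_volume is ascending with descending dose
    return float(np.interp(volume_cc, curve.cum_volume_cc, curve.doses_desc))


def dose_at_relative_volume(curve: DVHCurve, pct: float) -> float:
    """D_x%: minimum dose covering ``pct`` percent of the structure."""
    if not 0 < pct <= 100:
        raise ValueError(f"percentage {pct:g} outside (0, 100]")
    return dose_at_volume(curve, pct / 100.0 * curve.total_volume_cc)


def volume_at_dose(curve: DVHCurve, dose_gy: float) -> float:
    """Absolute volume (cc) receiving at least ``dose_gy`` (closed threshold).

    This is the irradiated-isodose-volume (IIV) lookup when the curve spans
    the whole evaluation region.
    """
    if dose_gy < 0:
        raise ValueError("dose must be non-negative")
    # doses_desc descending: count of entries >= dose_gy
    count = curve.doses_desc.size - np.searchsorted(curve.doses_desc[::-1], dose_gy,
                                                    side="left")
    return float(count * curve.voxel_volume_cc)
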