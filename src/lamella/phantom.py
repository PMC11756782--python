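"""Synthetic dose-phantom generator.

Emulates the dose distributions of stereotactic radiosurgery plans around a
single target: a steep concentrically layered dose gradient that falls off
outside the target surface and escalates toward the target interior. Plan
quality is degraded controllably through two factors standing in for the
calculation settings of a Monte-Carlo dose engine:

* ``gs_factor`` — the native calculation grid spacing (mm). Dose is sampled
  on this coarser lattice and trilinearly resampled onto the evaluation
  grid, which blurs gradients exactly the way a coarse calculation grid does.
* ``su_factor`` — per-plan statistical uncertainty (%): multiplicative
  Gaussian noise drawn per calculation-grid voxel and resampled with the
  dose, normalized so the per-voxel uncertainty of the final dose equals
  ``su_factor`` whatever the calculation grid. A coarse calculation grid
  therefore carries the same noise amplitude but a longer correlation
  length, displacing isodose surfaces coherently over whole patches. This
  is an emulation knob, not a model of any particular Monte-Carlo engine's
  stopping rule.

The radial dose profile is ``D(x) = boundary_dose * g(s(x) + a(x))`` where
``s`` is the signed distance to the target surface (negative inside), ``a``
is a smooth direction-dependent displacement breaking concentricity
(``anisotropy``), and::

    g(s) = 1 + (P - 1) * tanh(-s / (2 * w))   for s <= 0   (interior ramp)
    g(s) = 2 ** (-s / falloff_half_distance)   for s > 0    (exterior falloff)

with ``P = 100 / interior_ratio`` the deep-interior plateau relative to the
boundary (so ``interior_ratio`` is the boundary dose as % of the interior
dose) and ``w = 3 mm`` the interior ramp scale. ``g`` is monotone
decreasing with ``g(0) = 1`` and ``g(falloff_half_distance) = 0.5``.

For a spherical target with ``anisotropy = 0`` and ``su_factor = 0`` every
isodose surface is an exact concentric sphere, so isodose volumes have a
closed form; the generated :class:`Phantom` carries that analytic truth
record for use as an oracle.

Target centers default to a fixed sub-voxel offset from the voxel lattice.
Centering an integer-radius sphere exactly on a voxel center puts large
shells of lattice points at exactly integer distances from the surface,
making voxel counts discontinuous functions of any threshold; a generic
off-lattice center restores the smooth behaviour real anatomy has.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .geometry import DoseGrid, Grid3D, StructureMask

__all__ = ["PhantomSpec", "Phantom", "TruthRecord", "generate_phantom", "write_phantom"]

INTERIOR_RAMP_MM = 3.0  # scale of the interior dose escalation
# generic sub-voxel offset of the target center from the lattice (fractions of a voxel)
_CENTER_SUBVOXEL_OFFSET = (0.37, 0.203, 0.489)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic plan; the random stream is seeded.

    ``target_size`` is a radius (mm) for spheres, three semi-axes (mm) for
    ellipsoids. Lobulated targets are unions of spheres given as
    ``lobes=[(center_offset_mm, radius_mm), ...]`` relative to the target
    center, with ``target_size`` ignored.
    """

    shape: Literal["sphere", "ellipsoid", "lobulated"] = "sphere"
    target_size: float | tuple[float, float, float] = 10.0
    lobes: tuple[tuple[tuple[float, float, float], float], ...] | None = None
    grid_spacing_eval: float = 1.0  # mm, evaluation grid voxel edge
    gs_factor: float = 1.0  # mm, native calculation grid spacing
    su_factor: float = 0.0  # %, per-voxel noise level
    boundary_dose: float = 43.0  # Gy at the target surface
    interior_ratio: float = 80.0  # boundary dose as % of deep-interior dose
    falloff_half_distance: float = 6.0  # mm outside the surface where dose halves
    anisotropy: float = 0.0  # mm, magnitude of direction-dependent displacement
    padding_mm: float = 25.0  # grid extent beyond the target bounding radius
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_spacing_eval <= 0:
            raise ValueError("grid_spacing_eval must be positive")
        if self.gs_factor < self.grid_spacing_eval:
            raise ValueError("gs_factor (native spacing) must be >= grid_spacing_eval")
        if self.su_factor < 0:
            raise ValueError("su_factor must be >= 0")
        if not 0 < self.interior_ratio <= 100:
            raise ValueError("interior_ratio must be in (0, 100]")
        if self.falloff_half_distance <= 0:
            raise ValueError("falloff_half_distance must be positive")
        if self.anisotropy < 0:
            raise ValueError("anisotropy must be >= 0")
        if self.boundary_dose <= 0:
            raise ValueError("boundary_dose must be positive")
        if self.shape == "lobulated":
            if not self.lobes:
                raise ValueError("lobulated shape requires lobes")
        elif self.shape == "ellipsoid":
            size = np.atleast_1d(self.target_size)
            if size.size != 3 or np.any(size <= 0):
                raise ValueError("ellipsoid needs three positive semi-axes")
        elif self.shape == "sphere":
            if np.size(self.target_size) != 1 or float(np.squeeze(self.target_size)) <= 0:
                raise ValueError("sphere needs a positive radius")
        else:
            raise ValueError(f"unknown shape {self.shape!r}")

    @property
    def bounding_radius_mm(self) -> float:
        if self.shape == "sphere":
            return float(np.squeeze(self.target_size))
        if self.shape == "ellipsoid":
            return float(np.max(self.target_size))
        return max(float(np.linalg.norm(c)) + r for c, r in self.lobes)

    @property
    def interior_plateau(self) -> float:
        """Deep-interior dose relative to the boundary dose (>= 1)."""
        return 100.0 / self.interior_ratio


@dataclass(frozen=True)
class TruthRecord:
    """Closed-form quantities for the symmetric noiseless spherical case."""

    radius_mm: float
    boundary_dose: float
    interior_plateau: float
    falloff_half_distance: float
    interior_ramp_mm: float = INTERIOR_RAMP_MM

    def g(self, s_mm: np.ndarray | float) -> np.ndarray | float:
        return _dose_profile(np.asarray(s_mm, float), self.interior_plateau,
                             self.falloff_half_distance)

    def g_inverse(self, fraction: float) -> float:
        """Signed distance s (mm) where the dose equals ``fraction * boundary_dose``."""
        p = self.interior_plateau
        if not 0 < fraction < p:
            raise ValueError(f"dose fraction must be in (0, {p:g})")
        if fraction >= 1.0:
            if p == 1.0:
                return 0.0
            return float(-2.0 * self.interior_ramp_mm * np.arctanh((fraction - 1.0) / (p - 1.0)))
        return float(self.falloff_half_distance * np.log2(1.0 / fraction))

    def iso_radius_mm(self, fraction: float) -> float:
        """Radius of the isodose sphere at ``fraction * boundary_dose``."""
        return self.radius_mm + self.g_inverse(fraction)

    def iiv_cc(self, fraction: float) -> float:
        """Analytic irradiated isodose volume (cc) at ``fraction * boundary_dose``."""
        r = self.iso_radius_mm(fraction)
        return 4.0 / 3.0 * np.pi * max(r, 0.0) ** 3 / 1000.0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Phantom:
    dose: DoseGrid
    gtv: StructureMask
    spec: PhantomSpec
    truth: TruthRecord | None = None
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)  # target center, world mm


def _dose_profile(s: np.ndarray, plateau: float, half_distance: float) -> np.ndarray:
    """Monotone radial profile g(s); s is signed distance, negative inside."""
    inside = 1.0 + (plateau - 1.0) * np.tanh(-s / (2.0 * INTERIOR_RAMP_MM))
    outside = np.exp2(-s / half_distance)
    return np.where(s <= 0, inside, outside)


def _signed_distance(spec: PhantomSpec, x: np.ndarray, y: np.ndarray,
                     z: np.ndarray) -> np.ndarray:
    """Signed distance (mm) to the target surface; exact for spheres and
    sphere unions, first-order for ellipsoids."""
    if spec.shape == "sphere":
        r = float(np.squeeze(spec.target_size))
        return np.sqrt(x * x + y * y + z * z) - r
    if spec.shape == "lobulated":
        s = None
        for (cx, cy, cz), r in spec.lobes:
            d = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2) - r
            s = d if s is None else np.minimum(s, d)
        return s
    a, b, c = (float(v) for v in np.asarray(spec.target_size))
    rho = np.sqrt((x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2)
    grad = np.sqrt((x / a**2) ** 2 + (y / b**2) ** 2 + (z / c**2) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (rho - 1.0) * rho / np.where(grad > 0, grad, 1.0)
    return np.where(grad > 0, s, -float(min(a, b, c)))


def _anisotropy_displacement(spec: PhantomSpec, x: np.ndarray, y: np.ndarray,
                             z: np.ndarray) -> np.ndarray:
    """Smooth direction-dependent radial displacement, |a| <= anisotropy (mm).

    A fixed low-order spherical-harmonic pattern (the real sectoral l=2,
    m=2 lobe, sin^2(theta) cos(2*phi)) — deterministic, breaks concentricity
    without changing the target mask.
    """
    if spec.anisotropy == 0.0:
        return np.zeros_like(x)
    r2 = x * x + y * y + z * z
    with np.errstate(invalid="ignore", divide="ignore"):
        pattern = np.where(r2 > 0, (x * x - y * y) / r2, 0.0)  # sin^2(th) cos(2*phi)
    return spec.anisotropy * pattern


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build the voxelized dose grid and target mask for one synthetic plan.

    Deterministic given ``spec`` (including ``seed``); with ``su_factor=0``
    the seed has no effect at all.
    """
    h = spec.grid_spacing_eval
    extent = spec.bounding_radius_mm + spec.padding_mm
    n = int(np.ceil(2.0 * extent / h))
    if spec.bounding_radius_mm >= n * h / 2.0:
        raise ValueError("target larger than the grid extent; increase padding_mm")
    grid = Grid3D(shape=(n, n, n), spacing=(h, h, h), origin=(0.0, 0.0, 0.0))
    # target center: grid center shifted off-lattice by a fixed sub-voxel offset
    center = np.array([n * h / 2.0 + o * h for o in _CENTER_SUBVOXEL_OFFSET])

    def analytic_dose(x, y, z):
        s = _signed_distance(spec, x - center[0], y - center[1], z - center[2])
        a = _anisotropy_displacement(spec, x - center[0], y - center[1],
                                     z - center[2])
        return spec.boundary_dose * _dose_profile(s + a, spec.interior_plateau,
                                                  spec.falloff_half_distance)

    xs, ys, zs = grid.center_mesh()
    sigma = spec.su_factor / 100.0
    if spec.gs_factor == spec.grid_spacing_eval:
        # lattices coincide in resolution: sample the analytic dose directly
        # at evaluation voxel centers (no interpolation blur)
        dose_vals = analytic_dose(xs, ys, zs)
        if sigma > 0:
            rng = np.random.default_rng(spec.seed)
            dose_vals = dose_vals * (1.0 + rng.normal(0.0, sigma, size=grid.shape))
    else:
        # sample on the coarser native (calculation) grid, then trilinearly
        # resample onto the evaluation grid — the resolution-loss mechanism
        hn = spec.gs_factor
        m = int(np.ceil(2.0 * extent / hn)) + 1
        native_axes = [np.arange(m) * hn - (m - 1) * hn / 2.0 + center[i]
                       for i in range(3)]
        nx, ny, nz = np.meshgrid(*native_axes, indexing="ij")
        pts = np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)
        dose_vals = RegularGridInterpolator(
            tuple(native_axes), analytic_dose(nx, ny, nz), method="linear",
            bounds_error=False, fill_value=None,
        )(pts).reshape(grid.shape)
        if sigma > 0:
            # Statistical noise is drawn per *calculation-grid* voxel and
            # resampled with the dose, so a coarse grid carries spatially
            # correlated fluctuations; the separable trilinear variance
            # attenuation prod_a(u^2 + (1-u)^2) is divided out so the
            # per-voxel uncertainty of the final dose equals su_factor
            # regardless of the calculation grid.
            rng = np.random.default_rng(spec.seed)
            eps = rng.normal(0.0, sigma, size=(m, m, m))
            eps_r = RegularGridInterpolator(
                tuple(native_axes), eps, method="linear",
                bounds_error=False, fill_value=None,
            )(pts).reshape(grid.shape)
            atten = np.ones(grid.shape)
            for a, ax_centers in enumerate((native_axes[0], native_axes[1],
                                            native_axes[2])):
                coord = (grid.axis_centers(a) - ax_centers[0]) / hn
                u = coord - np.floor(coord)
                w = np.sqrt(u**2 + (1.0 - u) ** 2)
                shape = [1, 1, 1]
                shape[a] = -1
                atten = atten * w.reshape(shape)
            dose_vals = dose_vals * (1.0 + eps_r / atten)
    dose_vals = np.clip(dose_vals, 0.0, None)

    # --- target mask: voxel center inside the analytic surface --------------
    s_eval = _signed_distance(spec, xs - center[0], ys - center[1], zs - center[2])
    gtv = StructureMask(s_eval <= 0.0, grid, label="GTV")

    truth = None
    if spec.shape == "sphere" and spec.anisotropy == 0.0 and spec.su_factor == 0.0:
        truth = TruthRecord(
            radius_mm=float(np.squeeze(spec.target_size)),
            boundary_dose=spec.boundary_dose,
            interior_plateau=spec.interior_plateau,
            falloff_half_distance=spec.falloff_half_distance,
        )
    return Phantom(dose=DoseGrid(dose_vals, grid), gtv=gtv, spec=spec, truth=truth,
                   center_mm=tuple(float(c) for c in center))


def write_phantom(phantom: Phantom, out_dir: str | Path) -> dict[str, Path]:
    """Write dose and mask as NIfTI plus a JSON sidecar with spec and truth."""
    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "dose": out / "dose.nii",
        "gtv": out / "gtv.nii",
        "sidecar": out / "phantom.json",
    }
    _io.write_dose_nifti(phantom.dose, paths["dose"])
    _io.write_mask_nifti(phantom.gtv, paths["gtv"])
    spec_dict = asdict(phantom.spec)
    sidecar = {
        "spec": spec_dict,
        "truth": phantom.truth.to_dict() if phantom.truth else None,
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2, default=list))
    return paths
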