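"""Shared fixtures: session-scoped phantoms (expensive) and random-grid factories."""

from __future__ import annotations

import numpy as np
import pytest

import lamella as lm


@pytest.fixture(scope="session")
def sphere_phantom() -> lm.Phantom:
    """Noiseless concentric spherical phantom, r = 10 mm, 1 mm grid."""
    return lm.generate_phantom(lm.PhantomSpec(shape="sphere", target_size=10.0))


@pytest.fixture(scope="session")
def sphere_plan_metrics(sphere_phantom) -> lm.PlanMetrics:
    return lm.evaluate_plan(sphere_phantom.dose, sphere_phantom.gtv,
                            lm.EvalConfig(pd_gy=43.0, eval_margin_mm=20.0))


@pytest.fixture(scope="session")
def sphere_surface(sphere_phantom) -> "lm.structures.MaskSurface":
    return lm.mask_surface(sphere_phantom.gtv)


def random_plan(rng: np.random.Generator, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0),
                dose_scale: float = 40.0):
    """Small random dose grid + random nonempty mask for brute-force oracles."""
    grid = lm.Grid3D(shape=shape, spacing=spacing)
    dose = lm.DoseGrid(rng.uniform(0.0, dose_scale, size=shape), grid)
    voxels = rng.random(shape) < 0.5
    if not voxels.any():
        voxels.flat[rng.integers(0, voxels.size)] = True
    return dose, lm.StructureMask(voxels, grid, label="roi")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240101)
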