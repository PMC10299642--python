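"""Shared fixtures: small synthetic scenes used across the test modules."""

from __future__ import annotations

import numpy as np
import pytest

from kinoquant.synthetic import (
    GroundTruthCurve,
    SceneManifest,
    VoxelGrid,
    generate_curve,
    render_stack,
)


def make_filament_scene(pattern: str = "uniform", length_um: float = 33.0,
                        curvature_amp: float = 1.5, noise_sd: float = 0.0,
                        seed: int = 0, amplitude: float = 3000.0,
                        margin_y: float = 4.5, margin_z: float = 3.0,
                        nz: int = 12, ny: int = 160,
                        quantize: bool = True):
    """Render one kinocilium into a stack sized to fit it.

    Returns (grid, manifest); the manifest holds the ground-truth curve and
    the tracer seed voxels follow from it.
    """
    curve = generate_curve(length_um, curvature_amp, rng_seed=seed,
                           pattern=pattern, amplitude=amplitude)
    pts = curve.control_points.copy()
    pts[:, 1] += margin_y
    pts[:, 2] += margin_z
    shifted = GroundTruthCurve(pts, pattern=pattern, amplitude=amplitude,
                               pattern_params=curve.pattern_params)
    manifest = SceneManifest([shifted], gaussian_sd=noise_sd, seed=seed)
    nx = int(np.ceil(pts[:, 0].max() / 0.064)) + 8
    grid = render_stack(manifest, (nz, ny, nx), quantize=quantize)
    return grid, manifest


@pytest.fixture
def straight_scene():
    """Noise-free straight 33 um filament with its manifest."""
    return make_filament_scene(curvature_amp=0.0, noise_sd=0.0, seed=1)


@pytest.fixture
def curved_scene():
    """Noise-free curved (amp 3 um) 32 um filament with its manifest."""
    return make_filament_scene(length_um=32.0, curvature_amp=3.0,
                               noise_sd=0.0, seed=2, margin_y=6.0,
                               margin_z=4.0, nz=16, ny=200)


@pytest.fixture
def flat_grid():
    """Uniform background-only stack (value 100 everywhere)."""
    return VoxelGrid(np.full((4, 16, 16), 100, dtype=np.uint16), 0.064, 0.65)
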