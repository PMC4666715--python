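"""Shared fixtures: small synthetic scenes and cached expensive artifacts.

Everything is generated at test time from the synthetic module; session scope
amortises the level-set / curvature runs that several test modules share.
"""

from __future__ import annotations

import numpy as np
import pytest

from creasemap.curvature import SurfaceMesh, extract_mesh, gaussian_curvature
from creasemap.presets import small_config, small_scene
from creasemap.surface import ImplicitField, LevelSetParams, evolve, initialize_from_threshold
from creasemap.synthetic import MEMBRANE, SceneSpec, build_scene, rasterize


@pytest.fixture(scope="session")
def sphere_scene():
    """Noise-free bare dome (30 μm sphere clipped at the base)."""
    spec = SceneSpec(primordia=(), noise_sigma=0.0)
    gt = build_scene(spec)
    return gt, rasterize(gt)


@pytest.fixture(scope="session")
def sphere_phi_analytic():
    """Exact signed-distance field of a 20 μm sphere on a unit grid."""
    n = 56
    c = n / 2.0
    zz, yy, xx = np.meshgrid(*[(np.arange(n) + 0.5)] * 3, indexing="ij")
    phi = np.sqrt((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) - 20.0
    return ImplicitField(phi, (1.0, 1.0, 1.0)), np.array([c, c, c]), 20.0


@pytest.fixture(scope="session")
def small_gt_stack():
    gt = build_scene(small_scene(seed=1))
    return gt, rasterize(gt)


@pytest.fixture(scope="session")
def small_extracted(small_gt_stack):
    """Level-set surface + curvature mesh for the small two-primordium scene."""
    gt, stack = small_gt_stack
    phi = initialize_from_threshold(stack, MEMBRANE)
    phi = evolve(phi, stack, LevelSetParams(max_iterations=80))
    mesh = gaussian_curvature(extract_mesh(phi))
    return gt, stack, phi, mesh


def make_graph_mesh(height_fn, extent: float = 30.0, step: float = 1.0) -> SurfaceMesh:
    """Regular-grid triangle mesh of an explicit surface z = h(x, y)."""
    from creasemap.curvature import grid_mesh

    return grid_mesh(height_fn, extent=extent, step=step)


@pytest.fixture(scope="session")
def plane_mesh():
    return make_graph_mesh(lambda x, y: np.zeros_like(x))


@pytest.fixture(scope="session")
def saddle_mesh():
    return make_graph_mesh(lambda x, y: (x**2 - y**2) / 40.0)  # a = 20 μm


@pytest.fixture(scope="session")
def coupled_run():
    from creasemap.pipeline import run_pipeline

    return run_pipeline(small_config(seed=7))
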