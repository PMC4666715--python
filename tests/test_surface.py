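"""Level-set surface detection: initialisation, reinitialisation, evolution."""

import numpy as np
import pytest

from creasemap.stack import VoxelStack
from creasemap.surface import (
    ImplicitField,
    LevelSetParams,
    SurfaceError,
    evolve,
    initialize_from_threshold,
    reinitialize,
)
from creasemap.synthetic import MEMBRANE


def _ball_stack(radius=20.0, n=50, spacing=(1.0, 1.0, 1.0), value=100.0):
    sz, sy, sx = spacing
    c = np.array([n * sz / 2, n * sy / 2, n * sx / 2])
    zz, yy, xx = np.meshgrid(
        (np.arange(n) + 0.5) * sz, (np.arange(n) + 0.5) * sy, (np.arange(n) + 0.5) * sx,
        indexing="ij",
    )
    r = np.sqrt((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
    return VoxelStack({"c": np.where(r <= radius, value, 0.0)}, spacing), c


def test_init_solid_ball_center_distance():
    """phi at the ball centre equals -radius within a voxel diagonal."""
    stack, c = _ball_stack()
    f = initialize_from_threshold(stack, "c", threshold=50.0)
    centre = tuple(int(v) for v in c)
    assert f.phi[centre] == pytest.approx(-20.0, abs=np.sqrt(3.0))


def test_init_empty_stack_raises():
    stack = VoxelStack({"c": np.zeros((8, 8, 8))}, (1, 1, 1))
    with pytest.raises(SurfaceError):
        initialize_from_threshold(stack, "c", threshold=1.0)


def test_init_single_voxel_mask():
    img = np.zeros((9, 9, 9))
    img[4, 4, 4] = 10.0
    stack = VoxelStack({"c": img}, (1, 1, 1))
    f = initialize_from_threshold(stack, "c", threshold=5.0, presmooth_sigma=0.0)
    assert -0.87 <= f.phi[4, 4, 4] <= 0.0


def test_threshold_tie_is_inside():
    img = np.zeros((9, 9, 9))
    img[3:6, 3:6, 3:6] = 7.0
    stack = VoxelStack({"c": img}, (1, 1, 1))
    f = initialize_from_threshold(stack, "c", threshold=7.0, presmooth_sigma=0.0)
    assert f.phi[4, 4, 4] < 0  # voxels exactly at threshold count as tissue


def test_reinitialize_near_idempotent(sphere_phi_analytic):
    """Reinitialising an exact signed distance changes it only at the
    discretisation level, and the zero set stays within half a voxel."""
    f, c, R = sphere_phi_analytic
    out = reinitialize(f, band_width=6.0)
    band = np.abs(f.phi) <= 4.0
    assert np.abs(out.phi - f.phi)[band].max() < 0.2  # fraction of a voxel
    # zero-crossing radius preserved
    mid = int(c[0])
    row = out.phi[mid, mid, :]
    sign_change = np.where(np.diff(np.sign(row)) != 0)[0]
    x0 = sign_change[0] + row[sign_change[0]] / (row[sign_change[0]] - row[sign_change[0] + 1])
    assert abs(abs(x0 + 0.5 - c[2]) - R) < 0.5


def test_reinitialize_scale_invariant_zero_set(sphere_phi_analytic):
    """phi scaled x3 reinitialises to unit gradient with the zero set fixed."""
    f, c, R = sphere_phi_analytic
    scaled = ImplicitField(3.0 * f.phi, f.spacing)
    out = reinitialize(scaled, band_width=6.0)
    band = np.abs(out.phi) < 4.0
    gz, gy, gx = np.gradient(out.phi, *out.spacing)
    gmag = np.sqrt(gz**2 + gy**2 + gx**2)
    assert 0.5 < np.median(gmag[band]) < 1.5
    assert np.abs(out.phi - f.phi)[np.abs(f.phi) < 3.0].max() < 0.3


def test_reinitialize_anisotropic_distances_in_um():
    """Distances are physical (μm): verified against brute-force nearest
    surface point on an ellipsoidal field with (2,1,1) μm voxels."""
    spacing = (2.0, 1.0, 1.0)
    n = (26, 48, 48)
    c = np.array([n[0] * 2 / 2, 24.0, 24.0])
    zz, yy, xx = np.meshgrid(
        (np.arange(n[0]) + 0.5) * 2.0, (np.arange(n[1]) + 0.5) * 1.0, (np.arange(n[2]) + 0.5) * 1.0,
        indexing="ij",
    )
    # ellipsoid level set, not a distance function
    val = ((zz - c[0]) / 15.0) ** 2 + ((yy - c[1]) / 20.0) ** 2 + ((xx - c[2]) / 10.0) ** 2 - 1.0
    out = reinitialize(ImplicitField(val, spacing), band_width=5.0)

    # brute-force oracle: dense surface sample of the true ellipsoid
    th = np.linspace(0, np.pi, 200)
    ph = np.linspace(0, 2 * np.pi, 400)
    T, P = np.meshgrid(th, ph)
    surf = np.column_stack(
        [
            (c[0] + 15.0 * np.cos(T)).ravel(),
            (c[1] + 20.0 * np.sin(T) * np.cos(P)).ravel(),
            (c[2] + 10.0 * np.sin(T) * np.sin(P)).ravel(),
        ]
    )
    rng = np.random.default_rng(0)
    band_idx = np.argwhere(np.abs(out.phi) < 3.0)
    sel = band_idx[rng.choice(len(band_idx), size=40, replace=False)]
    pts = np.column_stack([sel[:, 0] * 2.0 + 1.0, sel[:, 1] + 0.5, sel[:, 2] + 0.5])
    d_true = np.sqrt(((pts[:, None, :] - surf[None]) ** 2).sum(axis=2)).min(axis=1)
    d_est = np.abs(out.phi[sel[:, 0], sel[:, 1], sel[:, 2]])
    # first-order upwind propagation: errors stay below the coarse (z) voxel
    assert np.abs(d_est - d_true).max() < 1.5
    assert np.abs(d_est - d_true).mean() < 0.7


def test_reinitialize_empty_zero_set_raises():
    f = ImplicitField(np.ones((8, 8, 8)), (1, 1, 1))
    with pytest.raises(SurfaceError):
        reinitialize(f)


def test_evolve_no_forces_is_noop(sphere_scene):
    gt, stack = sphere_scene
    f0 = initialize_from_threshold(stack, MEMBRANE)
    out = evolve(f0, stack, LevelSetParams(smoothing_weight=0.0, attraction_weight=0.0))
    assert np.array_equal(np.sign(out.phi), np.sign(f0.phi))


def test_evolve_noiseless_shell_accuracy(sphere_scene):
    """Extracted zero set of the ideal shell stays within one voxel diagonal
    of the analytic sphere."""
    from creasemap.curvature import extract_mesh

    gt, stack = sphere_scene
    f = evolve(initialize_from_threshold(stack, MEMBRANE), stack, LevelSetParams())
    mesh = extract_mesh(f)
    keep = mesh.vertices[:, 2] > 2.0  # away from the base clip
    d = np.linalg.norm(mesh.vertices[keep] - gt.dome_center, axis=1)
    assert np.abs(d - gt.spec.dome_radius).max() <= np.linalg.norm(stack.spacing)


def test_evolve_monotone_smoothing_area(small_gt_stack):
    """Total zero-set mesh area does not increase with smoothing weight."""
    from creasemap.curvature import extract_mesh

    gt, stack = small_gt_stack
    areas = []
    for w in (0.05, 0.6):
        f = evolve(
            initialize_from_threshold(stack, MEMBRANE),
            stack,
            LevelSetParams(smoothing_weight=w, max_iterations=60),
        )
        areas.append(extract_mesh(f).as_trimesh().area)
    assert areas[1] <= areas[0] * 1.01


def test_evolve_anisotropy_consistency():
    """Surface position agrees between (1,1,1) and (2,1,1) μm samplings of
    the same scene within a voxel diagonal."""
    from creasemap.curvature import extract_mesh
    from creasemap.synthetic import SceneSpec, build_scene, rasterize

    radii = {}
    for spacing in [(1.0, 1.0, 1.0), (2.0, 1.0, 1.0)]:
        spec = SceneSpec(primordia=(), dome_radius=24.0, noise_sigma=0.0, voxel_spacing=spacing,
                         margin=5.0)
        gt = build_scene(spec)
        stack = rasterize(gt)
        f = evolve(initialize_from_threshold(stack, MEMBRANE), stack,
                   LevelSetParams(max_iterations=100))
        mesh = extract_mesh(f)
        keep = mesh.vertices[:, 2] > gt.dome_center[2] + 2.0
        radii[spacing] = np.linalg.norm(mesh.vertices[keep] - gt.dome_center, axis=1).mean()
    assert abs(radii[(1.0, 1.0, 1.0)] - radii[(2.0, 1.0, 1.0)]) < np.sqrt(6.0)
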