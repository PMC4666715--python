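"""Reporter projection onto the mesh and nucleus quantification."""

import copy

import numpy as np
import pytest

from creasemap.projection import (
    NucleusRecord,
    ProjectionParams,
    ZoneGeometry,
    detect_nuclei,
    project_signal,
    zone_sample,
)
from creasemap.stack import VoxelStack
from creasemap.synthetic import REPORTER, SceneSpec, build_scene, rasterize


def _uniform_stack(value, shape=(30, 30, 30), spacing=(1.0, 1.0, 1.0)):
    return VoxelStack({"c": np.full(shape, float(value))}, spacing)


def test_projection_constant_field(small_extracted):
    """A uniform channel projects to that constant at every interior vertex."""
    gt, stack, phi, mesh = small_extracted
    mesh = copy.deepcopy(mesh)
    uni = VoxelStack({"c": np.full(stack.shape, 7.5)}, stack.spacing)
    out = project_signal(mesh, uni, "c", ProjectionParams(blur_radius=0.0))
    vals = out.attributes["projected_intensity"]
    interior = ~np.isnan(vals)
    assert interior.any()
    assert np.allclose(vals[interior], 7.5)


def test_projection_linearity(small_extracted):
    """project(A + B) == project(A) + project(B) for the mean statistic."""
    gt, stack, phi, mesh = small_extracted
    rng = np.random.default_rng(2)
    A = rng.random(stack.shape) * 10
    B = rng.random(stack.shape) * 5
    sp = stack.spacing
    params = ProjectionParams(blur_radius=3.0)

    def proj(img):
        m = copy.deepcopy(mesh)
        out = project_signal(m, VoxelStack({"c": img}, sp), "c", params)
        return out.attributes["projected_intensity"]

    pa, pb, pab = proj(A), proj(B), proj(A + B)
    ok = np.isfinite(pa) & np.isfinite(pb) & np.isfinite(pab)
    assert np.allclose(pab[ok], (pa + pb)[ok], rtol=1e-6)


def test_blur_preserves_total_signal():
    """Gaussian blur conserves the photon count of an interior blob."""
    img = np.zeros((40, 40, 40))
    img[18:22, 18:22, 18:22] = 50.0
    stack = VoxelStack({"c": img}, (1.0, 1.0, 1.0))
    from scipy import ndimage

    blurred = ndimage.gaussian_filter(img, sigma=3.0, mode="nearest")
    assert blurred.sum() == pytest.approx(img.sum(), rel=1e-3)


def test_projection_max_catches_buried_sheet():
    """A bright sheet 5 μm below a plane mesh is reached by a 10 μm-deep
    max projection."""
    from conftest import make_graph_mesh

    img = np.zeros((30, 40, 40))
    img[15, :, :] = 42.0  # z = 15.5 μm sheet
    stack = VoxelStack({"c": img}, (1.0, 1.0, 1.0))
    mesh = make_graph_mesh(lambda x, y: np.zeros_like(x), extent=8.0)
    mesh.vertices[:, 0] += 20.0
    mesh.vertices[:, 1] += 20.0
    mesh.vertices[:, 2] += 20.5  # plane 5 μm above the sheet
    mesh.vertex_normals = np.tile([0.0, 0.0, 1.0], (mesh.n_vertices, 1))  # outward = up
    out = project_signal(
        mesh, stack, "c",
        ProjectionParams(blur_radius=0.0, projection_thickness=10.0, projection_statistic="max"),
    )
    vals = out.attributes["projected_intensity"]
    ok = np.isfinite(vals)
    assert np.allclose(vals[ok], 42.0)


def test_projected_intensity_anticorrelates_with_curvature(small_extracted):
    """On a coupled scene the projected reporter decreases with true K."""
    gt, stack, phi, mesh = small_extracted
    mesh = copy.deepcopy(mesh)
    out = project_signal(mesh, stack, REPORTER)
    vals = out.attributes["projected_intensity"]
    ok = ~out.boundary_vertex_flags & np.isfinite(vals)
    K_true = gt.gaussian_curvature_fn(out.vertices[ok])
    r = np.corrcoef(K_true, vals[ok])[0, 1]
    assert r < 0


def test_detect_nuclei_exact_on_clean_blobs():
    """Three synthetic nuclei, zero noise: three records at the right spots."""
    img = np.zeros((40, 40, 40))
    centers = [(10.5, 12.5, 14.5), (25.5, 20.5, 8.5), (30.5, 30.5, 30.5)]
    zz, yy, xx = np.meshgrid(*[(np.arange(40) + 0.5)] * 3, indexing="ij")
    for cz, cy, cx in centers:
        img += 100 * np.exp(-((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 1.25**2))
    stack = VoxelStack({"n": img}, (1.0, 1.0, 1.0))
    recs = detect_nuclei(stack, "n", expected_radius=2.5)
    assert len(recs) == 3
    det = np.array([r.centroid for r in recs])
    true_xyz = np.array([(cx, cy, cz) for cz, cy, cx in centers])
    d = np.sqrt(((det[:, None] - true_xyz[None]) ** 2).sum(axis=2)).min(axis=1)
    assert (d <= np.sqrt(3.0)).all()


def test_detect_nuclei_empty_channel():
    stack = VoxelStack({"n": np.zeros((10, 10, 10))}, (1, 1, 1))
    assert detect_nuclei(stack, "n", 2.5) == []


def test_detect_nuclei_intensity_linearity():
    """Doubling a nucleus' brightness doubles its integrated intensity."""
    img = np.zeros((30, 60, 30))
    zz, yy, xx = np.meshgrid(
        (np.arange(30) + 0.5), (np.arange(60) + 0.5), (np.arange(30) + 0.5), indexing="ij"
    )
    img += 100 * np.exp(-((zz - 15) ** 2 + (yy - 15) ** 2 + (xx - 15) ** 2) / (2 * 1.25**2))
    img += 200 * np.exp(-((zz - 15) ** 2 + (yy - 45) ** 2 + (xx - 15) ** 2) / (2 * 1.25**2))
    stack = VoxelStack({"n": img}, (1.0, 1.0, 1.0))
    recs = detect_nuclei(stack, "n", expected_radius=2.5)
    assert len(recs) == 2
    ratio = recs[0].integrated_intensity / recs[1].integrated_intensity
    assert ratio == pytest.approx(2.0, rel=0.05)


def test_detect_nuclei_recall_precision_on_scene():
    """Recall and precision >= 0.95 on a mildly noisy synthetic meristem."""
    spec = SceneSpec(seed=9, coupling_beta=0.0, noise_sigma=5.0)  # 5% of nucleus peak
    gt = build_scene(spec)
    stack = rasterize(gt)
    recs = detect_nuclei(stack, REPORTER, expected_radius=spec.nucleus_radius)
    det = np.array([r.centroid for r in recs])
    true_xyz = gt.nuclei[["x", "y", "z"]].to_numpy()
    d = np.sqrt(((det[:, None] - true_xyz[None]) ** 2).sum(axis=2))
    recall = (d.min(axis=0) <= 2.5).mean()
    precision = (d.min(axis=1) <= 2.5).mean()
    assert recall >= 0.95
    assert precision >= 0.95


def _mk_nucleus(x, y, z, inten):
    return NucleusRecord(np.array([x, y, z]), 2.5, 0, inten)


def test_zone_sample_selection_contract():
    rng = np.random.default_rng(0)
    apex = np.array([0.0, 0.0, 30.0])
    nuclei = []
    for i in range(12):  # central cluster
        nuclei.append(_mk_nucleus(rng.normal(0, 4), rng.normal(0, 4), 29.0, 100 + i))
    for i in range(18):  # periphery
        nuclei.append(_mk_nucleus(35 + rng.normal(0, 2), 0.0, 12.0, 500 + i))
    zones = ZoneGeometry(apex=apex, central_radius=20.0)
    picked = zone_sample(nuclei, zones, k=10)
    assert len(picked) == 10
    assert all(r.zone == "central" for r in picked)
    # k=1 returns the single brightest in-zone nucleus
    top = zone_sample(nuclei, zones, k=1)
    assert len(top) == 1
    assert top[0].integrated_intensity == max(
        r.integrated_intensity for r in nuclei if r.zone == "central"
    )


def test_zone_sample_shortfall_warns():
    nuclei = [_mk_nucleus(0, 0, 29, 50.0)]
    zones = ZoneGeometry(apex=np.array([0.0, 0.0, 30.0]))
    with pytest.warns(UserWarning):
        picked = zone_sample(nuclei, zones, k=10)
    assert len(picked) == 1


def test_ablation_boost_recovered_in_zones():
    """Generator-boosted peri-ablation nuclei come out brighter than the
    opposite control side."""
    spec = SceneSpec(seed=4, coupling_beta=0.0, noise_sigma=2.0)
    gt0 = build_scene(spec)
    cx, cy = gt0.apex[0] + 12.0, gt0.apex[1]
    spec = spec.replace(ablation_disc=((cx, cy), 5.0), ablation_boost=2.5)
    gt = build_scene(spec)
    stack = rasterize(gt)
    recs = detect_nuclei(stack, REPORTER, expected_radius=spec.nucleus_radius)
    zones = ZoneGeometry(
        apex=gt.apex, ablation_center=np.array([cx, cy]), ablation_radius=5.0
    )
    near = zone_sample(recs, zones, k=10, requested=("near_ablation",))
    ctrl = zone_sample(recs, zones, k=10, requested=("control_side",))
    assert len(near) and len(ctrl)
    m_near = np.mean([r.integrated_intensity for r in near])
    m_ctrl = np.mean([r.integrated_intensity for r in ctrl])
    assert m_near > m_ctrl
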