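"""Orthogonal sections, folding angles, organ areas, expression areas."""

import numpy as np
import pytest

from creasemap.geometry import polygon_area
from creasemap.sections import (
    SectionImage,
    expression_area,
    folding_angle,
    organ_area_topview,
    orthogonal_section,
    section_profile,
)
from creasemap.stack import VoxelStack


def _stack_from(img, spacing=(1.0, 1.0, 1.0), name="c"):
    return VoxelStack({name: img}, spacing)


def test_section_of_uniform_stack_is_constant():
    stack = _stack_from(np.full((20, 20, 20), 3.0))
    sec = orthogonal_section(stack, point=[10, 10, 10], normal=[0, 1, 0], thickness=2.0)
    img = sec.channel("c")
    inside = img > 0  # pixels that sampled the volume
    assert inside.any()
    assert np.allclose(img[inside], 3.0)


def test_full_thickness_section_equals_global_mip():
    """A z-normal section spanning the whole stack reduces to the global
    maximum projection (for band-limited images, where the resampling grid
    offset does not erode the extremes)."""
    from scipy import ndimage as ndi

    rng = np.random.default_rng(3)
    vol = ndi.gaussian_filter(rng.random((12, 16, 16)) * 10, sigma=2.0)
    stack = _stack_from(vol)
    sec = orthogonal_section(stack, point=[8, 8, 6], normal=[0, 0, 1], thickness=40.0)
    mip = vol.max(axis=0)
    img = sec.channel("c")
    assert img.max() == pytest.approx(mip.max(), rel=0.05)
    thr = 0.8 * mip.max()
    assert (img > thr).sum() >= 0.5 * (mip > thr).sum()


def test_oblique_section_chord_radius():
    """Slicing a ball off-centre shows a disc of radius √(R²-d²)."""
    n, R, d = 60, 20.0, 8.0
    c = n / 2.0
    zz, yy, xx = np.meshgrid(*[(np.arange(n) + 0.5)] * 3, indexing="ij")
    ball = (np.sqrt((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= R) * 100.0
    stack = _stack_from(ball)
    normal = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
    point = np.array([c, c, c]) + d * normal
    sec = orthogonal_section(stack, point=point, normal=normal, thickness=1.0)
    img = sec.channel("c")
    area = (img > 50).sum() * sec.pixel_size**2
    r_measured = np.sqrt(area / np.pi)
    assert r_measured == pytest.approx(np.sqrt(R**2 - d**2), abs=1.0)


def test_degenerate_normal_raises():
    stack = _stack_from(np.ones((8, 8, 8)))
    with pytest.raises(ValueError):
        orthogonal_section(stack, point=[4, 4, 4], normal=[0, 0, 0])


def test_folding_angle_flat_and_v():
    flat = np.column_stack([np.linspace(0, 40, 200), np.zeros(200)])
    assert folding_angle(flat) == pytest.approx(180.0)

    xs = np.linspace(-15, 15, 301)
    v = np.column_stack([xs, np.abs(xs)])  # two lines meeting at 90°
    assert folding_angle(v) == pytest.approx(90.0, abs=2.0)


def test_folding_angle_rotation_invariant():
    """The angle does not depend on in-plane rotation of the profile."""
    xs = np.linspace(-15, 15, 301)
    v = np.column_stack([xs, 0.5 * np.abs(xs)])
    a0 = folding_angle(v)
    th = np.deg2rad(35.0)
    Rm = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    a1 = folding_angle(v @ Rm.T)
    assert a1 == pytest.approx(a0, abs=1.0)


def test_folding_angle_too_short_profile_is_nan():
    stub = np.column_stack([np.linspace(0, 3, 10), np.zeros(10)])
    assert np.isnan(folding_angle(stub))


def test_measured_angle_matches_ground_truth(small_extracted):
    """Pipeline-measured folding angle within 5° of the analytic profile's."""
    from creasemap.pipeline import measure_boundaries

    gt, stack, phi, mesh = small_extracted
    df = measure_boundaries(gt, stack, mesh)
    err = (df["folding_angle_deg"] - df["true_folding_angle_deg"]).abs()
    assert (err <= 5.0).all()


def test_polygon_circle_area():
    th = np.linspace(0, 2 * np.pi, 65)[:-1]
    circ = np.column_stack([10 * np.cos(th), 10 * np.sin(th)])
    assert organ_area_topview(circ) == pytest.approx(313.6, rel=0.01)


def test_polygon_errors():
    with pytest.raises(ValueError):
        polygon_area(np.array([[0.0, 0.0], [1.0, 1.0]]))  # degenerate
    bowtie = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
    with pytest.raises(ValueError):
        polygon_area(bowtie)


def test_auto_organ_outline_matches_truth(small_extracted):
    """Curvature-flood outline of each organ agrees with the analytic cap
    footprint to within the definitional spread of outline placement inside
    the crease band (a large fraction of these 7-10 μm organs)."""
    import copy

    from creasemap.curvature import CurvatureParams, gaussian_curvature
    from creasemap.sections import auto_organ_outline

    gt, stack, phi, mesh = small_extracted
    # organs here are narrower than the standard 15 μm scale: use a finer one
    fine = gaussian_curvature(
        copy.deepcopy(mesh), CurvatureParams(neighborhood_radius=6.0)
    )
    for i, prim in enumerate(gt.spec.primordia):
        theta = prim.radial_offset / gt.spec.dome_radius
        tip = gt.dome_center + (gt.spec.dome_radius + prim.bump_amplitude) * np.array(
            [np.sin(theta) * np.cos(prim.azimuth), np.sin(theta) * np.sin(prim.azimuth),
             np.cos(theta)]
        )
        outline, area = auto_organ_outline(fine, tip[:2], gt.apex[:2])
        truth = gt.boundary_profiles["organ_area_um2"][i]
        assert area == pytest.approx(truth, rel=0.5)
        assert len(outline) > 5


def test_expression_area_zero_and_rectangle():
    img = np.zeros((40, 60))
    sec = SectionImage(
        images={"g": img}, pixel_size=1.0, point=np.zeros(3), normal=np.array([0, 1, 0.0]),
        u=np.array([1, 0, 0.0]), v=np.array([0, 0, 1.0]), u0=0.0, v0=0.0, thickness=2.0,
    )
    assert expression_area(sec, "g", threshold=10.0) == 0.0

    img[10:15, 20:40] = 100.0  # 5 x 20 μm = 100 μm²
    assert expression_area(sec, "g", threshold=50.0) == pytest.approx(100.0, abs=4.0)


def test_expression_area_scales_with_width():
    """Doubling the painted width doubles the measured area."""
    def painted(width):
        img = np.zeros((50, 80))
        img[20:25, 10 : 10 + width] = 100.0
        sec = SectionImage(
            images={"g": img}, pixel_size=1.0, point=np.zeros(3), normal=np.array([0, 1, 0.0]),
            u=np.array([1, 0, 0.0]), v=np.array([0, 0, 1.0]), u0=0.0, v0=0.0, thickness=2.0,
        )
        return expression_area(sec, "g", threshold=50.0)

    assert painted(40) / painted(20) == pytest.approx(2.0, rel=0.10)


def test_expression_band_restriction():
    """Signal outside the sub-surface band is ignored."""
    img = np.zeros((60, 60))
    img[5:10, 10:30] = 100.0  # far below the curve
    img[38:42, 10:30] = 100.0  # just under the curve
    sec = SectionImage(
        images={"g": img}, pixel_size=1.0, point=np.zeros(3), normal=np.array([0, 1, 0.0]),
        u=np.array([1, 0, 0.0]), v=np.array([0, 0, 1.0]), u0=0.0, v0=0.0, thickness=2.0,
    )
    curve = np.column_stack([np.linspace(0, 59, 60), np.full(60, 45.0)])
    area = expression_area(sec, "g", threshold=50.0, surface_curve=curve, band_depth=15.0)
    assert area == pytest.approx(4 * 20, abs=6.0)
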