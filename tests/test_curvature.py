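"""Mesh extraction and quadric-fit Gaussian curvature."""

import numpy as np
import pytest

from creasemap.curvature import CurvatureParams, extract_mesh, gaussian_curvature, smooth_attribute
from creasemap.surface import ImplicitField

from conftest import make_graph_mesh


def test_extract_mesh_sphere_distance(sphere_phi_analytic):
    f, c, R = sphere_phi_analytic
    mesh = extract_mesh(f)
    d = np.linalg.norm(mesh.vertices - c[::-1], axis=1)  # c is (z,y,x) index-ish
    assert abs(d.mean() - R) < np.sqrt(3.0) / 2
    # closed surface: no extremities
    assert not mesh.boundary_vertex_flags.any()
    # outward normals
    out = np.einsum("ij,ij->i", mesh.vertex_normals, mesh.vertices - c[::-1])
    assert (out > 0).mean() > 0.99


def test_extract_mesh_clipped_dome_flags_rim():
    """A hemisphere cut by the grid base gets extremity flags on the rim."""
    n = 40
    zz, yy, xx = np.meshgrid(*[(np.arange(n) + 0.5)] * 3, indexing="ij")
    phi = np.sqrt((zz - 2.0) ** 2 + (yy - 20.0) ** 2 + (xx - 20.0) ** 2) - 15.0
    mesh = extract_mesh(ImplicitField(phi, (1.0, 1.0, 1.0)))
    rim = mesh.vertices[:, 2] < 1.5
    assert rim.any()
    assert mesh.boundary_vertex_flags[rim].all()
    top = mesh.vertices[:, 2] > 10.0
    assert not mesh.boundary_vertex_flags[top].any()


def test_extract_mesh_empty_raises():
    from creasemap.surface import SurfaceError

    with pytest.raises(SurfaceError):
        extract_mesh(ImplicitField(np.ones((6, 6, 6)), (1, 1, 1)))


@pytest.mark.parametrize("R,spacing", [(25.0, 1.0), (50.0, 1.5)])
def test_sphere_curvature_median(R, spacing):
    """Median estimated K within 10% of 1/R² (15 μm neighbourhoods)."""
    n = int((2 * R + 16) / spacing)
    c = n * spacing / 2
    zz, yy, xx = np.meshgrid(*[(np.arange(n) + 0.5) * spacing] * 3, indexing="ij")
    phi = np.sqrt((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) - R
    mesh = gaussian_curvature(extract_mesh(ImplicitField(phi, (spacing,) * 3)))
    K = mesh.attributes["gaussian_curvature"]
    med = np.nanmedian(K[~mesh.boundary_vertex_flags])
    assert med == pytest.approx(1.0 / R**2, rel=0.10)


def test_plane_curvature_zero(plane_mesh):
    mesh = gaussian_curvature(plane_mesh)
    K = mesh.attributes["gaussian_curvature"]
    assert np.nanmax(np.abs(K[~mesh.boundary_vertex_flags])) < 1e-5


def test_saddle_curvature_at_origin(saddle_mesh):
    """z = (x²-y²)/(2·20): K at the origin within 15% of -2.5e-3 μm⁻²."""
    mesh = gaussian_curvature(saddle_mesh)
    i0 = np.argmin(np.linalg.norm(mesh.vertices[:, :2], axis=1))
    assert mesh.attributes["gaussian_curvature"][i0] == pytest.approx(-2.5e-3, rel=0.15)


def test_scale_equivariance():
    """Scaling the mesh by s scales K by 1/s² (neighbourhood scaled along)."""
    base = make_graph_mesh(lambda x, y: (x**2 + y**2) / 80.0, extent=25.0)
    m1 = gaussian_curvature(base, CurvatureParams(neighborhood_radius=12.0))
    s = 2.0
    scaled = make_graph_mesh(lambda x, y: (x**2 + y**2) / (80.0 * s), extent=25.0 * s, step=s)
    m2 = gaussian_curvature(scaled, CurvatureParams(neighborhood_radius=12.0 * s))
    i1 = np.argmin(np.linalg.norm(m1.vertices[:, :2], axis=1))
    i2 = np.argmin(np.linalg.norm(m2.vertices[:, :2], axis=1))
    K1 = m1.attributes["gaussian_curvature"][i1]
    K2 = m2.attributes["gaussian_curvature"][i2]
    assert K2 == pytest.approx(K1 / s**2, rel=0.05)


def test_metric_consistency_on_plane(plane_mesh):
    """Geodesic and euclidean neighbourhoods agree on a flat patch."""
    import copy

    g = gaussian_curvature(copy.deepcopy(plane_mesh), CurvatureParams(neighborhood_metric="geodesic"))
    e = gaussian_curvature(copy.deepcopy(plane_mesh), CurvatureParams(neighborhood_metric="euclidean"))
    ok = ~(g.boundary_vertex_flags | e.boundary_vertex_flags)
    diff = np.abs(g.attributes["gaussian_curvature"][ok] - e.attributes["gaussian_curvature"][ok])
    assert np.nanmax(diff) < 1e-5


def test_min_neighbors_param_validation():
    with pytest.raises(ValueError):
        CurvatureParams(min_neighbors=4)
    with pytest.raises(ValueError):
        CurvatureParams(neighborhood_radius=0.0)
    with pytest.raises(ValueError):
        CurvatureParams(neighborhood_metric="chebyshev")


def test_smooth_attribute_identity_and_oracle(plane_mesh):
    import copy

    mesh = copy.deepcopy(plane_mesh)
    rng = np.random.default_rng(5)
    vals = rng.normal(size=mesh.n_vertices)
    mesh.attributes["a"] = vals.copy()
    # radius 0: identity
    out = smooth_attribute(mesh, "a", radius=0.0)
    assert np.array_equal(out.attributes["a"], vals)
    # constant: unchanged
    mesh.attributes["b"] = np.full(mesh.n_vertices, 3.25)
    out = smooth_attribute(mesh, "b", radius=5.0)
    assert np.allclose(out.attributes["b"], 3.25)
    # step attribute: matches brute-force neighbourhood averaging at probes
    step = (mesh.vertices[:, 0] > 0).astype(float)
    mesh.attributes["c"] = step.copy()
    out = smooth_attribute(mesh, "c", radius=4.0, metric="euclidean")
    rng = np.random.default_rng(1)
    probes = rng.choice(mesh.n_vertices, size=20, replace=False)
    for i in probes:
        d = np.linalg.norm(mesh.vertices - mesh.vertices[i], axis=1)
        expected = step[d <= 4.0].mean()
        assert out.attributes["c"][i] == pytest.approx(expected, abs=1e-12)


def test_smooth_attribute_unknown_name(plane_mesh):
    with pytest.raises(KeyError):
        smooth_attribute(plane_mesh, "no_such", radius=2.0)
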