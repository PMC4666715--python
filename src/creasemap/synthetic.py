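"""Synthetic meristem-like stacks with analytically known geometry.

The generator builds a shoot-apical-meristem phantom as the smooth (soft-min)
union of a spherical dome and one sphere per lateral primordium.  Because the
surface is an analytic implicit field, its Gaussian curvature is available in
closed form from the gradient and Hessian, so every downstream stage —
level-set surface detection, mesh curvature, signal projection, folding-angle
and area measures, binned statistics — can be checked against ground truth.

Two image channels are rasterised from the scene:

* ``membrane``: a thin bright Gaussian shell centred on the surface,
  emulating an FM4-64 counterstain;
* ``reporter``: Gaussian blobs at L1-nucleus positions whose amplitude is
  ``baseline + beta * max(0, -K)``, i.e. the reporter is brighter where the
  surface is saddle-shaped (boundary creases), emulating the boundary-enriched
  nuclear reporter the pipeline is designed to quantify.

``folding_delay_factor`` widens the soft-min blending of the dome/primordium
junction, producing shallower creases at unchanged organ footprint — a
katanin-mutant-like "delayed folding" phenotype.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import fit_folding_angle
from .stack import VoxelStack

__all__ = [
    "Primordium",
    "SceneSpec",
    "GroundTruth",
    "SphereUnion",
    "GraphSurface",
    "build_scene",
    "rasterize",
    "delayed_folding_variant",
]

MEMBRANE = "membrane"
REPORTER = "reporter"

_MAX_VOXELS = 2 * 10**8  # per channel; explicit failure instead of an OOM kill


@dataclass(frozen=True)
class Primordium:
    """One lateral organ bump.

    ``azimuth`` (rad) and ``radial_offset`` (μm of arc from the apex along the
    dome) place the bump; ``bump_amplitude`` (μm) is how far it protrudes
    beyond the dome; ``bump_width`` (μm) is the radius of the bump sphere.
    """

    azimuth: float
    radial_offset: float
    bump_amplitude: float
    bump_width: float


def _default_primordia() -> tuple[Primordium, ...]:
    # three successive primordia at ~137.5° divergence, increasing in size
    golden = np.deg2rad(137.5)
    return (
        Primordium(azimuth=0.0, radial_offset=28.0, bump_amplitude=5.0, bump_width=9.0),
        Primordium(azimuth=golden, radial_offset=31.0, bump_amplitude=7.0, bump_width=10.0),
        Primordium(azimuth=2 * golden, radial_offset=34.0, bump_amplitude=9.0, bump_width=11.0),
    )


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic scene; identical specs with identical
    seeds rasterise to bit-identical stacks."""

    dome_radius: float = 30.0  # μm
    primordia: tuple[Primordium, ...] = field(default_factory=_default_primordia)
    coupling_beta: float = 4.0e4  # a.u. per μm⁻²: reporter gain on -K
    baseline_intensity: float = 100.0  # a.u.
    noise_sigma: float = 5.0  # a.u., additive Gaussian, both channels
    shell_thickness: float = 2.0  # μm, membrane shell width (2σ)
    shell_peak: float = 200.0  # a.u., membrane shell amplitude
    nucleus_radius: float = 2.5  # μm
    nucleus_depth: float = 4.0  # μm below the surface (L1)
    nucleus_spacing: float = 5.0  # μm lattice pitch of L1 nuclei (epidermal cell size)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (z, y, x) μm
    seed: int = 0
    folding_delay_factor: float = 1.0  # 1 = wild-type-like; >1 = shallow creases
    ablation_disc: tuple[tuple[float, float], float] | None = None  # ((x, y), radius μm)
    ablation_boost: float = 1.0  # intensity factor for peri-ablation nuclei
    blend_width: float = 3.0  # μm smooth-min blending: creases round at cell scale
    margin: float = 6.0  # μm padding around the surface in the grid

    def __post_init__(self) -> None:
        if self.dome_radius <= 0:
            raise ValueError("dome_radius must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacings must be positive")
        if self.folding_delay_factor <= 0:
            raise ValueError("folding_delay_factor must be positive")
        for p in self.primordia:
            if p.bump_width <= 0:
                raise ValueError("bump_width must be positive")
            if not 0 < p.bump_amplitude < 2 * p.bump_width:
                raise ValueError(
                    "bump_amplitude must lie in (0, 2*bump_width) for a smooth, "
                    "attached bump"
                )

    def replace(self, **changes) -> "SceneSpec":
        return dataclasses.replace(self, **changes)


# --------------------------------------------------------------------------
# analytic implicit surfaces
# --------------------------------------------------------------------------


class AnalyticImplicit:
    """Scalar field f with f<0 inside, f=0 on the surface, f>0 outside, plus
    analytic gradient and Hessian, from which the Gaussian curvature of the
    zero level set is K = (∇f · adj(H) ∇f) / |∇f|⁴."""

    def value(self, pts: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def gradient(self, pts: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def hessian(self, pts: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def normal(self, pts: np.ndarray) -> np.ndarray:
        g = self.gradient(pts)
        return g / np.linalg.norm(g, axis=-1, keepdims=True)

    def gaussian_curvature(self, pts: np.ndarray) -> np.ndarray:
        """K of the level set through each point (exact on the zero set)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        g = self.gradient(pts)
        H = self.hessian(pts)
        adj = _adjugate_sym3(H)
        num = np.einsum("ni,nij,nj->n", g, adj, g)
        den = np.einsum("ni,ni->n", g, g) ** 2
        return num / den


def _adjugate_sym3(H: np.ndarray) -> np.ndarray:
    """Adjugate of a stack of symmetric 3x3 matrices."""
    a, b, c = H[..., 0, 0], H[..., 0, 1], H[..., 0, 2]
    d, e = H[..., 1, 1], H[..., 1, 2]
    f = H[..., 2, 2]
    adj = np.empty_like(H)
    adj[..., 0, 0] = d * f - e * e
    adj[..., 1, 1] = a * f - c * c
    adj[..., 2, 2] = a * d - b * b
    adj[..., 0, 1] = adj[..., 1, 0] = c * e - b * f
    adj[..., 0, 2] = adj[..., 2, 0] = b * e - c * d
    adj[..., 1, 2] = adj[..., 2, 1] = b * c - a * e
    return adj


class SphereUnion(AnalyticImplicit):
    """Smooth-min union of spheres with a compact cubic blend.

    Pairwise (accumulated left to right):

        smin(a, b) = min(a, b) - (w/6) * max(0, 1 - |a-b|/w)³

    which equals the exact union outside the band |a-b| < w and is C², so
    the Gaussian curvature of the zero set is well defined through the
    crease.  Because the blend has compact support, widening ``w`` rounds
    the crease without inflating the bump or moving its footprint.  With a
    single sphere this is exactly the sphere's signed distance.
    """

    def __init__(self, centers: np.ndarray, radii: np.ndarray, blend: float):
        self.centers = np.atleast_2d(np.asarray(centers, dtype=np.float64))
        self.radii = np.asarray(radii, dtype=np.float64).ravel()
        if len(self.centers) != len(self.radii):
            raise ValueError("centers and radii length mismatch")
        self.blend = float(blend)

    def _sphere(self, pts, k):
        diff = pts - self.centers[k]
        dist = np.maximum(np.linalg.norm(diff, axis=1), 1e-12)
        val = dist - self.radii[k]
        grad = diff / dist[:, None]
        proj = np.eye(3)[None] - grad[:, :, None] * grad[:, None, :]
        hess = proj / dist[:, None, None]
        return val, grad, hess

    @staticmethod
    def _smin_pair(va, ga, Ha, vb, gb, Hb, w):
        d = va - vb
        absd = np.abs(d)
        q = np.clip(1.0 - absd / w, 0.0, 1.0)
        sgn = np.sign(d)
        # f = (a+b)/2 - g(d);  g' = sign(d)(1-q²)/2,  g'' = q/w
        val = 0.5 * (va + vb) - 0.5 * absd - (w / 6.0) * q**3
        gp = 0.5 * sgn * (1.0 - q**2)
        gpp = q / w
        gd = ga - gb
        grad = 0.5 * (ga + gb) - gp[:, None] * gd
        hess = (
            0.5 * (Ha + Hb)
            - gp[:, None, None] * (Ha - Hb)
            - gpp[:, None, None] * gd[:, :, None] * gd[:, None, :]
        )
        return val, grad, hess

    def _chain(self, pts):
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        val, grad, hess = self._sphere(pts, 0)
        for k in range(1, len(self.radii)):
            vb, gb, Hb = self._sphere(pts, k)
            val, grad, hess = self._smin_pair(val, grad, hess, vb, gb, Hb, self.blend)
        return val, grad, hess

    def value(self, pts: np.ndarray) -> np.ndarray:
        return self._chain(pts)[0]

    def gradient(self, pts: np.ndarray) -> np.ndarray:
        return self._chain(pts)[1]

    def hessian(self, pts: np.ndarray) -> np.ndarray:
        return self._chain(pts)[2]


class GraphSurface(AnalyticImplicit):
    """Implicit form f = z - h(x, y) of an explicit height map (test scenes
    such as the saddle z = (x² - y²)/(2a))."""

    def __init__(self, h, hx, hy, hxx, hxy, hyy):
        self.h, self.hx, self.hy = h, hx, hy
        self.hxx, self.hxy, self.hyy = hxx, hxy, hyy

    @classmethod
    def saddle(cls, a: float) -> "GraphSurface":
        return cls(
            h=lambda x, y: (x**2 - y**2) / (2 * a),
            hx=lambda x, y: x / a,
            hy=lambda x, y: -y / a,
            hxx=lambda x, y: np.full_like(x, 1.0 / a),
            hxy=lambda x, y: np.zeros_like(x),
            hyy=lambda x, y: np.full_like(x, -1.0 / a),
        )

    def value(self, pts):
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        return pts[:, 2] - self.h(pts[:, 0], pts[:, 1])

    def gradient(self, pts):
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        g = np.empty_like(pts)
        g[:, 0] = -self.hx(pts[:, 0], pts[:, 1])
        g[:, 1] = -self.hy(pts[:, 0], pts[:, 1])
        g[:, 2] = 1.0
        return g

    def hessian(self, pts):
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        x, y = pts[:, 0], pts[:, 1]
        H = np.zeros((len(pts), 3, 3))
        H[:, 0, 0] = -self.hxx(x, y)
        H[:, 0, 1] = H[:, 1, 0] = -self.hxy(x, y)
        H[:, 1, 1] = -self.hyy(x, y)
        return H


# --------------------------------------------------------------------------
# scene construction
# --------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Analytic ground truth for one scene, all in the stack's world frame
    ((x, y, z) μm; voxel centres at (index + 0.5) * spacing)."""

    spec: SceneSpec
    surface: SphereUnion
    dome_center: np.ndarray
    grid_shape: tuple[int, int, int]  # (nz, ny, nx)
    nuclei: pd.DataFrame  # columns x, y, z, true_intensity, zone
    boundary_profiles: pd.DataFrame  # per primordium: folding angle, organ area

    @property
    def apex(self) -> np.ndarray:
        return self.dome_center + np.array([0.0, 0.0, self.spec.dome_radius])

    def implicit_surface(self, pts: np.ndarray) -> np.ndarray:
        return self.surface.value(pts)

    def gaussian_curvature_fn(self, pts: np.ndarray) -> np.ndarray:
        return self.surface.gaussian_curvature(pts)

    def surface_point(self, directions: np.ndarray) -> np.ndarray:
        """Cast rays from the dome centre along unit ``directions`` and return
        the zero-crossing points (bisection)."""
        d = np.atleast_2d(np.asarray(directions, dtype=np.float64))
        d = d / np.linalg.norm(d, axis=1, keepdims=True)
        spec = self.spec
        amax = max((p.bump_amplitude for p in spec.primordia), default=0.0)
        lo = np.full(len(d), 0.3 * spec.dome_radius)
        hi = np.full(len(d), spec.dome_radius + amax + 3 * spec.blend_width + 1.0)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            val = self.surface.value(self.dome_center + mid[:, None] * d)
            inside = val < 0
            lo = np.where(inside, mid, lo)
            hi = np.where(inside, hi, mid)
        t = 0.5 * (lo + hi)
        return self.dome_center + t[:, None] * d

    def surface_distance(self, pts: np.ndarray) -> np.ndarray:
        """Approximate unsigned distance from points to the analytic surface
        (|f| / |∇f|, one Newton correction; accurate near the surface)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        f = self.surface.value(pts)
        g = self.surface.gradient(pts)
        gn = np.linalg.norm(g, axis=1)
        step = f / np.maximum(gn, 1e-9)
        proj = pts - step[:, None] * (g / np.maximum(gn, 1e-9)[:, None])
        f2 = self.surface.value(proj)
        g2 = np.linalg.norm(self.surface.gradient(proj), axis=1)
        return np.abs(step + f2 / np.maximum(g2, 1e-9))

    def section_plane(self, primordium_index: int) -> tuple[np.ndarray, np.ndarray]:
        """Longitudinal section through the middle of one boundary: the plane
        containing the dome axis and the primordium centre.  Returns
        (point, unit normal) in world coordinates."""
        p = self.spec.primordia[primordium_index]
        horiz = np.array([np.cos(p.azimuth), np.sin(p.azimuth), 0.0])
        # oriented so the section frame's in-plane u axis points toward the bump
        normal = np.cross(horiz, np.array([0.0, 0.0, 1.0]))
        return self.dome_center.copy(), normal

    def analytic_profile(
        self, primordium_index: int, extent_deg: float = 3.0, n: int = 400
    ) -> np.ndarray:
        """Densely sampled surface profile in the boundary section plane,
        returned as (arc position, height) pairs from the apex to just past
        the bump tip.  The profile deliberately stops at the tip: beyond it
        lies the organ's distal crease, which is not the meristem-organ
        boundary the folding angle refers to."""
        spec = self.spec
        p = spec.primordia[primordium_index]
        theta_p = p.radial_offset / spec.dome_radius
        horiz = np.array([np.cos(p.azimuth), np.sin(p.azimuth), 0.0])
        zhat = np.array([0.0, 0.0, 1.0])
        psi = np.linspace(0.0, theta_p + np.deg2rad(extent_deg), n)
        dirs = np.sin(psi)[:, None] * horiz[None] + np.cos(psi)[:, None] * zhat[None]
        pts = self.surface_point(dirs)
        rel = pts - self.dome_center
        return np.column_stack([rel @ horiz, rel @ zhat])


def _bump_geometry(spec: SceneSpec):
    """Centres/radii of the dome and bump spheres (dome frame, dome at origin)."""
    centers = [np.zeros(3)]
    radii = [spec.dome_radius]
    for p in spec.primordia:
        theta = p.radial_offset / spec.dome_radius
        d = np.array(
            [np.sin(theta) * np.cos(p.azimuth), np.sin(theta) * np.sin(p.azimuth), np.cos(theta)]
        )
        centers.append((spec.dome_radius + p.bump_amplitude - p.bump_width) * d)
        radii.append(p.bump_width)
    return np.array(centers), np.array(radii)


def _validate_primordia(spec: SceneSpec, centers: np.ndarray, radii: np.ndarray) -> None:
    # pairwise bump spheres must not merge into a non-smooth blob
    for i in range(1, len(centers)):
        for j in range(i + 1, len(centers)):
            gap = np.linalg.norm(centers[i] - centers[j])
            if gap < 0.75 * (radii[i] + radii[j]):
                raise ValueError(
                    f"primordia {i - 1} and {j - 1} overlap (centre distance "
                    f"{gap:.1f} μm < 0.75*(r_i + r_j) = {0.75 * (radii[i] + radii[j]):.1f} μm); "
                    "the soft union would not be smooth"
                )


def _grid_layout(spec: SceneSpec):
    """Grid shape and the dome centre position in the stack frame.

    The grid clips the lower part of the dome sphere (like a real top-view
    acquisition), keeping everything above ~0.35 R below the dome centre.
    """
    amax = max((p.bump_amplitude for p in spec.primordia), default=0.0)
    half_xy = spec.dome_radius + amax + spec.margin
    z_below = 0.35 * spec.dome_radius
    z_above = spec.dome_radius + amax + spec.margin
    sz, sy, sx = spec.voxel_spacing
    nx = int(np.ceil(2 * half_xy / sx))
    ny = int(np.ceil(2 * half_xy / sy))
    nz = int(np.ceil((z_below + z_above) / sz))
    dome_center = np.array([nx * sx / 2.0, ny * sy / 2.0, z_below])
    return (nz, ny, nx), dome_center


def _fibonacci_directions(n: int) -> np.ndarray:
    """Quasi-uniform directions on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    cos_t = 1 - 2 * i / n
    sin_t = np.sqrt(np.maximum(0.0, 1 - cos_t**2))
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def build_scene(spec: SceneSpec) -> GroundTruth:
    """Assemble the analytic scene: implicit surface, L1 nuclei with
    curvature-coupled intensities, and per-boundary analytic measures."""
    centers0, radii = _bump_geometry(spec)
    _validate_primordia(spec, centers0, radii)
    grid_shape, dome_center = _grid_layout(spec)
    centers = centers0 + dome_center
    blend = spec.blend_width * spec.folding_delay_factor
    surface = SphereUnion(centers, radii, blend)

    gt = GroundTruth(
        spec=spec,
        surface=surface,
        dome_center=dome_center,
        grid_shape=grid_shape,
        nuclei=pd.DataFrame(),
        boundary_profiles=pd.DataFrame(),
    )
    gt.nuclei = _place_nuclei(gt)
    gt.boundary_profiles = _boundary_profiles(gt)
    return gt


def _place_nuclei(gt: GroundTruth) -> pd.DataFrame:
    spec = gt.spec
    # lattice density from the requested pitch; restrict to the upper dome
    n_total = max(16, int(round(4 * np.pi * spec.dome_radius**2 / spec.nucleus_spacing**2)))
    dirs = _fibonacci_directions(n_total)
    polar_max = np.deg2rad(75.0)  # stay above the clipped base
    dirs = dirs[dirs[:, 2] > np.cos(polar_max)]
    pts = gt.surface_point(dirs)
    K = gt.surface.gaussian_curvature(pts)
    normals = gt.surface.normal(pts)
    cent = pts - spec.nucleus_depth * normals
    # nuclei are solid bodies: discard lattice sites whose inward offsets
    # converge (across creases) to closer than ~a nucleus diameter
    min_sep = 0.8 * spec.nucleus_spacing
    keep: list[int] = []
    for i in range(len(cent)):
        if all(np.linalg.norm(cent[i] - cent[j]) >= min_sep for j in keep):
            keep.append(i)
    keep = np.array(keep, dtype=int)
    pts, K, normals, cent = pts[keep], K[keep], normals[keep], cent[keep]
    intensity = spec.baseline_intensity + spec.coupling_beta * np.maximum(0.0, -K)

    zone = np.full(len(pts), "other", dtype=object)
    apex = gt.apex
    central = np.linalg.norm(pts - apex, axis=1) < 20.0
    zone[central] = "central"
    if spec.ablation_disc is not None:
        (ax, ay), ar = spec.ablation_disc
        dxy = np.hypot(cent[:, 0] - ax, cent[:, 1] - ay)
        ablated = dxy <= ar
        near = (~ablated) & (dxy <= ar + 25.0) & (dxy > ar)
        opposite = dxy > 2 * ar + 25.0
        zone[near] = "near_ablation"
        zone[opposite & ~central] = "control_side"
        zone[ablated] = "ablated"
        intensity = np.where(near, intensity * spec.ablation_boost, intensity)
        intensity = np.where(ablated, 0.0, intensity)

    return pd.DataFrame(
        {
            "x": cent[:, 0],
            "y": cent[:, 1],
            "z": cent[:, 2],
            "true_intensity": intensity,
            "surface_K": K,
            "zone": zone,
        }
    )


def _boundary_profiles(gt: GroundTruth) -> pd.DataFrame:
    rows = []
    for i, p in enumerate(gt.spec.primordia):
        prof = gt.analytic_profile(i)
        angle = fit_folding_angle(prof, arm_length=10.0)
        area = _organ_footprint_area(gt, i)
        rows.append(
            {
                "primordium": i,
                "azimuth_rad": p.azimuth,
                "folding_angle_deg": angle,
                "organ_area_um2": area,
            }
        )
    return pd.DataFrame(rows)


def _organ_footprint_area(gt: GroundTruth, primordium_index: int, n_sample: int = 40000) -> float:
    """Top-view area of one organ: the planimetric projection of the bump
    cap (the part of the bump sphere lying outside the dome sphere), which
    is what an outline drawn around the organ as viewed from above encloses.
    Quadrature over the bump sphere; exactly independent of the smooth-min
    blending width, so delayed-folding variants keep their organ footprint."""
    spec = gt.spec
    p = spec.primordia[primordium_index]
    c0 = gt.dome_center
    c1 = gt.surface.centers[1 + primordium_index]
    r0, r1 = spec.dome_radius, p.bump_width
    dirs = _fibonacci_directions(n_sample)
    pts = c1[None] + r1 * dirs
    cap = np.linalg.norm(pts - c0[None], axis=1) > r0
    if not cap.any():
        return 0.0  # engulfed bump
    nz = dirs[cap, 2]
    dA = 4.0 * np.pi * r1**2 / n_sample
    return float(np.maximum(nz, 0.0).sum() * dA)


def label_organ_vertices(gt: GroundTruth, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assign surface points to the dome (-1) or the primordium whose implicit
    part dominates there, with an organ-stage value (bump amplitude, μm).

    The organ region is where the bump sphere is closer (in implicit value)
    than the dome, i.e. everything distal to the crease rim; stage 0 on the
    dome.  Used to reproduce the exclusion of organs from the quantified
    region (the analysed outline encloses the dome and its boundaries).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    diff = pts[:, None, :] - gt.surface.centers[None, :, :]
    fk = np.linalg.norm(diff, axis=2) - gt.surface.radii[None, :]
    comp = np.argmin(fk, axis=1)
    organ_id = comp - 1  # -1 = dome
    amps = np.array([0.0] + [p.bump_amplitude for p in gt.spec.primordia])
    stage = amps[comp]
    return organ_id, stage


def delayed_folding_variant(spec: SceneSpec, factor: float | None = None) -> SceneSpec:
    """Return a spec with delayed boundary folding (katanin-mutant-like).

    The factor widens the soft-min blending of the dome/bump junction, so at
    matched organ footprint the crease is rounder: the folding angle is larger
    (shallower fold) and the curvature minimum less negative.  ``factor = 1``
    returns the spec unchanged.
    """
    f = spec.folding_delay_factor if factor is None else float(factor)
    if f < 1:
        raise ValueError("folding_delay_factor must be >= 1")
    return spec.replace(folding_delay_factor=f)


# --------------------------------------------------------------------------
# rasterisation
# --------------------------------------------------------------------------


def rasterize(gt: GroundTruth, spec: SceneSpec | None = None) -> VoxelStack:
    """Render the analytic scene into a two-channel stack.

    Channel ``membrane`` is a Gaussian shell over the implicit surface,
    channel ``reporter`` is the sum of nucleus blobs; both get additive
    Gaussian noise (sd ``noise_sigma``) and are clipped at zero.
    """
    spec = gt.spec if spec is None else spec
    nz, ny, nx = gt.grid_shape
    if nz * ny * nx > _MAX_VOXELS:
        raise MemoryError(
            f"requested grid {gt.grid_shape} exceeds the {_MAX_VOXELS} voxel bound; "
            "coarsen voxel_spacing or shrink the scene"
        )
    sz, sy, sx = spec.voxel_spacing
    zc = (np.arange(nz) + 0.5) * sz
    yc = (np.arange(ny) + 0.5) * sy
    xc = (np.arange(nx) + 0.5) * sx
    Z, Y, X = np.meshgrid(zc, yc, xc, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    f = gt.surface.value(pts).reshape(nz, ny, nx)
    sigma_shell = spec.shell_thickness / 2.0
    membrane = spec.shell_peak * np.exp(-0.5 * (f / sigma_shell) ** 2)

    reporter = np.zeros((nz, ny, nx))
    sigma_n = spec.nucleus_radius / 2.0
    reach = 3.0 * sigma_n
    for row in gt.nuclei.itertuples(index=False):
        if row.true_intensity <= 0:
            continue
        k0 = max(0, int((row.z - reach) / sz - 0.5))
        k1 = min(nz, int((row.z + reach) / sz + 1.5))
        j0 = max(0, int((row.y - reach) / sy - 0.5))
        j1 = min(ny, int((row.y + reach) / sy + 1.5))
        i0 = max(0, int((row.x - reach) / sx - 0.5))
        i1 = min(nx, int((row.x + reach) / sx + 1.5))
        if k0 >= k1 or j0 >= j1 or i0 >= i1:
            continue
        d2 = (
            (zc[k0:k1, None, None] - row.z) ** 2
            + (yc[None, j0:j1, None] - row.y) ** 2
            + (xc[None, None, i0:i1] - row.x) ** 2
        )
        reporter[k0:k1, j0:j1, i0:i1] += row.true_intensity * np.exp(-0.5 * d2 / sigma_n**2)

    if spec.ablation_disc is not None:
        (ax, ay), ar = spec.ablation_disc
        hole = (Y - ay) ** 2 + (X - ax) ** 2 <= ar**2
        membrane[hole] = 0.0
        reporter[hole] = 0.0

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        membrane = membrane + rng.normal(0.0, spec.noise_sigma, membrane.shape)
        reporter = reporter + rng.normal(0.0, spec.noise_sigma, reporter.shape)

    return VoxelStack(
        channels={
            MEMBRANE: np.clip(membrane, 0.0, None),
            REPORTER: np.clip(reporter, 0.0, None),
        },
        spacing=spec.voxel_spacing,
        meta={"seed": spec.seed},
    )
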