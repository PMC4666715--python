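"""Section-based measurements: longitudinal optical sections through boundary
midpoints, the folding angle of the crease, organ top-view areas, and the
area of reporter expression on sections.

A longitudinal section is a thin maximal projection across a plane: the stack
is resampled on a 2D grid in the plane (trilinear interpolation) and the
per-pixel maximum is taken across the section thickness, the optical analogue
of the 2–5 μm thick orthogonal views used for boundary inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .curvature import SurfaceMesh
from .geometry import fit_folding_angle, polygon_area
from .stack import VoxelStack

__all__ = [
    "SectionImage",
    "orthogonal_section",
    "section_profile",
    "folding_angle",
    "organ_area_topview",
    "auto_organ_outline",
    "expression_area",
]


@dataclass
class SectionImage:
    """2D resampled section.  Pixel (row, col) maps to the world point
    ``point + (u0 + col*pixel_size)*u + (v0 + row*pixel_size)*v``; ``v`` is
    chosen to point upward (+z) whenever the plane allows it."""

    images: dict[str, np.ndarray]
    pixel_size: float
    point: np.ndarray
    normal: np.ndarray
    u: np.ndarray
    v: np.ndarray
    u0: float
    v0: float
    thickness: float
    meta: dict = field(default_factory=dict)

    def channel(self, name: str) -> np.ndarray:
        if name not in self.images:
            raise KeyError(f"no channel {name!r}; have {list(self.images)}")
        return self.images[name]

    def world_to_plane(self, pts: np.ndarray) -> np.ndarray:
        """World (x, y, z) -> in-plane (u, v) coordinates (μm)."""
        rel = np.atleast_2d(pts) - self.point
        return np.column_stack([rel @ self.u, rel @ self.v])

    def plane_to_pixel(self, uv: np.ndarray) -> np.ndarray:
        """In-plane (u, v) -> fractional (row, col)."""
        uv = np.atleast_2d(uv)
        return np.column_stack(
            [(uv[:, 1] - self.v0) / self.pixel_size, (uv[:, 0] - self.u0) / self.pixel_size]
        )


def _plane_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = np.asarray(normal, dtype=np.float64)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("degenerate section normal")
    n = n / nn
    zhat = np.array([0.0, 0.0, 1.0])
    v = zhat - (zhat @ n) * n
    if np.linalg.norm(v) < 1e-6:  # horizontal section plane
        v = np.array([1.0, 0.0, 0.0]) - n[0] * n
    v /= np.linalg.norm(v)
    u = np.cross(v, n)
    return u, v


def orthogonal_section(
    stack: VoxelStack,
    point: np.ndarray,
    normal: np.ndarray,
    thickness: float = 2.0,
    channels: list[str] | None = None,
) -> SectionImage:
    """Maximal projection of the stack across a plane of given thickness."""
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    point = np.asarray(point, dtype=np.float64)
    u, v = _plane_frame(normal)
    n = np.cross(u, v)

    # extent: project the stack's corners onto the plane frame
    ex, ey, ez = stack.extent()
    corners = np.array(
        [[x, y, z] for x in (0, ex) for y in (0, ey) for z in (0, ez)], dtype=np.float64
    )
    rel = corners - point
    uu = rel @ u
    vv = rel @ v
    px = float(min(stack.spacing))
    u0, v0 = uu.min(), vv.min()
    ncol = max(2, int(np.ceil((uu.max() - u0) / px)))
    nrow = max(2, int(np.ceil((vv.max() - v0) / px)))

    cols = u0 + np.arange(ncol) * px
    rows = v0 + np.arange(nrow) * px
    UU, VV = np.meshgrid(cols, rows)  # (nrow, ncol)
    base = point[None, None, :] + UU[..., None] * u[None, None, :] + VV[..., None] * v[None, None, :]

    steps = np.arange(-thickness / 2, thickness / 2 + px / 2, px)
    names = channels or stack.channel_names
    out = {name: np.full((nrow, ncol), -np.inf) for name in names}
    for t in steps:
        pts = (base + t * n[None, None, :]).reshape(-1, 3)
        idx = stack.world_to_index(pts).T
        for name in names:
            s = ndimage.map_coordinates(
                stack.channel(name), idx, order=1, mode="constant", cval=0.0
            ).reshape(nrow, ncol)
            np.maximum(out[name], s, out=out[name])
    for name in names:
        out[name][~np.isfinite(out[name])] = 0.0
    return SectionImage(
        images=out, pixel_size=px, point=point, normal=n, u=u, v=v,
        u0=float(u0), v0=float(v0), thickness=float(thickness),
    )


def section_profile(
    mesh: SurfaceMesh,
    section: SectionImage,
    u_range: tuple[float, float] | None = None,
    v_min: float | None = None,
) -> np.ndarray:
    """Surface profile in the section plane: the mesh ∩ plane intersection
    curve as ordered 2D (u, v) points.

    Segments are projected into the plane and chained by shared endpoints
    (profiles are not graphs over the horizontal axis once an organ flank
    steepens); the longest contiguous stretch surviving the ``u_range`` /
    ``v_min`` crop is returned, oriented with ``u`` increasing."""
    tm = mesh.as_trimesh()
    import trimesh.intersections as tin

    segs = tin.mesh_plane(tm, plane_normal=section.normal, plane_origin=section.point)
    if len(segs) == 0:
        raise ValueError("section plane does not intersect the mesh")
    uv_segs = np.stack(
        [section.world_to_plane(segs[:, 0]), section.world_to_plane(segs[:, 1])], axis=1
    )
    chain = _chain_segments(uv_segs)
    if u_range is not None:
        keep = (chain[:, 0] >= u_range[0]) & (chain[:, 0] <= u_range[1])
    else:
        keep = np.ones(len(chain), dtype=bool)
    if v_min is not None:
        keep &= chain[:, 1] >= v_min
    chain = _longest_true_run(chain, keep)
    if len(chain) < 2:
        raise ValueError("profile crop left fewer than 2 points")
    if chain[0, 0] > chain[-1, 0]:
        chain = chain[::-1]
    return chain


def _chain_segments(segs: np.ndarray, decimals: int = 5) -> np.ndarray:
    """Order 2D intersection segments into the longest open polyline by
    walking shared endpoints."""
    key = lambda p: tuple(np.round(p, decimals))
    adj: dict = {}
    for si, (a, b) in enumerate(segs):
        ka, kb = key(a), key(b)
        if ka == kb:
            continue
        adj.setdefault(ka, []).append((si, kb))
        adj.setdefault(kb, []).append((si, ka))
    if not adj:
        raise ValueError("degenerate plane intersection")
    ends = [k for k, v in adj.items() if len(v) == 1]
    starts = ends if ends else [next(iter(adj))]
    best: list = []
    for start in starts:
        seen_seg = set()
        path = [start]
        node = start
        while True:
            nxt = [(si, kb) for si, kb in adj[node] if si not in seen_seg]
            if not nxt:
                break
            si, kb = nxt[0]
            seen_seg.add(si)
            path.append(kb)
            node = kb
        if len(path) > len(best):
            best = path
    return np.array(best, dtype=np.float64)


def _longest_true_run(points: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Longest contiguous kept stretch of an ordered polyline."""
    best = (0, 0)
    start = None
    for i, k in enumerate(list(keep) + [False]):
        if k and start is None:
            start = i
        elif not k and start is not None:
            if i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    return points[best[0] : best[1]]


def folding_angle(surface_curve: np.ndarray, arm_length: float = 10.0) -> float:
    """Folding angle (degrees) at the crease of a 2D surface profile:
    180° = flat, smaller = deeper fold.  Returns NaN with no usable crease
    geometry (profile too short for the flank fit)."""
    return fit_folding_angle(surface_curve, arm_length=arm_length)


def organ_area_topview(outline: np.ndarray) -> float:
    """Planimetric top-view area (μm²) enclosed by a 2D outline (shoelace)."""
    return polygon_area(outline)


def auto_organ_outline(
    mesh: SurfaceMesh,
    organ_tip_xy: np.ndarray,
    apex_xy: np.ndarray,
    k_threshold: float = -1.0e-3,
) -> tuple[np.ndarray, float]:
    """Automatic organ footprint: flood the curvature mesh from the organ tip
    and stop at the boundary crease (the ring of Gaussian curvature below
    ``k_threshold``), then measure the planimetric (top-view) area of the
    flooded cap.  Returns (outline points in x-y μm, area μm²).

    Requires a ``gaussian_curvature`` attribute; raises if the flood leaks
    to the meristem apex (no closed crease ring around the tip).
    """
    if "gaussian_curvature" not in mesh.attributes:
        raise ValueError("mesh needs a gaussian_curvature attribute")
    v = mesh.vertices
    K = mesh.attributes["gaussian_curvature"]
    blocked = ~np.isfinite(K) | (K < k_threshold)

    # seed: highest vertex near the tip's top-view position
    d_xy = np.hypot(v[:, 0] - organ_tip_xy[0], v[:, 1] - organ_tip_xy[1])
    near = np.flatnonzero(d_xy < 5.0)
    if near.size == 0:
        raise ValueError("no mesh vertices near the organ tip")
    seed = int(near[np.argmax(v[near, 2])])
    apex_d = np.hypot(v[:, 0] - apex_xy[0], v[:, 1] - apex_xy[1])
    apex_vertex = int(np.argmin(apex_d))

    # BFS over mesh edges, not entering crease-negative vertices
    adj: dict[int, list[int]] = {}
    for a, b, c in mesh.faces:
        adj.setdefault(int(a), []).extend((int(b), int(c)))
        adj.setdefault(int(b), []).extend((int(a), int(c)))
        adj.setdefault(int(c), []).extend((int(a), int(b)))
    from collections import deque

    seen = np.zeros(mesh.n_vertices, dtype=bool)
    seen[seed] = True
    queue = deque([seed])
    while queue:
        u = queue.popleft()
        for w in adj.get(u, ()):
            if not seen[w] and not blocked[w]:
                seen[w] = True
                queue.append(w)
    if seen[apex_vertex]:
        raise ValueError("organ flood reached the apex: no closed crease ring")

    inside = seen
    faces_in = inside[mesh.faces].all(axis=1)
    tri = v[mesh.faces[faces_in]]
    # planimetric area: |z component| of each face's cross product / 2
    cz = np.abs(
        (tri[:, 1, 0] - tri[:, 0, 0]) * (tri[:, 2, 1] - tri[:, 0, 1])
        - (tri[:, 1, 1] - tri[:, 0, 1]) * (tri[:, 2, 0] - tri[:, 0, 0])
    )
    area = float(cz.sum() / 2.0)
    # outline: region-boundary vertices (inside with an outside neighbour)
    border = [
        i for i in np.flatnonzero(inside) if any(not inside[w] for w in adj.get(int(i), ()))
    ]
    outline = v[border][:, :2]
    return outline, area


def band_mask(
    section: SectionImage,
    surface_curve: np.ndarray | None,
    band_depth: float = 15.0,
) -> np.ndarray:
    """Boolean mask of section pixels within ``band_depth`` μm of the surface
    curve (everything when no curve is given)."""
    img = next(iter(section.images.values()))
    if surface_curve is None or len(surface_curve) < 2:
        return np.ones_like(img, dtype=bool)
    return _curve_band(section, img.shape, np.asarray(surface_curve, float), band_depth)


def expression_area(
    section: SectionImage,
    channel: str,
    threshold: float | str = "auto",
    surface_curve: np.ndarray | None = None,
    band_depth: float = 15.0,
    presmooth_sigma: float = 0.0,
) -> float:
    """Area (μm²) of the largest connected patch of above-threshold signal on
    a section, restricted to a band within ``band_depth`` of the surface
    curve when one is provided.

    ``presmooth_sigma`` (μm) optionally smooths the section first so that
    punctate nuclear signal merges into the contiguous expression domain the
    area is meant to capture.  Auto threshold is Otsu restricted to the band.
    Returns 0 when nothing is above threshold."""
    img = section.channel(channel)
    if presmooth_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=presmooth_sigma / section.pixel_size, mode="nearest")
    if surface_curve is not None and len(surface_curve) >= 2:
        band = _curve_band(section, img.shape, np.asarray(surface_curve, float), band_depth)
    else:
        band = np.ones_like(img, dtype=bool)

    vals = img[band]
    if vals.size == 0 or vals.max() <= 0:
        return 0.0
    if threshold == "auto":
        if np.ptp(vals) <= 0:
            return 0.0
        thr = float(threshold_otsu(vals))
    else:
        thr = float(threshold)
    mask = (img >= thr) & band
    if not mask.any():
        return 0.0
    lab, n = ndimage.label(mask)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return float(sizes.max()) * section.pixel_size**2


def _curve_band(section: SectionImage, shape, curve: np.ndarray, band_depth: float) -> np.ndarray:
    """Pixels within ``band_depth`` of a densified polyline (brute force)."""
    seg = np.diff(curve, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    npts = np.maximum(1, np.ceil(lens / section.pixel_size).astype(int))
    dense = [curve[:1]]
    for i, m in enumerate(npts):
        ts = np.linspace(0, 1, m + 1)[1:, None]
        dense.append(curve[i] + ts * seg[i])
    curve = np.concatenate(dense, axis=0)
    nrow, ncol = shape
    uu = section.u0 + np.arange(ncol) * section.pixel_size
    vv = section.v0 + np.arange(nrow) * section.pixel_size
    pix_uv = np.stack(np.meshgrid(uu, vv), axis=-1).reshape(-1, 2)
    d2 = np.full(len(pix_uv), np.inf)
    for start in range(0, len(curve), 512):
        blk = curve[start : start + 512]
        d2 = np.minimum(d2, ((pix_uv[:, None, :] - blk[None, :, :]) ** 2).sum(axis=2).min(axis=1))
    return (d2 <= band_depth**2).reshape(nrow, ncol)
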