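"""Reading and writing the pipeline's formats: TIFF stacks, PLY meshes with
scalar vertex properties, CSV tables with a units row, JSON configs."""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import trimesh

from .curvature import SurfaceMesh
from .stack import VoxelStack

__all__ = ["read_stack", "write_stack", "write_mesh_ply", "read_mesh_ply", "write_table", "read_table"]


def read_stack(
    path: str | Path,
    spacing_override: tuple[float, float, float] | None = None,
    channel_names: list[str] | None = None,
) -> VoxelStack:
    """Read a (multi-channel) TIFF stack into a :class:`VoxelStack`.

    Axis order is normalised to (z, y, x) per channel; 2D images become
    single-slice stacks.  Spacing (z, y, x in μm) comes from ImageJ-style
    metadata when present; ``spacing_override`` always wins (and is recorded
    in ``meta``); with neither, an error is raised.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            meta = tf.imagej_metadata or {}
            axes = tf.series[0].axes if tf.series else ""
            # pixel size from resolution tags (pixels per unit)
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
    except tifffile.TiffFileError as exc:
        raise ValueError(f"{path} is not a readable TIFF: {exc}") from None

    meta_spacing = None
    z = meta.get("spacing")
    if z and xres and yres:
        sx = xres.value[1] / xres.value[0]
        sy = yres.value[1] / yres.value[0]
        meta_spacing = (float(z), float(sy), float(sx))
    spacing = spacing_override or meta_spacing
    if spacing is None:
        raise ValueError(
            f"{path} carries no voxel spacing metadata; pass spacing_override=(z, y, x) μm"
        )

    # normalise to (C, Z, Y, X)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        if "C" in axes and "Z" not in axes:
            ax_c = axes.index("C")
            arr = np.moveaxis(arr, ax_c, 0)[:, None]
        else:
            arr = arr[None]  # single channel z-stack
    elif arr.ndim == 4:
        if "C" in axes and "Z" in axes and len(axes) == 4:
            order = [axes.index(a) for a in "CZYX"]
            arr = np.transpose(arr, order)
        # otherwise assume (C, Z, Y, X) already
    else:
        raise ValueError(f"unsupported TIFF dimensionality {arr.shape}")

    names = channel_names or [f"channel{i}" for i in range(arr.shape[0])]
    if len(names) != arr.shape[0]:
        raise ValueError(f"{len(names)} channel names for {arr.shape[0]} channels")
    channels = {name: arr[i].astype(np.float64) for i, name in enumerate(names)}
    m = {"path": str(path)}
    if spacing_override and meta_spacing and tuple(spacing_override) != meta_spacing:
        m["spacing_override"] = True
        m["metadata_spacing"] = meta_spacing
    return VoxelStack(channels=channels, spacing=tuple(spacing), meta=m)


def write_stack(stack: VoxelStack, path: str | Path) -> Path:
    """Write a stack as an ImageJ-style multi-channel TIFF (CZYX)."""
    path = Path(path)
    arr = np.stack([stack.channels[n] for n in stack.channel_names]).astype(np.float32)
    sz, sy, sx = stack.spacing
    tifffile.imwrite(
        path,
        np.moveaxis(arr, 0, 1),  # -> (Z, C, Y, X), ImageJ hyperstack order
        imagej=True,
        resolution=(1.0 / sx, 1.0 / sy),
        metadata={"spacing": sz, "unit": "um", "axes": "ZCYX"},
    )
    return path


def write_mesh_ply(mesh: SurfaceMesh, path: str | Path) -> Path:
    """ASCII PLY with per-vertex scalar properties (one per attribute, plus
    the extremity flag)."""
    path = Path(path)
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    for name, vals in mesh.attributes.items():
        tm.vertex_attributes[name] = np.asarray(vals, dtype=np.float64)
    tm.vertex_attributes["extremity"] = mesh.boundary_vertex_flags.astype(np.uint8)
    data = trimesh.exchange.ply.export_ply(tm, encoding="ascii", include_attributes=True)
    path.write_bytes(data)
    return path


def read_mesh_ply(path: str | Path) -> SurfaceMesh:
    """Read back a PLY written by :func:`write_mesh_ply`, restoring scalar
    vertex attributes."""
    loaded = trimesh.load(str(path), file_type="ply", process=False)
    raw = loaded.metadata.get("_ply_raw", {}).get("vertex", {})
    data = raw.get("data")
    attrs = {}
    flags = None
    if data is not None:
        for name in raw.get("properties", {}):
            if name in ("x", "y", "z"):
                continue
            col = np.asarray(data[name]).ravel()
            if name == "extremity":
                flags = col.astype(bool)
            else:
                attrs[name] = col.astype(np.float64)
    tm = loaded
    mesh = SurfaceMesh(
        vertices=np.asarray(tm.vertices),
        faces=np.asarray(tm.faces),
        vertex_normals=np.asarray(tm.vertex_normals),
        attributes=attrs,
    )
    if flags is not None:
        mesh.boundary_vertex_flags = flags
    return mesh


def write_table(df: pd.DataFrame, path: str | Path, units: dict[str, str] | None = None) -> Path:
    """CSV with a units row right under the header ('.' decimal, ',' sep)."""
    path = Path(path)
    units = units or {}
    unit_row = ",".join(str(units.get(c, "")) for c in df.columns)
    buf = _io.StringIO()
    df.to_csv(buf, index=False, lineterminator="\n", float_format="%.10g")
    lines = buf.getvalue().split("\n")
    lines.insert(1, unit_row)
    path.write_text("\n".join(lines))
    return path


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a units-row CSV back into (frame, units)."""
    path = Path(path)
    head = pd.read_csv(path, nrows=0)
    units_line = path.read_text().split("\n")[1]
    units = dict(zip(head.columns, units_line.split(",")))
    df = pd.read_csv(path, skiprows=[1])
    return df, units


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")
    return path


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")
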