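"""Voxel stack container.

Conventions used throughout the package:

* image arrays are indexed ``[z, y, x]``; ``spacing`` is the matching
  ``(z, y, x)`` tuple in micrometres;
* world coordinates are ``(x, y, z)`` vectors in micrometres, with the voxel
  at index ``(k, j, i)`` centred at ``((i + 0.5) sx, (j + 0.5) sy, (k + 0.5) sz)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelStack"]


@dataclass
class VoxelStack:
    """Multi-channel 3D intensity grid with physical voxel spacing.

    Parameters
    ----------
    channels
    	Mapping from channel name to a 3D ``float`` array of shape
    	``(nz, ny, nx)``; all channels share one grid.
    spacing
        Voxel spacing ``(z, y, x)`` in micrometres.
    """

    channels: dict[str, np.ndarray]
    spacing: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        shapes = {name: np.asarray(a).shape for name, a in self.channels.items()}
        if not shapes:
            raise ValueError("stack needs at least one channel")
        first = next(iter(shapes.values()))
        if any(len(s) != 3 or s != first for s in shapes.values()):
            raise ValueError(f"all channels must share one 3D shape, got {shapes}")
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=np.float64)
            if not np.isfinite(arr).all():
                raise ValueError(f"channel {name!r} contains non-finite values")
            if (arr < 0).any():
                raise ValueError(f"channel {name!r} contains negative intensities")
            self.channels[name] = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"no channel {name!r}; have {self.channel_names}")
        return self.channels[name]

    # ---- coordinate transforms -------------------------------------------------

    def index_to_world(self, idx_zyx: np.ndarray) -> np.ndarray:
        """Voxel indices ``(k, j, i)`` (may be fractional) -> world ``(x, y, z)`` μm."""
        idx = np.atleast_2d(np.asarray(idx_zyx, dtype=np.float64))
        sz, sy, sx = self.spacing
        out = np.empty_like(idx)
        out[:, 0] = (idx[:, 2] + 0.5) * sx
        out[:, 1] = (idx[:, 1] + 0.5) * sy
        out[:, 2] = (idx[:, 0] + 0.5) * sz
        return out

    def world_to_index(self, pts_xyz: np.ndarray) -> np.ndarray:
        """World ``(x, y, z)`` μm -> fractional voxel indices ``(k, j, i)``."""
        pts = np.atleast_2d(np.asarray(pts_xyz, dtype=np.float64))
        sz, sy, sx = self.spacing
        out = np.empty_like(pts)
        out[:, 0] = pts[:, 2] / sz - 0.5
        out[:, 1] = pts[:, 1] / sy - 0.5
        out[:, 2] = pts[:, 0] / sx - 0.5
        return out

    def extent(self) -> np.ndarray:
        """Physical size ``(x, y, z)`` of the grid in μm."""
        nz, ny, nx = self.shape
        sz, sy, sx = self.spacing
        return np.array([nx * sx, ny * sy, nz * sz])
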