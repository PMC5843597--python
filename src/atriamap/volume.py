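"""Voxel-grid containers shared by every pipeline stage.

Conventions (fixed across the package):

* array axis order is ``(x, y, z)`` with ``z`` the slice axis; the atrial
  roof sits at low ``z`` and the base (mitral annulus) at high ``z``;
* voxel indices are 0-based; the centre of voxel ``(i, j, k)`` lies at
  ``origin + (i + 1/2, j + 1/2, k + 1/2) * spacing`` in world millimetres
  (half-voxel offset, so analytic surfaces generically fall between voxel
  centres);
* all physical quantities are millimetres / HU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CTVolume", "world_coords", "voxel_centres"]


def _as_triplet(v) -> tuple[float, float, float]:
    a = np.asarray(v, dtype=float).reshape(-1)
    if a.size == 1:
        a = np.repeat(a, 3)
    if a.size != 3:
        raise ValueError(f"expected scalar or length-3 spacing/origin, got {v!r}")
    return (float(a[0]), float(a[1]), float(a[2]))


@dataclass
class CTVolume:
    """A 3D HU-valued scalar grid with anisotropic physical spacing.

    This is the image space *v*: either a loaded cardiac CT scan or a
    simulated acquisition of a digital phantom.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("CTVolume.data must be 3-dimensional (x, y, z)")
        self.spacing = _as_triplet(self.spacing)
        self.origin = _as_triplet(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on all axes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world(self, index) -> np.ndarray:
        """World-mm coordinates of voxel centre(s) for (…, 3) index arrays."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + (idx + 0.5) * np.asarray(self.spacing)

    def index_of(self, point_mm) -> np.ndarray:
        """Nearest voxel index of world-mm point(s)."""
        p = np.asarray(point_mm, dtype=float)
        idx = np.rint((p - np.asarray(self.origin)) / np.asarray(self.spacing) - 0.5)
        return idx.astype(int)


def voxel_centres(shape, spacing, origin):
    """Open-mesh arrays of voxel-centre world coordinates per axis."""
    spacing = _as_triplet(spacing)
    origin = _as_triplet(origin)
    axes = [origin[a] + (np.arange(shape[a]) + 0.5) * spacing[a] for a in range(3)]
    return np.ix_(axes[0], axes[1], axes[2])


def world_coords(indices, spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """World-mm centres of an (N, 3) integer index array."""
    spacing = _as_triplet(spacing)
    origin = _as_triplet(origin)
    return np.asarray(origin) + (np.asarray(indices, dtype=float) + 0.5) * np.asarray(spacing)
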