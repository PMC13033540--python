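"""Voxel-grid containers shared across the pipeline.

Conventions
-----------
* Volume arrays are indexed ``(i, j, k)`` along the physical axes
  ``(x, y, z)``; spacing is per-axis in mm and may be anisotropic.
* Voxel *centers* sit at ``origin + (index + 0.5) * spacing``; all
  physical coordinates are in mm.
* Anatomical planes map to constant-index slices: sagittal = axis 0,
  dorsal = axis 1, transverse = axis 2.  The in-plane axes of a slice
  are the two remaining axes in ascending order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "SpectralVolume",
    "BMDMap",
    "GridMismatchError",
    "PLANE_AXIS",
]

#: plane name -> axis held constant when slicing
PLANE_AXIS = {"sagittal": 0, "dorsal": 1, "transverse": 2}


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


def _as_spacing(spacing_mm) -> tuple[float, float, float]:
    sp = tuple(float(s) for s in spacing_mm)
    if len(sp) != 3 or any(s <= 0 for s in sp):
        raise ValueError(f"spacing_mm must be 3 strictly positive values, got {spacing_mm!r}")
    return sp


@dataclass
class SpectralVolume:
    """A 3D HU grid tagged with its virtual-monoenergetic energy.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Attenuation in Hounsfield units.
    energy_kev : float
        Virtual-monoenergetic reconstruction energy in keV.  The BMD
        pipeline consumes co-registered (50, 200) keV pairs.
    spacing_mm : tuple of 3 floats
        Voxel size per axis, mm.
    origin_mm : tuple of 3 floats
        Physical coordinate of the corner of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    energy_kev: float
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels must be finite HU values")
        self.spacing_mm = _as_spacing(self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        self.energy_kev = float(self.energy_kev)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def grid(self) -> tuple:
        """Hashable grid descriptor (shape, spacing, origin)."""
        return (self.voxels.shape, self.spacing_mm, self.origin_mm)

    def same_grid(self, other: "SpectralVolume | BMDMap") -> bool:
        return self.grid() == other.grid()

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class BMDMap:
    """Voxel grid of bone mineral density (mgHA/cm^3).

    Shares its grid with the spectral pair it was decomposed from;
    ``provenance`` records the calibration model and clamp policy so
    maps remain comparable across runs.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        self.spacing_mm = _as_spacing(self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def grid(self) -> tuple:
        return (self.voxels.shape, self.spacing_mm, self.origin_mm)

    def same_grid(self, other: "SpectralVolume | BMDMap") -> bool:
        return self.grid() == other.grid()

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


def require_same_grid(a: SpectralVolume | BMDMap, b: SpectralVolume | BMDMap) -> None:
    if not a.same_grid(b):
        raise GridMismatchError(
            f"volumes are not co-registered: {a.grid()} vs {b.grid()}"
        )


def pixel_centers_mm(
    shape: tuple[int, int, int],
    spacing_mm: tuple[float, float, float],
    origin_mm: tuple[float, float, float],
    plane: str,
) -> tuple[tuple[int, int], np.ndarray, np.ndarray]:
    """In-plane pixel-center coordinate vectors for a named plane.

    Returns ``(in_plane_axes, centers_u, centers_v)`` where the u/v axes
    are the two retained volume axes in ascending order.
    """
    try:
        axis = PLANE_AXIS[plane]
    except KeyError:
        raise ValueError(f"unknown plane {plane!r}; expected one of {sorted(PLANE_AXIS)}")
    in_plane = tuple(a for a in range(3) if a != axis)
    centers = []
    for a in in_plane:
        centers.append(origin_mm[a] + (np.arange(shape[a]) + 0.5) * spacing_mm[a])
    return in_plane, centers[0], centers[1]
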