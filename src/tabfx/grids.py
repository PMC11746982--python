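"""Voxel grids and typed volumes.

World coordinate convention (fixed across the whole package):

* ``x`` — patient left (axis 0)
* ``y`` — patient posterior, i.e. the table side is ``+y`` ("below" a supine
  patient) (axis 1)
* ``z`` — axial, along the long axis of the table (axis 2)

Voxel indexing is 0-based and voxel *centers* sit at
``origin_mm + index * spacing_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GridSpec",
    "VoxelVolume",
    "CTVolume",
    "ActivityVolume",
    "MuMap",
    "HU_AIR",
    "HU_MIN",
    "HU_MAX",
]

HU_AIR = -1000.0
HU_MIN = -1024.0
HU_MAX = 3071.0


@dataclass(frozen=True)
class GridSpec:
    """Regular 3-D voxel grid: shape, spacing and world origin.

    ``origin_mm`` is the world position of the center of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing_mm)
        origin = tuple(float(o) for o in self.origin_mm)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("GridSpec fields must be length-3 triples")
        if any(n < 8 for n in shape):
            raise ValueError(f"all grid dimensions must be >= 8, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacings must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", origin)

    @classmethod
    def centered(
        cls,
        shape: tuple[int, int, int],
        spacing_mm: tuple[float, float, float],
        center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "GridSpec":
        """Grid whose field of view is centered on ``center_mm``."""
        origin = tuple(
            c - (n - 1) / 2.0 * s for n, s, c in zip(shape, spacing_mm, center_mm)
        )
        return cls(tuple(shape), tuple(spacing_mm), origin)

    def coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along ``axis``."""
        n = self.shape[axis]
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(n)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Open (broadcastable) world-coordinate grids ``(X, Y, Z)``."""
        x = self.coords(0)[:, None, None]
        y = self.coords(1)[None, :, None]
        z = self.coords(2)[None, None, :]
        return x, y, z

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world points (..., 3) to fractional voxel indices."""
        pts = np.asarray(points_mm, dtype=float)
        return (pts - np.array(self.origin_mm)) / np.array(self.spacing_mm)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices, dtype=float)
        return np.array(self.origin_mm) + idx * np.array(self.spacing_mm)

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    @property
    def center_mm(self) -> tuple[float, float, float]:
        return tuple(
            o + (n - 1) / 2.0 * s
            for o, n, s in zip(self.origin_mm, self.shape, self.spacing_mm)
        )

    def extent_mm(self, axis: int) -> tuple[float, float]:
        """World extent of the grid along ``axis`` including voxel half-widths."""
        lo = self.origin_mm[axis] - self.spacing_mm[axis] / 2.0
        hi = lo + self.shape[axis] * self.spacing_mm[axis]
        return lo, hi


@dataclass
class VoxelVolume:
    """A scalar field sampled on a :class:`GridSpec`."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        self._validate()

    def _validate(self) -> None:  # overridden by subclasses
        pass

    def copy(self) -> "VoxelVolume":
        return type(self)(self.grid, self.values.copy())

    def with_values(self, values: np.ndarray) -> "VoxelVolume":
        return type(self)(self.grid, values)


class CTVolume(VoxelVolume):
    """CT volume in Hounsfield units."""

    def _validate(self) -> None:
        vmin, vmax = float(self.values.min()), float(self.values.max())
        if vmin < HU_MIN or vmax > HU_MAX:
            raise ValueError(f"HU values [{vmin}, {vmax}] outside [{HU_MIN}, {HU_MAX}]")


class ActivityVolume(VoxelVolume):
    """Emission activity per voxel (arbitrary units); non-negative."""

    def _validate(self) -> None:
        if float(self.values.min()) < 0:
            raise ValueError("activity values must be >= 0")


class MuMap(VoxelVolume):
    """Linear attenuation coefficients in cm^-1 at the emission energy."""

    def _validate(self) -> None:
        if float(self.values.min()) < 0:
            raise ValueError("attenuation coefficients must be >= 0")
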