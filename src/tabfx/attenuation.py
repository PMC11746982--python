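"""CT (HU) to linear attenuation coefficient conversion and grid resampling.

A standard two-segment (bilinear) model is used at the Tc-99m emission
energy of 140 keV: below 0 HU the coefficient scales linearly from air
(mu = 0 at -1000 HU) to water (``mu_water_cm`` at 0 HU); above 0 HU a
reduced slope accounts for the smaller energy dependence of bone relative
to water.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import GridSpec, MuMap, CTVolume, VoxelVolume

__all__ = ["MuCalibration", "hu_to_mu", "resample_to_grid"]


@dataclass(frozen=True)
class MuCalibration:
    """Bilinear HU -> mu model. ``mu_water_cm`` at the emission energy."""

    mu_water_cm: float = 0.154  # cm^-1 at 140 keV
    bone_slope: float = 0.5

    def __post_init__(self) -> None:
        if self.mu_water_cm <= 0:
            raise ValueError("mu_water_cm must be > 0")
        if not 0 < self.bone_slope <= 1:
            raise ValueError("bone_slope must be in (0, 1]")


def hu_to_mu(ct: CTVolume, calib: MuCalibration = MuCalibration()) -> MuMap:
    """Convert HU to attenuation coefficients (cm^-1), clamped at zero."""
    hu = ct.values
    mu = np.where(
        hu <= 0,
        calib.mu_water_cm * (1.0 + hu / 1000.0),
        calib.mu_water_cm * (1.0 + calib.bone_slope * hu / 1000.0),
    )
    return MuMap(ct.grid, np.maximum(mu, 0.0))


def resample_to_grid(
    vol: VoxelVolume, target: GridSpec, fill_value: float | None = None
) -> VoxelVolume:
    """Trilinear resampling of ``vol`` onto ``target`` in world coordinates.

    Points outside the source extent take ``fill_value`` (default: -1000 for
    CT, 0 otherwise).  Source and target grids share the world frame.
    """
    if fill_value is None:
        fill_value = -1000.0 if isinstance(vol, CTVolume) else 0.0
    src = vol.grid
    coords = [
        (target.coords(ax) - src.origin_mm[ax]) / src.spacing_mm[ax] for ax in range(3)
    ]
    ix = coords[0][:, None, None]
    iy = coords[1][None, :, None]
    iz = coords[2][None, None, :]
    pts = np.broadcast_arrays(ix, iy, iz)
    sampled = ndimage.map_coordinates(
        vol.values.astype(float),
        np.stack([p.ravel() for p in pts]),
        order=1,
        mode="constant",
        cval=fill_value,
    ).reshape(target.shape)
    return type(vol)(target, sampled)
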