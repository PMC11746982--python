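"""AHA 17-segment polar maps and integer perfusion scores.

The left-ventricular volume is resampled into short-axis orientation (long
axis along ``+z``, apex at low ``z``), sampled along radial rays with
maximal-count sampling (the standard choice in perfusion quantification),
normalized to the polar-map maximum, and averaged over the 17 standard
segments (6 basal, 6 mid, 4 apical, 1 apex).  Angles are measured from
anterior (0 degrees) increasing toward the lateral wall, as viewed from
the apex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import ActivityVolume
from .synthetic import lv_frame

__all__ = [
    "PolarMapModel",
    "PolarMap",
    "SegmentScores",
    "LVGeometry",
    "reorient_short_axis",
    "polar_map",
    "score_segments",
    "segment_labels",
    "AHA_SEGMENT_NAMES",
]

AHA_SEGMENT_NAMES = {
    1: "basal anterior",
    2: "basal anteroseptal",
    3: "basal inferoseptal",
    4: "basal inferior",
    5: "basal inferolateral",
    6: "basal anterolateral",
    7: "mid anterior",
    8: "mid anteroseptal",
    9: "mid inferoseptal",
    10: "mid inferior",
    11: "mid inferolateral",
    12: "mid anterolateral",
    13: "apical anterior",
    14: "apical septal",
    15: "apical inferior",
    16: "apical lateral",
    17: "apex",
}

# Sector centers (deg from anterior, increasing toward lateral) per ring.
_RING6_CENTERS = {1: 0.0, 2: 300.0, 3: 240.0, 4: 180.0, 5: 120.0, 6: 60.0}
_RING4_CENTERS = {13: 0.0, 14: 270.0, 15: 180.0, 16: 90.0}


@dataclass(frozen=True)
class PolarMapModel:
    n_angles: int = 60  # radial samples per short-axis slice
    n_slices: int = 20  # short-axis slices apex -> base
    # fractional apex->base boundaries of the apex / apical / mid / basal zones
    zone_bounds: tuple[float, float, float] = (0.25, 0.5, 0.75)
    # sampled span of the long axis, excluding the extreme tip and base edge
    apex_margin: float = 0.05
    base_margin: float = 0.08

    def __post_init__(self) -> None:
        if self.n_angles < 8 or self.n_slices < 4:
            raise ValueError("polar map sampling too coarse")


@dataclass(frozen=True)
class LVGeometry:
    """Minimal LV geometry for polar sampling (short-axis frame)."""

    center_mm: tuple[float, float, float]
    radius_mm: float  # maximal expected outer radius of the myocardium
    long_axis_mm: float  # apex-to-base length


@dataclass
class PolarMap:
    samples: np.ndarray  # (n_slices, n_angles) maximal-count samples
    normalized: np.ndarray  # same, in % of the polar-map maximum
    segment_means: np.ndarray  # (17,) normalized means, index = AHA number - 1
    model: PolarMapModel


@dataclass
class SegmentScores:
    scores: np.ndarray  # (17,) integers 0..4
    thresholds_pct: tuple[float, ...] = (70.0, 50.0, 30.0, 10.0)


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Rotation taking the LV axis onto ``+z`` with anterior mapped to ``-y``.

    Built from the LV frame (e1 = projected anterior, e2 = axis x e1) so the
    angular convention of the polar map (0 degrees anterior, increasing
    toward lateral) is preserved exactly, without azimuthal twist.
    """
    w = np.asarray(axis, dtype=float)
    if np.linalg.norm(w) < 1e-12:
        raise ValueError("LV axis has zero length")
    e1, e2, wn = lv_frame(w)
    return np.stack([e2, -e1, wn])


def reorient_short_axis(
    recon: ActivityVolume, lv_axis: np.ndarray, lv_center_mm: np.ndarray
) -> ActivityVolume:
    """Resample so the LV long axis (apex->base) aligns with ``+z``.

    The rotation is about ``lv_center_mm``; the output grid equals the input
    grid, so the LV stays centered at the same world position with the apex
    at low ``z`` and the base at high ``z``.
    """
    rot = _rotation_to_z(lv_axis)
    grid = recon.grid
    x, y, z = grid.meshgrid()
    c = np.asarray(lv_center_mm, dtype=float)
    dx, dy, dz = x - c[0], y - c[1], z - c[2]
    # output point offset r samples input at c + R^T r
    rt = rot.T
    qx = c[0] + rt[0, 0] * dx + rt[0, 1] * dy + rt[0, 2] * dz
    qy = c[1] + rt[1, 0] * dx + rt[1, 1] * dy + rt[1, 2] * dz
    qz = c[2] + rt[2, 0] * dx + rt[2, 1] * dy + rt[2, 2] * dz
    coords = np.stack(
        [
            ((q - grid.origin_mm[ax]) / grid.spacing_mm[ax]).ravel()
            for ax, q in enumerate((qx, qy, qz))
        ]
    )
    vals = ndimage.map_coordinates(
        recon.values.astype(float), coords, order=1, mode="constant", cval=0.0
    ).reshape(grid.shape)
    return ActivityVolume(grid, np.maximum(vals, 0.0))


def _zone_of(slice_frac: np.ndarray, bounds: tuple[float, float, float]) -> np.ndarray:
    """0 = apex cap, 1 = apical, 2 = mid, 3 = basal."""
    return np.digitize(slice_frac, bounds)


def segment_labels(model: PolarMapModel) -> np.ndarray:
    """AHA segment number (1..17) for each (slice, angle) sample."""
    sl = (np.arange(model.n_slices) + 0.5) / model.n_slices
    zones = _zone_of(sl, model.zone_bounds)
    phi = np.arange(model.n_angles) * (360.0 / model.n_angles)
    # segments ordered by sector center angle (anterior -> lateral -> ...)
    ring6 = np.array([1, 6, 5, 4, 3, 2])
    ring4 = np.array([13, 16, 15, 14])
    sector6 = np.floor(((phi + 30.0) % 360.0) / 60.0).astype(int)
    sector4 = np.floor(((phi + 45.0) % 360.0) / 90.0).astype(int)
    labels = np.zeros((model.n_slices, model.n_angles), dtype=int)
    for i, zone in enumerate(zones):
        if zone == 0:
            labels[i, :] = 17
        elif zone == 1:
            labels[i, :] = ring4[sector4]
        elif zone == 2:
            labels[i, :] = ring6[sector6] + 6
        else:
            labels[i, :] = ring6[sector6]
    return labels


def polar_map(
    sa_volume: ActivityVolume,
    model: PolarMapModel,
    lv_geometry: LVGeometry,
) -> PolarMap:
    """Maximal-count polar sampling of a short-axis-aligned volume."""
    grid = sa_volume.grid
    cx, cy, cz = lv_geometry.center_mm
    apex_z = cz - lv_geometry.long_axis_mm
    span = 1.0 - model.apex_margin - model.base_margin
    slice_fracs = model.apex_margin + span * (np.arange(model.n_slices) + 0.5) / model.n_slices
    zs = apex_z + slice_fracs * lv_geometry.long_axis_mm
    phi = np.deg2rad(np.arange(model.n_angles) * (360.0 / model.n_angles))
    r_step = min(grid.spacing_mm[0], grid.spacing_mm[1]) / 2.0
    radii = np.arange(0.0, 1.3 * lv_geometry.radius_mm + r_step, r_step)
    # ray direction: phi=0 anterior (-y), increasing toward patient-left (+x)
    dirx = np.sin(phi)
    diry = -np.cos(phi)
    px = cx + radii[None, :, None] * dirx[:, None, None] * np.ones_like(zs)[None, None, :]
    py = cy + radii[None, :, None] * diry[:, None, None] * np.ones_like(zs)[None, None, :]
    pz = np.broadcast_to(zs[None, None, :], px.shape)
    coords = np.stack(
        [
            ((p - grid.origin_mm[ax]) / grid.spacing_mm[ax]).ravel()
            for ax, p in enumerate((px, py, pz))
        ]
    )
    vals = ndimage.map_coordinates(
        sa_volume.values.astype(float), coords, order=1, mode="constant", cval=0.0
    ).reshape(px.shape)
    samples = vals.max(axis=1).T  # (n_slices, n_angles)
    if not samples.any():
        warnings.warn("no counts found along any polar-map ray")
    peak = samples.max()
    normalized = 100.0 * samples / peak if peak > 0 else samples.copy()
    labels = segment_labels(model)
    seg_means = np.array(
        [normalized[labels == seg].mean() for seg in range(1, 18)]
    )
    return PolarMap(samples=samples, normalized=normalized, segment_means=seg_means, model=model)


def score_segments(
    pm: PolarMap, thresholds_pct: tuple[float, ...] = (70.0, 50.0, 30.0, 10.0)
) -> SegmentScores:
    """Map normalized segment means to integer perfusion scores 0-4.

    ``thresholds_pct`` is a strictly descending cut list: a mean at or above
    the first cut scores 0, at or above the second scores 1, and so on; a
    mean below the last cut takes the maximal score.
    """
    cuts = tuple(float(t) for t in thresholds_pct)
    if len(cuts) < 1 or any(b <= a for a, b in zip(cuts[1:], cuts[:-1])):
        raise ValueError("thresholds must be strictly descending")
    scores = np.array(
        [
            next((r for r, cut in enumerate(cuts) if m >= cut), len(cuts))
            for m in pm.segment_means
        ],
        dtype=int,
    )
    return SegmentScores(scores=scores, thresholds_pct=cuts)
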