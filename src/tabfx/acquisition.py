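"""SPECT acquisition simulation: protocols, projections, noise and scatter.

Two acquisition protocols are modeled:

* quality control (``qc``): 64 projections over a 360 degree circular orbit;
* myocardial perfusion (``mpi``): 34 projections over a 204 degree orbit
  placed symmetric about the anterior axis (-102 to +102 degrees), so that
  most views avoid looking through the table.

Counts are accumulated in a 129-150 keV photopeak window; a 108-129 keV
lower window feeds the energy-window scatter correction (triple-energy-window
form with the upper-window term zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import ActivityVolume, GridSpec, MuMap
from .projector import ParallelProjector

__all__ = [
    "EnergyWindows",
    "AcquisitionProtocol",
    "ProjectionSet",
    "NoiseModel",
    "QC_PROTOCOL",
    "MPI_PROTOCOL",
    "forward_project",
    "add_noise_and_scatter",
    "scatter_correct",
    "count_reduction_profile",
]


@dataclass(frozen=True)
class EnergyWindows:
    peak_lo_keV: float = 129.0
    peak_hi_keV: float = 150.0
    scat_lo_keV: float = 108.0
    scat_hi_keV: float = 129.0

    def __post_init__(self) -> None:
        if self.peak_hi_keV <= self.peak_lo_keV or self.scat_hi_keV <= self.scat_lo_keV:
            raise ValueError("energy windows must have positive width")
        if abs(self.scat_hi_keV - self.peak_lo_keV) > 1e-9:
            raise ValueError("scatter and photopeak windows must be contiguous")

    @property
    def peak_width(self) -> float:
        return self.peak_hi_keV - self.peak_lo_keV

    @property
    def scatter_width(self) -> float:
        return self.scat_hi_keV - self.scat_lo_keV


@dataclass(frozen=True)
class AcquisitionProtocol:
    """View sampling of a circular orbit.

    For a full 360 degree orbit the view angles are ``start + arc*k/n``
    (end point excluded); partial arcs include both end points.
    """

    n_projections: int
    arc_deg: float
    start_angle_deg: float
    orbit_radius_mm: float = 250.0
    label: str = "qc"

    def __post_init__(self) -> None:
        if self.n_projections < 2:
            raise ValueError("n_projections must be >= 2")
        if self.orbit_radius_mm <= 0:
            raise ValueError("orbit_radius_mm must be > 0")

    @property
    def angles_deg(self) -> np.ndarray:
        if abs(self.arc_deg) >= 360.0 - 1e-9:
            return self.start_angle_deg + np.arange(self.n_projections) * (
                self.arc_deg / self.n_projections
            )
        return np.linspace(
            self.start_angle_deg, self.start_angle_deg + self.arc_deg, self.n_projections
        )


QC_PROTOCOL = AcquisitionProtocol(64, 360.0, 0.0, label="qc")
MPI_PROTOCOL = AcquisitionProtocol(34, 204.0, -102.0, label="mpi")


@dataclass
class ProjectionSet:
    """Per-view photopeak and lower-window projections plus geometry."""

    peak: np.ndarray  # (n_views, nu, nz)
    scatter_window: np.ndarray  # same shape
    angles_deg: np.ndarray
    detector_spacing_mm: tuple[float, float]
    protocol: AcquisitionProtocol
    grid: GridSpec  # image grid the projections were/will be modeled on

    def __post_init__(self) -> None:
        if self.peak.shape != self.scatter_window.shape:
            raise ValueError("peak and scatter_window shapes differ")
        if self.peak.shape[0] != len(self.angles_deg):
            raise ValueError("angle count does not match number of projections")
        if self.peak.min() < 0 or self.scatter_window.min() < 0:
            raise ValueError("projection counts must be >= 0")

    def copy(self) -> "ProjectionSet":
        return ProjectionSet(
            self.peak.copy(),
            self.scatter_window.copy(),
            self.angles_deg.copy(),
            self.detector_spacing_mm,
            self.protocol,
            self.grid,
        )

    @property
    def total_counts(self) -> float:
        return float(self.peak.sum())


@dataclass(frozen=True)
class NoiseModel:
    """Poisson count statistics and a simple broad-scatter emulation."""

    enabled: bool = True
    total_expected_counts: float = 5e6
    seed: int = 0
    scatter_fraction: float = 0.3  # lower-window total / primary total
    scatter_blur_mm: float = 40.0
    in_window_fraction: float = 0.5  # share of the scatter shape added to the peak

    def __post_init__(self) -> None:
        if self.enabled and self.total_expected_counts <= 0:
            raise ValueError("total_expected_counts must be > 0")
        if not 0 <= self.scatter_fraction < 1:
            raise ValueError("scatter_fraction must be in [0, 1)")
        if self.scatter_blur_mm <= 0:
            raise ValueError("scatter_blur_mm must be > 0")


def forward_project(
    activity: ActivityVolume,
    mu: MuMap | None,
    protocol: AcquisitionProtocol,
    projector: ParallelProjector | None = None,
) -> ProjectionSet:
    """Noiseless attenuated parallel-beam projections (photopeak only)."""
    if mu is not None and mu.grid != activity.grid:
        raise ValueError("activity and mu-map must share one grid")
    grid = activity.grid
    proj = projector or ParallelProjector(grid, protocol.angles_deg)
    weights = proj.attenuation_weights(None if mu is None else mu.values)
    peak = proj.forward(activity.values.astype(float), weights)
    return ProjectionSet(
        peak=peak,
        scatter_window=np.zeros_like(peak),
        angles_deg=proj.angles_deg.copy(),
        detector_spacing_mm=(grid.spacing_mm[0], grid.spacing_mm[2]),
        protocol=protocol,
        grid=grid,
    )


def add_noise_and_scatter(noiseless: ProjectionSet, model: NoiseModel) -> ProjectionSet:
    """Scale to the expected count level, add scatter, Poisson-sample.

    The noiseless primary is scaled so primary + lower-window totals equal
    ``total_expected_counts`` with lower-window/primary = ``scatter_fraction``.
    The lower-window shape is a transaxial Gaussian blur of the primary; a
    configurable fraction of that shape also contaminates the photopeak.
    """
    if not model.enabled:
        out = noiseless.copy()
        out.scatter_window[:] = 0.0
        return out
    total = float(noiseless.peak.sum())
    if total <= 0:
        raise ValueError("cannot scale zero-count projections to a target count level")
    sf = model.scatter_fraction
    primary_total = model.total_expected_counts / (1.0 + sf)
    primary = noiseless.peak * (primary_total / total)
    sigma_px = (
        model.scatter_blur_mm / noiseless.detector_spacing_mm[0],
        model.scatter_blur_mm / noiseless.detector_spacing_mm[1],
    )
    blurred = ndimage.gaussian_filter(primary, sigma=(0.0, *sigma_px))
    bsum = blurred.sum()
    scatter = blurred * (sf * primary_total / bsum) if bsum > 0 else blurred
    peak_expect = primary + model.in_window_fraction * scatter
    rng = np.random.default_rng(model.seed)
    return ProjectionSet(
        peak=rng.poisson(peak_expect).astype(float),
        scatter_window=rng.poisson(scatter).astype(float),
        angles_deg=noiseless.angles_deg.copy(),
        detector_spacing_mm=noiseless.detector_spacing_mm,
        protocol=noiseless.protocol,
        grid=noiseless.grid,
    )


def scatter_correct(
    projs: ProjectionSet, windows: EnergyWindows = EnergyWindows()
) -> ProjectionSet:
    """Energy-window scatter correction (TEW with zero upper-window term).

    Per pixel the scatter estimate is ``S = (C_low / W_low) * W_peak / 2``;
    the corrected photopeak is ``max(0, C_peak - S)`` and the lower window
    is zeroed in the output.
    """
    s = (projs.scatter_window / windows.scatter_width) * windows.peak_width / 2.0
    corrected = np.maximum(projs.peak - s, 0.0)
    out = projs.copy()
    out.peak = corrected
    out.scatter_window = np.zeros_like(corrected)
    return out


def count_reduction_profile(
    activity: ActivityVolume,
    mu_with_table: MuMap,
    mu_without_table: MuMap,
    protocol: AcquisitionProtocol,
) -> np.ndarray:
    """Per-view fractional count loss caused by the table attenuation.

    Returns ``1 - counts_with[k] / counts_without[k]`` for each view of
    noiseless projections.
    """
    proj = ParallelProjector(activity.grid, protocol.angles_deg)
    with_tab = forward_project(activity, mu_with_table, protocol, projector=proj)
    without = forward_project(activity, mu_without_table, protocol, projector=proj)
    totals_wo = without.peak.sum(axis=(1, 2))
    if np.any(totals_wo <= 0):
        raise ValueError("zero counts in a table-free view: cannot form a ratio")
    totals_w = with_tab.peak.sum(axis=(1, 2))
    return 1.0 - totals_w / totals_wo
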