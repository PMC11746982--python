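"""Synthetic CT + activity studies: Jaszczak-type phantom and torso/LV cohort.

All generated objects rest *in* an arc-shaped carbon-fiber patient table
placed posterior (``+y``) of the object, mirroring the physical acquisition
setup this package studies.  Each generator returns a CT volume (HU), an
emission activity volume, and voxelized ground-truth masks so downstream
algorithms (table removal, reconstruction, polar maps) can be scored against
known geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .grids import HU_AIR, ActivityVolume, CTVolume, GridSpec, VoxelVolume

__all__ = [
    "TableModel",
    "PhantomSpec",
    "CardiacStudySpec",
    "DefectSpec",
    "CohortRanges",
    "GroundTruth",
    "generate_jaszczak",
    "generate_cardiac_study",
    "sample_cohort",
    "lv_frame",
    "table_arc_inner_radius_mm",
    "table_shell_cross_section_mm2",
]

# Angular position (deg) of each named LV wall, measured from anterior (0)
# increasing toward patient-left/lateral.  Matches the polar-map convention.
_WALL_ANGLE_DEG = {
    "anterior": 0.0,
    "lateral": 90.0,
    "inferior": 180.0,
    "septal": 270.0,
}


@dataclass(frozen=True)
class TableModel:
    """Parametric arc-shell patient table (a shallow cradle, concave anterior).

    The cross-section is a circular-arc annulus of ``thickness_mm`` whose
    inner surface has chord ``chord_width_mm`` and sagitta ``arc_sagitta_mm``.
    The deepest (most posterior) inner point sits ``gap_mm`` posterior of the
    supported object's lowest point.  The carbon-fiber sandwich (skins plus
    foam core) is modeled as a uniform HU value, well above the -700 HU
    removal threshold.  The defaults are calibrated so the table's effect is
    consistent with published measurements of clinical pallets: mean
    per-angle count loss inside the 2-12% band and a phantom reconstruction
    difference that stays below the published 17.5% maximum.  The table
    spans the full axial extent of the CT grid.
    """

    enabled: bool = True
    arc_sagitta_mm: float = 60.0
    chord_width_mm: float = 450.0
    thickness_mm: float = 12.0
    gap_mm: float = 10.0
    hu_value: float = -620.0

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError("table thickness_mm must be > 0")
        if self.arc_sagitta_mm <= 0 or self.chord_width_mm <= 0:
            raise ValueError("table arc dimensions must be > 0")
        if self.gap_mm < 0:
            raise ValueError("table gap_mm must be >= 0")
        if self.enabled and self.hu_value <= -700.0:
            raise ValueError(
                "table hu_value must exceed -700 HU (the removal threshold), "
                f"got {self.hu_value}"
            )


def table_arc_inner_radius_mm(table: TableModel) -> float:
    """Radius of the table's inner arc from its chord and sagitta."""
    c, s = table.chord_width_mm, table.arc_sagitta_mm
    return (c * c / 4.0 + s * s) / (2.0 * s)


def table_shell_cross_section_mm2(table: TableModel) -> float:
    """Analytic cross-sectional area of the arc shell (annular sector).

    The shell occupies the annulus ``R_i <= r <= R_i + t`` restricted to
    ``|x| <= chord/2`` on the posterior side.  For each ``x`` the radial
    band has height ``sqrt(Ro^2-x^2) - sqrt(Ri^2-x^2)``; integrate over x.
    """
    ri = table_arc_inner_radius_mm(table)
    ro = ri + table.thickness_mm
    half = table.chord_width_mm / 2.0

    def _seg(r: float) -> float:
        # integral of sqrt(r^2 - x^2) dx over [-half, half]
        h = min(half, r)
        return h * math.sqrt(r * r - h * h) + r * r * math.asin(h / r)

    return _seg(ro) - _seg(ri)


def _table_mask(
    grid: GridSpec, table: TableModel, object_lowest_y_mm: float
) -> np.ndarray:
    """Boolean table-shell mask on ``grid`` for an object whose most
    posterior point is at ``object_lowest_y_mm``."""
    if not table.enabled:
        return np.zeros(grid.shape, dtype=bool)
    ri = table_arc_inner_radius_mm(table)
    ro = ri + table.thickness_mm
    y_deepest_inner = object_lowest_y_mm + table.gap_mm
    y_arc_center = y_deepest_inner - ri  # anterior of the cradle
    x, y, _ = grid.meshgrid()
    r = np.hypot(x, y - y_arc_center)
    mask2d = (
        (r >= ri)
        & (r <= ro)
        & (y > y_arc_center)
        & (np.abs(x) <= table.chord_width_mm / 2.0)
    )
    return np.broadcast_to(mask2d, grid.shape).copy()


def _check_fits(grid: GridSpec, axis: int, lo: float, hi: float, what: str) -> None:
    glo, ghi = grid.extent_mm(axis)
    margin = 2 * grid.spacing_mm[axis]
    if lo < glo + margin or hi > ghi - margin:
        raise ValueError(
            f"{what} spans [{lo:.1f}, {hi:.1f}] mm along axis {axis} but the grid "
            f"covers [{glo:.1f}, {ghi:.1f}] mm (>= 2 voxel margin required)"
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Cylindrical (Jaszczak-type) quality-control phantom.

    Defaults follow the common flangeless model: 216 mm interior diameter,
    186 mm interior height, 9.5 mm acrylic shell.  Interior filled with
    water (0 HU) carrying a uniform activity concentration.
    """

    interior_diameter_mm: float = 216.0
    interior_height_mm: float = 186.0
    shell_thickness_mm: float = 9.5
    shell_hu: float = 120.0
    fill_hu: float = 0.0
    activity_concentration: float = 1.0

    def __post_init__(self) -> None:
        if min(self.interior_diameter_mm, self.interior_height_mm) <= 0:
            raise ValueError("phantom interior dimensions must be > 0")
        if self.shell_thickness_mm <= 0:
            raise ValueError("phantom shell thickness must be > 0")
        if self.activity_concentration <= 0:
            raise ValueError("activity_concentration must be > 0")


@dataclass(frozen=True)
class DefectSpec:
    """Regional perfusion defect: LV wall region with reduced uptake."""

    region: str = "inferior"
    residual_fraction: float = 0.4
    span_deg: float = 90.0
    length_fraction: float = 0.85  # fraction of apex->base length, from base

    def __post_init__(self) -> None:
        if self.region not in _WALL_ANGLE_DEG:
            raise ValueError(
                f"defect region must be one of {sorted(_WALL_ANGLE_DEG)}, "
                f"got {self.region!r}"
            )
        if not 0.0 <= self.residual_fraction <= 1.0:
            raise ValueError("defect residual_fraction must be in [0, 1]")


@dataclass(frozen=True)
class CardiacStudySpec:
    """Torso proxy with a half-ellipsoid-shell left ventricle.

    The torso is an elliptic cylinder of soft tissue; the LV shell sits in
    the anterior half ("the heart is close to the front of the body"), its
    long axis tilted apex-anterior-left-inferior.  ``lv_axis_tilt_deg`` is
    ``(azimuth, elevation)`` of the apex->base unit vector: elevation from
    ``+z``, azimuth in the x-y plane from ``+x`` toward ``+y``.
    """

    body_axes_mm: tuple[float, float] = (165.0, 115.0)
    body_hu: float = 0.0
    lv_center_mm: tuple[float, float, float] = (40.0, -50.0, 0.0)
    lv_outer_axes_mm: tuple[float, float, float] = (32.0, 32.0, 45.0)
    lv_inner_axes_mm: tuple[float, float, float] = (20.0, 20.0, 33.0)
    lv_axis_tilt_deg: tuple[float, float] = (140.0, 40.0)
    myocardium_activity: float = 100.0
    background_activity_fraction: float = 0.1
    defect: Optional[DefectSpec] = None
    protocol_label: str = "stress"

    def __post_init__(self) -> None:
        if not all(
            i < o for i, o in zip(self.lv_inner_axes_mm, self.lv_outer_axes_mm)
        ):
            raise ValueError("lv_inner_axes_mm must lie strictly inside lv_outer_axes_mm")
        if not 0.0 <= self.background_activity_fraction < 1.0:
            raise ValueError("background_activity_fraction must be in [0, 1)")
        if self.lv_center_mm[1] >= 0:
            raise ValueError("LV center must be anterior of the torso center (y < 0)")
        if self.protocol_label not in ("stress", "rest"):
            raise ValueError("protocol_label must be 'stress' or 'rest'")

    @property
    def lv_axis_unit(self) -> np.ndarray:
        az, el = np.deg2rad(self.lv_axis_tilt_deg)
        return np.array(
            [math.sin(el) * math.cos(az), math.sin(el) * math.sin(az), math.cos(el)]
        )


@dataclass
class GroundTruth:
    """Voxelized truth for scoring downstream algorithms.

    ``table_mask`` and ``body_mask`` live on the CT grid; ``lv_shell_mask``
    (cardiac studies) and ``interior_mask`` (phantom) live on the SPECT grid.
    """

    table_mask: VoxelVolume
    body_mask: VoxelVolume
    lv_shell_mask: Optional[VoxelVolume] = None
    defect_mask: Optional[VoxelVolume] = None
    interior_mask: Optional[VoxelVolume] = None
    lv_axis: Optional[np.ndarray] = None
    lv_center_mm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        overlap = self.table_mask.values & self.body_mask.values
        if overlap.any():
            raise ValueError("table_mask and body_mask overlap: object sits inside the table")


def generate_jaszczak(
    spec: PhantomSpec,
    table: TableModel,
    ct_grid: GridSpec,
    spect_grid: GridSpec,
) -> tuple[CTVolume, ActivityVolume, GroundTruth]:
    """Cylindrical phantom CT (HU) + uniform activity + ground truth.

    The phantom axis runs along ``z`` through the world origin; the table
    is posterior with its cradle ``gap_mm`` below the phantom shell.
    """
    r_in = spec.interior_diameter_mm / 2.0
    r_out = r_in + spec.shell_thickness_mm
    h_in = spec.interior_height_mm
    h_out = h_in + 2 * spec.shell_thickness_mm

    _check_fits(ct_grid, 0, -r_out, r_out, "phantom diameter")
    _check_fits(ct_grid, 1, -r_out, r_out, "phantom diameter")
    _check_fits(ct_grid, 2, -h_out / 2, h_out / 2, "phantom height")
    if table.enabled:
        half_c = table.chord_width_mm / 2.0
        _check_fits(ct_grid, 0, -half_c, half_c, "table chord")
        _check_fits(
            ct_grid, 1, -r_out, r_out + table.gap_mm + table.thickness_mm, "table depth"
        )

    def masks_on(grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
        x, y, z = grid.meshgrid()
        r2 = x * x + y * y
        interior = (r2 <= r_in * r_in) & (np.abs(z) <= h_in / 2.0)
        body = (r2 <= r_out * r_out) & (np.abs(z) <= h_out / 2.0)
        return (
            np.broadcast_to(interior, grid.shape).copy(),
            np.broadcast_to(body, grid.shape).copy(),
        )

    interior_ct, body_ct = masks_on(ct_grid)
    tmask = _table_mask(ct_grid, table, object_lowest_y_mm=r_out)

    hu = np.full(ct_grid.shape, HU_AIR)
    hu[tmask] = table.hu_value
    hu[body_ct] = spec.shell_hu
    hu[interior_ct] = spec.fill_hu
    ct = CTVolume(ct_grid, hu)

    interior_sp, _ = masks_on(spect_grid)
    act = np.zeros(spect_grid.shape)
    act[interior_sp] = spec.activity_concentration
    activity = ActivityVolume(spect_grid, act)

    truth = GroundTruth(
        table_mask=VoxelVolume(ct_grid, tmask),
        body_mask=VoxelVolume(ct_grid, body_ct),
        interior_mask=VoxelVolume(spect_grid, interior_sp),
    )
    return ct, activity, truth


def lv_frame(axis_unit: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal LV frame (e1 toward anterior, e2 = w x e1, w = apex->base)."""
    w = np.asarray(axis_unit, dtype=float)
    n = np.linalg.norm(w)
    if n == 0:
        raise ValueError("LV axis has zero length")
    w = w / n
    anterior = np.array([0.0, -1.0, 0.0])
    e1 = anterior - np.dot(anterior, w) * w
    if np.linalg.norm(e1) < 1e-9:  # axis parallel to y: fall back to +x reference
        e1 = np.array([1.0, 0.0, 0.0]) - np.dot([1.0, 0.0, 0.0], w) * w
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(w, e1)
    return e1, e2, w


def _lv_masks(
    grid: GridSpec, spec: CardiacStudySpec
) -> tuple[np.ndarray, np.ndarray]:
    """LV shell mask and defect-region mask on ``grid``."""
    e1, e2, w = lv_frame(spec.lv_axis_unit)
    cx, cy, cz = spec.lv_center_mm
    x, y, z = grid.meshgrid()
    dx, dy, dz = x - cx, y - cy, z - cz
    u1 = dx * e1[0] + dy * e1[1] + dz * e1[2]
    u2 = dx * e2[0] + dy * e2[1] + dz * e2[2]
    zeta = dx * w[0] + dy * w[1] + dz * w[2]  # 0 at base, -c at apex

    ao, bo, co = spec.lv_outer_axes_mm
    ai, bi, ci = spec.lv_inner_axes_mm
    outer = (u1 / ao) ** 2 + (u2 / bo) ** 2 + (zeta / co) ** 2 <= 1.0
    inner = (u1 / ai) ** 2 + (u2 / bi) ** 2 + (zeta / ci) ** 2 <= 1.0
    shell = outer & ~inner & (zeta <= 0.0)

    defect = np.zeros(grid.shape, dtype=bool)
    if spec.defect is not None:
        d = spec.defect
        phi = np.rad2deg(np.arctan2(u2, u1)) % 360.0
        center = _WALL_ANGLE_DEG[d.region]
        dphi = np.abs((phi - center + 180.0) % 360.0 - 180.0)
        longitudinal = zeta >= -d.length_fraction * co
        defect = shell & (dphi <= d.span_deg / 2.0) & longitudinal
    return shell, defect


def generate_cardiac_study(
    spec: CardiacStudySpec,
    table: TableModel,
    ct_grid: GridSpec,
    spect_grid: GridSpec,
    seed: int = 0,
) -> tuple[CTVolume, ActivityVolume, GroundTruth]:
    """Torso + LV study: CT (HU), activity with optional defect, truth masks.

    Generation is fully determined by ``spec``; ``seed`` is accepted for
    interface symmetry with stochastic generators and reserved for optional
    activity heterogeneity.
    """
    del seed  # geometry is deterministic given the spec
    ax, ay = spec.body_axes_mm
    _check_fits(ct_grid, 0, -ax, ax, "torso width")
    _check_fits(ct_grid, 1, -ay, ay, "torso depth")
    if table.enabled:
        half_c = table.chord_width_mm / 2.0
        _check_fits(ct_grid, 0, -half_c, half_c, "table chord")
        _check_fits(
            ct_grid, 1, -ay, ay + table.gap_mm + table.thickness_mm, "table depth"
        )

    def body_on(grid: GridSpec) -> np.ndarray:
        x, y, _ = grid.meshgrid()
        body2d = (x / ax) ** 2 + (y / ay) ** 2 <= 1.0
        return np.broadcast_to(body2d, grid.shape).copy()

    body_ct = body_on(ct_grid)
    tmask = _table_mask(ct_grid, table, object_lowest_y_mm=ay)

    hu = np.full(ct_grid.shape, HU_AIR)
    hu[tmask] = table.hu_value
    hu[body_ct] = spec.body_hu
    ct = CTVolume(ct_grid, hu)

    shell, defect = _lv_masks(spect_grid, spec)
    body_sp = body_on(spect_grid)
    act = np.zeros(spect_grid.shape)
    act[body_sp] = spec.background_activity_fraction * spec.myocardium_activity
    act[shell] = spec.myocardium_activity
    if spec.defect is not None:
        act[defect] = spec.defect.residual_fraction * spec.myocardium_activity
    activity = ActivityVolume(spect_grid, act)

    truth = GroundTruth(
        table_mask=VoxelVolume(ct_grid, tmask),
        body_mask=VoxelVolume(ct_grid, body_ct),
        lv_shell_mask=VoxelVolume(spect_grid, shell),
        defect_mask=VoxelVolume(spect_grid, defect) if spec.defect else None,
        lv_axis=spec.lv_axis_unit,
        lv_center_mm=np.asarray(spec.lv_center_mm, dtype=float),
    )
    return ct, activity, truth


@dataclass(frozen=True)
class CohortRanges:
    """Habitus and study-mix distributions for cohort sampling.

    BMI is drawn from the published cohort distribution (mean 29.7, SD 6.0,
    range 17.3-40.8) and mapped linearly onto torso semi-axis bounds.
    """

    bmi_mean: float = 29.7
    bmi_sd: float = 6.0
    bmi_range: tuple[float, float] = (17.3, 40.8)
    body_ax_range_mm: tuple[float, float] = (140.0, 195.0)
    body_ay_range_mm: tuple[float, float] = (95.0, 140.0)
    stress_fraction: float = 13.0 / 19.0
    defect_prevalence: float = 1.0 / 3.0
    defect_residual_range: tuple[float, float] = (0.3, 0.7)
    defect_regions: tuple[str, ...] = ("inferior", "anterior", "lateral", "septal")
    lv_scale_range: tuple[float, float] = (0.9, 1.1)
    tilt_jitter_deg: float = 8.0


def sample_cohort(
    n_studies: int,
    seed: int,
    ranges: CohortRanges = CohortRanges(),
) -> list[CardiacStudySpec]:
    """Draw ``n_studies`` reproducible study specs with habitus variation."""
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    rng = np.random.default_rng(seed)
    base = CardiacStudySpec()
    lo, hi = ranges.bmi_range
    specs: list[CardiacStudySpec] = []
    for _ in range(n_studies):
        bmi = float(np.clip(rng.normal(ranges.bmi_mean, ranges.bmi_sd), lo, hi))
        t = (bmi - lo) / (hi - lo)
        ax = ranges.body_ax_range_mm[0] + t * np.ptp(ranges.body_ax_range_mm)
        ay = ranges.body_ay_range_mm[0] + t * np.ptp(ranges.body_ay_range_mm)
        scale = rng.uniform(*ranges.lv_scale_range)
        az = base.lv_axis_tilt_deg[0] + rng.uniform(-1, 1) * ranges.tilt_jitter_deg
        el = base.lv_axis_tilt_deg[1] + rng.uniform(-1, 1) * ranges.tilt_jitter_deg
        defect = None
        if rng.random() < ranges.defect_prevalence:
            defect = DefectSpec(
                region=str(rng.choice(ranges.defect_regions)),
                residual_fraction=float(rng.uniform(*ranges.defect_residual_range)),
            )
        label = "stress" if rng.random() < ranges.stress_fraction else "rest"
        specs.append(
            replace(
                base,
                body_axes_mm=(float(ax), float(ay)),
                lv_outer_axes_mm=tuple(s * scale for s in base.lv_outer_axes_mm),
                lv_inner_axes_mm=tuple(s * scale for s in base.lv_inner_axes_mm),
                lv_axis_tilt_deg=(float(az), float(el)),
                defect=defect,
                protocol_label=label,
            )
        )
    return specs
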