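"""End-to-end experiments: QC phantom, MPI phantom, and synthetic cohort.

Each experiment generates its synthetic study, simulates projections with
the table present (as in reality), scatter-corrects, reconstructs with the
table included in and excluded from the attenuation map, and quantifies the
difference.  All stages are deterministic given the configuration seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .acquisition import (
    MPI_PROTOCOL,
    QC_PROTOCOL,
    AcquisitionProtocol,
    EnergyWindows,
    NoiseModel,
    ProjectionSet,
    add_noise_and_scatter,
    count_reduction_profile,
    forward_project,
    scatter_correct,
)
from .attenuation import MuCalibration, hu_to_mu, resample_to_grid
from .cardiac_polar import (
    LVGeometry,
    PolarMapModel,
    polar_map,
    reorient_short_axis,
    score_segments,
)
from .comparison import (
    DiffResult,
    ScoreComparison,
    compare_scores,
    percentage_difference,
)
from .grids import ActivityVolume, CTVolume, GridSpec, MuMap
from .io import spec_to_yaml, write_nifti
from .reconstruction import ReconParams, osem_reconstruct
from .synthetic import (
    CardiacStudySpec,
    CohortRanges,
    GroundTruth,
    PhantomSpec,
    TableModel,
    generate_cardiac_study,
    generate_jaszczak,
    sample_cohort,
)
from .table_removal import TableRemovalParams, remove_table

logger = logging.getLogger("tabfx")

__all__ = [
    "ExperimentConfig",
    "PhantomReport",
    "CohortReport",
    "default_spect_grid",
    "default_ct_grid",
    "run_phantom_experiment",
    "run_cohort_experiment",
    "CONFIG_REGISTRY",
]


def default_spect_grid(downsample: int = 1) -> GridSpec:
    """The clinical SPECT grid (128^3 at 4.8 mm), optionally downsampled
    preserving the 614 mm field of view."""
    n = 128 // downsample
    s = 4.8 * downsample
    return GridSpec.centered((n, n, n), (s, s, s))

def default_ct_grid(downsample: int = 1, n_slices: int = 48) -> GridSpec:
    """CT grid with 5 mm slices and in-plane coverage of the full table.

    In-plane spacing is ``downsample`` mm over a fixed 512 mm field of view
    (the clinical 1 mm pixels cannot cover a 450 mm-wide table on a 128
    matrix, so the matrix, not the pixel size, is widened).
    """
    n = 512 // downsample
    return GridSpec.centered((n, n, n_slices), (float(downsample), float(downsample), 5.0))


@dataclass(frozen=True)
class ExperimentConfig:
    experiment: str = "qc_phantom"  # qc_phantom | mpi_phantom | cohort
    seed: int = 0
    table: TableModel = TableModel()
    phantom: PhantomSpec = PhantomSpec()
    spect_grid: GridSpec = field(default_factory=default_spect_grid)
    ct_grid: GridSpec = field(default_factory=default_ct_grid)
    protocol: Optional[AcquisitionProtocol] = None  # default by experiment
    noise: NoiseModel = NoiseModel(enabled=False)
    recon: ReconParams = ReconParams()
    removal: TableRemovalParams = TableRemovalParams()
    calib: MuCalibration = MuCalibration()
    windows: EnergyWindows = EnergyWindows()
    polar: PolarMapModel = PolarMapModel()
    cohort: CohortRanges = CohortRanges()
    n_studies: int = 19
    mask_frac: float = 0.05
    output_dir: Optional[str] = None

    def resolved_protocol(self) -> AcquisitionProtocol:
        if self.protocol is not None:
            return self.protocol
        return QC_PROTOCOL if self.experiment == "qc_phantom" else MPI_PROTOCOL


CONFIG_REGISTRY = {
    cls.__name__: cls
    for cls in (
        ExperimentConfig,
        TableModel,
        PhantomSpec,
        GridSpec,
        AcquisitionProtocol,
        NoiseModel,
        ReconParams,
        TableRemovalParams,
        MuCalibration,
        EnergyWindows,
        PolarMapModel,
        CohortRanges,
        CardiacStudySpec,
    )
}


@dataclass
class PhantomReport:
    config: ExperimentConfig
    ct: CTVolume
    activity: ActivityVolume
    truth: GroundTruth
    projections: ProjectionSet
    recon_with_table_ac: ActivityVolume
    recon_without_table_ac: ActivityVolume
    diff: DiffResult
    count_reduction: np.ndarray


@dataclass
class StudyRecord:
    spec: CardiacStudySpec
    scores_with: np.ndarray
    scores_without: np.ndarray
    polar_with: object
    polar_without: object


@dataclass
class CohortReport:
    config: ExperimentConfig
    comparison: ScoreComparison
    studies: list[StudyRecord]


def _mu_pair(
    ct: CTVolume, cfg: ExperimentConfig, grid: GridSpec
) -> tuple[MuMap, MuMap]:
    """(mu with table, mu with table stripped) resampled onto ``grid``."""
    mu_with = resample_to_grid(hu_to_mu(ct, cfg.calib), grid)
    stripped = remove_table(ct, cfg.removal).ct_without_table
    mu_without = resample_to_grid(hu_to_mu(stripped, cfg.calib), grid)
    return mu_with, mu_without


def _simulate_projections(
    activity: ActivityVolume,
    mu_true: MuMap,
    cfg: ExperimentConfig,
    protocol: AcquisitionProtocol,
) -> ProjectionSet:
    projs = forward_project(activity, mu_true, protocol)
    logger.info(
        "projected %d views, total counts %.3g", len(projs.angles_deg), projs.total_counts
    )
    if cfg.noise.enabled:
        projs = add_noise_and_scatter(projs, cfg.noise)
    return scatter_correct(projs, cfg.windows)


def run_phantom_experiment(cfg: ExperimentConfig) -> PhantomReport:
    """Full phantom pipeline for the QC or MPI protocol; see module docs."""
    if cfg.experiment not in ("qc_phantom", "mpi_phantom"):
        raise ValueError(f"not a phantom experiment: {cfg.experiment!r}")
    protocol = cfg.resolved_protocol()
    ct, activity, truth = generate_jaszczak(
        cfg.phantom, cfg.table, cfg.ct_grid, cfg.spect_grid
    )
    mu_with, mu_without = _mu_pair(ct, cfg, cfg.spect_grid)
    projs = _simulate_projections(activity, mu_with, cfg, protocol)
    recon_a = osem_reconstruct(projs, mu_with, cfg.recon)
    recon_b = osem_reconstruct(projs, mu_without, cfg.recon)
    diff = percentage_difference(recon_a, recon_b, cfg.mask_frac)
    reduction = count_reduction_profile(activity, mu_with, mu_without, protocol)
    logger.info(
        "max |pct diff| %.2f%% at %s; mean count reduction %.2f%%",
        diff.max_abs_pct,
        diff.argmax_index,
        100 * reduction.mean(),
    )
    report = PhantomReport(
        config=cfg,
        ct=ct,
        activity=activity,
        truth=truth,
        projections=projs,
        recon_with_table_ac=recon_a,
        recon_without_table_ac=recon_b,
        diff=diff,
        count_reduction=reduction,
    )
    if cfg.output_dir is not None:
        _write_phantom_outputs(report)
    return report


def _study_scores(
    spec: CardiacStudySpec, cfg: ExperimentConfig, study_seed: int
) -> StudyRecord:
    ct, activity, truth = generate_cardiac_study(
        spec, cfg.table, cfg.ct_grid, cfg.spect_grid, seed=study_seed
    )
    protocol = cfg.protocol if cfg.protocol is not None else MPI_PROTOCOL
    mu_with, mu_without = _mu_pair(ct, cfg, cfg.spect_grid)
    noise = replace(cfg.noise, seed=study_seed) if cfg.noise.enabled else cfg.noise
    local = replace(cfg, noise=noise)
    projs = _simulate_projections(activity, mu_with, local, protocol)
    recon_a = osem_reconstruct(projs, mu_with, cfg.recon)
    recon_b = osem_reconstruct(projs, mu_without, cfg.recon)
    geom = LVGeometry(
        center_mm=tuple(truth.lv_center_mm),
        radius_mm=max(spec.lv_outer_axes_mm[:2]),
        long_axis_mm=spec.lv_outer_axes_mm[2],
    )
    records = []
    for recon in (recon_a, recon_b):
        sa = reorient_short_axis(recon, truth.lv_axis, truth.lv_center_mm)
        pm = polar_map(sa, cfg.polar, geom)
        records.append((pm, score_segments(pm).scores))
    (pm_a, scores_a), (pm_b, scores_b) = records
    return StudyRecord(
        spec=spec,
        scores_with=scores_a,
        scores_without=scores_b,
        polar_with=pm_a,
        polar_without=pm_b,
    )


def run_cohort_experiment(cfg: ExperimentConfig) -> CohortReport:
    """Sample a cohort, run both arms per study, compare segment scores."""
    if cfg.experiment != "cohort":
        raise ValueError(f"not a cohort experiment: {cfg.experiment!r}")
    specs = sample_cohort(cfg.n_studies, cfg.seed, cfg.cohort)
    studies = []
    for i, spec in enumerate(specs):
        logger.info("cohort study %d/%d (%s)", i + 1, len(specs), spec.protocol_label)
        studies.append(_study_scores(spec, cfg, study_seed=cfg.seed * 100003 + i))
    comparison = compare_scores(
        [(s.scores_with, s.scores_without) for s in studies]
    )
    report = CohortReport(config=cfg, comparison=comparison, studies=studies)
    if cfg.output_dir is not None:
        _write_cohort_outputs(report)
    return report


# -- output writing ---------------------------------------------------------


def _manifest(cfg: ExperimentConfig, extra: dict) -> dict:
    cfg_yaml = spec_to_yaml(cfg)
    return {
        "package": "tabfx",
        "version": __version__,
        "seed": cfg.seed,
        "config_yaml": cfg_yaml,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        **extra,
    }


def _write_phantom_outputs(report: PhantomReport) -> None:
    from . import figures

    out = Path(report.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        write_nifti(out / "ct.nii.gz", report.ct)
        write_nifti(out / "activity.nii.gz", report.activity)
        write_nifti(out / "recon_with_table_ac.nii.gz", report.recon_with_table_ac)
        write_nifti(out / "recon_without_table_ac.nii.gz", report.recon_without_table_ac)
        figures.phantom_difference_figure(report, out / "difference.png")
        summary = {
            "max_abs_pct": report.diff.max_abs_pct,
            "argmax_index": list(report.diff.argmax_index),
            "mean_count_reduction_pct": float(100 * report.count_reduction.mean()),
        }
        (out / "manifest.json").write_text(
            json.dumps(_manifest(report.config, {"results": summary}), indent=2)
        )
    except Exception:
        for p in out.glob("*"):
            p.unlink(missing_ok=True)
        raise


def _write_cohort_outputs(report: CohortReport) -> None:
    from . import figures

    out = Path(report.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    comp = report.comparison
    rows = []
    for i, s in enumerate(report.studies):
        for seg in range(17):
            rows.append(
                {
                    "study": i,
                    "protocol": s.spec.protocol_label,
                    "segment": seg + 1,
                    "score_with_table": int(s.scores_with[seg]),
                    "score_without_table": int(s.scores_without[seg]),
                }
            )
    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "segment_scores.csv", index=False)
    stats = {
        "n_pairs": comp.n_pairs,
        "mean_diff": comp.mean_diff,
        "ttest_p": comp.ttest_p,
        "pearson_r": comp.pearson_r,
        "shapiro_p_with": comp.shapiro_p_with,
        "shapiro_p_without": comp.shapiro_p_without,
        "per_segment": [dataclasses.asdict(s) for s in comp.per_segment],
    }
    (out / "score_comparison.json").write_text(json.dumps(stats, indent=2))
    figures.score_scatter_figure(comp, out / "score_scatter.png")
    figures.segment_panels_figure(comp, out / "segment_panels.png")
    # the study with the largest absolute score difference, as paired maps
    diffs = [np.abs(s.scores_with - s.scores_without).sum() for s in report.studies]
    figures.paired_polar_figure(
        report.studies[int(np.argmax(diffs))], out / "largest_difference_polar.png"
    )
    (out / "manifest.json").write_text(
        json.dumps(_manifest(report.config, {"results": {"ttest_p": comp.ttest_p}}), indent=2)
    )
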