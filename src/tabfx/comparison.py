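"""Differences between the two attenuation-correction arms.

Phantom studies are compared through a voxelwise percentage-difference
volume (reference = reconstruction with the table included in the mu-map,
masked at a fraction of its maximum); cohort studies through paired
segment-perfusion-score statistics: a pooled paired t-test across all
study-segment pairs, Shapiro-Wilk normality per arm, Pearson correlation,
and per-segment paired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grids import ActivityVolume

__all__ = [
    "DiffResult",
    "ScoreComparison",
    "SegmentStat",
    "percentage_difference",
    "compare_scores",
    "segment_panels",
]


@dataclass
class DiffResult:
    pct_diff: np.ndarray  # % difference volume, zero outside mask
    max_abs_pct: float
    argmax_index: tuple[int, int, int]
    argmax_slice: int  # axial (z) slice of the maximum
    mask: np.ndarray


@dataclass
class SegmentStat:
    segment: int
    mean_diff: float
    ttest_p: float
    n: int


@dataclass
class ScoreComparison:
    n_pairs: int
    mean_diff: float
    shapiro_p_with: float
    shapiro_p_without: float
    ttest_p: float
    pearson_r: float
    per_segment: list[SegmentStat]
    degenerate: bool
    scores_with: np.ndarray  # (n_studies, 17)
    scores_without: np.ndarray


def percentage_difference(
    a: ActivityVolume, b: ActivityVolume, mask_frac: float = 0.05
) -> DiffResult:
    """``100 * (a - b) / a`` inside ``a > mask_frac * max(a)``, else zero.

    ``a`` is the reference arm (table included in the attenuation map).
    Returns the maximum absolute percentage difference and its location.
    """
    if a.grid != b.grid:
        raise ValueError("volumes must share one grid")
    amax = float(a.values.max())
    if amax <= 0:
        raise ValueError("reference volume is identically zero")
    mask = a.values > mask_frac * amax
    pct = np.zeros_like(a.values, dtype=float)
    pct[mask] = 100.0 * (a.values[mask] - b.values[mask]) / a.values[mask]
    flat = int(np.abs(pct).argmax())
    idx = np.unravel_index(flat, pct.shape)
    return DiffResult(
        pct_diff=pct,
        max_abs_pct=float(np.abs(pct).max()),
        argmax_index=tuple(int(i) for i in idx),
        argmax_slice=int(idx[2]),
        mask=mask,
    )


def _paired_t_p(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if np.allclose(d.std(), 0.0):
        return 1.0, True
    return float(stats.ttest_rel(x, y).pvalue), False


def compare_scores(
    pairs: list[tuple[np.ndarray, np.ndarray]],
) -> ScoreComparison:
    """Paired statistics over per-study 17-segment score vectors.

    Each element of ``pairs`` is ``(scores_with_table, scores_without)``.
    Scores are pooled across studies for the global t-test, Shapiro-Wilk
    and Pearson correlation; per-segment t-tests run across studies.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 studies to compare")
    sw = np.array([np.asarray(p[0]) for p in pairs])
    swo = np.array([np.asarray(p[1]) for p in pairs])
    if sw.shape[1] != 17 or swo.shape[1] != 17:
        raise ValueError("each study must contribute 17 segment scores per arm")
    pooled_w = sw.ravel().astype(float)
    pooled_wo = swo.ravel().astype(float)

    ttest_p, degenerate = _paired_t_p(pooled_w, pooled_wo)
    if np.ptp(pooled_w) == 0 or np.ptp(pooled_wo) == 0:
        r = 1.0 if np.array_equal(pooled_w, pooled_wo) else float("nan")
        degenerate = True
    elif np.array_equal(pooled_w, pooled_wo):
        r = 1.0  # self-correlation is exact by definition
    else:
        r = float(stats.pearsonr(pooled_w, pooled_wo).statistic)

    def _shapiro(x: np.ndarray) -> float:
        if np.ptp(x) == 0:
            return 0.0  # degenerate: constant scores are trivially non-normal
        return float(stats.shapiro(x).pvalue)

    per_segment = []
    for seg in range(17):
        p, _ = _paired_t_p(sw[:, seg], swo[:, seg])
        per_segment.append(
            SegmentStat(
                segment=seg + 1,
                mean_diff=float((sw[:, seg] - swo[:, seg]).mean()),
                ttest_p=p,
                n=sw.shape[0],
            )
        )

    return ScoreComparison(
        n_pairs=int(pooled_w.size),
        mean_diff=float((pooled_w - pooled_wo).mean()),
        shapiro_p_with=_shapiro(pooled_w),
        shapiro_p_without=_shapiro(pooled_wo),
        ttest_p=ttest_p,
        pearson_r=r,
        per_segment=per_segment,
        degenerate=degenerate,
        scores_with=sw,
        scores_without=swo,
    )


def segment_panels(comparison: ScoreComparison) -> list[dict]:
    """Per-segment scatter data (17 panels, AHA order) for figure rendering.

    Each panel carries the per-study (with, without) score points plus the
    frequency of each distinct combination, ready for an identity-line
    scatter display.
    """
    panels = []
    for seg in range(17):
        x = comparison.scores_with[:, seg]
        y = comparison.scores_without[:, seg]
        combos, counts = np.unique(np.stack([x, y], axis=1), axis=0, return_counts=True)
        panels.append(
            {
                "segment": seg + 1,
                "points": np.stack([x, y], axis=1),
                "combos": combos,
                "counts": counts,
            }
        )
    return panels
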