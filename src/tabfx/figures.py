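"""Figure rendering: difference slices, bull's-eye maps, score scatters."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .cardiac_polar import PolarMap
from .comparison import ScoreComparison

__all__ = [
    "phantom_difference_figure",
    "score_scatter_figure",
    "segment_panels_figure",
    "paired_polar_figure",
    "bullseye_axes",
]


def phantom_difference_figure(report, path: str | Path) -> None:
    """Side-by-side slice of both arms plus the percentage-difference map,
    shown at the axial slice of the maximum difference, with a colorbar tick
    at the observed maximum."""
    k = report.diff.argmax_slice
    a = report.recon_with_table_ac.values[:, :, k].T
    b = report.recon_without_table_ac.values[:, :, k].T
    d = report.diff.pct_diff[:, :, k].T
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    vmax = max(a.max(), b.max())
    for ax, img, title in zip(axes[:2], (a, b), ("with table AC", "without table AC")):
        ax.imshow(img, cmap="gray", vmin=0, vmax=vmax, origin="upper")
        ax.set_title(title)
        ax.axis("off")
    m = report.diff.max_abs_pct
    im = axes[2].imshow(d, cmap="RdBu_r", vmin=-m, vmax=m, origin="upper")
    axes[2].set_title("percentage difference")
    axes[2].axis("off")
    cbar = fig.colorbar(im, ax=axes[2])
    cbar.set_ticks(sorted({-m, 0.0, m, float(np.round(m, 1))}))
    fig.suptitle(f"slice {k}: max |diff| = {m:.1f}%")
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def score_scatter_figure(comp: ScoreComparison, path: str | Path) -> None:
    """Pooled score scatter with identity line; darker = more frequent."""
    x = comp.scores_with.ravel()
    y = comp.scores_without.ravel()
    combos, counts = np.unique(np.stack([x, y], axis=1), axis=0, return_counts=True)
    fig, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(
        combos[:, 0], combos[:, 1], c=counts, cmap="Greens", s=80, edgecolors="k"
    )
    ax.plot([0, 4], [0, 4], color="gold", lw=2)
    ax.set_xlabel("score, with table in AC")
    ax.set_ylabel("score, without table in AC")
    ax.set_xticks(range(5))
    ax.set_yticks(range(5))
    ax.set_title(f"{comp.n_pairs} segment scores, r={comp.pearson_r:.2f}, p={comp.ttest_p:.2f}")
    fig.colorbar(sc, ax=ax, label="frequency")
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def segment_panels_figure(comp: ScoreComparison, path: str | Path) -> None:
    """17 per-segment scatter panels in AHA numbering order."""
    from .comparison import segment_panels

    panels = segment_panels(comp)
    fig, axes = plt.subplots(3, 6, figsize=(15, 8))
    for ax in axes.ravel()[17:]:
        ax.axis("off")
    for panel, ax in zip(panels, axes.ravel()):
        ax.scatter(
            panel["combos"][:, 0],
            panel["combos"][:, 1],
            c=panel["counts"],
            cmap="Greens",
            s=40,
            edgecolors="k",
        )
        ax.plot([0, 4], [0, 4], color="gold", lw=1)
        ax.set_title(f"segment {panel['segment']}", fontsize=8)
        ax.set_xlim(-0.5, 4.5)
        ax.set_ylim(-0.5, 4.5)
        ax.set_xticks(range(5))
        ax.set_yticks(range(5))
        ax.tick_params(labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def bullseye_axes(ax, pm: PolarMap, title: str = "") -> None:
    """Render one polar map as a bull's-eye (apex center, base rim)."""
    n_sl, n_ang = pm.normalized.shape
    theta = np.linspace(0, 2 * np.pi, n_ang + 1)
    r = np.linspace(0, 1, n_sl + 1)
    tt, rr = np.meshgrid(theta, r)
    ax.pcolormesh(tt, rr, pm.normalized, cmap="inferno", vmin=0, vmax=100)
    ax.set_title(title, fontsize=9)
    ax.set_xticks([])
    ax.set_yticks([])


def paired_polar_figure(study, path: str | Path) -> None:
    """Paired bull's-eye maps of one study (with vs without table in AC)."""
    fig, axes = plt.subplots(
        1, 2, figsize=(8, 4), subplot_kw={"projection": "polar"}
    )
    bullseye_axes(axes[0], study.polar_with, "with table AC")
    bullseye_axes(axes[1], study.polar_without, "without table AC")
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
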