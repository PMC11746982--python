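"""Automatic removal of the patient table from a CT volume.

The algorithm thresholds the central axial slice at -700 HU, labels the
connected regions, classifies the most posterior region as the table,
enlarges it by three dilations with a 9x9 square kernel, and removes the
resulting in-slice region from every slice.  Because the dilation could
encroach on the body when the two regions are close, pixels belonging to the
un-dilated body regions are subtracted from the dilated mask before removal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import CTVolume
from .synthetic import GroundTruth

__all__ = [
    "TableRemovalParams",
    "RemovalResult",
    "remove_table",
    "removal_report",
    "EmptyCTError",
    "InseparableRegionsError",
]


class EmptyCTError(ValueError):
    """No voxels above the threshold in the central slice."""


class InseparableRegionsError(ValueError):
    """A thresholded region touches both the anterior and posterior image edge."""


@dataclass(frozen=True)
class TableRemovalParams:
    threshold_hu: float = -700.0
    dilation_iterations: int = 3
    kernel_size: int = 9
    replacement_hu: float = -1000.0
    connectivity: int = 8  # in-slice pixel connectivity: 4 or 8

    def __post_init__(self) -> None:
        if self.kernel_size < 3 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 3")
        if self.dilation_iterations < 0:
            raise ValueError("dilation_iterations must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class RemovalResult:
    ct_without_table: CTVolume
    table_mask_2d: np.ndarray  # (nx, ny) bool, applied to all slices
    n_components_found: int


def _label_structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def remove_table(ct: CTVolume, params: TableRemovalParams = TableRemovalParams()) -> RemovalResult:
    """Strip the patient table from ``ct``; see the module docstring.

    The returned CT equals the input except at in-slice mask positions,
    which are replaced by ``params.replacement_hu`` (air) in every slice.
    """
    nz = ct.grid.shape[2]
    central = ct.values[:, :, nz // 2]
    binary = central > params.threshold_hu

    labels, n = ndimage.label(binary, structure=_label_structure(params.connectivity))
    if n == 0:
        raise EmptyCTError("empty CT: no voxels above threshold in the central slice")

    ny = central.shape[1]
    for lab in range(1, n + 1):
        ys = np.nonzero(labels == lab)[1]
        if ys.min() == 0 and ys.max() == ny - 1:
            raise InseparableRegionsError(
                "cannot separate body from table: a region spans the full "
                "anterior-posterior extent of the slice"
            )

    if n == 1:
        warnings.warn("only one region above threshold: no table found, CT unchanged")
        return RemovalResult(
            ct_without_table=ct.copy(),
            table_mask_2d=np.zeros(central.shape, dtype=bool),
            n_components_found=1,
        )

    # centroid y per component; the most posterior (+y) one is the table
    centroids = ndimage.center_of_mass(binary, labels, index=range(1, n + 1))
    table_label = 1 + int(np.argmax([c[1] for c in centroids]))

    table = labels == table_label
    body = binary & ~table
    kernel = np.ones((params.kernel_size, params.kernel_size), dtype=bool)
    dilated = ndimage.binary_dilation(
        table, structure=kernel, iterations=max(params.dilation_iterations, 1)
    ) if params.dilation_iterations > 0 else table
    mask = dilated & ~body

    out = ct.values.copy()
    out[mask, :] = params.replacement_hu
    return RemovalResult(
        ct_without_table=CTVolume(ct.grid, out),
        table_mask_2d=mask,
        n_components_found=n,
    )


def removal_report(result: RemovalResult, truth: GroundTruth) -> tuple[float, float]:
    """Sensitivity/specificity of table removal against ground-truth masks.

    Sensitivity: fraction of true table voxels set to the replacement value.
    Specificity: fraction of true body voxels left untouched.
    """
    t = truth.table_mask.values
    if not t.any():
        raise ValueError("ground-truth table mask is empty")
    removed3d = np.broadcast_to(
        result.table_mask_2d[:, :, None], result.ct_without_table.grid.shape
    )
    sensitivity = float((removed3d & t).sum() / t.sum())
    b = truth.body_mask.values
    specificity = float((b & ~removed3d).sum() / b.sum()) if b.any() else float("nan")
    return sensitivity, specificity


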