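"""NIfTI-1 volume I/O and YAML (de)serialization of experiment specs.

Volumes are stored with the package's world convention in the affine
(diagonal spacing, translation = origin); mu-maps carry a ``cm-1`` unit
annotation in the header description.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Type

import nibabel as nib
import numpy as np
import yaml

from .grids import ActivityVolume, CTVolume, GridSpec, MuMap, VoxelVolume

__all__ = ["write_nifti", "read_nifti", "spec_to_yaml", "spec_from_yaml"]

_KIND_TO_CLS: dict[str, Type[VoxelVolume]] = {
    "ct": CTVolume,
    "activity": ActivityVolume,
    "mu": MuMap,
    "scalar": VoxelVolume,
}
_CLS_TO_KIND = {v: k for k, v in _KIND_TO_CLS.items()}


def write_nifti(path: str | Path, vol: VoxelVolume) -> None:
    """Write a volume as NIfTI-1 (.nii or .nii.gz), float32 data."""
    affine = np.diag([*vol.grid.spacing_mm, 1.0])
    affine[:3, 3] = vol.grid.origin_mm
    data = vol.values.astype(np.float32)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.grid.spacing_mm)
    kind = _CLS_TO_KIND.get(type(vol), "scalar")
    descrip = f"tabfx:{kind}" + (" cm-1" if isinstance(vol, MuMap) else "")
    img.header["descrip"] = descrip.encode()
    nib.save(img, str(path))


def read_nifti(path: str | Path, kind: str | None = None) -> VoxelVolume:
    """Read a NIfTI volume; ``kind`` in {ct, activity, mu, scalar} or inferred."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        affine = img.affine
    except Exception as exc:  # malformed file
        raise ValueError(f"cannot parse NIfTI file {path}: {exc}") from exc
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume in {path}, got shape {data.shape}")
    off = affine[:3, :3] - np.diag(np.diag(affine[:3, :3]))
    if np.abs(off).max() > 1e-6:
        raise ValueError(f"non-axis-aligned affine in {path} is not supported")
    spacing = tuple(float(s) for s in np.diag(affine[:3, :3]))
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive voxel spacing in affine of {path}")
    grid = GridSpec(data.shape, spacing, tuple(float(o) for o in affine[:3, 3]))
    if kind is None:
        descrip = img.header["descrip"].tobytes().decode(errors="ignore")
        kind = "scalar"
        for key in _KIND_TO_CLS:
            if f"tabfx:{key}" in descrip:
                kind = key
                break
    cls = _KIND_TO_CLS.get(kind)
    if cls is None:
        raise ValueError(f"unknown volume kind {kind!r}")
    return cls(grid, data)


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        d["__type__"] = type(obj).__name__
        return d
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def spec_to_yaml(obj: Any) -> str:
    """Serialize a (possibly nested) spec dataclass to YAML."""
    return yaml.safe_dump(_to_plain(obj), sort_keys=True)


def spec_from_yaml(text: str, registry: dict[str, type]) -> Any:
    """Inverse of :func:`spec_to_yaml` given a name -> class registry."""

    def _build(node: Any) -> Any:
        if isinstance(node, dict) and "__type__" in node:
            name = node.pop("__type__")
            cls = registry[name]
            kwargs = {k: _build(v) for k, v in node.items()}
            for f in dataclasses.fields(cls):
                if f.name in kwargs and isinstance(kwargs[f.name], list):
                    hint = str(f.type)
                    if "tuple" in hint:
                        kwargs[f.name] = tuple(kwargs[f.name])
            return cls(**kwargs)
        if isinstance(node, dict):
            return {k: _build(v) for k, v in node.items()}
        if isinstance(node, list):
            return [_build(v) for v in node]
        return node

    return _build(yaml.safe_load(text))
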