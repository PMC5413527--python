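"""Containers and I/O for gated short-axis studies and tabular results.

A gated study is stored in memory as a 4-D nonnegative integer array indexed
``[frame][slice][row][col]`` with slice 0 at the apex.  On disk it is a NIfTI
file (dims x, y, slice, frame) plus a JSON sidecar carrying the calibration a
nuclear-medicine header would: pixel size, slice thickness, frame count and
optional frame duration.  Tables are plain CSV with a header row.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


class FormatError(ValueError):
    """File does not look like a gated short-axis study."""


class MetadataError(ValueError):
    """Required calibration metadata is missing."""


@dataclass
class GatedStudy:
    """4-D count volume plus geometry/timing metadata."""

    counts: np.ndarray
    pixel_mm: float
    slice_mm: float
    frame_ms: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 4:
            raise FormatError(f"counts must be 4-D, got {c.ndim}-D")
        if not np.issubdtype(c.dtype, np.number):
            raise FormatError("counts must be numeric")
        if not np.all(np.isfinite(c.astype(float))):
            raise FormatError("counts contain non-finite values")
        if np.any(c < 0):
            raise FormatError("counts must be nonnegative")
        if self.pixel_mm <= 0 or self.slice_mm <= 0:
            raise MetadataError("pixel_mm and slice_mm must be positive")
        self.counts = c

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]

    @property
    def n_slices(self) -> int:
        return self.counts.shape[1]

    @property
    def matrix_size(self) -> int:
        return self.counts.shape[2]


def sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return p.with_name(name[: -len(suf)] + ".json")
    return p.with_suffix(".json")


def write_gated(study: GatedStudy, path) -> Path:
    """Write NIfTI + JSON sidecar; round-trips bit-exactly through read_gated."""
    path = Path(path)
    counts = study.counts
    if np.issubdtype(counts.dtype, np.integer):
        if counts.max(initial=0) > np.iinfo(np.int32).max:
            raise FormatError("integer counts exceed int32 range")
        data = counts.astype(np.int32)
    else:
        data = counts.astype(np.float64)
    affine = np.diag([study.pixel_mm, study.pixel_mm, study.slice_mm, 1.0])
    img = nib.Nifti1Image(data.transpose(3, 2, 1, 0), affine)
    nib.save(img, path)
    side = {
        "pixel_mm": study.pixel_mm,
        "slice_mm": study.slice_mm,
        "n_frames": study.n_frames,
        "meta": study.meta,
    }
    if study.frame_ms is not None:
        side["frame_ms"] = study.frame_ms
    sidecar_path(path).write_text(json.dumps(side, indent=1, default=str))
    return path


def read_gated(path) -> GatedStudy:
    """Load a 4-D NIfTI + sidecar written by :func:`write_gated`."""
    path = Path(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"expected a 4-D gated study, got {data.ndim}-D")
    sp = sidecar_path(path)
    if not sp.exists():
        raise MetadataError(f"missing JSON sidecar {sp.name}")
    side = json.loads(sp.read_text())
    for key in ("pixel_mm", "slice_mm", "n_frames"):
        if key not in side:
            raise MetadataError(f"sidecar missing required key {key!r}")
    counts = data.transpose(3, 2, 1, 0)
    if counts.shape[0] != side["n_frames"]:
        raise FormatError("frame axis length does not match sidecar n_frames")
    if np.any(counts < 0):
        raise FormatError("negative voxel values")
    return GatedStudy(
        counts=counts,
        pixel_mm=float(side["pixel_mm"]),
        slice_mm=float(side["slice_mm"]),
        frame_ms=float(side["frame_ms"]) if "frame_ms" in side else None,
        meta=side.get("meta", {}),
    )


def _row_dict(row) -> dict:
    if is_dataclass(row) and not isinstance(row, type):
        return asdict(row)
    if isinstance(row, dict):
        return dict(row)
    raise TypeError(f"cannot serialize row of type {type(row).__name__}")


def write_table(rows, path) -> Path:
    """Write records sharing one schema as CSV (header, stable column order)."""
    path = Path(path)
    if isinstance(rows, pd.DataFrame):
        if rows.shape[1] == 0:
            raise ValueError("empty schema")
        rows.to_csv(path, index=False)
        return path
    dicts = [_row_dict(r) for r in rows]
    if not dicts:
        raise ValueError("no rows to write")
    cols = list(dicts[0].keys())
    if not cols:
        raise ValueError("empty schema")
    for d in dicts[1:]:
        if list(d.keys()) != cols:
            raise ValueError("rows do not share a schema")
    pd.DataFrame(dicts, columns=cols).to_csv(path, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
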