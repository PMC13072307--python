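"""Volume, mask, rating-table and measurement I/O.

Conventions
-----------
* A volume is indexed ``(z, x, y)``: axial depth ``z`` (0 = most anterior,
  increasing posteriorly), A-scan index ``x`` along the fast lateral axis,
  B-scan index ``y`` along the slow lateral axis.
* On disk a volume is a multi-page TIFF, one page per B-scan; each page is a
  ``(z, x)`` image.  Geometry metadata (voxel spacings, labels) travels in a
  JSON sidecar next to the TIFF.
* Boolean masks are stored as 0/255 ``uint8`` TIFF stacks with the same page
  layout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "OctVolume",
    "RatingTable",
    "DEFAULT_AXIAL_SPACING_UM",
    "DEFAULT_LATERAL_SPACING_MM",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_rating_table",
    "write_rating_table",
    "read_measurements",
    "write_measurements",
]

DEFAULT_AXIAL_SPACING_UM = 2.0
DEFAULT_LATERAL_SPACING_MM = 0.02

_SIDECAR_SUFFIX = ".json"


@dataclass
class OctVolume:
    """A 3D intensity grid with explicit voxel geometry.

    ``intensities`` is indexed ``(z, x, y)`` with the anterior surface at low
    ``z``.  Spacings are per voxel: axial in micrometres, lateral in
    millimetres.
    """

    intensities: np.ndarray
    axial_spacing_um: float = DEFAULT_AXIAL_SPACING_UM
    lateral_spacing_mm_x: float = DEFAULT_LATERAL_SPACING_MM
    lateral_spacing_mm_y: float = DEFAULT_LATERAL_SPACING_MM
    eye_id: str = ""
    timepoint_label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3:
            raise ValueError(f"intensities must be 3D (z, x, y), got ndim={arr.ndim}")
        nz, nx, ny = arr.shape
        if nz < 8 or nx < 8 or ny < 2:
            raise ValueError(
                f"volume dimensions {arr.shape} below minimum (8, 8, 2)"
            )
        if np.issubdtype(arr.dtype, np.floating) and not np.isfinite(arr).all():
            raise ValueError("intensities contain non-finite values")
        if arr.min() < 0:
            raise ValueError("intensities must be non-negative")
        for name in ("axial_spacing_um", "lateral_spacing_mm_x", "lateral_spacing_mm_y"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        self.intensities = arr

    # -- convenience -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return (
            self.axial_spacing_um * 1e-3
            * self.lateral_spacing_mm_x
            * self.lateral_spacing_mm_y
        )

    def with_intensities(self, arr: np.ndarray) -> "OctVolume":
        """Same geometry/labels, new intensity grid."""
        return replace(self, intensities=arr)

    def copy(self) -> "OctVolume":
        return replace(self, intensities=self.intensities.copy())


@dataclass
class RatingTable:
    """Complete subjects x raters measurement matrix (e.g. % scar volume)."""

    values: np.ndarray
    subject_ids: Sequence[str] = field(default_factory=list)
    rater_ids: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("values must be a 2D subjects x raters matrix")
        n, k = vals.shape
        if n < 2:
            raise ValueError(f"need >=2 subjects, got {n}")
        if k < 2:
            raise ValueError(f"need >=2 raters, got {k}")
        if not np.isfinite(vals).all():
            bad = [tuple(ix) for ix in np.argwhere(~np.isfinite(vals))]
            raise ValueError(f"missing/non-finite cells at (subject, rater) {bad}")
        if (vals < 0).any():
            raise ValueError("ratings must be >= 0")
        if not self.subject_ids:
            self.subject_ids = [f"s{i}" for i in range(n)]
        if not self.rater_ids:
            self.rater_ids = [f"rater{j + 1}" for j in range(k)]
        if len(self.subject_ids) != n or len(self.rater_ids) != k:
            raise ValueError("id lists do not match matrix shape")
        self.values = vals

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# volumes


def _sidecar_for(path: Path) -> Path:
    return path.with_suffix(_SIDECAR_SUFFIX)


def write_volume(vol: OctVolume, path: str | Path) -> tuple[Path, Path]:
    """Write a volume as multi-page TIFF (one page per B-scan) + JSON sidecar.

    Only integer grids are written (lossless roundtrip); float grids must be
    quantized by the caller first.
    """
    path = Path(path)
    arr = vol.intensities
    if not np.issubdtype(arr.dtype, np.integer):
        raise TypeError(
            f"refusing to write dtype {arr.dtype}: quantize to uint8/uint16 "
            "(e.g. np.clip(...).round().astype(np.uint8)) before writing"
        )
    pages = np.ascontiguousarray(arr.transpose(2, 0, 1))  # (y, z, x)
    tifffile.imwrite(path, pages, photometric='minisblack')
    meta = {
        "axial_spacing_um": vol.axial_spacing_um,
        "lateral_spacing_mm_x": vol.lateral_spacing_mm_x,
        "lateral_spacing_mm_y": vol.lateral_spacing_mm_y,
        "eye_id": vol.eye_id,
        "timepoint_label": vol.timepoint_label,
        "axis_order": "page=y, rows=z, cols=x",
    }
    sidecar = _sidecar_for(path)
    sidecar.write_text(json.dumps(meta, indent=2))
    return path, sidecar


def read_volume(path: str | Path, sidecar_path: str | Path | None = None) -> OctVolume:
    """Read a multi-page TIFF volume; metadata from the JSON sidecar.

    A missing sidecar falls back to documented default spacings with a
    warning.  Pages with inconsistent shapes are rejected, naming the first
    offending page.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        shapes = [p.shape for p in tif.pages]
        first = shapes[0]
        for i, s in enumerate(shapes):
            if s != first:
                raise ValueError(
                    f"ragged TIFF stack: page {i} has shape {s}, expected {first}"
                )
        pages = tif.asarray()
    if pages.ndim == 2:  # single page
        pages = pages[None, ...]
    arr = pages.transpose(1, 2, 0)  # (y, z, x) -> (z, x, y)

    sidecar = Path(sidecar_path) if sidecar_path is not None else _sidecar_for(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        warnings.warn(
            f"no sidecar at {sidecar}; assuming default spacings "
            f"({DEFAULT_AXIAL_SPACING_UM} um axial, "
            f"{DEFAULT_LATERAL_SPACING_MM} mm lateral)",
            stacklevel=2,
        )
        meta = {}
    return OctVolume(
        intensities=arr,
        axial_spacing_um=float(meta.get("axial_spacing_um", DEFAULT_AXIAL_SPACING_UM)),
        lateral_spacing_mm_x=float(
            meta.get("lateral_spacing_mm_x", DEFAULT_LATERAL_SPACING_MM)
        ),
        lateral_spacing_mm_y=float(
            meta.get("lateral_spacing_mm_y", DEFAULT_LATERAL_SPACING_MM)
        ),
        eye_id=str(meta.get("eye_id", "")),
        timepoint_label=str(meta.get("timepoint_label", "")),
    )


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a boolean (z, x, y) mask as a 0/255 uint8 TIFF stack."""
    path = Path(path)
    arr = (np.asarray(mask, dtype=bool).astype(np.uint8) * 255).transpose(2, 0, 1)
    tifffile.imwrite(path, np.ascontiguousarray(arr), photometric='minisblack')
    return path


def read_mask(path: str | Path) -> np.ndarray:
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None, ...]
    return pages.transpose(1, 2, 0) > 0


# ---------------------------------------------------------------------------
# rating tables


def write_rating_table(table: RatingTable, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(table.values, columns=list(table.rater_ids))
    df.insert(0, "subject", list(table.subject_ids))
    df.to_csv(path, index=False)
    return path


def read_rating_table(path: str | Path) -> RatingTable:
    """Read a ratings CSV: first column subject id, remaining columns raters."""
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise ValueError(
            f"rating table needs >=2 rater columns, found {df.shape[1] - 1}"
        )
    subject_ids = df.iloc[:, 0].astype(str).tolist()
    rater_ids = list(df.columns[1:])
    raw = df.iloc[:, 1:]
    values = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        coords = [
            f"(subject {subject_ids[i]}, rater {rater_ids[j]})" for i, j in bad[:10]
        ]
        raise ValueError("non-numeric or missing cells at " + ", ".join(coords))
    return RatingTable(values=values, subject_ids=subject_ids, rater_ids=rater_ids)


# ---------------------------------------------------------------------------
# measurements

_MEASUREMENT_COLUMNS = [
    "eye_id",
    "timepoint",
    "corneal_volume_voxels",
    "opacity_volume_voxels",
    "corneal_volume_mm3",
    "opacity_volume_mm3",
    "percent_opacity",
    "t_button",
    "t_opacity",
    "cct_um",
]


def write_measurements(rows: pd.DataFrame | list[dict], path: str | Path) -> Path:
    """Write per eye-timepoint measurement rows to CSV."""
    path = Path(path)
    df = pd.DataFrame(rows)
    missing = [c for c in ("eye_id", "timepoint", "percent_opacity") if c not in df]
    if missing:
        raise ValueError(f"measurement rows missing required columns {missing}")
    cols = [c for c in _MEASUREMENT_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in _MEASUREMENT_COLUMNS
    ]
    df[cols].to_csv(path, index=False)
    return path


def read_measurements(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "percent_opacity" not in df.columns:
        raise ValueError("measurements CSV lacks a percent_opacity column")
    return df
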