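"""Dual-threshold segmentation and opacity measurement.

Two fixed intensity cutoffs drive the whole measurement: ``t_button``
separates the corneal button from background (calibrated as the mean
intensity of normal, preprocessed corneas) and ``t_opacity`` separates
normal from hyperreflective stroma (calibrated as an upper percentile of
pooled naive-cornea stromal intensities).  Voxels above ``t_opacity`` inside
the button are counted as opacity; % opacity is a pure voxel-count ratio so
spacing metadata cannot bias it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .geometry import SurfaceMap
from .volio import OctVolume

__all__ = [
    "ThresholdModel",
    "OpacityMeasurement",
    "calibrate_thresholds",
    "segment_button",
    "segment_opacity",
    "measure_opacity",
    "measure_cct",
    "percent_scar_area",
]


@dataclass
class ThresholdModel:
    """The two calibrated cutoffs plus calibration provenance.

    Button membership uses ``intensity >= t_button``; opacity uses the strict
    ``intensity > t_opacity`` so ties at the cutoff count as normal tissue.
    """

    t_button: float
    t_opacity: float
    calibration: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.t_opacity > self.t_button:
            raise ValueError(
                f"t_opacity ({self.t_opacity}) must exceed t_button "
                f"({self.t_button}); recalibrate"
            )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdModel":
        d = json.loads(Path(path).read_text())
        return cls(**d)


@dataclass
class OpacityMeasurement:
    """Per eye/timepoint volumetric readout."""

    eye_id: str
    timepoint_label: str
    corneal_volume_voxels: int
    opacity_volume_voxels: int
    corneal_volume_mm3: float
    opacity_volume_mm3: float
    percent_opacity: float
    thresholds: ThresholdModel
    cct_um: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 <= self.opacity_volume_voxels <= self.corneal_volume_voxels:
            raise ValueError("opacity volume must be within [0, corneal volume]")
        if not 0.0 <= self.percent_opacity <= 100.0:
            raise ValueError("percent_opacity outside [0, 100]")

    def as_row(self) -> dict:
        return {
            "eye_id": self.eye_id,
            "timepoint": self.timepoint_label,
            "corneal_volume_voxels": self.corneal_volume_voxels,
            "opacity_volume_voxels": self.opacity_volume_voxels,
            "corneal_volume_mm3": self.corneal_volume_mm3,
            "opacity_volume_mm3": self.opacity_volume_mm3,
            "percent_opacity": self.percent_opacity,
            "t_button": self.thresholds.t_button,
            "t_opacity": self.thresholds.t_opacity,
            "cct_um": self.cct_um,
        }


# ---------------------------------------------------------------------------
# calibration


def _largest_component(mask: np.ndarray, bridge_px: int = 9) -> np.ndarray:
    """Largest 3D connected component of ``mask``.

    Before labeling, gaps of up to ``bridge_px`` columns along x are closed so
    that the corneal shell is not split in two by the cleared specular stripe;
    the returned mask is still a subset of the input.
    """
    work = mask
    if bridge_px > 1:
        structure = np.ones((1, bridge_px, 1))
        work = ndimage.binary_erosion(
            ndimage.binary_dilation(mask, structure=structure),
            structure=structure,
            border_value=1,  # do not eat the grid edges
        )
    labels, nlab = ndimage.label(work)
    if nlab <= 1:
        return mask & work if bridge_px > 1 else mask
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return mask & (labels == sizes.argmax())


def calibrate_thresholds(
    button_cohort: Sequence[OctVolume],
    naive_cohort: Sequence[OctVolume],
    opacity_percentile: float = 99.0,
    method: str = "percentile",
    k_sd: float = 3.0,
) -> ThresholdModel:
    """Calibrate both cutoffs from scar-free, geometry-preprocessed cohorts.

    ``t_button`` is the mean intensity over all nonzero voxels pooled across
    the button cohort.  ``t_opacity`` is, by default, the
    ``opacity_percentile`` of corneal-voxel intensities pooled over the naive
    cohort (corneal voxels = largest connected component at ``t_button``);
    ``method="mean_sd"`` uses mean + ``k_sd``*SD of the same pool instead.
    """
    if len(button_cohort) == 0 or len(naive_cohort) == 0:
        raise ValueError("calibration cohorts must be non-empty")
    if not 0 < opacity_percentile <= 100:
        raise ValueError("opacity_percentile must be in (0, 100]")

    total, count = 0.0, 0
    for vol in button_cohort:
        arr = vol.intensities
        nz = arr[arr > 0]
        total += float(nz.sum())
        count += nz.size
    if count == 0:
        raise ValueError("button cohort contains no nonzero voxels")
    t_button = total / count

    pooled = []
    for vol in naive_cohort:
        mask = _largest_component(vol.intensities >= t_button)
        if not mask.any():
            raise ValueError(
                f"naive volume {vol.eye_id!r} has no voxel above t_button"
            )
        pooled.append(vol.intensities[mask].ravel())
    pool = np.concatenate(pooled).astype(float)
    if method == "percentile":
        t_opacity = float(np.percentile(pool, opacity_percentile))
    elif method == "mean_sd":
        t_opacity = float(pool.mean() + k_sd * pool.std(ddof=1))
    else:
        raise ValueError(f"unknown calibration method {method!r}")

    return ThresholdModel(
        t_button=float(t_button),
        t_opacity=t_opacity,
        calibration={
            "n_volumes_button": len(button_cohort),
            "n_volumes_naive": len(naive_cohort),
            "method": method,
            "percentile": opacity_percentile if method == "percentile" else None,
            "k_sd": k_sd if method == "mean_sd" else None,
            "n_pooled_voxels": int(pool.size),
        },
    )


# ---------------------------------------------------------------------------
# segmentation


def segment_button(vol: OctVolume, model: ThresholdModel) -> np.ndarray:
    """Corneal-button mask: ``intensity >= t_button`` restricted to the
    largest 3D connected component."""
    mask = vol.intensities >= model.t_button
    if not mask.any():
        raise ValueError("empty button mask: no voxel reaches t_button")
    out = _largest_component(mask)
    if not out.any():
        raise ValueError("empty button mask after component cleanup")
    return out


def segment_opacity(
    vol: OctVolume, model: ThresholdModel, button_mask: np.ndarray
) -> np.ndarray:
    """Hyperreflective-voxel mask: strictly above ``t_opacity`` and inside
    the button (a subset of ``button_mask`` by construction)."""
    if not button_mask.any():
        raise ValueError("button mask is empty")
    return (vol.intensities > model.t_opacity) & button_mask


def measure_opacity(
    vol: OctVolume,
    model: ThresholdModel,
    eye_id: str | None = None,
    timepoint_label: str | None = None,
    cct_um: float | None = None,
) -> OpacityMeasurement:
    """Segment button and opacity and convert counts to volumes.

    ``percent_opacity`` is computed on voxel counts, not mm^3.
    """
    button = segment_button(vol, model)
    opacity = segment_opacity(vol, model, button)
    n_button = int(button.sum())
    n_opacity = int(opacity.sum())
    vox_mm3 = vol.voxel_volume_mm3
    return OpacityMeasurement(
        eye_id=eye_id if eye_id is not None else vol.eye_id,
        timepoint_label=(
            timepoint_label if timepoint_label is not None else vol.timepoint_label
        ),
        corneal_volume_voxels=n_button,
        opacity_volume_voxels=n_opacity,
        corneal_volume_mm3=n_button * vox_mm3,
        opacity_volume_mm3=n_opacity * vox_mm3,
        percent_opacity=100.0 * n_opacity / n_button,
        thresholds=model,
        cct_um=cct_um,
    )


# ---------------------------------------------------------------------------
# thickness and en-face area


def measure_cct(
    surface: SurfaceMap,
    axial_spacing_um: float,
    lateral_spacing_mm_x: float,
    lateral_spacing_mm_y: float,
    center: tuple[int, int] | None = None,
    offset_mm: float = 0.5,
) -> float:
    """Central corneal thickness: mean over 5 sample points (center and
    ``offset_mm`` along both lateral meridians) of the anterior-to-posterior
    distance, in micrometres."""
    if surface.posterior is None:
        raise ValueError("CCT needs a posterior surface")
    nx, ny = surface.anterior.shape
    cx, cy = center if center is not None else ((nx - 1) // 2, (ny - 1) // 2)
    dx = int(round(offset_mm / lateral_spacing_mm_x))
    dy = int(round(offset_mm / lateral_spacing_mm_y))
    points = {
        "center": (cx, cy),
        "+x": (cx + dx, cy),
        "-x": (cx - dx, cy),
        "+y": (cx, cy + dy),
        "-y": (cx, cy - dy),
    }
    bad = [
        name
        for name, (x, y) in points.items()
        if not (0 <= x < nx and 0 <= y < ny and surface.valid_mask[x, y])
    ]
    if bad:
        raise ValueError(f"CCT sample points invalid or off-grid: {bad}")
    thickness = [
        (surface.posterior[x, y] - surface.anterior[x, y]) for x, y in points.values()
    ]
    return float(np.mean(thickness) * axial_spacing_um)


def percent_scar_area(cornea_mask_2d: np.ndarray, scar_mask_2d: np.ndarray) -> float:
    """En-face scarred-area percentage: 100 * |scar| / |cornea|."""
    cornea = np.asarray(cornea_mask_2d, dtype=bool)
    scar = np.asarray(scar_mask_2d, dtype=bool)
    if cornea.shape != scar.shape:
        raise ValueError("mask shapes differ")
    if not cornea.any():
        raise ValueError("empty cornea mask")
    if (scar & ~cornea).any():
        raise ValueError("scar mask extends outside the cornea mask")
    return 100.0 * scar.sum() / cornea.sum()
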