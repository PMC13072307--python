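"""End-to-end composition of the geometry and segmentation stages."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.filters import threshold_otsu

from . import geometry, segmentation
from .geometry import ButtonRegion, SurfaceMap
from .segmentation import OpacityMeasurement, ThresholdModel
from .volio import OctVolume

__all__ = ["PipelineConfig", "PreprocessResult", "preprocess_volume",
           "calibrate_pipeline", "quantify_volume"]

log = logging.getLogger("octquant")


@dataclass
class PipelineConfig:
    """Geometry + calibration parameters for a full quantification run."""

    button_radius_mm: float = 1.0
    button_center: Optional[tuple[int, int]] = None
    anterior_fraction: float = 2.0 / 3.0
    ref_row: Optional[int] = None  # None: anchor at the shallowest surface point
    jitter_window_px: int = 10
    specular_band: Optional[tuple[int, int]] = None  # None: auto-detect
    median_window: int = 5
    opacity_percentile: float = 99.0
    calibration_method: str = "percentile"
    k_sd: float = 3.0
    surface_threshold: Optional[float] = None  # None: t_button (or Otsu bootstrap)
    fallback_trim_px: Optional[int] = None
    measure_cct: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.button_radius_mm <= 0:
            raise ValueError("button_radius_mm must be > 0")
        if not 0 < self.anterior_fraction <= 1:
            raise ValueError("anterior_fraction must be in (0, 1]")
        if self.jitter_window_px < 0:
            raise ValueError("jitter_window_px must be >= 0")


@dataclass
class PreprocessResult:
    volume: OctVolume
    surface: SurfaceMap
    shifts: np.ndarray
    ref_row: int
    t_surface: float
    cct_um: Optional[float] = None


def _cct_center(surface: SurfaceMap) -> tuple[int, int]:
    """Apex-most valid A-scan nearest the grid center.

    The exact apex column can be invalid after specular clearing, so the
    thickness sampling center is moved to the closest valid column at the
    shallowest detected surface depth.
    """
    nx, ny = surface.anterior.shape
    v = surface.valid_mask
    if not v.any():
        raise ValueError("no valid A-scans for CCT")
    zmin = surface.anterior[v].min()
    apex = v & (surface.anterior <= zmin + 1)
    xs, ys = np.nonzero(apex)
    d2 = (xs - (nx - 1) / 2) ** 2 + (ys - (ny - 1) / 2) ** 2
    i = int(np.argmin(d2))
    return int(xs[i]), int(ys[i])


def _surface_threshold(vol: OctVolume, cfg: PipelineConfig,
                       model: ThresholdModel | None) -> float:
    if cfg.surface_threshold is not None:
        return cfg.surface_threshold
    if model is not None:
        return model.t_button
    # calibration bootstrap: no button threshold exists yet
    return float(threshold_otsu(vol.intensities[vol.intensities > 0]))


def preprocess_volume(
    vol: OctVolume,
    cfg: PipelineConfig | None = None,
    model: ThresholdModel | None = None,
) -> PreprocessResult:
    """register -> crop -> despecular -> surface -> flatten -> trim.

    The surface threshold defaults to the calibrated button threshold; during
    calibration (no model yet) an Otsu bootstrap on nonzero voxels is used.
    """
    cfg = cfg or PipelineConfig()
    registered, shifts = geometry.register_bscans(vol, cfg.jitter_window_px)
    log.info("registered %s: max |shift| = %d px", vol.eye_id, np.abs(shifts).max())

    region = ButtonRegion(
        center_x=None if cfg.button_center is None else cfg.button_center[0],
        center_y=None if cfg.button_center is None else cfg.button_center[1],
        radius_mm=cfg.button_radius_mm,
        anterior_fraction=cfg.anterior_fraction,
    )
    cropped = geometry.crop_button(registered, region)
    cleared = geometry.remove_specular(cropped, band=cfg.specular_band)

    t_surface = _surface_threshold(cleared, cfg, model)
    surface = geometry.detect_surface(cleared, t_surface, cfg.median_window)
    ref_row = (
        cfg.ref_row
        if cfg.ref_row is not None
        else int(surface.anterior[surface.valid_mask].min())
    )
    flat = geometry.flatten_volume(cleared, surface, ref_row)
    trimmed = geometry.trim_anterior_fraction(
        flat, surface, ref_row, cfg.anterior_fraction, cfg.fallback_trim_px
    )
    log.info(
        "%s: t_surface=%.2f ref_row=%d thickness=%.1f px",
        vol.eye_id, t_surface, ref_row, surface.thickness_px(),
    )

    cct = None
    if cfg.measure_cct:
        try:
            cct = segmentation.measure_cct(
                surface,
                vol.axial_spacing_um,
                vol.lateral_spacing_mm_x,
                vol.lateral_spacing_mm_y,
                center=_cct_center(surface),
            )
        except ValueError as exc:
            log.warning("CCT unavailable for %s: %s", vol.eye_id, exc)
    return PreprocessResult(
        volume=trimmed, surface=surface, shifts=shifts,
        ref_row=ref_row, t_surface=t_surface, cct_um=cct,
    )


def calibrate_pipeline(
    button_cohort: Sequence[OctVolume],
    naive_cohort: Sequence[OctVolume],
    cfg: PipelineConfig | None = None,
) -> ThresholdModel:
    """Preprocess both scar-free cohorts and calibrate the dual thresholds."""
    cfg = cfg or PipelineConfig()
    prepped_button = [preprocess_volume(v, cfg).volume for v in button_cohort]
    prepped_naive = [preprocess_volume(v, cfg).volume for v in naive_cohort]
    model = segmentation.calibrate_thresholds(
        prepped_button,
        prepped_naive,
        opacity_percentile=cfg.opacity_percentile,
        method=cfg.calibration_method,
        k_sd=cfg.k_sd,
    )
    log.info("calibrated: t_button=%.2f t_opacity=%.2f", model.t_button, model.t_opacity)
    return model


def quantify_volume(
    vol: OctVolume,
    model: ThresholdModel,
    cfg: PipelineConfig | None = None,
) -> OpacityMeasurement:
    """Full preprocessing + dual-threshold measurement for one volume."""
    cfg = cfg or PipelineConfig()
    prep = preprocess_volume(vol, cfg, model=model)
    return segmentation.measure_opacity(
        prep.volume, model, eye_id=vol.eye_id,
        timepoint_label=vol.timepoint_label, cct_um=prep.cct_um,
    )
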