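"""Geometric preprocessing of corneal OCT volumes.

Pipeline order: B-scan motion correction -> corneal-button cropping ->
specular-stripe clearing -> anterior-surface detection -> surface-referenced
flattening -> anterior-fraction trim.  All axial shifts are integer-only so
intensity histograms (and hence threshold semantics downstream) are
preserved exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .volio import OctVolume

__all__ = [
    "SurfaceMap",
    "ButtonRegion",
    "register_bscans",
    "crop_button",
    "remove_specular",
    "detect_surface",
    "flatten_volume",
    "trim_anterior_fraction",
    "shift_bscans",
    "shift_columns",
]


@dataclass
class SurfaceMap:
    """Per-(x, y) axial indices of the corneal surfaces.

    ``anterior[x, y]`` is the first corneal voxel; ``posterior[x, y]`` is an
    *exclusive* bound (one past the last corneal voxel), so
    ``posterior - anterior`` is the corneal thickness in voxels and an empty
    column would have ``anterior == posterior``.  Entries are meaningful only
    where ``valid_mask`` is True.
    """

    anterior: np.ndarray
    posterior: Optional[np.ndarray]
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.anterior.shape != self.valid_mask.shape:
            raise ValueError("anterior and valid_mask shapes differ")
        v = self.valid_mask
        if v.any() and (self.anterior[v] < 0).any():
            raise ValueError("anterior indices must be >= 0 where valid")
        if self.posterior is not None and v.any():
            if (self.posterior[v] < self.anterior[v]).any():
                raise ValueError("posterior must be >= anterior where valid")

    def thickness_px(self) -> float:
        """Median corneal thickness (voxels) over valid A-scans."""
        if self.posterior is None:
            raise ValueError("no posterior surface available")
        v = self.valid_mask
        if not v.any():
            raise ValueError("no valid A-scans")
        return float(np.median(self.posterior[v] - self.anterior[v]))


@dataclass
class ButtonRegion:
    """Cylindrical analysis region (axis along z)."""

    center_x: Optional[int] = None
    center_y: Optional[int] = None
    radius_mm: float = 1.0
    anterior_fraction: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")
        if not 0 < self.anterior_fraction <= 1:
            raise ValueError("anterior_fraction must be in (0, 1]")


# ---------------------------------------------------------------------------
# axial shift primitives


def shift_bscans(arr: np.ndarray, shifts: Sequence[int]) -> np.ndarray:
    """Rigid integer axial shift of each (z, x) B-scan with zero fill.

    Positive shift moves content toward larger z (deeper).
    """
    out = np.zeros_like(arr)
    nz = arr.shape[0]
    for y, s in enumerate(shifts):
        s = int(s)
        if abs(s) >= nz:
            continue
        if s == 0:
            out[:, :, y] = arr[:, :, y]
        elif s > 0:
            out[s:, :, y] = arr[: nz - s, :, y]
        else:
            out[:s, :, y] = arr[-s:, :, y]
    return out


def shift_columns(arr: np.ndarray, shift_xy: np.ndarray) -> np.ndarray:
    """Integer axial shift of each A-scan column with zero fill.

    ``shift_xy[x, y]`` positive moves the column content deeper.
    """
    nz, nx, ny = arr.shape
    out = np.zeros_like(arr)
    for x in range(nx):
        for y in range(ny):
            s = int(shift_xy[x, y])
            if abs(s) >= nz:
                continue
            if s == 0:
                out[:, x, y] = arr[:, x, y]
            elif s > 0:
                out[s:, x, y] = arr[: nz - s, x, y]
            else:
                out[:s, x, y] = arr[-s:, x, y]
    return out


# ---------------------------------------------------------------------------
# motion correction


def _ncc_best_shift(ref: np.ndarray, img: np.ndarray, window: int) -> int:
    """Integer axial shift of B-scan ``img`` maximizing normalized
    cross-correlation with B-scan ``ref`` over the overlapping rows; ties
    break toward smaller |shift|.

    Correlating the full (z, x) B-scans rather than their mean A-line
    profiles keeps the per-column band edges sharp: averaging across a
    curved surface smears the axial profile and makes it insensitive to
    single-pixel shifts.
    """
    nz = ref.shape[0]
    best_r, best_s = -np.inf, 0
    for s in sorted(range(-window, window + 1), key=abs):
        lo, hi = max(0, s), nz + min(0, s)
        if hi - lo < 8:
            continue
        a = ref[lo:hi].ravel()
        b = img[lo - s : hi - s].ravel()
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            continue
        r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
        if r > best_r + 1e-12:
            best_r, best_s = r, s
    return best_s


def register_bscans(
    vol: OctVolume, jitter_window_px: int = 10
) -> tuple[OctVolume, np.ndarray]:
    """Axially register B-scans against a running reference.

    Each B-scan is rigidly shifted by the integer found by maximizing
    normalized cross-correlation against the previous *registered* B-scan
    over shifts in ``+-jitter_window_px``; the first B-scan anchors the chain
    at shift 0.  Returns the corrected volume and the corrections applied
    (one per B-scan).  A flat (zero-variance) B-scan gets correction 0 with a
    warning.
    """
    arr = vol.intensities
    ny = arr.shape[2]
    if ny < 2:
        raise ValueError("registration needs >= 2 B-scans")
    corrections = np.zeros(ny, dtype=int)
    work = arr.astype(float)
    ref = work[:, :, 0]
    nz = arr.shape[0]
    for y in range(1, ny):
        img = work[:, :, y]
        if img.std() == 0 or ref.std() == 0:
            warnings.warn(f"flat B-scan {y}; correction 0")
            s = 0
        else:
            s = _ncc_best_shift(ref, img, jitter_window_px)
        corrections[y] = s
        # running reference = this B-scan after correction
        shifted = np.zeros_like(img)
        if s == 0:
            shifted = img
        elif s > 0:
            shifted[s:] = img[: nz - s]
        else:
            shifted[:s] = img[-s:]
        ref = shifted
    out = shift_bscans(arr, corrections)
    return vol.with_intensities(out), corrections


# ---------------------------------------------------------------------------
# button crop


def _auto_center(arr: np.ndarray) -> tuple[int, int]:
    """Centroid of the brightest-surface columns (the apex)."""
    colmax = arr.max(axis=0).astype(float)  # (x, y)
    thresh = np.percentile(colmax, 99)
    sel = colmax >= thresh
    xs, ys = np.nonzero(sel)
    return int(round(xs.mean())), int(round(ys.mean()))


def crop_button(vol: OctVolume, region: ButtonRegion | None = None) -> OctVolume:
    """Zero out voxels outside a cylindrical corneal button.

    Grid dimensions are unchanged.  An omitted center is auto-placed at the
    centroid of the brightest-surface voxels (the apex).
    """
    region = region or ButtonRegion()
    arr = vol.intensities
    _, nx, ny = arr.shape
    cx = region.center_x if region.center_x is not None else None
    cy = region.center_y if region.center_y is not None else None
    if cx is None or cy is None:
        ax, ay = _auto_center(arr)
        cx = ax if cx is None else cx
        cy = ay if cy is None else cy
    dx_mm = (np.arange(nx) - cx) * vol.lateral_spacing_mm_x
    dy_mm = (np.arange(ny) - cy) * vol.lateral_spacing_mm_y
    inside = dx_mm[:, None] ** 2 + dy_mm[None, :] ** 2 <= region.radius_mm**2
    if not inside.any():
        raise ValueError(
            f"button cylinder (center=({cx},{cy}), r={region.radius_mm} mm) "
            "lies wholly outside the grid"
        )
    out = arr * inside[None, :, :].astype(arr.dtype)
    return vol.with_intensities(out)


# ---------------------------------------------------------------------------
# specular artifact


def _detect_specular_band(
    arr: np.ndarray, sat_percentile: float, min_bscan_frac: float
) -> tuple[int, int] | None:
    colmax = arr.max(axis=0)  # (x, y)
    sat = float(np.percentile(arr, sat_percentile))
    # a genuine saturation stripe clips at the top of the intensity range:
    # if the upper percentile sits well below the volume maximum there is no
    # saturated band (keeps the operation idempotent after clearing)
    if sat < 0.98 * float(arr.max()):
        return None
    frac = (colmax >= sat).mean(axis=1)  # per column, over B-scans
    candidates = frac >= min_bscan_frac
    if not candidates.any():
        return None
    # largest contiguous run of candidate columns
    labels, nlab = ndimage.label(candidates)
    sizes = ndimage.sum_labels(candidates, labels, index=range(1, nlab + 1))
    best = int(np.argmax(sizes)) + 1
    cols = np.nonzero(labels == best)[0]
    return int(cols[0]), int(cols[-1])


def remove_specular(
    vol: OctVolume,
    band: tuple[int, int] | None = None,
    sat_percentile: float = 99.5,
    min_bscan_frac: float = 0.8,
) -> OctVolume:
    """Clear the constant-size specular stripe throughout the volume.

    ``band`` is ``(column_center, half_width_px)``; when omitted, the stripe
    is auto-detected as the contiguous group of columns whose maximum
    intensity saturates (>= the ``sat_percentile`` of the volume) in at least
    ``min_bscan_frac`` of B-scans.  Idempotent; no-op with a warning if
    nothing saturates.
    """
    arr = vol.intensities
    nx = arr.shape[1]
    if band is not None:
        center, hw = band
        if hw < 0 or not 0 <= center < nx:
            raise ValueError(f"specular band {band} outside x-range [0, {nx})")
        lo, hi = max(0, center - hw), min(nx - 1, center + hw)
    else:
        found = _detect_specular_band(arr, sat_percentile, min_bscan_frac)
        if found is None:
            warnings.warn("no saturated specular band detected; volume unchanged")
            return vol.with_intensities(arr.copy())
        lo, hi = found
    out = arr.copy()
    out[:, lo : hi + 1, :] = 0
    return vol.with_intensities(out)


# ---------------------------------------------------------------------------
# surface detection


def _nanmedian_filter(img: np.ndarray, size: int) -> np.ndarray:
    """Median filter ignoring NaNs (window ``size`` x ``size``)."""
    pad = size // 2
    padded = np.pad(img, pad, mode="constant", constant_values=np.nan)
    win = np.lib.stride_tricks.sliding_window_view(padded, (size, size))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        return np.nanmedian(win.reshape(*img.shape, -1), axis=-1)


def detect_surface(
    vol: OctVolume,
    t_surface: float,
    median_window: int = 5,
    min_valid_frac: float = 0.5,
) -> SurfaceMap:
    """Detect the anterior (and posterior) corneal surface.

    The volume is binarized at ``t_surface`` and reduced to its largest 3D
    connected component — an automated stand-in for manual cleanup of
    residual reflections in a 3D viewer.  Per A-scan, the anterior index is
    the first suprathreshold voxel of that component and the posterior bound
    is one past the last; both maps are smoothed with a 2D median filter.
    A-scans whose column is entirely zero (cropped/cleared regions) are
    excluded from the validity quorum.
    """
    arr = vol.intensities
    nz, nx, ny = arr.shape
    binary = arr >= t_surface
    if not binary.any():
        raise ValueError("surface not found: no voxel reaches t_surface")
    # bridge the cleared specular stripe along x so the shell stays one piece;
    # restricting to the labeled component also drops isolated specks that
    # the closing erased
    structure = np.ones((1, 9, 1))
    closed = ndimage.binary_erosion(
        ndimage.binary_dilation(binary, structure=structure),
        structure=structure,
        border_value=1,  # do not eat the grid edges
    )
    labels, nlab = ndimage.label(closed)
    if nlab == 0:
        raise ValueError("surface not found: nothing survives component cleanup")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    binary = binary & (labels == sizes.argmax())

    valid = binary.any(axis=0)  # (x, y)
    considered = arr.any(axis=0)  # non-empty columns only
    denom = int(considered.sum())
    if denom == 0 or valid.sum() / denom < min_valid_frac:
        raise ValueError(
            f"surface not found: only {int(valid.sum())}/{denom} usable A-scans "
            "have a threshold crossing"
        )

    zgrid = np.arange(nz)[:, None, None]
    anterior = np.where(valid, binary.argmax(axis=0), 0)
    last = np.where(valid, nz - 1 - binary[::-1].argmax(axis=0), -1)
    posterior = last + 1  # exclusive bound

    # median-smooth the maps, but only where the full window is valid:
    # at the validity rim the one-sided window would drag steep surface
    # values toward the interior
    ant_f = np.where(valid, anterior.astype(float), np.nan)
    post_f = np.where(valid, posterior.astype(float), np.nan)
    ant_s = np.round(_nanmedian_filter(ant_f, median_window))
    post_s = np.round(_nanmedian_filter(post_f, median_window))
    full = (
        ndimage.uniform_filter(
            valid.astype(float), size=median_window, mode="constant"
        )
        > 1.0 - 0.5 / median_window**2
    )
    anterior = np.where(full, ant_s, anterior).astype(int)
    posterior_sm = np.where(full, np.maximum(post_s, ant_s), posterior).astype(int)
    anterior[~valid] = 0
    posterior_sm[~valid] = 0
    return SurfaceMap(anterior=anterior, posterior=posterior_sm, valid_mask=valid)


# ---------------------------------------------------------------------------
# flattening and trimming


def flatten_volume(vol: OctVolume, surface: SurfaceMap, ref_row: int) -> OctVolume:
    """Shift each A-scan so the anterior surface lands on ``ref_row``.

    Integer shifts with zero fill; invalid A-scans are left untouched.  With
    enough axial headroom the corneal voxel content of each column is
    preserved exactly.
    """
    arr = vol.intensities
    nz = arr.shape[0]
    if not 0 <= ref_row < nz:
        raise ValueError(f"ref_row {ref_row} outside depth range [0, {nz})")
    shifts = np.where(surface.valid_mask, ref_row - surface.anterior, 0)
    out = shift_columns(arr, shifts)
    # untouched (invalid) columns keep their content
    inv = ~surface.valid_mask
    if inv.any():
        out[:, inv] = arr[:, inv]
    return vol.with_intensities(out)


def trim_anterior_fraction(
    vol: OctVolume,
    surface: SurfaceMap,
    ref_row: int,
    fraction: float = 2.0 / 3.0,
    fallback_trim_px: int | None = None,
) -> OctVolume:
    """Zero all voxels deeper than ``ref_row + fraction * median thickness``.

    Run on a *flattened* volume; removes posterior stroma plus any iris/lens
    clutter, which lies entirely below the trim plane after flattening.  If
    the posterior surface (hence thickness) is unavailable, falls back to a
    fixed-depth trim with a warning.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    try:
        thickness = surface.thickness_px()
    except ValueError:
        if fallback_trim_px is None:
            raise ValueError(
                "corneal thickness undeterminable and no fallback_trim_px given"
            )
        warnings.warn(
            f"thickness undeterminable; fixed-depth trim at ref_row + {fallback_trim_px}"
        )
        thickness = None
    plane = (
        ref_row + int(round(fraction * thickness))
        if thickness is not None
        else ref_row + fallback_trim_px
    )
    arr = vol.intensities.copy()
    if plane < arr.shape[0] - 1:
        arr[plane + 1 :, :, :] = 0
    return vol.with_intensities(arr)
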