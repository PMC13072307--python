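"""Synthetic OCT-like corneal phantoms and rater tables with known truth.

The generator renders a curved hyperreflective stromal shell over a
hyporeflective background, then layers on the artifact inventory of a real
anterior-segment scan: multiplicative speckle, depth-dependent signal
falloff, per-B-scan axial jitter (heartbeat/respiration), a saturated
specular stripe at the apex, and posterior iris/lens-like clutter.  An
ellipsoidal hyperreflective inclusion of known voxel volume plays the role
of a stromal scar.

Ground truth (``PhantomTruth``) is computed analytically from the geometry
*before* any noise is applied and is stored in the motion-free frame: the
masks of two phantoms that share geometry are identical regardless of seed,
and the injected per-B-scan shifts are reported separately so callers can
map between frames.

By default the anterior surface curves along the fast (x) axis only and is
constant across B-scans.  With curvature along the slow axis, smooth
physiological jitter and slow-axis geometry are confounded and no
registration scheme can recover the injected shifts exactly; a full
spherical cap is available via ``spherical=True`` for surface-detection
work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .volio import OctVolume, RatingTable

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "RatingSpec",
    "generate_phantom",
    "generate_naive_cohort",
    "generate_rating_table",
    "scar_spec_for_fraction",
    "true_icc_single",
]


@dataclass
class PhantomSpec:
    """Parameters of a synthetic corneal volume.

    ``scar`` is ``((center_x_px, center_y_px, depth_below_surface_px),
    (semi_x_px, semi_y_px, semi_z_px), intensity_offset)``; the inclusion is
    an ellipsoid in the surface-referenced (flattened) frame, i.e. it follows
    the stromal layers, which lets large scar fractions fit inside the curved
    shell while keeping the analytic ellipsoid voxel volume.

    ``specular`` is ``(column_center or None, half_width_px, intensity)``;
    ``None`` as center means the apex column.  Set ``specular=None`` to
    disable.
    """

    grid_dims: tuple[int, int, int] = (256, 200, 40)  # (depth, ascans, bscans)
    lateral_extent_mm: float = 4.0
    axial_spacing_um: float = 2.0
    apex_depth_px: int = 30
    curvature_radius_mm: float = 4.5
    thickness_um: float = 100.0
    background_level: float = 30.0
    stroma_level: float = 120.0
    speckle_sd: float = 0.10
    falloff_per_px: float = 0.0008
    specular: Optional[tuple] = (None, 2, 255.0)
    jitter_amplitude_px: int = 4
    scar: Optional[tuple] = None
    posterior_clutter: bool = False
    clutter_level: float = 90.0
    spherical: bool = False
    bit_depth: int = 8
    seed: int = 0

    # -- derived geometry --------------------------------------------------
    @property
    def depth_px(self) -> int:
        return self.grid_dims[0]

    @property
    def ascans_px(self) -> int:
        return self.grid_dims[1]

    @property
    def bscans_px(self) -> int:
        return self.grid_dims[2]

    @property
    def lateral_spacing_mm_x(self) -> float:
        return self.lateral_extent_mm / self.ascans_px

    @property
    def lateral_spacing_mm_y(self) -> float:
        return self.lateral_extent_mm / self.bscans_px

    @property
    def thickness_px(self) -> int:
        return int(round(self.thickness_um / self.axial_spacing_um))

    def sag_px(self, r_mm: np.ndarray | float) -> np.ndarray | float:
        """Axial sag of the anterior sphere at lateral distance ``r_mm``.

        Beyond the sphere radius the sag is +inf (no surface).
        """
        R = self.curvature_radius_mm
        r = np.asarray(r_mm, dtype=float)
        inside = r < R
        sag_mm = np.where(inside, R - np.sqrt(np.maximum(R * R - r * r, 0.0)), np.inf)
        out = sag_mm * 1000.0 / self.axial_spacing_um
        return out if out.ndim else float(out)

    def validate(self) -> None:
        nz, nx, ny = self.grid_dims
        if min(nz, nx, ny) <= 0:
            raise ValueError(f"grid_dims must be positive, got {self.grid_dims}")
        if self.lateral_extent_mm <= 0 or self.axial_spacing_um <= 0:
            raise ValueError("spacings/extents must be > 0")
        if self.curvature_radius_mm <= 0 or self.thickness_um <= 0:
            raise ValueError("curvature radius and thickness must be > 0")
        if self.jitter_amplitude_px < 0:
            raise ValueError("jitter_amplitude_px must be >= 0")
        if self.speckle_sd < 0 or self.falloff_per_px < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        vmax = 255.0 if self.bit_depth == 8 else 65535.0
        for name in ("background_level", "stroma_level", "clutter_level"):
            v = getattr(self, name)
            if not 0 <= v <= vmax:
                raise ValueError(f"{name}={v} outside representable range [0, {vmax}]")
        floor = self.apex_depth_px + self.thickness_px + self.jitter_amplitude_px
        if not 0 <= self.apex_depth_px < nz:
            raise ValueError(f"apex_depth_px={self.apex_depth_px} outside depth range")
        if floor > nz - 1:
            raise ValueError(
                f"apex_depth_px + thickness ({self.thickness_px} px) + jitter "
                f"margin = {floor} exceeds grid depth {nz}"
            )
        if self.specular is not None:
            _, hw, _ = self.specular
            if hw < 0:
                raise ValueError("specular half width must be >= 0")
        if self.scar is not None:
            (cx, cy, _), (a, b, c), _ = self.scar
            if min(a, b, c) <= 0:
                raise ValueError("scar semi-axes must be > 0")
            if not (0 <= cx < nx and 0 <= cy < ny):
                raise ValueError("scar center outside lateral grid")


@dataclass
class PhantomTruth:
    """Analytic ground truth for one phantom, in the motion-free frame."""

    cornea_mask: np.ndarray
    scar_mask: np.ndarray
    true_percent_opacity: float
    applied_shifts: np.ndarray
    anterior_surface_true: np.ndarray  # float (x, y), NaN where no cornea
    clutter_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.scar_mask & ~self.cornea_mask).any():
            raise ValueError("scar_mask must be a subset of cornea_mask")
        if not 0.0 <= self.true_percent_opacity <= 100.0:
            raise ValueError("true_percent_opacity outside [0, 100]")


@dataclass
class RatingSpec:
    """Two-way random-effects sampling design for synthetic rater tables.

    ``y_ij = grand_mean + subject_i + rater_j + e_ij`` with independent
    centered normal components; the true single-measure absolute-agreement
    ICC is ``subject_sd**2 / (subject_sd**2 + rater_sd**2 + error_sd**2)``.
    """

    n_subjects: int = 12
    n_raters: int = 2
    subject_sd: float = 3.0
    rater_sd: float = 1.0
    error_sd: float = 1.0
    grand_mean: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2 or self.n_raters < 2:
            raise ValueError("need n_subjects >= 2 and n_raters >= 2")
        if min(self.subject_sd, self.rater_sd, self.error_sd) < 0:
            raise ValueError("standard deviations must be >= 0")


def true_icc_single(spec: RatingSpec) -> float:
    """Population ICC(A,1) implied by a :class:`RatingSpec`."""
    num = spec.subject_sd**2
    den = spec.subject_sd**2 + spec.rater_sd**2 + spec.error_sd**2
    if den == 0:
        raise ValueError("all variance components are zero; ICC undefined")
    return num / den


# ---------------------------------------------------------------------------
# geometry rendering


def _anterior_surface(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Integer anterior-surface depth per (x, y) and validity mask."""
    nz, nx, ny = spec.grid_dims
    sx, sy = spec.lateral_spacing_mm_x, spec.lateral_spacing_mm_y
    x_mm = (np.arange(nx) - (nx - 1) / 2.0) * sx
    y_mm = (np.arange(ny) - (ny - 1) / 2.0) * sy
    if spec.spherical:
        r = np.sqrt(x_mm[:, None] ** 2 + y_mm[None, :] ** 2)
    else:
        r = np.abs(x_mm)[:, None] * np.ones((1, ny))
    sag = spec.sag_px(r)
    z_ant = spec.apex_depth_px + sag
    valid = np.isfinite(z_ant) & (
        np.round(z_ant) + spec.thickness_px + spec.jitter_amplitude_px <= nz - 1
    )
    z_int = np.where(valid, np.round(z_ant), -1).astype(int)
    return z_int, valid


def _masks(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    nz, nx, ny = spec.grid_dims
    z_int, valid = _anterior_surface(spec)
    zgrid = np.arange(nz)[:, None, None]
    cornea = valid[None, :, :] & (zgrid >= z_int[None, :, :]) & (
        zgrid < z_int[None, :, :] + spec.thickness_px
    )

    scar = np.zeros_like(cornea)
    if spec.scar is not None:
        (cx, cy, dz), (a, b, c), _ = spec.scar
        xs = np.arange(nx)[None, :, None]
        ys = np.arange(ny)[None, None, :]
        # ellipsoid in the surface-referenced frame, sheared by the surface
        z_rel = zgrid - z_int[None, :, :]
        q = (
            ((xs - cx) / a) ** 2
            + ((ys - cy) / b) ** 2
            + ((z_rel - dz) / c) ** 2
        )
        scar = (q <= 1.0) & valid[None, :, :]
        if (scar & ~cornea).any():
            raise ValueError(
                "scar ellipsoid extends outside the stromal shell; shrink its "
                "semi-axes or move its center"
            )

    surf = np.where(valid, z_int, np.nan).astype(float)
    return cornea, scar, surf, valid


def _jitter(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smoothed random-walk axial shift per B-scan, first B-scan anchored at 0."""
    ny = spec.bscans_px
    if spec.jitter_amplitude_px == 0:
        return np.zeros(ny, dtype=int)
    walk = np.cumsum(rng.normal(size=ny))
    walk = gaussian_filter1d(walk, sigma=2.0, mode="nearest")
    walk -= walk[0]
    peak = np.abs(walk).max()
    if peak > 0:
        walk *= spec.jitter_amplitude_px / peak
    return np.round(walk).astype(int)


def _shift_bscans(arr: np.ndarray, shifts: Sequence[int], fill=0) -> np.ndarray:
    """Rigidly shift each (z, x) B-scan axially; positive shift moves content
    to larger z. Vacated rows are filled with ``fill``."""
    out = np.full_like(arr, fill)
    nz = arr.shape[0]
    for y, s in enumerate(shifts):
        s = int(s)
        if s == 0:
            out[:, :, y] = arr[:, :, y]
        elif s > 0:
            out[s:, :, y] = arr[: nz - s, :, y]
        else:
            out[:s, :, y] = arr[-s:, :, y]
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[OctVolume, PhantomTruth]:
    """Render one phantom volume and its analytic ground truth.

    Deterministic for a fixed ``spec.seed``.  Rendering order: shell and scar
    levels, axial falloff, multiplicative speckle, per-B-scan jitter, then
    posterior clutter and the specular stripe overlaid last.
    """
    spec.validate()
    nz, nx, ny = spec.grid_dims
    rng = np.random.default_rng(spec.seed)

    cornea, scar, surf, valid = _masks(spec)

    img = np.full(spec.grid_dims, spec.background_level, dtype=float)
    img[cornea] = spec.stroma_level
    if spec.scar is not None:
        img[scar] = spec.stroma_level + spec.scar[2]  # scar intensity offset

    falloff = np.exp(-spec.falloff_per_px * np.arange(nz))[:, None, None]
    img *= falloff
    if spec.speckle_sd > 0:
        sd = spec.speckle_sd
        img *= rng.lognormal(mean=-0.5 * sd * sd, sigma=sd, size=spec.grid_dims)

    shifts = _jitter(spec, rng)
    img = _shift_bscans(img, shifts)

    clutter = None
    if spec.posterior_clutter:
        clutter = _clutter_mask(spec)
        noise = (
            rng.lognormal(-0.5 * spec.speckle_sd**2, spec.speckle_sd, clutter.sum())
            if spec.speckle_sd > 0
            else 1.0
        )
        zs = np.nonzero(clutter)[0]
        img[clutter] = spec.clutter_level * np.exp(-spec.falloff_per_px * zs) * noise

    if spec.specular is not None:
        center, hw, intensity = spec.specular
        if center is None:
            center = (nx - 1) // 2
        lo, hi = max(0, center - hw), min(nx - 1, center + hw)
        img[:, lo : hi + 1, :] = intensity

    vmax = 255.0 if spec.bit_depth == 8 else 65535.0
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    quantized = np.clip(np.round(img), 0, vmax).astype(dtype)

    vol = OctVolume(
        intensities=quantized,
        axial_spacing_um=spec.axial_spacing_um,
        lateral_spacing_mm_x=spec.lateral_spacing_mm_x,
        lateral_spacing_mm_y=spec.lateral_spacing_mm_y,
    )
    n_cornea = int(cornea.sum())
    n_scar = int(scar.sum())
    truth = PhantomTruth(
        cornea_mask=cornea,
        scar_mask=scar,
        true_percent_opacity=100.0 * n_scar / n_cornea if n_cornea else 0.0,
        applied_shifts=shifts,
        anterior_surface_true=surf,
        clutter_mask=clutter,
    )
    return vol, truth


def _clutter_mask(spec: PhantomSpec) -> np.ndarray:
    """Iris/lens-like slab posterior to the cornea, central columns only."""
    nz, nx, ny = spec.grid_dims
    half_mm = min(1.0, spec.lateral_extent_mm / 4.0)
    half_px = int(round(half_mm / spec.lateral_spacing_mm_x))
    gap_px = 20
    z0 = spec.apex_depth_px + int(math.ceil(spec.sag_px(half_mm))) + spec.thickness_px
    z0 += gap_px + spec.jitter_amplitude_px
    if z0 >= nz - 4:
        raise ValueError(
            f"no axial room for posterior clutter: slab would start at z={z0} "
            f"in a {nz}-deep grid"
        )
    z1 = min(nz, z0 + 40)
    cx = (nx - 1) // 2
    mask = np.zeros(spec.grid_dims, dtype=bool)
    mask[z0:z1, max(0, cx - half_px) : cx + half_px + 1, :] = True
    return mask


def generate_naive_cohort(
    n: int, base_spec: PhantomSpec, seed: int = 0
) -> list[OctVolume]:
    """``n`` scar-free phantoms with identical geometry and per-volume seeds
    derived deterministically from ``seed``."""
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    if base_spec.scar is not None:
        raise ValueError("naive cohort spec must have scar=None")
    children = np.random.SeedSequence(seed).spawn(n)
    out = []
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0])
        vol, _ = generate_phantom(replace(base_spec, seed=sub_seed))
        vol.eye_id = f"naive{i:03d}"
        out.append(vol)
    return out


def scar_spec_for_fraction(
    base_spec: PhantomSpec,
    fraction_percent: float,
    intensity_offset: float = 70.0,
    depth_frac: float = 0.5,
) -> PhantomSpec:
    """Return a copy of ``base_spec`` carrying a centered scar whose analytic
    ellipsoid volume is ``fraction_percent`` of the corneal voxel count.

    The slow-axis (y) semi-axis is fixed at 42% of the B-scan count and the
    fast/axial semi-axes scale together at a fixed x:z aspect ratio, giving a
    wide, thin lens-shaped inclusion at every size (so the fixed-width
    specular stripe at the apex removes only a small, size-independent share
    of the scar).
    """
    if not 0 < fraction_percent < 100:
        raise ValueError("fraction_percent must be in (0, 100)")
    probe = replace(base_spec, scar=None)
    cornea, _, _, _ = _masks(probe)
    n_cornea = int(cornea.sum())
    aspect_xz = 4.6
    b = max(2.0, 0.42 * probe.bscans_px)
    c = max(
        2.0,
        math.sqrt(
            3.0 * fraction_percent / 100.0 * n_cornea / (4.0 * math.pi * aspect_xz * b)
        ),
    )
    a = aspect_xz * c
    cx, cy = (probe.ascans_px - 1) // 2, (probe.bscans_px - 1) // 2
    dz = depth_frac * probe.thickness_px
    spec = replace(
        base_spec, scar=((cx, cy, dz), (a, b, c), intensity_offset)
    )
    spec.validate()
    return spec


def generate_rating_table(spec: RatingSpec) -> RatingTable:
    """Draw a complete subjects x raters table from the additive two-way
    random-effects model; deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_subjects, spec.n_raters
    subjects = rng.normal(0.0, spec.subject_sd, size=n)
    raters = rng.normal(0.0, spec.rater_sd, size=k)
    errors = rng.normal(0.0, spec.error_sd, size=(n, k))
    values = spec.grand_mean + subjects[:, None] + raters[None, :] + errors
    values = np.maximum(values, 0.0)  # ratings are percentages, >= 0
    return RatingTable(values=values)
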