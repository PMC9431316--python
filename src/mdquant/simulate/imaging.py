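"""Synthetic fluorescence micrographs with known ground truth.

Renders equatorial cross-sections of yeast-like cells: a bright
elliptical membrane ring with a dimmer interior, carrying Gaussian
angular patches whose noiseless peak/valley intensity ratio equals the
requested contrast exactly.  Variants generate two-channel fields with a
controlled shared-patch fraction, time-lapse series with exponentially
decaying patch survival, and dye-uptake fields with a controlled
interior signal fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ..geometry import Ellipse, Field

__all__ = [
    "FieldParams",
    "CellTruth",
    "GroundTruth",
    "PlacementError",
    "generate_field",
    "generate_timelapse",
    "generate_coloc_pair",
    "generate_uptake_field",
    "ring_profile",
]

TWO_PI = 2.0 * np.pi
MAX_PLACEMENT_ATTEMPTS = 10_000


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap."""


@dataclass(frozen=True)
class FieldParams:
    """Parameters of one synthetic field.

    Intensities are in photons/pixel; sizes in micrometres unless the
    name says pixels.  ``patch_contrast`` is the true noiseless
    peak/valley ratio along the membrane ring.
    """

    n_cells: int = 8
    image_shape: tuple[int, int] = (320, 320)
    pixel_size_um: float = 0.1
    semi_axis_range_um: tuple[float, float] = (1.6, 2.4)
    pm_band_width_um: float = 0.5
    pm_intensity: float = 300.0
    pm_interior_ratio: float = 3.0
    patch_lambda: float = 6.0
    patch_count_fixed: bool = False
    patch_contrast: float = 2.0
    patch_angular_sigma_rad: float = 0.10
    min_patch_separation_rad: float = 0.5
    background: float = 20.0
    psf_sigma_um: float = 0.04
    read_noise_sd: float = 3.0
    poisson_noise: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        lo, hi = self.semi_axis_range_um
        if not (0 < lo <= hi):
            raise ValueError("semi_axis_range_um must satisfy 0 < min <= max")
        for name in ("pm_intensity", "background", "pm_band_width_um", "pixel_size_um"):
            if getattr(self, name) < 0 or (
                name in ("pm_band_width_um", "pixel_size_um") and getattr(self, name) <= 0
            ):
                raise ValueError(f"{name} must be non-negative (positive for sizes)")
        if self.pm_interior_ratio <= 0:
            raise ValueError("pm_interior_ratio must be > 0")
        if self.patch_contrast < 1:
            raise ValueError("patch_contrast must be >= 1")
        if self.patch_lambda < 0:
            raise ValueError("patch_lambda must be >= 0")
        if self.patch_angular_sigma_rad <= 0:
            raise ValueError("patch_angular_sigma_rad must be > 0")
        if self.min_patch_separation_rad < 0:
            raise ValueError("min_patch_separation_rad must be >= 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.psf_sigma_um < 0:
            raise ValueError("psf_sigma_um must be >= 0")

    def noiseless(self) -> "FieldParams":
        """Copy with photon and read noise switched off."""
        return replace(self, poisson_noise=False, read_noise_sd=0.0)


@dataclass
class CellTruth:
    """Ground truth for one rendered cell."""

    label: int
    center: tuple[float, float]  # (row, col), pixels
    semi_axes: tuple[float, float]  # (major, minor), pixels
    orientation: float  # radians
    patch_angles: np.ndarray  # radians in [0, 2pi)
    contrast: float
    pm_interior_ratio: float
    angular_sigma: float = 0.10  # angular width of each patch, radians
    ring_amplitude: float = 0.0  # amplitude multiplier of the bump sum
    ring_mean_factor: float = 1.0  # angular mean of the ring modulation
    patch_angles_ch2: np.ndarray | None = None
    patch_death_min: np.ndarray | None = None  # per-patch loss time (time-lapse)

    @property
    def true_patch_count(self) -> int:
        return self.patch_angles.size

    @property
    def true_pm_interior_ratio(self) -> float:
        """Expected mean-band over mean-interior intensity ratio.

        Patches raise the angular mean of the ring above its baseline, so
        the measurable ratio is the baseline ratio times the mean ring
        modulation factor.
        """
        return self.pm_interior_ratio * self.ring_mean_factor

    def ellipse(self) -> Ellipse:
        return Ellipse(self.center, self.semi_axes, self.orientation % np.pi)


@dataclass
class GroundTruth:
    """Ground truth for a whole synthetic field."""

    cells: list[CellTruth]
    pixel_size_um: float
    shared_fraction: float | None = None
    true_shift: tuple[int, int] | None = None
    half_life_min: float | None = None
    uptake_fraction: float | None = None
    frame_times_min: list[float] | None = None
    frame_patch_counts: np.ndarray | None = None  # (n_frames, n_cells)
    meta: dict = dc_field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label": c.label,
                "center_row": c.center[0],
                "center_col": c.center[1],
                "semi_major_px": c.semi_axes[0],
                "semi_minor_px": c.semi_axes[1],
                "orientation_rad": c.orientation,
                "true_patch_count": c.true_patch_count,
                "true_contrast": c.contrast,
                "true_pm_interior_ratio": c.true_pm_interior_ratio,
                "true_patch_angles": ";".join(f"{a:.6f}" for a in c.patch_angles),
            }
            for c in self.cells
        ]
        return pd.DataFrame(rows)


def _sample_separated_angles(rng: np.random.Generator, k: int, min_sep: float) -> np.ndarray:
    """k uniform angles on the circle with pairwise circular gaps >= min_sep.

    Uses the spacings construction (uniform points on the reduced
    circumference, then re-inflated), which is exact and rejection-free.
    """
    if k == 0:
        return np.array([])
    if k == 1:
        return np.array([rng.uniform(0, TWO_PI)])
    free = TWO_PI - k * min_sep
    if free <= 0:
        raise ValueError(
            f"cannot place {k} patches with minimum separation {min_sep:.3f} rad"
        )
    pts = np.sort(rng.uniform(0, free, size=k))
    angles = (pts + np.arange(k) * min_sep + rng.uniform(0, TWO_PI)) % TWO_PI
    return np.sort(angles)


def _bump_sum(theta: np.ndarray, angles: np.ndarray, sigma: float) -> np.ndarray:
    """Sum of wrapped Gaussian angular bumps of unit height."""
    if angles.size == 0:
        return np.zeros_like(theta)
    d = theta[..., None] - angles[None, :]
    d = (d + np.pi) % TWO_PI - np.pi
    return np.exp(-0.5 * (d / sigma) ** 2).sum(axis=-1)


def _solve_ring_amplitude(angles: np.ndarray, sigma: float, contrast: float) -> float:
    """Amplitude so the noiseless ring peak/valley ratio equals contrast.

    The ring intensity is ``base * (1 + a * m(theta))`` with m the bump
    sum; a is solved from the max and min of m on a dense grid so that
    ``(1 + a*max) / (1 + a*min) == contrast`` exactly.
    """
    if angles.size == 0 or contrast == 1.0:
        return 0.0
    grid = np.linspace(0, TWO_PI, 4096, endpoint=False)
    m = _bump_sum(grid, angles, sigma)
    m_max, m_min = float(m.max()), float(m.min())
    denom = m_max - contrast * m_min
    if denom <= 0:  # bumps overlap so much the requested ratio is unreachable
        raise ValueError(
            "patch bumps overlap too strongly for the requested contrast; "
            "increase min_patch_separation_rad or decrease patch_angular_sigma_rad"
        )
    return (contrast - 1.0) / denom


def ring_profile(cell: CellTruth, theta: np.ndarray, base: float = 1.0) -> np.ndarray:
    """Noiseless, blur-free ring intensity at parametric angles ``theta``."""
    m = _bump_sum(np.asarray(theta, dtype=float), cell.patch_angles, cell.angular_sigma)
    return base * (1.0 + cell.ring_amplitude * m)


def _place_cells(params: FieldParams, rng: np.random.Generator) -> list[CellTruth]:
    """Rejection-sample non-overlapping cell positions and shapes."""
    h, w = params.image_shape
    px = params.pixel_size_um
    lo, hi = (v / px for v in params.semi_axis_range_um)
    band_px = params.pm_band_width_um / px
    margin_extra = band_px + 3.0 * params.psf_sigma_um / px + 2.0
    cells: list[CellTruth] = []
    attempts = 0
    while len(cells) < params.n_cells:
        if attempts >= MAX_PLACEMENT_ATTEMPTS:
            raise PlacementError(
                f"placed only {len(cells)}/{params.n_cells} cells after "
                f"{MAX_PLACEMENT_ATTEMPTS} attempts; the requested cell density is "
                f"too high for image shape {params.image_shape}"
            )
        attempts += 1
        axes = np.sort(rng.uniform(lo, hi, size=2))[::-1]  # (major, minor)
        margin = axes[0] + margin_extra
        if 2 * margin >= min(h, w):
            raise PlacementError("cells are too large for the image shape")
        cy = rng.uniform(margin, h - 1 - margin)
        cx = rng.uniform(margin, w - 1 - margin)
        ok = True
        for c in cells:
            min_dist = axes[0] + c.semi_axes[0] + band_px + 2.0
            if np.hypot(cy - c.center[0], cx - c.center[1]) < min_dist:
                ok = False
                break
        if not ok:
            continue
        if params.patch_count_fixed:
            k = int(round(params.patch_lambda))
        else:
            k = int(rng.poisson(params.patch_lambda))
        if params.min_patch_separation_rad > 0:
            # the circle can only hold so many separated patches; truncate
            # (negligible for Poisson means used here)
            k = min(k, int(TWO_PI / params.min_patch_separation_rad) - 1)
        angles = _sample_separated_angles(rng, k, params.min_patch_separation_rad)
        amp = _solve_ring_amplitude(
            angles, params.patch_angular_sigma_rad, params.patch_contrast
        )
        grid = np.linspace(0, TWO_PI, 2048, endpoint=False)
        mean_factor = float(
            1.0 + amp * _bump_sum(grid, angles, params.patch_angular_sigma_rad).mean()
        )
        cells.append(
            CellTruth(
                label=len(cells) + 1,
                center=(float(cy), float(cx)),
                semi_axes=(float(axes[0]), float(axes[1])),
                orientation=float(rng.uniform(0, np.pi)),
                patch_angles=angles,
                contrast=params.patch_contrast,
                pm_interior_ratio=params.pm_interior_ratio,
                angular_sigma=params.patch_angular_sigma_rad,
                ring_amplitude=amp,
                ring_mean_factor=mean_factor,
            )
        )
    return cells


def _render_cell_signal(
    canvas: np.ndarray,
    cell: CellTruth,
    params: FieldParams,
    patch_angles: np.ndarray | None = None,
    ring_scale: float = 1.0,
    interior_value: float | None = None,
    center_offset: tuple[float, float] = (0.0, 0.0),
) -> None:
    """Add one cell's noiseless signal (ring + interior) to ``canvas``."""
    px = params.pixel_size_um
    band_half = 0.5 * params.pm_band_width_um / px
    cy = cell.center[0] + center_offset[0]
    cx = cell.center[1] + center_offset[1]
    a, b = cell.semi_axes
    phi = cell.orientation
    ext = int(np.ceil(a + band_half + 2))
    r0 = max(0, int(np.floor(cy)) - ext)
    r1 = min(canvas.shape[0], int(np.ceil(cy)) + ext + 1)
    c0 = max(0, int(np.floor(cx)) - ext)
    c1 = min(canvas.shape[1], int(np.ceil(cx)) + ext + 1)
    rows = np.arange(r0, r1)[:, None] - cy
    cols = np.arange(c0, c1)[None, :] - cx
    u = cols * np.cos(phi) + rows * np.sin(phi)
    v = -cols * np.sin(phi) + rows * np.cos(phi)
    rho = np.hypot(u / a, v / b)
    theta = np.arctan2(v / b, u / a)
    dist = (rho - 1.0) * np.hypot(a * np.cos(theta), b * np.sin(theta))

    ring = np.abs(dist) <= band_half
    interior = dist < -band_half

    angles = cell.patch_angles if patch_angles is None else patch_angles
    if angles.size and cell.contrast > 1.0:
        amp = _solve_ring_amplitude(angles, cell.angular_sigma, cell.contrast)
        m = _bump_sum(theta[ring], angles, cell.angular_sigma)
        ring_vals = params.pm_intensity * (1.0 + amp * m)
    else:
        ring_vals = np.full(int(ring.sum()), params.pm_intensity)
    if interior_value is None:
        interior_value = params.pm_intensity / params.pm_interior_ratio

    block = canvas[r0:r1, c0:c1]
    block[ring] += ring_scale * ring_vals
    block[interior] += interior_value


def _finalize_image(signal: np.ndarray, params: FieldParams, rng: np.random.Generator) -> np.ndarray:
    """Background + PSF blur + Poisson photon noise + Gaussian read noise."""
    img = signal + params.background
    psf_px = params.psf_sigma_um / params.pixel_size_um
    if psf_px > 0:
        img = gaussian_filter(img, psf_px)
    if params.poisson_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if params.read_noise_sd > 0:
        img = img + rng.normal(0.0, params.read_noise_sd, size=img.shape)
    return img


def _label_mask(cells: Sequence[CellTruth], shape: tuple[int, int]) -> np.ndarray:
    """Integer label mask whose edge bisects each cell's membrane ring."""
    mask = np.zeros(shape, dtype=np.int32)
    for cell in cells:
        cy, cx = cell.center
        a, b = cell.semi_axes
        phi = cell.orientation
        ext = int(np.ceil(a + 2))
        r0, r1 = max(0, int(cy) - ext), min(shape[0], int(cy) + ext + 1)
        c0, c1 = max(0, int(cx) - ext), min(shape[1], int(cx) + ext + 1)
        rows = np.arange(r0, r1)[:, None] - cy
        cols = np.arange(c0, c1)[None, :] - cx
        u = cols * np.cos(phi) + rows * np.sin(phi)
        v = -cols * np.sin(phi) + rows * np.cos(phi)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        mask[r0:r1, c0:c1][inside] = cell.label
    return mask


def generate_field(params: FieldParams) -> tuple[Field, np.ndarray, GroundTruth]:
    """Render one single-channel field of patched cells.

    Returns (field, label mask, ground truth); identical params and seed
    give bit-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    cells = _place_cells(params, rng)
    signal = np.zeros(params.image_shape, dtype=float)
    for cell in cells:
        _render_cell_signal(signal, cell, params)
    image = _finalize_image(signal, params, rng)
    field = Field(
        data=image[None, None],
        pixel_size_um=params.pixel_size_um,
        channel_names=["ch1"],
        meta={"seed": params.seed, "generator": "field"},
    )
    truth = GroundTruth(cells=cells, pixel_size_um=params.pixel_size_um)
    return field, _label_mask(cells, params.image_shape), truth


def generate_timelapse(
    params: FieldParams,
    n_frames: int,
    frame_interval_min: float,
    half_life_min: float,
) -> tuple[Field, np.ndarray, GroundTruth]:
    """Time-lapse in which each frame-0 patch survives to time t with
    probability 2**(-t/half_life); lost patches stay lost.

    ``half_life_min=np.inf`` disables decay.  Cells and the label mask
    are static across frames.
    """
    params.validate()
    if not half_life_min > 0:
        raise ValueError("half_life_min must be positive")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(params.seed)
    cells = _place_cells(params, rng)
    times = [i * frame_interval_min for i in range(n_frames)]

    # one uniform draw per patch; survival at t iff u <= 2^(-t/T), which is
    # monotone in t, so a lost patch never returns
    for cell in cells:
        u = rng.uniform(size=cell.true_patch_count)
        with np.errstate(divide="ignore"):
            cell.patch_death_min = np.where(
                u > 0, -half_life_min * np.log2(u), np.inf
            )

    frames = []
    counts = np.zeros((n_frames, len(cells)), dtype=int)
    for fi, t in enumerate(times):
        signal = np.zeros(params.image_shape, dtype=float)
        for ci, cell in enumerate(cells):
            alive = cell.patch_angles[cell.patch_death_min > t]
            counts[fi, ci] = alive.size
            _render_cell_signal(signal, cell, params, patch_angles=alive)
        frames.append(_finalize_image(signal, params, rng))

    field = Field(
        data=np.asarray(frames)[:, None],
        pixel_size_um=params.pixel_size_um,
        channel_names=["ch1"],
        frame_times_min=times,
        meta={"seed": params.seed, "generator": "timelapse", "half_life_min": half_life_min},
    )
    truth = GroundTruth(
        cells=cells,
        pixel_size_um=params.pixel_size_um,
        half_life_min=half_life_min,
        frame_times_min=times,
        frame_patch_counts=counts,
    )
    return field, _label_mask(cells, params.image_shape), truth


def generate_coloc_pair(
    params: FieldParams,
    shared_fraction: float,
    true_shift: tuple[int, int] = (0, 0),
    ch2_gain: float = 0.8,
    max_shift: int = 8,
) -> tuple[Field, np.ndarray, GroundTruth]:
    """Two-channel field sharing a controlled fraction of patch angles.

    Channel 2 reuses each channel-1 patch angle with probability
    ``shared_fraction`` (the remainder is redrawn independently), is
    scaled by ``ch2_gain`` and rigidly translated by ``true_shift``
    (row, col) pixels.
    """
    params.validate()
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in [0, 1]")
    if max(abs(true_shift[0]), abs(true_shift[1])) > max_shift:
        raise ValueError(f"|true_shift| must be <= {max_shift}")
    rng = np.random.default_rng(params.seed)
    cells = _place_cells(params, rng)

    for cell in cells:
        k = cell.true_patch_count
        if shared_fraction >= 1.0:
            cell.patch_angles_ch2 = cell.patch_angles.copy()
            continue
        keep = rng.uniform(size=k) < shared_fraction
        kept = cell.patch_angles[keep]
        n_new = k - kept.size
        fresh = _sample_separated_angles(
            rng, n_new, params.min_patch_separation_rad
        )
        cell.patch_angles_ch2 = np.sort(np.r_[kept, fresh])

    sig1 = np.zeros(params.image_shape, dtype=float)
    sig2 = np.zeros(params.image_shape, dtype=float)
    for cell in cells:
        _render_cell_signal(sig1, cell, params)
        _render_cell_signal(
            sig2,
            cell,
            params,
            patch_angles=cell.patch_angles_ch2,
            center_offset=(float(true_shift[0]), float(true_shift[1])),
        )
    ch1 = _finalize_image(sig1, params, rng)
    # gain scales signal and background alike, so with a full overlap and no
    # noise the channels differ exactly by the scalar gain
    ch2 = _finalize_image(
        ch2_gain * sig2,
        replace(params, background=ch2_gain * params.background),
        rng,
    )

    field = Field(
        data=np.stack([ch1, ch2])[None],
        pixel_size_um=params.pixel_size_um,
        channel_names=["ch1", "ch2"],
        meta={"seed": params.seed, "generator": "coloc", "true_shift": list(true_shift)},
    )
    truth = GroundTruth(
        cells=cells,
        pixel_size_um=params.pixel_size_um,
        shared_fraction=shared_fraction,
        true_shift=tuple(true_shift),
    )
    return field, _label_mask(cells, params.image_shape), truth


def generate_uptake_field(
    params: FieldParams, uptake_fraction: float
) -> tuple[Field, np.ndarray, GroundTruth]:
    """Field in which a set fraction of each cell's noiseless integrated
    signal lies in the interior, the rest on the membrane ring."""
    params.validate()
    if not 0.0 <= uptake_fraction <= 1.0:
        raise ValueError("uptake_fraction must be in [0, 1]")
    rng = np.random.default_rng(params.seed)
    cells = _place_cells(params, rng)
    signal = np.zeros(params.image_shape, dtype=float)
    for cell in cells:
        ring_only = np.zeros_like(signal)
        _render_cell_signal(ring_only, cell, params, interior_value=0.0)
        ring_sum = float(ring_only.sum())
        interior_only = np.zeros_like(signal)
        _render_cell_signal(
            interior_only,
            cell,
            replace(params, pm_intensity=0.0, patch_contrast=1.0),
            interior_value=1.0,
        )
        a_interior = float(interior_only.sum())
        total = ring_sum  # baseline: all signal on the ring at fraction 0
        signal += (1.0 - uptake_fraction) * ring_only
        if a_interior > 0:
            signal += (uptake_fraction * total / a_interior) * interior_only
    image = _finalize_image(signal, params, rng)
    field = Field(
        data=image[None, None],
        pixel_size_um=params.pixel_size_um,
        channel_names=["ch1"],
        meta={"seed": params.seed, "generator": "uptake"},
    )
    truth = GroundTruth(
        cells=cells,
        pixel_size_um=params.pixel_size_um,
        uptake_fraction=uptake_fraction,
    )
    return field, _label_mask(cells, params.image_shape), truth
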