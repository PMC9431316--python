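"""Per-cell plasma-membrane quantification.

Implements the per-cell metrics: region partitioning (membrane band /
interior / whole cell), mean and integrated intensities, membrane-to-
interior intensity ratio, circular membrane intensity profiles, patch
detection with topographic prominence, patch density per perimeter, and
dye-uptake ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, map_coordinates
from scipy.signal import find_peaks, peak_prominences

from .geometry import CellROI, Ellipse, Field

__all__ = [
    "QuantConfig",
    "MembraneProfile",
    "PatchSet",
    "GeometryError",
    "partition_regions",
    "region_intensities",
    "pm_interior_ratio",
    "extract_membrane_profile",
    "detect_patches",
    "patch_prominence",
    "patch_density",
    "uptake_ratio",
    "quantify_field",
]

TWO_PI = 2.0 * np.pi


class GeometryError(ValueError):
    """Raised when a geometric precondition is violated."""


@dataclass(frozen=True)
class QuantConfig:
    """Tunable parameters of the per-cell quantification.

    Defaults were chosen so that parameter-recovery checks on synthetic
    ground truth pass at the default noise level; all are exposed because
    no canonical values exist.
    """

    band_width_um: float = 0.4
    n_profile_samples: int = 360
    n_radial_samples: int = 7
    smoothing_sigma_samples: float = 2.0
    min_peak_prominence_frac: float = 0.10
    min_separation_rad: float = np.deg2rad(4.0)
    background: float = 0.0  # constant subtracted from intensities


@dataclass
class MembraneProfile:
    """Circular intensity trace sampled along a cell's fitted membrane."""

    angles: np.ndarray  # radians, evenly spaced in [0, 2pi)
    intensities: np.ndarray  # mean band intensity at each angle
    perimeter_um: float

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.angles.shape != self.intensities.shape:
            raise ValueError("angles and intensities must have the same length")
        if self.n_samples < 64:
            raise ValueError("membrane profiles require >= 64 samples")

    @property
    def n_samples(self) -> int:
        return self.angles.size


@dataclass
class PatchSet:
    """Detected membrane patches: peak angles and peak/valley intensities."""

    angles: np.ndarray  # radians, sorted
    peak_values: np.ndarray  # smoothed profile at each peak
    valley_values: np.ndarray  # smoothed minima between consecutive peaks
    smoothed: np.ndarray = dc_field(repr=False, default=None)

    @property
    def count(self) -> int:
        return self.angles.size


def partition_regions(
    ellipse: Ellipse,
    band_width_um: float,
    pixel_size_um: float,
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a cell into (PM band, interior, whole cell) boolean masks.

    The band is an annulus of the stated width centered on the ellipse
    boundary (half inside, half outside); the whole cell is the ellipse
    grown by the outer half-band, so band and interior partition it
    exactly.
    """
    half_px = 0.5 * band_width_um / pixel_size_um
    if half_px * 2 >= ellipse.semi_axes[1]:
        raise GeometryError(
            f"band width {band_width_um} um is not thinner than the minor semi-axis"
        )
    (cy, cx), (a, b), phi = ellipse.center, ellipse.semi_axes, ellipse.orientation
    # evaluate the elliptical coordinates on a bounding box only
    ext = a + half_px + 2.0
    r0 = max(0, int(np.floor(cy - ext)))
    r1 = min(shape[0], int(np.ceil(cy + ext)) + 1)
    c0 = max(0, int(np.floor(cx - ext)))
    c1 = min(shape[1], int(np.ceil(cx + ext)) + 1)
    rows = np.arange(r0, r1)[:, None] - cy
    cols = np.arange(c0, c1)[None, :] - cx
    u = cols * np.cos(phi) + rows * np.sin(phi)
    v = -cols * np.sin(phi) + rows * np.cos(phi)
    rho = np.hypot(u / a, v / b)
    theta = np.arctan2(v / b, u / a)
    # signed radial distance from the ellipse boundary, pixels
    dist = (rho - 1.0) * np.hypot(a * np.cos(theta), b * np.sin(theta))
    band, interior, whole = (np.zeros(shape, dtype=bool) for _ in range(3))
    whole[r0:r1, c0:c1] = dist <= half_px
    interior[r0:r1, c0:c1] = dist < -half_px
    band[r0:r1, c0:c1] = whole[r0:r1, c0:c1] & ~interior[r0:r1, c0:c1]
    return band, interior, whole


def region_intensities(
    image: np.ndarray,
    masks: dict[str, np.ndarray],
    background: float = 0.0,
) -> dict[str, dict[str, float]]:
    """Mean and integrated intensity per named region mask.

    Returns ``{region: {"mean": m, "integral": s, "n_px": n}}``; empty
    masks yield NaNs with ``n_px == 0``.
    """
    out: dict[str, dict[str, float]] = {}
    for name, mask in masks.items():
        vals = image[mask] - background
        n = vals.size
        if n == 0:
            out[name] = {"mean": np.nan, "integral": np.nan, "n_px": 0}
        else:
            s = float(vals.sum())
            out[name] = {"mean": s / n, "integral": s, "n_px": n}
    return out


def pm_interior_ratio(pm_mean: float, interior_mean: float) -> float:
    """Ratio of mean membrane-band to mean interior intensity.

    Returns NaN (flagged undefined) when the interior mean is not
    positive.
    """
    if not np.isfinite(interior_mean) or interior_mean <= 0:
        return np.nan
    return float(pm_mean / interior_mean)


def extract_membrane_profile(
    image: np.ndarray,
    ellipse: Ellipse,
    band_width_um: float,
    pixel_size_um: float,
    n_samples: int = 360,
    n_radial: int = 7,
) -> MembraneProfile:
    """Sample the mean band intensity along the fitted membrane.

    At each of ``n_samples`` evenly spaced parametric angles the intensity
    is averaged over a short radial segment spanning the band, using
    bilinear interpolation.  The perimeter is Ramanujan's approximation
    scaled to micrometres.
    """
    (cy, cx), (a, b), phi = ellipse.center, ellipse.semi_axes, ellipse.orientation
    half_px = 0.5 * band_width_um / pixel_size_um
    theta = np.linspace(0.0, TWO_PI, n_samples, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    # boundary points and radial unit vectors (from the center outwards)
    bx = a * ct * np.cos(phi) - b * st * np.sin(phi)
    by = a * ct * np.sin(phi) + b * st * np.cos(phi)
    norm = np.hypot(bx, by)
    ux, uy = bx / norm, by / norm
    # sample strictly inside the band so edge pixels (half in, half out of
    # the membrane) do not dilute the profile
    offsets = np.linspace(-half_px, half_px, n_radial + 2)[1:-1]
    cols = cx + bx[None, :] + offsets[:, None] * ux[None, :]
    rows = cy + by[None, :] + offsets[:, None] * uy[None, :]
    if rows.min() < 0 or cols.min() < 0 or rows.max() > image.shape[0] - 1 or cols.max() > image.shape[1] - 1:
        raise GeometryError(
            "membrane band extends outside the image; the cell should have been QC-filtered"
        )
    sampled = map_coordinates(
        np.asarray(image, dtype=float), [rows, cols], order=1, mode="nearest"
    )
    intensities = sampled.mean(axis=0)
    return MembraneProfile(
        angles=theta,
        intensities=intensities,
        perimeter_um=ellipse.perimeter_px() * pixel_size_um,
    )


def detect_patches(
    profile: MembraneProfile,
    smoothing_sigma_samples: float = 2.0,
    min_peak_prominence_frac: float = 0.10,
    min_separation_rad: float = np.deg2rad(4.0),
) -> PatchSet:
    """Detect high-intensity membrane patches on a circular profile.

    The profile is smoothed with a circular Gaussian; peaks are local
    maxima whose topographic prominence is at least
    ``min_peak_prominence_frac`` times the smoothed-profile median and
    whose circular separation is at least ``min_separation_rad`` (the
    higher peak wins a conflict, ties break towards the smaller angle).
    Valleys are the circular minima between consecutive retained peaks.
    """
    n = profile.n_samples
    y = gaussian_filter1d(profile.intensities, smoothing_sigma_samples, mode="wrap")
    if not np.any(y > 0) or np.ptp(y) == 0:
        empty = np.array([])
        return PatchSet(empty, empty, empty, smoothed=y)

    tripled = np.tile(y, 3)
    idx, _ = find_peaks(tripled)
    idx = idx[(idx >= n) & (idx < 2 * n)]
    if idx.size == 0:
        empty = np.array([])
        return PatchSet(empty, empty, empty, smoothed=y)
    prom = peak_prominences(tripled, idx)[0]
    threshold = min_peak_prominence_frac * float(np.median(y))
    keep = prom >= threshold
    idx = idx[keep] - n

    # greedy circular non-maximum suppression: height desc, then angle asc
    order = sorted(range(idx.size), key=lambda i: (-y[idx[i]], idx[i]))
    min_sep_samples = min_separation_rad / (TWO_PI / n)
    retained: list[int] = []
    for i in order:
        p = idx[i]
        ok = True
        for q in retained:
            d = abs(p - q)
            if min(d, n - d) < min_sep_samples:
                ok = False
                break
        if ok:
            retained.append(p)
    retained.sort()
    peaks = np.asarray(retained, dtype=int)

    k = peaks.size
    valleys = np.empty(k)
    for i in range(k):
        lo, hi = peaks[i], peaks[(i + 1) % k]
        if k == 1:
            arc = np.r_[y[lo + 1 :], y[:lo]]
        elif hi > lo:
            arc = y[lo + 1 : hi]
        else:
            arc = np.r_[y[lo + 1 :], y[:hi]]
        valleys[i] = arc.min() if arc.size else min(y[lo], y[hi])

    return PatchSet(
        angles=profile.angles[peaks],
        peak_values=y[peaks],
        valley_values=valleys,
        smoothed=y,
    )


def patch_prominence(patches: PatchSet) -> float:
    """Mean peak over mean valley intensity of the smoothed profile.

    NaN when no patches were detected (the cell is then excluded from
    aggregation) or when the valley mean is not positive.
    """
    if patches.count == 0:
        return np.nan
    valley_mean = float(patches.valley_values.mean())
    if valley_mean <= 0:
        return np.nan
    return float(patches.peak_values.mean()) / valley_mean


def patch_density(patch_count: int, perimeter_um: float) -> float:
    """Patches per micrometre of fitted-ellipse perimeter."""
    if perimeter_um <= 0:
        raise GeometryError("perimeter must be positive")
    return patch_count / perimeter_um


def uptake_ratio(whole_integral: float, interior_integral: float) -> float:
    """Interior over whole-cell integrated intensity (dye uptake).

    NaN when the whole-cell integral is not positive.
    """
    if not np.isfinite(whole_integral) or whole_integral <= 0:
        return np.nan
    return float(interior_integral / whole_integral)


def _region_stats(flat: np.ndarray, idx: np.ndarray, background: float) -> tuple[float, float, int]:
    n = idx.size
    if n == 0:
        return np.nan, np.nan, 0
    s = float(flat[idx].sum()) - background * n
    return s / n, s, n


def _quantify_cell_indexed(
    image: np.ndarray,
    flat: np.ndarray,
    roi: CellROI,
    band_idx: np.ndarray,
    int_idx: np.ndarray,
    whole_idx: np.ndarray,
    pixel_size_um: float,
    config: QuantConfig,
) -> dict[str, float]:
    pm_mean, pm_int, _ = _region_stats(flat, band_idx, config.background)
    in_mean, in_int, _ = _region_stats(flat, int_idx, config.background)
    wh_mean, wh_int, _ = _region_stats(flat, whole_idx, config.background)
    profile = extract_membrane_profile(
        image,
        roi.ellipse,
        config.band_width_um,
        pixel_size_um,
        n_samples=config.n_profile_samples,
        n_radial=config.n_radial_samples,
    )
    if config.background:
        profile.intensities = profile.intensities - config.background
    patches = detect_patches(
        profile,
        smoothing_sigma_samples=config.smoothing_sigma_samples,
        min_peak_prominence_frac=config.min_peak_prominence_frac,
        min_separation_rad=config.min_separation_rad,
    )
    return {
        "label": roi.label,
        "area_px": roi.area_px,
        "whole_mean": wh_mean,
        "whole_integral": wh_int,
        "pm_mean": pm_mean,
        "pm_integral": pm_int,
        "interior_mean": in_mean,
        "interior_integral": in_int,
        "pm_interior_ratio": pm_interior_ratio(pm_mean, in_mean),
        "patch_count": patches.count,
        "patch_density_per_um": patch_density(patches.count, profile.perimeter_um),
        "prominence": patch_prominence(patches),
        "uptake_ratio": uptake_ratio(wh_int, in_int),
        "perimeter_um": profile.perimeter_um,
    }


def quantify_cell(
    image: np.ndarray,
    roi: CellROI,
    pixel_size_um: float,
    config: QuantConfig = QuantConfig(),
) -> dict[str, float]:
    """All per-cell metrics for one ROI on one image plane."""
    if roi.ellipse is None:
        raise GeometryError(f"ROI {roi.label} has no fitted ellipse")
    band, interior, whole = partition_regions(
        roi.ellipse, config.band_width_um, pixel_size_um, image.shape
    )
    flat = np.asarray(image, dtype=float).ravel()
    return _quantify_cell_indexed(
        image,
        flat,
        roi,
        np.flatnonzero(band.ravel()),
        np.flatnonzero(interior.ravel()),
        np.flatnonzero(whole.ravel()),
        pixel_size_um,
        config,
    )


def quantify_field(
    field: Field,
    rois: list[CellROI],
    config: QuantConfig = QuantConfig(),
    channel: int = 0,
) -> pd.DataFrame:
    """Per-cell metrics for every ROI, over every frame of a field.

    Returns one row per (frame, cell); single-frame fields simply get
    ``frame == 0``.  Cells whose band would leave the image are skipped
    with a warning (they should have been QC-filtered upstream).
    """
    records = []
    times = field.frame_times_min
    # ROIs are static across frames: precompute region pixel indices once
    geo: dict[int, tuple] = {}
    for roi in rois:
        if roi.ellipse is None:
            warnings.warn(f"skipping cell {roi.label}: no fitted ellipse", stacklevel=2)
            continue
        try:
            band, interior, whole = partition_regions(
                roi.ellipse, config.band_width_um, field.pixel_size_um, field.image_shape
            )
        except GeometryError as exc:
            warnings.warn(f"skipping cell {roi.label}: {exc}", stacklevel=2)
            continue
        geo[roi.label] = (
            roi,
            np.flatnonzero(band.ravel()),
            np.flatnonzero(interior.ravel()),
            np.flatnonzero(whole.ravel()),
        )
    for f in range(field.n_frames):
        image = field.plane(f, channel)
        flat = np.asarray(image, dtype=float).ravel()
        for label, (roi, band_idx, int_idx, whole_idx) in geo.items():
            try:
                rec = _quantify_cell_indexed(
                    image, flat, roi, band_idx, int_idx, whole_idx,
                    field.pixel_size_um, config,
                )
            except GeometryError as exc:
                warnings.warn(f"skipping cell {label} in frame {f}: {exc}", stacklevel=2)
                continue
            rec["frame"] = f
            rec["time_min"] = times[f] if times is not None else float(f)
            records.append(rec)
    df = pd.DataFrame.from_records(records)
    if not df.empty:
        lead = ["frame", "time_min", "label"]
        df = df[lead + [c for c in df.columns if c not in lead]]
    return df
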