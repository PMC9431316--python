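"""Cell geometry: fields, label-mask ingestion, ellipse fitting and QC.

Conventions
-----------
* Coordinates are 0-based ``(row, col)``.
* Angles are measured from the +col axis, counter-clockwise in array
  coordinates, i.e. towards +row.
* Label masks use 0 for background and a unique positive integer per cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Field",
    "Ellipse",
    "CellROI",
    "QCPolicy",
    "FormatError",
    "load_label_mask",
    "fit_ellipse",
    "filter_cells",
    "max_project",
    "prepare_rois",
]


class FormatError(ValueError):
    """Raised when an input image or mask violates the expected format."""


@dataclass
class Field:
    """A multi-channel, optionally timed, 2D fluorescence field.

    ``data`` is always stored as a 4D array ``(frames, channels, rows,
    cols)``; plain 2D input is promoted to a single frame and channel.
    """

    data: np.ndarray
    pixel_size_um: float
    channel_names: list[str] | None = None
    frame_times_min: list[float] | None = None
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 2:
            arr = arr[None, None]
        elif arr.ndim != 4:
            raise FormatError(
                f"field data must be 2D or 4D (frames, channels, rows, cols); got {arr.ndim}D"
            )
        self.data = arr
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.channel_names is None:
            self.channel_names = [f"ch{i + 1}" for i in range(arr.shape[1])]
        if len(self.channel_names) != arr.shape[1]:
            raise ValueError("channel_names length must match channel axis")
        if self.frame_times_min is not None and len(self.frame_times_min) != arr.shape[0]:
            raise ValueError("frame_times_min length must match frame axis")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.data.shape[2:]

    def plane(self, frame: int = 0, channel: int = 0) -> np.ndarray:
        """Return one 2D image plane."""
        return self.data[frame, channel]


@dataclass(frozen=True)
class Ellipse:
    """Ellipse in pixel units: center, semi-axes (major >= minor), orientation.

    ``orientation`` is the angle of the major axis in radians, normalized
    to [0, pi).
    """

    center: tuple[float, float]  # (row, col)
    semi_axes: tuple[float, float]  # (major, minor), pixels
    orientation: float  # radians in [0, pi)

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a > 0 and b > 0):
            raise ValueError("semi-axes must be positive")
        if a < b:
            raise ValueError("semi_axes must be ordered (major, minor)")

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_axes[0] * self.semi_axes[1])

    def perimeter_px(self) -> float:
        """Ramanujan's approximation to the ellipse perimeter, in pixels."""
        a, b = self.semi_axes
        h = ((a - b) / (a + b)) ** 2
        return float(np.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h))))


@dataclass
class CellROI:
    """One segmented cell: label, pixel mask and (once fitted) an ellipse."""

    label: int
    mask: np.ndarray  # boolean, full image shape
    touches_border: bool = False
    ellipse: Ellipse | None = None
    qc_reason: str | None = None

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class QCPolicy:
    """Rule-based replacement for the manual ROI curation step."""

    min_area_px: int = 50
    max_area_px: int = 20_000
    remove_border: bool = True


def load_label_mask(mask: np.ndarray, field: Field | None = None) -> list[CellROI]:
    """Convert an integer label mask into one :class:`CellROI` per cell.

    Parameters
    ----------
    mask
        2D array of non-negative integers; 0 is background.
    field
        Optional field the mask belongs to; shapes must match.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise FormatError("label mask must be 2D")
    if not np.issubdtype(mask.dtype, np.integer):
        if np.issubdtype(mask.dtype, np.floating) and np.all(mask == np.round(mask)):
            mask = mask.astype(np.int64)
        else:
            raise FormatError("label mask must contain integers")
    if mask.min() < 0:
        raise FormatError("label mask must be non-negative")
    if field is not None and tuple(mask.shape) != tuple(field.image_shape):
        raise FormatError(
            f"mask shape {mask.shape} does not match field shape {field.image_shape}"
        )

    border = np.zeros_like(mask, dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True

    rois: list[CellROI] = []
    for label in np.unique(mask):
        if label <= 0:
            continue
        m = mask == label
        rois.append(
            CellROI(
                label=int(label),
                mask=m,
                touches_border=bool((m & border).any()),
            )
        )
    return rois


def fit_ellipse(roi: CellROI, min_area_px: int = 50) -> CellROI:
    """Fit an area-preserving moment ellipse to the ROI mask.

    The center is the mask centroid; axes and orientation come from the
    eigendecomposition of the second central moments, rescaled so the
    ellipse area equals the mask pixel count.  Degenerate masks are
    flagged for QC rejection rather than raising.
    """
    rows, cols = np.nonzero(roi.mask)
    n = rows.size
    if n < min_area_px:
        roi.qc_reason = "degenerate"
        roi.ellipse = None
        return roi
    cy, cx = rows.mean(), cols.mean()
    dy, dx = rows - cy, cols - cx
    # second central moments (population)
    mu_rr = float(dy @ dy) / n
    mu_cc = float(dx @ dx) / n
    mu_rc = float(dy @ dx) / n
    cov = np.array([[mu_cc, mu_rc], [mu_rc, mu_rr]])  # (col, row) frame
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-9:
        roi.qc_reason = "degenerate"
        roi.ellipse = None
        return roi
    # for an ideal filled ellipse the second moment along an axis is (semi/2)^2
    semi = 2.0 * np.sqrt(evals)  # ascending: (minor, major)
    scale = np.sqrt(n / (np.pi * semi[0] * semi[1]))
    semi *= scale
    vx, vy = evecs[:, 1]  # eigenvector of the major axis, (col, row) components
    orientation = float(np.arctan2(vy, vx)) % np.pi
    roi.ellipse = Ellipse(
        center=(float(cy), float(cx)),
        semi_axes=(float(semi[1]), float(semi[0])),
        orientation=orientation,
    )
    roi.qc_reason = None
    return roi


def filter_cells(
    rois: Sequence[CellROI], policy: QCPolicy = QCPolicy()
) -> tuple[list[CellROI], list[tuple[int, str]]]:
    """Apply cell-level QC; returns (retained ROIs, rejection log).

    Removes border-touching cells (incompletely imaged), cells outside the
    area gates, and ellipse-fit failures.  Order is preserved and the
    operation is idempotent.
    """
    kept: list[CellROI] = []
    rejected: list[tuple[int, str]] = []
    for roi in rois:
        if policy.remove_border and roi.touches_border:
            rejected.append((roi.label, "touches_border"))
        elif roi.area_px < policy.min_area_px:
            rejected.append((roi.label, "area_too_small"))
        elif roi.area_px > policy.max_area_px:
            rejected.append((roi.label, "area_too_large"))
        elif roi.qc_reason is not None:
            rejected.append((roi.label, roi.qc_reason))
        else:
            kept.append(roi)
    return kept, rejected


def max_project(field: Field) -> Field:
    """Maximum-intensity projection across the frame/plane axis."""
    if field.n_frames < 2:
        warnings.warn("max_project on a single plane is the identity", stacklevel=2)
        out = field.data.copy()
    else:
        out = field.data.max(axis=0, keepdims=True)
    meta = dict(field.meta)
    meta["projection"] = "max"
    return Field(
        data=out,
        pixel_size_um=field.pixel_size_um,
        channel_names=list(field.channel_names),
        frame_times_min=None,
        meta=meta,
    )


def prepare_rois(
    mask: np.ndarray,
    field: Field | None = None,
    policy: QCPolicy = QCPolicy(),
) -> tuple[list[CellROI], list[tuple[int, str]]]:
    """Load, fit and QC-filter ROIs from a label mask in one call."""
    rois = load_label_mask(mask, field)
    rois = [fit_ellipse(r, min_area_px=policy.min_area_px) for r in rois]
    return filter_cells(rois, policy)
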