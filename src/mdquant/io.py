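"""TIFF / CSV / YAML input-output helpers.

Fields are written as multi-page 16-bit TIFF (pages ordered frame-major,
then channel) with a JSON metadata block in the ImageDescription tag;
label masks as single-page integer TIFF.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .geometry import Field

log = logging.getLogger(__name__)

__all__ = [
    "write_field_tiff",
    "read_field_tiff",
    "write_label_mask",
    "read_label_mask",
    "load_params_yaml",
    "dump_params_yaml",
]

U16_MAX = 65535


def write_field_tiff(path: str | Path, field: Field) -> float:
    """Write a field as 16-bit TIFF, clipping to the dtype range.

    Returns the fraction of saturated pixels (also logged and stored in
    the metadata).
    """
    data = field.data
    saturation = float((data > U16_MAX).mean())
    if saturation > 0:
        log.warning("%.4f%% of pixels saturate 16-bit range", 100 * saturation)
    clipped = np.clip(np.round(data), 0, U16_MAX).astype(np.uint16)
    f, c, h, w = clipped.shape
    meta = {
        "pixel_size_um": field.pixel_size_um,
        "channel_names": field.channel_names,
        "frame_times_min": field.frame_times_min,
        "n_frames": f,
        "n_channels": c,
        "saturation_fraction": saturation,
        **field.meta,
    }
    tifffile.imwrite(
        str(path),
        clipped.reshape(f * c, h, w),
        photometric="minisblack",
        description=json.dumps(meta, default=str),
    )
    return saturation


def read_field_tiff(path: str | Path, pixel_size_um: float | None = None) -> Field:
    """Read a field TIFF written by :func:`write_field_tiff` (or any plain
    TIFF, in which case pixel size must be given and a single channel is
    assumed)."""
    with tifffile.TiffFile(str(path)) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if pages.ndim == 2:
        pages = pages[None]
    f = int(meta.get("n_frames", pages.shape[0]))
    c = int(meta.get("n_channels", 1))
    data = pages.reshape(f, c, *pages.shape[-2:]).astype(float)
    px = meta.get("pixel_size_um", pixel_size_um)
    if px is None:
        raise ValueError("pixel_size_um not in TIFF metadata; pass it explicitly")
    return Field(
        data=data,
        pixel_size_um=float(px),
        channel_names=meta.get("channel_names"),
        frame_times_min=meta.get("frame_times_min"),
        meta={k: v for k, v in meta.items() if k not in (
            "pixel_size_um", "channel_names", "frame_times_min", "n_frames", "n_channels"
        )},
    )


def write_label_mask(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(mask, dtype=np.int32))


def read_label_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int64)


def load_params_yaml(path: str | Path, cls):
    """Instantiate a params dataclass from a YAML mapping (tuples restored
    from lists for fields typed as tuples)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in raw:
            v = raw[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
    if unknown:
        raise ValueError(f"unknown parameter(s) in {path}: {sorted(unknown)}")
    return cls(**kwargs)


def dump_params_yaml(path: str | Path, params) -> None:
    d = dataclasses.asdict(params)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
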