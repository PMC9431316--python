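"""Time-lapse patch-density statistics and half-decay-time estimation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["DecayCurve", "patch_density_timeseries", "half_decay_time"]


@dataclass
class DecayCurve:
    """Median +/- IQR of per-cell patch density per frame."""

    times_min: np.ndarray
    median_density: np.ndarray
    q1: np.ndarray
    q3: np.ndarray
    n_cells: np.ndarray
    half_decay_min: float | None = None

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.n_cells < 1):
            raise ValueError("reported frames need >= 1 cell")
        if np.any(self.q1 > self.median_density) or np.any(self.median_density > self.q3):
            raise ValueError("quartiles must satisfy q1 <= median <= q3")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times_min,
                "median_density": self.median_density,
                "q1": self.q1,
                "q3": self.q3,
                "n_cells": self.n_cells,
            }
        )


def patch_density_timeseries(
    metrics: pd.DataFrame,
    value_col: str = "patch_density_per_um",
    time_col: str = "time_min",
) -> DecayCurve:
    """Per-frame median and interquartile range of per-cell patch density.

    Quartiles use linear interpolation (numpy default, type 7).  Frames
    with zero cells are dropped with a warning.
    """
    if metrics[time_col].nunique() < 2:
        raise ValueError("need >= 2 frames")
    times, med, q1, q3, n = [], [], [], [], []
    for t, grp in metrics.groupby(time_col, sort=True):
        vals = grp[value_col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            warnings.warn(f"frame at t={t} has no cells; dropped", stacklevel=2)
            continue
        times.append(float(t))
        med.append(float(np.median(vals)))
        q1.append(float(np.percentile(vals, 25)))
        q3.append(float(np.percentile(vals, 75)))
        n.append(vals.size)
    return DecayCurve(
        times_min=np.array(times),
        median_density=np.array(med),
        q1=np.array(q1),
        q3=np.array(q3),
        n_cells=np.array(n),
    )


def half_decay_time(curve: DecayCurve, method: str = "crossing") -> float:
    """Time for the median density to fall to half its initial value.

    ``method="crossing"``: first time the median reaches <= d0/2, linearly
    interpolated between the bracketing frames; NaN if never reached.
    ``method="expfit"``: least-squares fit of d0 * 2**(-t/T), returning T;
    NaN if the fit fails.
    """
    if curve.times_min.size < 3:
        raise ValueError("need >= 3 frames")
    t = curve.times_min
    d = curve.median_density
    d0 = d[0]
    if d0 <= 0:
        return np.nan
    if np.any(d[1:-1] > 1.2 * d0):
        warnings.warn(
            "median density rises >20% above its initial value mid-series",
            stacklevel=2,
        )
    if method == "crossing":
        half = 0.5 * d0
        below = np.flatnonzero(d <= half)
        below = below[below > 0]
        if below.size == 0:
            return np.nan
        i = below[0]
        t0, t1, y0, y1 = t[i - 1], t[i], d[i - 1], d[i]
        if y0 == y1:
            return float(t1)
        return float(t0 + (y0 - half) * (t1 - t0) / (y0 - y1))
    if method == "expfit":
        def model(tt, amp, half_life):
            return amp * np.exp2(-tt / half_life)

        span = t[-1] - t[0]
        try:
            popt, _ = curve_fit(
                model,
                t,
                d,
                p0=(d0, max(span / 2.0, 1e-6)),
                bounds=((0, 1e-9), (np.inf, np.inf)),
                maxfev=10_000,
            )
        except (RuntimeError, ValueError):
            return np.nan
        return float(popt[1])
    raise ValueError(f"unknown method {method!r}")
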