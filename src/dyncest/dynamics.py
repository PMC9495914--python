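"""Dynamic MTR quantification: S0 baseline, normalization, curves, AUC maps.

The quantification chain is:

1. ROI-mean (or per-pixel) intensities of the interleaved far-off-resonance
   S0 images are Savitzky-Golay smoothed (window 3, order 2) and linearly
   interpolated in time to every image, giving the drift-tracking baseline
   ``S0_SG``.
2. Each retained measurement image is normalized, ``Z = S / S0_SG``, which
   cancels multiplicative signal drift common to both.
3. A pre-injection baseline correction yields the dynamic MTR curve,
   ``MTR = Z_pre_avg - Z``, positive for saturation-induced signal loss; the
   pre-injection MTR mean is zero by construction.
4. Pixel-wise application of the same chain followed by trapezoidal
   integration over a time window gives AUC maps.

Note the faithful window-3/order-2 Savitzky-Golay filter is the identity
(a quadratic through three points interpolates them); larger windows are
accepted for genuine smoothing, including the window-7 display smoothing of
group-average curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .schedule import AcquisitionSchedule, ScheduleEntry

__all__ = [
    "BaselineCurve",
    "MTRCurve",
    "AUCMap",
    "sg_filter",
    "build_s0_baseline",
    "normalize",
    "mtr_curve",
    "roi_mtr_curves",
    "pixelwise_mtr",
    "pixelwise_auc",
    "group_average",
]


def sg_filter(values: np.ndarray, window: int = 3, order: int = 2) -> np.ndarray:
    """Savitzky-Golay least-squares polynomial smoothing.

    Edges are handled by fitting the boundary windows' polynomials
    (scipy's ``mode="interp"``).  Window 3 / order 2 reproduces the input
    exactly.
    """
    values = np.asarray(values, dtype=float)
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if order >= window:
        raise ValueError("order must be smaller than the window")
    if values.shape[-1] < window:
        raise ValueError("input shorter than the filter window")
    return savgol_filter(values, window, order, axis=-1, mode="interp")


@dataclass
class BaselineCurve:
    """Smoothed S0 baseline interpolated to every schedule entry time."""

    times_s: np.ndarray
    s0_sg_values: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.s0_sg_values = np.asarray(self.s0_sg_values, dtype=float)
        if self.times_s.shape[0] != self.s0_sg_values.shape[0]:
            raise ValueError("times and baseline values must align")
        if np.any(self.s0_sg_values <= 0):
            raise ValueError("baseline must be strictly positive")

    def at(self, t_s: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(t_s, float), self.times_s, self.s0_sg_values)


@dataclass
class MTRCurve:
    """Dynamic MTR curve for one ROI/pixel and one saturation offset."""

    times_min: np.ndarray
    z_values: np.ndarray
    z_pre_avg: float
    mtr_values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.z_values = np.asarray(self.z_values, dtype=float)
        self.mtr_values = np.asarray(self.mtr_values, dtype=float)
        if not (len(self.times_min) == len(self.z_values) == len(self.mtr_values)):
            raise ValueError("curve arrays must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_min": self.times_min, "Z": self.z_values, "MTR": self.mtr_values,
             "label": self.label}
        )


@dataclass
class AUCMap:
    """Per-pixel area under the dynamic MTR curve within a time window."""

    window_min: tuple[float, float]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.window_min[1] <= self.window_min[0]:
            raise ValueError("AUC window must have positive length")


def _roi_means(images: np.ndarray, roi: np.ndarray) -> np.ndarray:
    roi = np.asarray(roi, bool)
    if roi.sum() == 0:
        raise ValueError("ROI mask is empty")
    return images[:, roi].mean(axis=1)


def build_s0_baseline(series, roi: np.ndarray | None = None,
                      window: int = 3, order: int = 2) -> BaselineCurve:
    """ROI-mean S0 baseline: SG-filter the non-dummy S0 intensities, then
    interpolate linearly to all entry midpoint times (boundary values held).

    Dummy S0 images (pre-steady-state) are excluded from the fit.
    """
    roi = series.masks["liver"] if roi is None else roi
    idx = [i for i, e in enumerate(series.entries) if e.role == "s0"]
    if len(idx) < 2:
        raise ValueError("need at least 2 non-dummy S0 entries for a baseline")
    t_s0 = np.array([series.entries[i].t_mid_s for i in idx])
    s0 = _roi_means(series.images[idx], roi)
    s0_sg = sg_filter(s0, window, order)
    t_all = np.array([e.t_mid_s for e in series.entries])
    return BaselineCurve(t_all, np.interp(t_all, t_s0, s0_sg))


def normalize(series, baseline: BaselineCurve, roi: np.ndarray | None = None,
              offset_ppm: float | None = None) -> pd.DataFrame:
    """Z = S / S0_SG at every retained measurement entry (ROI mean).

    Returns a tidy frame (time_min, offset_ppm, cycle, Z), optionally
    restricted to one saturation offset.
    """
    roi = series.masks["liver"] if roi is None else roi
    if np.any(baseline.s0_sg_values <= 0):
        raise ValueError("baseline must be strictly positive")
    rows = []
    for i, e in enumerate(series.entries):
        if e.role != "measure" or not e.retain:
            continue
        if offset_ppm is not None and not np.isclose(e.offset_ppm, offset_ppm):
            continue
        s = float(series.images[i][np.asarray(roi, bool)].mean())
        rows.append((e.t_mid_s / 60.0, e.offset_ppm, e.cycle,
                     s / baseline.at(e.t_mid_s)))
    return pd.DataFrame(rows, columns=["time_min", "offset_ppm", "cycle", "Z"])


def mtr_curve(
    z: np.ndarray,
    times_min: np.ndarray,
    injection_start_min: float,
    pre_window_min: tuple[float, float] | None = None,
    label: str = "",
) -> MTRCurve:
    """Pre-injection-referenced MTR curve: MTR = Z_pre_avg - Z.

    ``pre_window_min`` optionally restricts the pre-injection average (e.g. to
    exclude early entries before the saturation quasi-steady-state); default
    uses every point before the injection start.
    """
    z = np.asarray(z, float)
    times_min = np.asarray(times_min, float)
    lo, hi = pre_window_min if pre_window_min is not None else (-np.inf, injection_start_min)
    hi = min(hi, injection_start_min)
    pre = (times_min >= lo) & (times_min < hi)
    if not np.any(pre):
        raise ValueError("no pre-injection points in the requested window")
    z_pre_avg = float(z[pre].mean())
    return MTRCurve(times_min, z, z_pre_avg, z_pre_avg - z, label)


def roi_mtr_curves(series, roi: np.ndarray | None = None,
                   pre_window_min: tuple[float, float] | None = None,
                   label: str = "") -> dict[float, MTRCurve]:
    """Full ROI pipeline: baseline -> Z -> MTR, one curve per tracked offset."""
    baseline = build_s0_baseline(series, roi)
    tidy = normalize(series, baseline, roi)
    inj = series.timing.injection_start_min
    out: dict[float, MTRCurve] = {}
    for w, grp in tidy.groupby("offset_ppm", sort=False):
        out[float(w)] = mtr_curve(
            grp["Z"].to_numpy(), grp["time_min"].to_numpy(), inj,
            pre_window_min, label=f"{label}@{w:+.1f}ppm",
        )
    return out


def _pixel_baseline(series, eps: float = 1e-12) -> np.ndarray:
    """Per-pixel S0_SG baseline interpolated to all entry times -> (T, H, W)."""
    idx = [i for i, e in enumerate(series.entries) if e.role == "s0"]
    if len(idx) < 2:
        raise ValueError("need at least 2 non-dummy S0 entries for a baseline")
    t_s0 = np.array([series.entries[i].t_mid_s for i in idx])
    s0 = series.images[idx].astype(float)  # (n_s0, H, W)
    s0_sg = savgol_filter(s0, 3, 2, axis=0, mode="interp")
    t_all = np.array([e.t_mid_s for e in series.entries])
    # vectorized linear interpolation along time
    j = np.clip(np.searchsorted(t_s0, t_all) - 1, 0, len(t_s0) - 2)
    w = np.clip((t_all - t_s0[j]) / (t_s0[j + 1] - t_s0[j]), 0.0, 1.0)
    base = (1 - w)[:, None, None] * s0_sg[j] + w[:, None, None] * s0_sg[j + 1]
    return np.maximum(base, eps)


def pixelwise_mtr(series, offset_ppm: float,
                  pre_window_min: tuple[float, float] | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel MTR stack at one tracked offset.

    Returns ``(times_min, mtr)`` with ``mtr`` of shape (T_retained, H, W),
    built from per-pixel S0 baselines (the ROI chain applied pixel-wise).
    """
    base = _pixel_baseline(series)
    keep = [i for i, e in enumerate(series.entries)
            if e.role == "measure" and e.retain and np.isclose(e.offset_ppm, offset_ppm)]
    if not keep:
        raise ValueError(f"no retained entries at {offset_ppm} ppm")
    times_min = np.array([series.entries[i].t_mid_s for i in keep]) / 60.0
    z = series.images[keep].astype(float) / base[keep]
    inj = series.timing.injection_start_min
    lo, hi = pre_window_min if pre_window_min is not None else (-np.inf, inj)
    pre = (times_min >= lo) & (times_min < min(hi, inj))
    if not np.any(pre):
        raise ValueError("no pre-injection points in the requested window")
    mtr = z[pre].mean(axis=0)[None] - z
    return times_min, mtr


def pixelwise_auc(series, window_min: tuple[float, float], offset_ppm: float,
                  pre_window_min: tuple[float, float] | None = None) -> AUCMap:
    """Pixel-wise AUC of the dynamic MTR curve over a closed time window.

    Trapezoidal integration on the retained-point grid (minutes), with the
    window endpoints interpolated onto the curve.
    """
    t1, t2 = window_min
    times, mtr = pixelwise_mtr(series, offset_ppm, pre_window_min)
    if t2 <= t1:
        raise ValueError("AUC window must have positive length")
    if t1 < times[0] - np.diff(times).max() or t2 > times[-1] + np.diff(times).max():
        raise ValueError("AUC window outside the scanned time range")
    grid = np.unique(np.concatenate([[t1], times[(times > t1) & (times < t2)], [t2]]))
    flat = mtr.reshape(len(times), -1)
    vals = np.empty((len(grid), flat.shape[1]))
    for k, t in enumerate(grid):  # linear interpolation at window edges
        j = np.clip(np.searchsorted(times, t) - 1, 0, len(times) - 2)
        w = np.clip((t - times[j]) / (times[j + 1] - times[j]), 0.0, 1.0)
        vals[k] = (1 - w) * flat[j] + w * flat[j + 1]
    auc = np.trapezoid(vals, grid, axis=0).reshape(mtr.shape[1:])
    return AUCMap((t1, t2), auc)


@dataclass
class GroupCurve:
    """Pointwise mean and sample SD across subjects' MTR curves."""

    times_min: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: int
    smoothed: np.ndarray


def group_average(curves: list[MTRCurve], smooth_window: int = 7,
                  smooth_order: int = 2) -> GroupCurve:
    """Average MTR curves across subjects on a common time grid.

    The per-time sample SD is the statistical uncertainty; a display-smoothed
    variant of the mean (Savitzky-Golay window 7, order 2) is also returned.
    With a single curve the SD is undefined and returned as NaN.
    """
    if not curves:
        raise ValueError("no curves to average")
    t0 = curves[0].times_min
    for c in curves[1:]:
        if len(c.times_min) != len(t0) or not np.allclose(c.times_min, t0):
            raise ValueError("curves must share a common time grid")
    stack = np.vstack([c.mtr_values for c in curves])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(curves) > 1 else np.full_like(mean, np.nan)
    smoothed = sg_filter(mean, smooth_window, smooth_order) if len(mean) >= smooth_window else mean.copy()
    return GroupCurve(t0.copy(), mean, sd, len(curves), smoothed)
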