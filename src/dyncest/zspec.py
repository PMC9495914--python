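"""Z-spectrum assembly, inverted-Lorentzian B0 mapping, partial-spectrum maps.

The direct-water-saturation (DWS) dip dominates the centre of a Z-spectrum;
its minimum sits at the apparent water resonance, so fitting an inverted
Lorentzian

    Z(w) = b - d * (G/2)^2 / ((G/2)^2 + (w - delta)^2)

per pixel and reading off the centre ``delta`` gives that pixel's B0 shift in
ppm.  Fits are bounded (|delta| <= 1 ppm, 0.2 <= G <= 4 ppm) so they cannot
chase the shallower solute dips; a pixel that fails to fit is flagged rather
than raised.

Partial Z-spectral maps arrange the dynamic MTR values of the five swept
offsets into an offsets x time matrix per subject (one column per sweep),
averaged across a group for display and compared cellwise between groups for
significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .bmc import ZSpectrum
from .dynamics import build_s0_baseline, mtr_curve, normalize

logger = logging.getLogger(__name__)

__all__ = [
    "LorentzianFit",
    "PartialMap",
    "fit_dws",
    "b0_map",
    "partial_map",
    "group_partial_map",
]


@dataclass
class LorentzianFit:
    """Inverted-Lorentzian DWS fit: centre = per-pixel B0 shift in ppm."""

    center_ppm: float
    fwhm_ppm: float
    depth: float
    baseline: float
    residual_rms: float
    ok: bool = True

    def __post_init__(self) -> None:
        if self.ok:
            if self.fwhm_ppm <= 0:
                raise ValueError("fwhm must be positive")
            if not np.isfinite(self.residual_rms):
                raise ValueError("residual must be finite")


def _lorentzian(w: np.ndarray, center: float, fwhm: float, depth: float,
                base: float) -> np.ndarray:
    hw2 = (fwhm / 2.0) ** 2
    return base - depth * hw2 / (hw2 + (w - center) ** 2)


def fit_dws(
    zspec: ZSpectrum,
    init: tuple[float, float, float, float] | None = None,
    center_bound_ppm: float = 1.0,
    fwhm_bounds_ppm: tuple[float, float] = (0.2, 4.0),
) -> LorentzianFit:
    """Least-squares inverted-Lorentzian fit of the DWS dip.

    Initialized at the discrete grid minimum (clipped into the centre bound).
    Returns a flagged (not raised) result when the spectrum has no usable dip
    or the solver fails.
    """
    w = np.asarray(zspec.offsets_ppm, float)
    z = np.asarray(zspec.z_values, float)
    if w.size < 5:
        raise ValueError("need at least 5 offsets spanning the dip")
    if init is None:
        base0 = float(np.percentile(z, 90))
        depth0 = base0 - float(z.min())
        center0 = float(np.clip(w[np.argmin(z)], -center_bound_ppm, center_bound_ppm))
        init = (center0, 1.0, depth0, base0)
    if init[2] < 1e-3:  # no dip to fit
        return LorentzianFit(np.nan, np.nan, np.nan, np.nan, np.nan, ok=False)
    lo = [-center_bound_ppm, fwhm_bounds_ppm[0], 0.0, 0.0]
    hi = [center_bound_ppm, fwhm_bounds_ppm[1], 1.5, 1.5]
    x0 = np.clip(init, lo, hi)
    try:
        res = least_squares(
            lambda p: _lorentzian(w, *p) - z, x0, bounds=(lo, hi), method="trf")
    except Exception:  # pragma: no cover - solver pathologies
        return LorentzianFit(np.nan, np.nan, np.nan, np.nan, np.nan, ok=False)
    if not res.success:
        return LorentzianFit(np.nan, np.nan, np.nan, np.nan, np.nan, ok=False)
    c, g, d, b = res.x
    rms = float(np.sqrt(np.mean(res.fun**2)))
    if abs(c) > 0.999 * center_bound_ppm and abs(c) > np.abs(w).max():
        return LorentzianFit(np.nan, np.nan, np.nan, np.nan, np.nan, ok=False)
    return LorentzianFit(float(c), float(g), float(d), float(b), rms)


def b0_map(series, offsets_ppm: np.ndarray | None = None,
           mask: np.ndarray | None = None,
           flag_warn_fraction: float = 0.2) -> np.ndarray:
    """Per-pixel B0-shift map (ppm) from a full Z-spectrum scan.

    ``series`` is a DynamicSeries whose measure entries sweep the full offset
    grid; pixel spectra are normalized by the scan's S0 entry.  Unfittable
    pixels are NaN; a warning is logged when more than ``flag_warn_fraction``
    of mask pixels are flagged.
    """
    mask = series.masks["liver"] if mask is None else np.asarray(mask, bool)
    midx = [i for i, e in enumerate(series.entries) if e.role == "measure"]
    s0idx = [i for i, e in enumerate(series.entries) if e.role == "s0"]
    if not s0idx:
        raise ValueError("series lacks an S0 reference entry")
    w = np.array([series.entries[i].offset_ppm for i in midx])
    if offsets_ppm is not None:
        sel = np.isin(np.round(w, 6), np.round(offsets_ppm, 6))
        midx = [i for i, keep in zip(midx, sel) if keep]
        w = w[sel]
    if w.size < 5:
        raise ValueError("need a full Z-spectrum sweep (>= 5 offsets)")
    s0 = series.images[s0idx].mean(axis=0)
    out = np.full(series.images.shape[1:], np.nan)
    n_flagged = 0
    ys, xs = np.nonzero(mask)
    for y, x in zip(ys, xs):
        if s0[y, x] <= 0:
            n_flagged += 1
            continue
        z = series.images[midx, y, x] / s0[y, x]
        fit = fit_dws(ZSpectrum(w, z))
        if fit.ok:
            out[y, x] = fit.center_ppm
        else:
            n_flagged += 1
    if len(ys) and n_flagged / len(ys) > flag_warn_fraction:
        logger.warning("B0 map: %.0f%% of mask pixels could not be fitted",
                       100.0 * n_flagged / len(ys))
    return out


@dataclass
class PartialMap:
    """MTR_Avg as a matrix of swept offsets x sweep times for one group."""

    offsets_ppm: np.ndarray
    times_min: np.ndarray
    mtr_avg: np.ndarray        # (n_offsets, n_sweeps)
    group: str = ""
    cell_height_min: float = 0.0   # sweep duration (display cell height)

    def __post_init__(self) -> None:
        self.mtr_avg = np.asarray(self.mtr_avg, float)
        if self.mtr_avg.shape != (len(self.offsets_ppm), len(self.times_min)):
            raise ValueError("matrix dimensions must match the axes")

    def profile_at(self, time_min: float) -> np.ndarray:
        """MTR profile (one value per offset) of the sweep nearest a time."""
        j = int(np.argmin(np.abs(self.times_min - time_min)))
        return self.mtr_avg[:, j]


def partial_map(series, roi: np.ndarray | None = None,
                pre_window_min: tuple[float, float] | None = None,
                group: str = "") -> PartialMap:
    """Single-subject offsets x sweeps MTR matrix from a partial-list series.

    Each retained entry contributes the Eq-style normalized, pre-injection
    corrected MTR of its offset; sweeps (schedule cycles) form the columns,
    stamped at the midpoint of the sweep's retained entries.
    """
    baseline = build_s0_baseline(series, roi)
    tidy = normalize(series, baseline, roi)
    inj = series.timing.injection_start_min
    offsets = np.array(sorted(tidy["offset_ppm"].unique()))
    curves = {}
    for wv, grp in tidy.groupby("offset_ppm"):
        curves[wv] = (grp["cycle"].to_numpy(),
                      mtr_curve(grp["Z"].to_numpy(), grp["time_min"].to_numpy(),
                                inj, pre_window_min).mtr_values)
    cycles = np.array(sorted(tidy["cycle"].unique()))
    mat = np.full((len(offsets), len(cycles)), np.nan)
    for i, wv in enumerate(offsets):
        cyc, mtr = curves[wv]
        mat[i, np.searchsorted(cycles, cyc)] = mtr
    t_by_cycle = tidy.groupby("cycle")["time_min"].mean()
    times = t_by_cycle.reindex(cycles).to_numpy()
    span = tidy.groupby("cycle")["time_min"].agg(np.ptp).median()
    return PartialMap(offsets, times, mat, group, float(span))


def group_partial_map(maps: list[PartialMap], group: str = "") -> tuple[PartialMap, np.ndarray]:
    """Group-mean partial map and the (n_subjects, offsets, sweeps) stack."""
    if not maps:
        raise ValueError("no maps to average")
    ref = maps[0]
    for m in maps[1:]:
        if m.mtr_avg.shape != ref.mtr_avg.shape or not np.allclose(
                m.offsets_ppm, ref.offsets_ppm):
            raise ValueError("maps must share offsets and sweep axes")
    stack = np.stack([m.mtr_avg for m in maps])
    mean = PartialMap(ref.offsets_ppm.copy(), ref.times_min.copy(),
                      stack.mean(axis=0), group, ref.cell_height_min)
    return mean, stack
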