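"""Unit conversions and calibrated NanoLUC quantification.

Copies-per-cell to nuclear concentration assumes clock proteins are nuclear:
``conc = copies / (N_A * V_nuc)``.  The default nuclear volume is back-derived
from the published copy/nM pairs of the rescaled clock model (mean ratio
~69.05 copies per nM, giving V ~= 1.147e-13 L ~= 115 fL), so that e.g. 596
copies/cell corresponds to 8.6 nM and 1.44 nM to ~100 molecules per nucleus.

NanoLUC calibration follows the spike-in protocol: recombinant enzyme added
to tissue at 0, 1e2 ... 1e6 monomers per cell, ln-transformed, and fitted by
linear regression per plate.  The zero-spike wells estimate the background
and are excluded from the regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

AVOGADRO = 6.02214076e23          # mol^-1
NUCLEAR_VOLUME_L = 1.1467e-13     # litres, back-derived (see module docstring)
CELLS_PER_GFW = 2.5e7             # cells per gramme fresh weight
TISSUE_CONC_GFW_PER_ML = 0.4


@dataclass(frozen=True)
class QuantConstants:
    """Physical constants tying copies/cell to nM and gFW to cells."""

    nuclear_volume: float = NUCLEAR_VOLUME_L   # litres
    avogadro: float = AVOGADRO                 # mol^-1
    cells_per_gfw: float = CELLS_PER_GFW
    tissue_conc: float = TISSUE_CONC_GFW_PER_ML

    def __post_init__(self) -> None:
        for name in ("nuclear_volume", "avogadro", "cells_per_gfw", "tissue_conc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def copies_per_nM(self) -> float:
        return self.avogadro * self.nuclear_volume * 1e-9


def copies_to_conc(copies: float | np.ndarray, qc: QuantConstants = QuantConstants()) -> float | np.ndarray:
    """Molecules per cell (nucleus) -> nuclear concentration in nM."""
    if np.any(np.asarray(copies) < 0):
        raise ValueError("copy number must be non-negative")
    return copies / qc.copies_per_nM


def conc_to_copies(conc_nM: float | np.ndarray, qc: QuantConstants = QuantConstants()) -> float | np.ndarray:
    """Nuclear concentration in nM -> molecules per cell; exact inverse of
    :func:`copies_to_conc`."""
    if np.any(np.asarray(conc_nM) < 0):
        raise ValueError("concentration must be non-negative")
    return conc_nM * qc.copies_per_nM


def nuclear_volume_from_pairs(copies: np.ndarray, conc_nM: np.ndarray,
                              avogadro: float = AVOGADRO) -> tuple[float, float]:
    """Back-solve the nuclear volume from (copies/cell, nM) pairs.

    Returns (mean volume in litres, relative spread = (max-min)/mean of the
    per-pair solutions).
    """
    copies = np.asarray(copies, dtype=float)
    conc = np.asarray(conc_nM, dtype=float)
    if copies.shape != conc.shape or copies.size == 0:
        raise ValueError("need matching, non-empty arrays")
    v = copies / (avogadro * conc * 1e-9)
    return float(v.mean()), float((v.max() - v.min()) / v.mean())


@dataclass(frozen=True)
class CalibrationModel:
    """ln-space standard curve: ln(signal - bg) = intercept + slope*ln(copies)."""

    intercept: float
    slope: float
    residual_sd: float
    n_points: int
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("calibration needs at least 2 points")
        if not (math.isfinite(self.intercept) and math.isfinite(self.slope)):
            raise ValueError("non-finite calibration coefficients")


def fit_standard_curve(spike_table: pd.DataFrame, subtract_background: bool = True) -> CalibrationModel:
    """Fit the per-plate ln-linear standard curve.

    ``spike_table`` needs columns ``spike_copies_per_cell`` and
    ``luminescence``.  Zero-spike wells estimate the background (mean signal)
    and are excluded from the regression.
    """
    t = spike_table
    pos = t[t["spike_copies_per_cell"] > 0]
    zero = t[t["spike_copies_per_cell"] == 0]
    levels = np.unique(pos["spike_copies_per_cell"].to_numpy(dtype=float))
    if levels.size < 2:
        raise ValueError("need at least 2 distinct positive spike levels")
    bg = float(zero["luminescence"].mean()) if (subtract_background and len(zero)) else 0.0
    signal = pos["luminescence"].to_numpy(dtype=float) - bg
    if np.any(signal <= 0):
        raise ValueError("background exceeds some positive-spike signals")
    x = np.log(pos["spike_copies_per_cell"].to_numpy(dtype=float))
    y = np.log(signal)
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    dof = max(len(x) - 2, 1)
    return CalibrationModel(
        intercept=float(res.intercept), slope=float(res.slope),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        n_points=int(len(x)), background=bg,
    )


def luminescence_to_copies(signal: float | np.ndarray, model: CalibrationModel) -> float | np.ndarray:
    """Invert the standard curve: signal -> molecules per cell."""
    signal = np.asarray(signal, dtype=float)
    if np.any(signal <= 0):
        raise ValueError("signal must be positive")
    net = signal - model.background
    if np.any(net <= 0):
        raise ValueError("signal must exceed the plate background")
    out = np.exp((np.log(net) - model.intercept) / model.slope)
    return float(out) if out.ndim == 0 else out


@dataclass
class DetrendResult:
    time_h: np.ndarray
    signal: np.ndarray
    decay_rate_per_h: float      # lambda of the removed exp(-lambda t) trend


def detrend_invivo(time_h: np.ndarray, signal: np.ndarray,
                   trend_start: float | None = None, day_h: float = 24.0) -> DetrendResult:
    """Remove the exponential (furimazine-decay) trend from an in vivo series.

    The trend is estimated on whole-day bin means of ln(signal), starting at
    ``trend_start`` (default: the start of the series), i.e. over the constant
    light span when one is supplied.  The fitted exp(slope*(t - t_mean)) is
    divided out, preserving the overall mean and the rhythmic component.
    Idempotent: a second pass estimates a ~zero slope.
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(signal, dtype=float)
    if np.any(y <= 0):
        raise ValueError("signals must be strictly positive")
    if t.size < 3 or t.max() - t.min() <= day_h:
        raise ValueError("need >=3 timepoints spanning more than 24 h")
    start = t.min() if trend_start is None else trend_start
    mask = t >= start
    tb, yb = t[mask], np.log(y[mask])
    n_days = int(np.floor((tb.max() - start) / day_h))
    if n_days < 2:
        raise ValueError("need at least two whole days to estimate the trend")
    centers, means = [], []
    for d in range(n_days):
        sel = (tb >= start + d * day_h) & (tb < start + (d + 1) * day_h)
        if sel.any():
            centers.append(tb[sel].mean())
            means.append(yb[sel].mean())
    res = stats.linregress(centers, means)
    t_ref = float(np.mean(centers))
    detrended = y * np.exp(-res.slope * (t - t_ref))
    return DetrendResult(t, detrended, decay_rate_per_h=float(-res.slope))


def scale_invivo_to_copies(invivo_t: np.ndarray, invivo_y: np.ndarray,
                           invitro_t: np.ndarray, invitro_y: np.ndarray,
                           ) -> tuple[np.ndarray, float]:
    """Scale an in vivo signal so its mean matches the cognate in vitro data
    (copies/cell) over the overlapping time window.

    Returns (scaled in vivo series, multiplicative factor).  The factor is
    reusable on other reporters recorded in the same run.
    """
    a_t, a_y = np.asarray(invivo_t, float), np.asarray(invivo_y, float)
    b_t, b_y = np.asarray(invitro_t, float), np.asarray(invitro_y, float)
    lo, hi = max(a_t.min(), b_t.min()), min(a_t.max(), b_t.max())
    if hi <= lo:
        raise ValueError("series have no overlapping time coverage")
    a_m = a_y[(a_t >= lo) & (a_t <= hi)].mean()
    b_m = b_y[(b_t >= lo) & (b_t <= hi)].mean()
    if b_m == 0:
        raise ValueError("in vitro series has zero mean over the overlap")
    if a_m == 0:
        raise ValueError("in vivo series has zero mean over the overlap")
    factor = float(b_m / a_m)
    return a_y * factor, factor
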