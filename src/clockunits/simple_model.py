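"""Data-driven protein predictor: dP/dt = s*M(t) - k(t)*P.

Absolute mRNA timeseries (copies/cell) are interpolated with a cubic spline
in ln-space and drive a one-state translation/degradation ODE per protein.
The translation rate s comes from a ribosome elongation rate of 3 codons/s
and a density of 6.6 ribosomes per kb of transcript; degradation switches
between light and dark rates at dawn/dusk, since light destabilises several
clock proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from .regimes import LightRegime


@dataclass
class RnaTimeseries:
    """Absolute mRNA abundance (copies/cell) against ZT time."""

    gene_id: str
    time_h: np.ndarray
    copies_per_cell: np.ndarray
    light: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.copies_per_cell = np.asarray(self.copies_per_cell, dtype=float)
        if self.time_h.shape != self.copies_per_cell.shape:
            raise ValueError("time and abundance arrays must match")

    def to_frame(self) -> pd.DataFrame:
        d = {"gene_id": self.gene_id, "time_h": self.time_h,
             "copies_per_cell": self.copies_per_cell}
        if self.light is not None:
            d["light_state"] = np.asarray(self.light).astype(int)
        return pd.DataFrame(d)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RnaTimeseries":
        gene = str(frame["gene_id"].iloc[0]) if "gene_id" in frame else ""
        light = frame["light_state"].to_numpy() if "light_state" in frame else None
        return cls(gene, frame["time_h"].to_numpy(dtype=float),
                   frame["copies_per_cell"].to_numpy(dtype=float), light)


@dataclass
class ProteinTimeseries:
    gene_id: str
    time_h: np.ndarray
    copies_per_cell: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.gene_id, "time_h": self.time_h,
                             "copies_per_cell": self.copies_per_cell})


@dataclass(frozen=True)
class ProteinKinetics:
    """Per-protein translation/degradation constants.

    ``s`` (proteins per mRNA per hour) is derived from the elongation rate
    and ribosome density unless given explicitly.  The ORF length is retained
    for auditability; it cancels in steady ribosome traversal, and the
    density may be read per kb of ORF or of full transcript with an identical
    result (``density_basis`` records the convention).
    """

    gene_id: str
    k_light: float            # h^-1
    k_dark: float             # h^-1
    orf_length_codons: int = 500
    elongation_rate_codons_s: float = 3.0
    ribosome_density_per_kb: float = 6.6
    s: float | None = None    # proteins mRNA^-1 h^-1, derived if None
    density_basis: str = "transcript"

    def __post_init__(self) -> None:
        for name in ("k_light", "k_dark", "elongation_rate_codons_s",
                     "ribosome_density_per_kb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.orf_length_codons <= 0:
            raise ValueError("orf_length_codons must be positive")


def translation_rate(kin: ProteinKinetics) -> float:
    """Proteins produced per mRNA per hour under steady ribosome traversal.

    s = density (nt^-1) * elongation (nt/s) * 3600; with the defaults
    (6.6 ribosomes/kb, 3 codons/s = 9 nt/s) this is ~213.8 h^-1 ~ 0.0594 s^-1.
    """
    if kin.s is not None:
        return kin.s
    per_nt = kin.ribosome_density_per_kb / 1000.0
    nt_per_s = kin.elongation_rate_codons_s * 3.0
    return per_nt * nt_per_s * 3600.0


def interpolate_rna(ts: RnaTimeseries, zero_floor: bool = True):
    """Cubic-spline interpolation of ln(copies/cell); returns M(t), strictly
    positive and exact at the knots.  Zero values are floored at half the
    smallest positive observation (with a warning) before the ln-transform.
    """
    t = ts.time_h
    y = ts.copies_per_cell.copy()
    if t.size < 4:
        raise ValueError("need at least 4 timepoints for a cubic spline")
    if np.unique(t).size != t.size:
        raise ValueError("duplicate timepoints")
    if np.any(y < 0):
        raise ValueError("negative mRNA abundance")
    if np.any(y == 0):
        if not zero_floor:
            raise ValueError("zero mRNA abundance and zero_floor disabled")
        floor = 0.5 * y[y > 0].min()
        warnings.warn(f"flooring {np.sum(y == 0)} zero mRNA values at {floor:g}")
        y[y == 0] = floor
    order = np.argsort(t)
    spline = CubicSpline(t[order], np.log(y[order]))

    def M(tq):
        return np.exp(spline(tq))

    M.t_min, M.t_max = float(t.min()), float(t.max())
    return M


def simulate_protein(M, kin: ProteinKinetics, regime: LightRegime,
                     init: float | str = "cyclic", grid_h: float = 0.1,
                     cycle_h: float = 24.0, cyclic_tol: float = 1e-3,
                     max_cycles: int = 200, rtol: float = 1e-8,
                     atol: float = 1e-9) -> ProteinTimeseries:
    """Integrate dP/dt = s*M(t) - k*P over the regime.

    k switches instantaneously between light and dark values; integration is
    restarted at each switch.  ``init='cyclic'`` pre-entrains by integrating
    repeated copies of the first ``cycle_h`` of the regime until the
    start-of-cycle value changes by <0.1% (relative), then integrates the full
    span from that value.
    """
    s = translation_rate(kin)

    def k_at(t):
        return kin.k_light if regime.light_at(t) else kin.k_dark

    def integrate(t_start, t_end, p0, t_eval=None):
        bounds = [t_start] + [b for b in regime.switch_times()
                              if t_start < b < t_end] + [t_end]
        times, values = [], []
        p = p0
        for a, b in zip(bounds[:-1], bounds[1:]):
            k = k_at(a)
            sol = solve_ivp(lambda t, y: [s * M(t) - k * y[0]], (a, b), [p],
                            method="LSODA", rtol=rtol, atol=atol,
                            dense_output=True)
            if not sol.success:
                raise RuntimeError(f"integration failed in [{a}, {b}]: {sol.message}")
            if t_eval is not None:
                sel = t_eval[(t_eval >= a) & (t_eval < b)]
                times.append(sel)
                values.append(sol.sol(sel)[0])
            p = float(sol.y[0, -1])
        if t_eval is not None and t_eval.size and np.isclose(t_eval[-1], t_end):
            times.append(np.array([t_end]))
            values.append(np.array([p]))
        return p, times, values

    if init == "cyclic":
        p = 0.0
        t0 = regime.t0
        for _ in range(max_cycles):
            p_next, _, _ = integrate(t0, min(t0 + cycle_h, regime.t1), p)
            if p > 0 and abs(p_next - p) / max(p, 1e-30) < cyclic_tol:
                p = p_next
                break
            p = p_next
        p0 = p
    else:
        p0 = float(init)
        if p0 < 0:
            raise ValueError("negative initial protein level")

    t_eval = np.arange(regime.t0, regime.t1 + 0.5 * grid_h, grid_h)
    t_eval = t_eval[t_eval <= regime.t1 + 1e-12]
    _, times, values = integrate(regime.t0, regime.t1, p0, t_eval=t_eval)
    t_out = np.concatenate(times)
    y_out = np.concatenate(values)
    uniq = np.unique(t_out, return_index=True)[1]
    return ProteinTimeseries(kin.gene_id, t_out[uniq], y_out[uniq])


def fit_decay_rate(time_h: np.ndarray, level: np.ndarray) -> float:
    """Least-squares exponential decay rate k (h^-1) in ln-space."""
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(level, dtype=float)
    if np.any(y <= 0):
        raise ValueError("levels must be strictly positive")
    if t.size < 2:
        raise ValueError("need at least 2 points")
    if t.size == 2:
        k = float(np.log(y[0] / y[1]) / (t[1] - t[0]))
    else:
        res = stats.linregress(t, np.log(y))
        k = float(-res.slope)
    if k <= 0:
        raise ValueError("series is not decaying; cannot estimate a decay rate")
    return k


@dataclass(frozen=True)
class ProteinSummary:
    """Peak/trough copy numbers and relative amplitudes, Table-1 style.

    ``peak``, ``trough`` and ``fold_change`` describe the LD window (ZT0-24);
    ``window`` is the LL window used and ``ll_ld_ratio`` the LL fold-change
    relative to LD.
    """

    gene_id: str
    peak: float
    trough: float
    fold_change: float
    window: tuple[float, float]
    ll_ld_ratio: float
    peak_ll: float
    trough_ll: float
    fold_change_ll: float

    def __post_init__(self) -> None:
        if not (self.peak >= self.trough > 0):
            raise ValueError("require peak >= trough > 0")


def _window_stats(ts: ProteinTimeseries, window: tuple[float, float]) -> tuple[float, float]:
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty window")
    sel = (ts.time_h >= lo) & (ts.time_h <= hi)
    if not sel.any():
        raise ValueError(f"window {window} outside trajectory span")
    y = ts.copies_per_cell[sel]
    return float(y.max()), float(y.min())


def summarize(ts: ProteinTimeseries, ld_window: tuple[float, float] = (0.0, 24.0),
              ll_window: tuple[float, float] = (24.0, 48.0)) -> ProteinSummary:
    """Peak, trough and fold-change within the LD and LL windows; the LL/LD
    ratio compares the relative amplitudes between the light conditions."""
    pk, tr = _window_stats(ts, ld_window)
    pk_ll, tr_ll = _window_stats(ts, ll_window)
    fold = pk / tr
    fold_ll = pk_ll / tr_ll
    return ProteinSummary(ts.gene_id, pk, tr, fold, ll_window,
                          fold_ll / fold, pk_ll, tr_ll, fold_ll)
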