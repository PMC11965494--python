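"""Clock gene-circuit ODE engine: load, simulate, rescale, extract Kd.

Models are defined in JSON: named state variables (mRNAs ``c*m``, proteins
``cL``, ``cP7``, ``cEC``...), positive parameters (``n*`` transcription,
``m*`` degradation, ``g*`` Michaelis/dissociation constants, Hill
coefficients fixed at 2 in the rate expressions), a binary light input ``L``
and three protein scale factors (``s_L``, ``s_P7``, ``s_LUX``).  Rate
expressions are written in the absolute (copies/cell) frame with the scale
factors appearing explicitly (e.g. ``(s_L*g5)**2 / ((s_L*g5)**2 + cL**2)``),
so that:

* factors at 1 give the RNA-only-absolute model (version ``.3``),
* setting fitted factors gives ``.4`` (explicit scaling parameters), and
* folding each factor into the parameters it multiplies and resetting the
  factors to 1 gives ``.5`` — algebraically identical dynamics to ``.4``.

The shipped model files are *synthetic reconstructions* of the published
U2019/U2020 circuit architecture: same wiring, variable and parameter
naming, light forcing and scaling scheme, but parameter values chosen here
(the published supplementary parameter sets are not redistributed with this
package).
"""

from __future__ import annotations

import ast
import copy as _copy
import json
import math
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from .regimes import LightRegime, ld_cycles
from .units import QuantConstants, copies_to_conc

_MATH_NS = {"exp": math.exp, "log": math.log, "sqrt": math.sqrt,
            "tanh": math.tanh, "pow": pow, "min": min, "max": max}
_VERSION_RE = re.compile(r"^U\d{4}\.[345]$")


class ModelDefinitionError(ValueError):
    pass


@dataclass
class ClockModel:
    """A clock circuit: states, parameters, rate expressions, scaling state."""

    version: str
    species: dict[str, float]
    parameters: dict[str, float]
    rates: dict[str, str]
    scale_factors: tuple[str, ...] = ("s_L", "s_P7", "s_LUX")
    scaled_parameters: dict[str, str] = field(default_factory=dict)
    pools: dict[str, list[str]] = field(default_factory=dict)
    kd_map: list[dict[str, str]] = field(default_factory=list)
    reporters: dict[str, dict] = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        self.validate()
        self._rhs = None

    # -- validation and (de)serialisation ---------------------------------
    def validate(self) -> None:
        if not _VERSION_RE.match(self.version):
            raise ModelDefinitionError(f"unknown version tag {self.version!r}")
        if set(self.rates) != set(self.species):
            missing = set(self.species) ^ set(self.rates)
            raise ModelDefinitionError(f"rates/species mismatch: {sorted(missing)}")
        for p, v in self.parameters.items():
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ModelDefinitionError(f"non-finite parameter {p}")
        allowed = set(self.species) | set(self.parameters) | {"L", "t"} | set(_MATH_NS)
        for var, expr in self.rates.items():
            self._check_expr(expr, allowed, var)
        for name, rep in self.reporters.items():
            self._check_expr(rep["rate"], allowed | set(self.reporters), name)
        for f in self.scale_factors:
            if f not in self.parameters:
                raise ModelDefinitionError(f"missing parameter {f!r} (scale factor)")
        for p, f in self.scaled_parameters.items():
            if p not in self.parameters:
                raise ModelDefinitionError(f"missing parameter {p!r} (scaled)")
            if f not in self.scale_factors:
                raise ModelDefinitionError(f"unknown scale factor {f!r} for {p!r}")
        for rec in self.kd_map:
            if rec["parameter"] not in self.parameters:
                raise ModelDefinitionError(
                    f"missing parameter {rec['parameter']!r} (kd_map)")

    @staticmethod
    def _check_expr(expr: str, allowed: set[str], owner: str) -> None:
        try:
            tree = ast.parse(expr, mode="eval")
        except SyntaxError as e:
            raise ModelDefinitionError(f"bad rate expression for {owner!r}: {e}")
        for node in ast.walk(tree):
            if isinstance(node, ast.Name) and node.id not in allowed:
                raise ModelDefinitionError(
                    f"missing parameter {node.id!r} in rate for {owner!r}")

    def to_definition(self) -> dict:
        return {
            "version": self.version,
            "notes": self.notes,
            "species": dict(self.species),
            "parameters": dict(self.parameters),
            "rates": dict(self.rates),
            "scale_factors": list(self.scale_factors),
            "scaled_parameters": dict(self.scaled_parameters),
            "pools": _copy.deepcopy(self.pools),
            "kd_map": _copy.deepcopy(self.kd_map),
            "reporters": _copy.deepcopy(self.reporters),
        }

    @classmethod
    def from_definition(cls, d: dict) -> "ClockModel":
        return cls(
            version=d["version"], species=dict(d["species"]),
            parameters=dict(d["parameters"]), rates=dict(d["rates"]),
            scale_factors=tuple(d.get("scale_factors", ("s_L", "s_P7", "s_LUX"))),
            scaled_parameters=dict(d.get("scaled_parameters", {})),
            pools={k: list(v) for k, v in d.get("pools", {}).items()},
            kd_map=[dict(r) for r in d.get("kd_map", [])],
            reporters=_copy.deepcopy(d.get("reporters", {})),
            notes=d.get("notes", ""),
        )

    def copy(self) -> "ClockModel":
        return ClockModel.from_definition(self.to_definition())

    # -- compiled right-hand side -----------------------------------------
    def _compiled_rhs(self):
        if self._rhs is not None:
            return self._rhs
        names = list(self.species)
        lines = ["def _rhs(t, y, L):"]
        for i, n in enumerate(names):
            lines.append(f"    {n} = y[{i}]")
        for p, v in self.parameters.items():
            lines.append(f"    {p} = {float(v)!r}")
        derivs = ", ".join(f"({self.rates[n]})" for n in names)
        lines.append(f"    return ({derivs},)")
        ns: dict = {}
        exec(compile("\n".join(lines), f"<rates:{self.version}>", "exec"),
             dict(_MATH_NS, __builtins__={}), ns)
        self._rhs = ns["_rhs"]
        return self._rhs


def load_model(path: str | Path) -> ClockModel:
    with open(path) as fh:
        return ClockModel.from_definition(json.load(fh))


def save_model(model: ClockModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_definition(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def shipped_model(version: str) -> ClockModel:
    """Load one of the packaged synthetic circuit reconstructions
    (``U2019.3`` or ``U2020.3``)."""
    fname = f"{version}.synthetic.json"
    ref = resources.files("clockunits").joinpath("models").joinpath(fname)
    with resources.as_file(ref) as p:
        return load_model(p)


# -- simulation ------------------------------------------------------------

@dataclass
class Trajectories:
    """Dense recorded trajectories after entrainment; ZT0 = dawn of the
    first recorded cycle."""

    model: ClockModel
    regime: LightRegime
    zt: np.ndarray
    states: dict[str, np.ndarray]
    record_start_abs: float
    _sols: list = field(default_factory=list, repr=False)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[name]

    def light(self) -> np.ndarray:
        return np.array([self.regime.light_at(min(z + self.record_start_abs,
                                                  self.regime.t1))
                         for z in self.zt])

    def state_at_abs(self, t: float) -> dict[str, float]:
        for a, b, sol in self._sols:
            if a <= t <= b:
                vals = sol(t)
                return dict(zip(self.model.species, vals))
        raise ValueError(f"time {t} outside integrated span")

    def to_frame(self):
        import pandas as pd
        d = {"zt": self.zt}
        d.update(self.states)
        return pd.DataFrame(d)


def simulate(model: ClockModel, regime: LightRegime, entrain_cycles: int = 10,
             record_span: float = 48.0, grid_h: float = 0.1,
             cycle_h: float = 24.0, rtol: float = 1e-8, atol: float = 1e-6,
             check_entrainment: bool = True,
             entrain_tol: float = 0.005) -> Trajectories:
    """Entrain the circuit then record dense trajectories.

    The first ``entrain_cycles`` cycles of the regime are integrated and
    discarded; the following ``record_span`` hours are recorded on a
    ``grid_h`` grid.  Light is a binary step; integration restarts at every
    dawn/dusk.  With ``check_entrainment``, the recorded first and second
    cycle states are compared and a warning is issued above ``entrain_tol``
    relative difference (the entrained state should be periodic).
    """
    if entrain_cycles < 1:
        raise ValueError("entrain_cycles must be >= 1")
    t_rec = regime.t0 + entrain_cycles * cycle_h
    t_end = t_rec + record_span
    if t_end > regime.t1 + 1e-9:
        raise ValueError(f"regime ends at {regime.t1} h but simulation needs "
                         f"{t_end} h; extend the regime")
    rhs = model._compiled_rhs()
    y = np.array([model.species[n] for n in model.species], dtype=float)
    bounds = [regime.t0] + [b for b in regime.switch_times() if b < t_end] + [t_end]
    sols = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        Lval = 1.0 if regime.light_at(a) else 0.0
        sol = solve_ivp(rhs, (a, b), y, args=(Lval,), method="LSODA",
                        rtol=rtol, atol=atol, dense_output=True)
        if not sol.success:
            raise RuntimeError(
                f"integration failed at t={sol.t[-1]:.2f} h (segment "
                f"[{a},{b}], L={Lval}): {sol.message}; state={sol.y[:, -1]}")
        if b > t_rec:
            sols.append((a, b, sol.sol))
        y = sol.y[:, -1]

    zt = np.arange(0.0, record_span + 0.5 * grid_h, grid_h)
    zt = zt[zt <= record_span + 1e-12]
    names = list(model.species)
    out = np.empty((len(names), zt.size))
    for j, z in enumerate(zt):
        t = t_rec + z
        for a, b, s in sols:
            if a <= t <= b:
                out[:, j] = s(t)
                break
    out = np.clip(out, 0.0, None)
    states = {n: out[i] for i, n in enumerate(names)}
    traj = Trajectories(model, regime, zt, states, t_rec, sols)

    if check_entrainment and record_span >= 2 * cycle_h - 1e-9:
        err = entrainment_error(traj, cycle_h)
        if err > entrain_tol:
            warnings.warn(f"cycle-to-cycle state difference {err:.3%} exceeds "
                          f"{entrain_tol:.1%} after {entrain_cycles} cycles; "
                          "consider extending entrainment")
    if model.reporters:
        _simulate_reporters(model, traj, rtol=rtol, atol=atol)
    return traj


def entrainment_error(traj: Trajectories, cycle_h: float = 24.0) -> float:
    """Max relative state difference between ZT0 and ZT0+24h of the record."""
    a = traj.state_at_abs(traj.record_start_abs)
    b = traj.state_at_abs(traj.record_start_abs + cycle_h)
    va = np.array(list(a.values()))
    vb = np.array([b[k] for k in a])
    scale = np.maximum(np.abs(va), 1e-6 * max(np.abs(va).max(), 1.0))
    return float(np.max(np.abs(va - vb) / scale))


def _simulate_reporters(model: ClockModel, traj: Trajectories,
                        rtol: float, atol: float) -> None:
    """Integrate feedback-free reporter species driven by the core solution.

    The core trajectories are computed first and the reporters read them
    through the solver's dense output, so adding a reporter cannot perturb
    the core states.
    """
    names = list(model.reporters)
    exprs = [model.reporters[n]["rate"] for n in names]
    core = list(model.species)
    lines = ["def _rrhs(t, r, L, core_vals):"]
    for i, n in enumerate(core):
        lines.append(f"    {n} = core_vals[{i}]")
    for i, n in enumerate(names):
        lines.append(f"    {n} = r[{i}]")
    for p, v in model.parameters.items():
        lines.append(f"    {p} = {float(v)!r}")
    lines.append("    return (" + ", ".join(f"({e})" for e in exprs) + ",)")
    ns: dict = {}
    exec(compile("\n".join(lines), "<reporter-rates>", "exec"),
         dict(_MATH_NS, __builtins__={}), ns)
    rrhs = ns["_rrhs"]

    def wrapped(t, r, L):
        for a, b, s in traj._sols:
            if a <= t <= b:
                return rrhs(t, r, L, s(t))
        raise ValueError(f"reporter time {t} outside core span")

    t_rec = traj.record_start_abs
    t_end = t_rec + float(traj.zt[-1])
    core_at_start = traj.state_at_abs(t_rec)

    def _init(rep):
        """A numeric initial value, or a core species name to copy the
        entrained state from at record start."""
        iv = rep.get("init", 0.0)
        return core_at_start[iv] if isinstance(iv, str) else float(iv)

    r = np.array([_init(model.reporters[n]) for n in names], float)
    bounds = [t_rec] + [b for b in traj.regime.switch_times()
                        if t_rec < b < t_end] + [t_end]
    grids, vals = [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        Lval = 1.0 if traj.regime.light_at(a) else 0.0
        sel = traj.zt[(traj.zt + t_rec >= a) & (traj.zt + t_rec < b)]
        sol = solve_ivp(wrapped, (a, b), r, args=(Lval,), method="LSODA",
                        rtol=rtol, atol=atol, dense_output=True)
        if not sol.success:
            raise RuntimeError(f"reporter integration failed: {sol.message}")
        grids.append(sel)
        vals.append(sol.sol(sel + t_rec) if sel.size else np.empty((len(names), 0)))
        r = sol.y[:, -1]
    grids.append(np.array([traj.zt[-1]]))
    vals.append(r.reshape(-1, 1))
    allv = np.concatenate(vals, axis=1)
    allt = np.concatenate(grids)
    uniq = np.unique(allt, return_index=True)[1]
    for i, n in enumerate(names):
        traj.states[n] = np.clip(np.interp(traj.zt, allt[uniq], allv[i][uniq]),
                                 0.0, None)


def combine_pools(traj: Trajectories, protein: str) -> np.ndarray:
    """Pointwise sum of all state-variable pools of a protein (e.g. free LUX
    plus LUX within the Evening Complex)."""
    pools = traj.model.pools
    if protein not in pools:
        raise KeyError(f"unknown protein label {protein!r}; have {sorted(pools)}")
    total = np.zeros_like(traj.zt)
    for member in pools[protein]:
        total = total + traj.states[member]
    return total


# -- scaling ---------------------------------------------------------------

def apply_scaling(model: ClockModel, factors: dict[str, float]) -> ClockModel:
    """Set the protein scale factors (``.3`` -> ``.4``).

    The rate expressions already carry the factors, so this is a pure
    parameter update; the protein variables now read in copies/cell.
    """
    for f, v in factors.items():
        if f not in model.scale_factors:
            raise ValueError(f"unknown scale factor {f!r}")
        if v <= 0:
            raise ValueError(f"scale factor {f} must be positive, got {v}")
    out = model.copy()
    out.parameters.update({f: float(v) for f, v in factors.items()})
    if out.version.endswith(".3"):
        out.version = out.version[:-2] + ".4"
    out._rhs = None
    return out


def propagate_scaling(model: ClockModel) -> ClockModel:
    """Fold the scale factors into every parameter they multiply (``.4`` ->
    ``.5``), e.g. g5 takes the value s*g5; the factors reset to 1.  The
    ``.4`` and ``.5`` models simulate identical trajectories."""
    out = model.copy()
    for p, f in out.scaled_parameters.items():
        out.parameters[p] = out.parameters[p] * out.parameters[f]
    for f in out.scale_factors:
        out.parameters[f] = 1.0
    if out.version.endswith(".4"):
        out.version = out.version[:-2] + ".5"
    out._rhs = None
    return out


# -- dissociation constants ------------------------------------------------

@dataclass
class KdRecord:
    """A simulated DNA-binding dissociation constant in absolute units."""

    regulator: str
    target: str
    parameter: str
    kd_copies: float
    kd_nM: float
    kd_per_peak_nM: float | None = None

    def __post_init__(self) -> None:
        if self.kd_copies <= 0:
            raise ValueError("Kd must be positive")


def extract_kd(model: ClockModel, qc: QuantConstants = QuantConstants()) -> list[KdRecord]:
    """One record per (regulator, target) pair in the model's kd map; the
    parameter value (with any unfolded scale factor applied) is the Kd in
    copies/cell, converted to nM via the nuclear volume."""
    records = []
    for rec in model.kd_map:
        p = rec["parameter"]
        if p not in model.parameters:
            raise KeyError(f"unmapped parameter {p!r}")
        value = model.parameters[p]
        f = model.scaled_parameters.get(p)
        if f is not None:
            value = value * model.parameters[f]
        records.append(KdRecord(rec["regulator"], rec["target"], p,
                                kd_copies=float(value),
                                kd_nM=float(copies_to_conc(value, qc))))
    return records


def chip_recalibrate(record: KdRecord, n_peaks: float) -> KdRecord:
    """Divide the simulated Kd by the number of genome-wide binding regions
    (ChIP-seq peaks) competing for the protein; identity at n_peaks = 1."""
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    return KdRecord(record.regulator, record.target, record.parameter,
                    record.kd_copies, record.kd_nM,
                    kd_per_peak_nM=record.kd_nM / n_peaks)


def add_driven_species(model: ClockModel, name: str, rate: str,
                       init: float | str = 0.0) -> ClockModel:
    """Add a feedback-free (reporter) species integrated after the core.

    ``init`` is a number, or a core species name whose entrained value at
    record start seeds the reporter."""
    if name in model.species or name in model.reporters:
        raise ValueError(f"species {name!r} already exists")
    if isinstance(init, str) and init not in model.species:
        raise ValueError(f"unknown init species {init!r}")
    out = model.copy()
    out.reporters[name] = {"rate": rate,
                           "init": init if isinstance(init, str) else float(init)}
    out.validate()
    return out
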