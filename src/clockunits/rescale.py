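"""Estimate the three protein scale factors (.3 -> .4 step).

The scale of every protein in the circuit is set by three factors: s_L for
the combined LHY/CCA1 protein, s_P7 for the PRR family (the PRRs and TOC1
act as additive repressors, so one factor covers all four) and s_LUX for the
Evening Complex components.  The factors are fitted by least squares between
the model's simulated, pool-combined proteins and target waveforms (in
practice, the simple model's predictions) — the model is re-simulated inside
the cost function, with no linearisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .clock_model import ClockModel, Trajectories, apply_scaling, combine_pools, simulate
from .regimes import LightRegime

FACTOR_FOR_POOL = {"LHY/CCA1": "s_L", "PRR7": "s_P7", "LUX": "s_LUX"}


@dataclass
class ScalingFit:
    s_L: float
    s_P7: float
    s_LUX: float
    cost: float
    cost_at_unity: float
    targets_used: tuple[str, ...]
    diagnostics: dict[str, dict] = field(default_factory=dict)
    n_evaluations: int = 0
    converged: bool = True
    message: str = ""

    @property
    def factors(self) -> dict[str, float]:
        return {"s_L": self.s_L, "s_P7": self.s_P7, "s_LUX": self.s_LUX}


def _residuals(traj: Trajectories, targets: dict, scale: str) -> dict[str, np.ndarray]:
    out = {}
    for pool, (t_t, t_y) in targets.items():
        sim = combine_pools(traj, pool)
        sim_at = np.interp(t_t, traj.zt, sim)
        if scale == "ln":
            out[pool] = np.log(np.maximum(sim_at, 1e-12)) - np.log(np.maximum(t_y, 1e-12))
        else:
            out[pool] = sim_at - t_y
    return out


def fit_scaling(model: ClockModel, targets: dict, regime: LightRegime,
                entrain_cycles: int = 10, record_span: float = 24.0,
                scale: str = "linear", weights: dict | None = None,
                bounds_log10: tuple[float, float] = (-5.0, 5.0),
                sim_opts: dict | None = None,
                xatol: float = 1e-4, fatol: float = 1e-10,
                max_iter: int = 400) -> ScalingFit:
    """Fit (s_L, s_P7, s_LUX) to target protein waveforms.

    ``targets`` maps pool labels (must include "LHY/CCA1", "PRR7" and "LUX";
    other pools are allowed and add constraints) to ``(time_zt, copies)``
    pairs sampled within the recorded span.  Residuals are computed on the
    linear copy-number scale by default (``scale='ln'`` switches).  The
    optimizer is a deterministic Nelder-Mead simplex over log10-factors
    started at factors 1, so fits are reproducible without seeds; the
    returned cost never exceeds the cost at factors 1.
    """
    required = set(FACTOR_FOR_POOL)
    if not required.issubset(targets):
        raise ValueError(f"targets must include {sorted(required)}")
    for pool in targets:
        if pool not in model.pools:
            raise KeyError(f"model has no pool {pool!r}")
    weights = weights or {}
    targets = {k: (np.asarray(t, float), np.asarray(y, float))
               for k, (t, y) in targets.items()}
    opts = dict(grid_h=0.25, rtol=1e-7, atol=1e-8, check_entrainment=False)
    opts.update(sim_opts or {})
    n_eval = 0

    def cost(log10_f: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        factors = {k: 10.0 ** v for k, v in
                   zip(("s_L", "s_P7", "s_LUX"), log10_f)}
        scaled = apply_scaling(model, factors)
        traj = simulate(scaled, regime, entrain_cycles=entrain_cycles,
                        record_span=record_span, **opts)
        res = _residuals(traj, targets, scale)
        return float(sum(weights.get(p, 1.0) * np.sum(r ** 2)
                         for p, r in res.items()))

    x0 = np.zeros(3)
    c0 = cost(x0)
    result = minimize(cost, x0, method="Nelder-Mead",
                      bounds=[bounds_log10] * 3,
                      options=dict(xatol=xatol, fatol=fatol,
                                   maxiter=max_iter, adaptive=True))
    if result.fun <= c0:
        best = 10.0 ** result.x
        best_cost = float(result.fun)
    else:   # optimizer never worsens the start
        best = np.ones(3)
        best_cost = c0

    fitted = apply_scaling(model, dict(zip(("s_L", "s_P7", "s_LUX"), best)))
    traj = simulate(fitted, regime, entrain_cycles=entrain_cycles,
                    record_span=record_span, **opts)
    res = _residuals(traj, targets, scale)
    diagnostics = {}
    for pool, r in res.items():
        t_t, t_y = targets[pool]
        sim_mean = float(np.interp(t_t, traj.zt, combine_pools(traj, pool)).mean())
        diagnostics[pool] = {
            "rmse": float(np.sqrt(np.mean(r ** 2))),
            "target_mean": float(np.mean(t_y)),
            "sim_mean": sim_mean,
            "sim_to_target_mean_ratio": sim_mean / max(float(np.mean(t_y)), 1e-300),
        }
    return ScalingFit(
        s_L=float(best[0]), s_P7=float(best[1]), s_LUX=float(best[2]),
        cost=best_cost, cost_at_unity=c0, targets_used=tuple(sorted(targets)),
        diagnostics=diagnostics, n_evaluations=n_eval,
        converged=bool(result.success or result.fun <= c0),
        message=str(result.message),
    )
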