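"""Rescale the clock circuit models to the predicted absolute protein
levels: fit the three scale factors (s_L, s_P7, s_LUX) by least squares
against the combined LHY+CCA1, PRR7 and LUX predictions, then write the .4
(explicit factors) and .5 (factors folded into parameters) model files for
both circuit variants."""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import FIT_OPTS, RESULTS

from clockunits.clock_model import (apply_scaling, propagate_scaling,
                                    save_model, shipped_model)
from clockunits.regimes import ld_cycles
from clockunits.rescale import fit_scaling

pred = pd.read_csv(RESULTS / "predicted_proteins.csv")
wide = pred.pivot(index="time_h", columns="gene_id", values="copies_per_cell")
sel = wide.index <= 24.0
t = wide.index[sel].to_numpy()
targets = {
    "LHY/CCA1": (t, (wide.LHY + wide.CCA1)[sel].to_numpy()),
    "PRR7": (t, wide.PRR7[sel].to_numpy()),
    "LUX": (t, wide.LUX[sel].to_numpy()),
}

regime = ld_cycles(12)
report = {}
for version in ("U2019.3", "U2020.3"):
    model3 = shipped_model(version)
    fit = fit_scaling(model3, targets, regime, **FIT_OPTS)
    model4 = apply_scaling(model3, fit.factors)
    model5 = propagate_scaling(model4)
    save_model(model4, RESULTS / f"{model4.version}.synthetic.json")
    save_model(model5, RESULTS / f"{model5.version}.synthetic.json")
    report[version] = {
        "factors": fit.factors, "cost": fit.cost,
        "cost_at_unity": fit.cost_at_unity,
        "n_evaluations": fit.n_evaluations,
        "diagnostics": fit.diagnostics,
    }
    print(f"{version}: factors "
          + ", ".join(f"{k}={v:,.1f}" for k, v in fit.factors.items())
          + f"  (cost {fit.cost:.3g}, {fit.n_evaluations} simulations)")
    for pool, d in fit.diagnostics.items():
        print(f"    {pool:9s} sim/target mean ratio "
              f"{d['sim_to_target_mean_ratio']:.2f}")

with open(RESULTS / "scaling_fit_report.json", "w") as fh:
    json.dump(report, fh, indent=1, sort_keys=True)
print("wrote .4/.5 model files and scaling_fit_report.json")
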