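"""Build the protein-level summary table (Pred. vs Sim. rows), the
TOC1-protein vs LHY-mRNA phase plane, and the short- vs long-photoperiod
waveform comparison from the rescaled circuit."""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import LD_WINDOW, LL_WINDOW, RESULTS

from clockunits.clock_model import combine_pools, load_model, simulate
from clockunits.regimes import ld_cycles, ld_then_ll
from clockunits.report import (build_phase_plane, build_protein_table,
                               compare_photoperiods)

pred = pd.read_csv(RESULTS / "predicted_proteins.csv")
wide = pred.pivot(index="time_h", columns="gene_id", values="copies_per_cell")
t_pred = wide.index.to_numpy()

model5 = load_model(RESULTS / "U2019.5.synthetic.json")
traj = simulate(model5, ld_then_ll(11, 72), entrain_cycles=10,
                record_span=96, check_entrainment=False)

sources = {}
for pool, gene in (("LHY/CCA1", None), ("PRR7", "PRR7"), ("TOC1", "TOC1"),
                   ("ELF3", "ELF3"), ("LUX", "LUX")):
    y_pred = ((wide.LHY + wide.CCA1) if gene is None else wide[gene]).to_numpy()
    sources[pool] = [
        ("Pred.", (t_pred, y_pred)),
        (f"Sim. {model5.version}", (traj.zt, combine_pools(traj, pool))),
    ]
table = build_protein_table(sources, LD_WINDOW, LL_WINDOW)
table.to_csv(RESULTS / "protein_table.csv", index=False)
print("protein-level summary (copies/cell):")
cols = ["protein", "source", "peak_ld", "trough_ld", "fold_ld", "ll_ld_ratio"]
print(table[cols].round(1).to_string(index=False))

pp = build_phase_plane(traj.zt, np.maximum(traj["cT"], 1e-6),
                       traj.zt, np.maximum(traj["cLm"], 1e-6),
                       marker_times=(0.0, 18.0, 24.0))
pp.to_csv(RESULTS / "phase_plane_toc1_lhy.csv", index=False)
ld_part = pp[pp.time_h <= 24]
print(f"\nphase plane: under LD, LHY mRNA peaks while TOC1 protein is at "
      f"{ld_part.x[ld_part.y.idxmax()] / ld_part.x.max():.0%} of its peak "
      "(reciprocal regulation)")

short = simulate(model5, ld_cycles(12, 8.0, 16.0), record_span=48,
                 check_entrainment=False)
long_ = simulate(model5, ld_cycles(12, 16.0, 8.0), record_span=48,
                 check_entrainment=False)
cmp_ = compare_photoperiods(short.zt, np.maximum(short["cL"], 1e-6),
                            long_.zt, np.maximum(long_["cL"], 1e-6))
cmp_.to_csv(RESULTS / "photoperiod_comparison.csv", index=False)
i = cmp_.abs_diff.idxmax()
print(f"photoperiod comparison (8L:16D vs 16L:8D, dawn TF): largest "
      f"normalised difference {cmp_.abs_diff[i]:.2f} at ZT{cmp_.time_h[i] % 24:.1f}"
      " (the dusk-sensitive night-time rise)")
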