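"""Extract DNA-binding dissociation constants from the rescaled (.5)
circuits in absolute units, convert copies/cell to nM via the nuclear
volume, and recalibrate by the number of genome-wide ChIP-seq binding
regions.  Also re-derives the nuclear volume and peak counts from the
published copy/nM table to show the conversions are mutually consistent."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS

from clockunits.clock_model import chip_recalibrate, extract_kd, load_model
from clockunits.data import table2_kd
from clockunits.pipeline import CHIP_PEAKS
from clockunits.units import QuantConstants, nuclear_volume_from_pairs

qc = QuantConstants()

t2 = table2_kd()
vol, spread = nuclear_volume_from_pairs(t2.kd_copies_per_cell.to_numpy(),
                                        t2.kd_nM.to_numpy())
print(f"published table: nuclear volume back-derived {vol*1e15:.1f} fL "
      f"(spread {spread:.1%}); package default {qc.nuclear_volume*1e15:.1f} fL")
ratios = t2.kd_nM / t2.kd_per_chip_peak_nM
print(f"back-derived ChIP peak counts: CCA1 ~{ratios[t2.protein=='CCA1'].mean():.0f}, "
      f"EC ~{ratios[t2.protein=='LUX'].mean():.1f}")

frames = []
for version in ("U2019.5", "U2020.5"):
    model5 = load_model(RESULTS / f"{version}.synthetic.json")
    records = [chip_recalibrate(r, CHIP_PEAKS.get(r.regulator, 1.0))
               for r in extract_kd(model5, qc)]
    df = pd.DataFrame([{
        "model": version, "regulator": r.regulator, "target": r.target,
        "parameter": r.parameter, "kd_copies_per_cell": r.kd_copies,
        "kd_nM": r.kd_nM, "kd_per_chip_peak_nM": r.kd_per_peak_nM}
        for r in records])
    frames.append(df)
    ec = df[df.regulator == "cEC"]
    print(f"\n{version}: {len(df)} Kd records; EC targets "
          f"{ec.kd_nM.min():.1f}-{ec.kd_nM.max():.1f} nM, "
          f"dawn-TF targets up to {df.kd_nM.max():,.0f} nM")

kd = pd.concat(frames)
kd.to_csv(RESULTS / "simulated_kd.csv", index=False)
print("\nwrote simulated_kd.csv")
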