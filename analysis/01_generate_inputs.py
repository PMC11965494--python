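"""Generate every synthetic input: absolute mRNA timeseries for seven clock
genes (LD then LL, 2 h sampling), a NanoLUC spike-in calibration plate, a
PBM E-score table from a planted energy matrix, and a promoter set with
planted consensus sites.

Ground truth (labels, matrix, planted positions) is written alongside, so
later stages can be scored."""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED

from clockunits.pipeline import RNA_SPECS
from clockunits.regimes import ld_then_ll
from clockunits.report import write_provenance
from clockunits.synth import (PbmTruth, RhythmSpec, gen_calibration_curve,
                              gen_pbm_dataset, gen_promoter_set,
                              gen_rna_timeseries, random_energy_matrix)

regime = ld_then_ll(1, 72)
frames = []
for i, (gene, kw) in enumerate(RNA_SPECS.items()):
    spec = RhythmSpec(gene_id=gene, noise_sd=0.0, seed=SEED * 1000 + i, **kw)
    frames.append(gen_rna_timeseries(spec, regime).to_frame())
rna = pd.concat(frames)
rna.to_csv(RESULTS / "rna_timeseries.csv", index=False)
peak_fold = rna.groupby("gene_id").copies_per_cell.agg(lambda s: s.max() / s.min())
print("RNA series written; LD+LL fold-changes per gene:")
print(peak_fold.round(1).to_string())

plate = gen_calibration_curve(true_intercept=2.0, true_slope=1.0,
                              noise_sd=0.1, replicates=4, seed=SEED * 1000 + 50)
plate.to_csv(RESULTS / "calibration_plate.csv", index=False)
print(f"calibration plate: {len(plate)} wells, "
      f"{plate.spike_copies_per_cell.nunique()} spike levels")

matrix = random_energy_matrix(seed=SEED + 7)
np.savetxt(RESULTS / "true_energy_matrix.tsv", matrix.energies, delimiter="\t")
truth = PbmTruth(matrix=matrix, seed=SEED * 1000 + 60)
pbm, labels = gen_pbm_dataset(truth)
pbm.assign(bound=labels.values).to_csv(RESULTS / "pbm_escores.csv", index=False)
print(f"PBM: {len(pbm)} 8-mers, {int(labels.sum())} bound; "
      f"consensus {matrix.consensus()}")

consensus = matrix.consensus()
planted = [(consensus, 200, "+"), (consensus, 600, "-")]
haps = gen_promoter_set(1000, planted, n_haplotypes=6, mutation_rate=0.01,
                        seed=SEED * 1000 + 70)
SeqIO.write(haps, RESULTS / "promoters.fasta", "fasta")
with open(RESULTS / "planted_sites.json", "w") as fh:
    json.dump([{"kmer": k, "position": p, "strand": s} for k, p, s in planted],
              fh, indent=1)
print(f"promoters: {len(haps)} haplotypes, sites planted at "
      f"{[p for _, p, _ in planted]}")

write_provenance(RESULTS / "provenance_01.json",
                 {"stage": "generate_inputs", "seed": SEED})
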