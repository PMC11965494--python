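"""End-to-end synthetic pipeline: generate -> predict -> rescale ->
extract-Kd -> PBM/scan -> report.

Every stage runs on synthetic inputs whose ground truth is known, so the
pipeline doubles as an integration test of the whole analysis: scaling
factors, energy matrices, planted binding sites and calibration lines must
all be recovered.  All randomness derives from a single seed and outputs are
plain CSV/JSON, so repeated runs are bit-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from . import data as pkgdata
from .binding import (calibrate_escore_kd, ema_infer, inject_reporter_gene,
                      scan_promoter, variant_kd_effects)
from .clock_model import (apply_scaling, chip_recalibrate, combine_pools,
                          entrainment_error, extract_kd, propagate_scaling,
                          shipped_model, simulate)
from .regimes import ld_cycles, ld_then_ll
from .report import build_protein_table, build_phase_plane, compare_photoperiods, write_provenance
from .rescale import fit_scaling
from .simple_model import interpolate_rna, simulate_protein
from .synth import (PbmTruth, RhythmSpec, gen_calibration_curve, gen_pbm_dataset,
                    gen_promoter_set, gen_rna_timeseries, random_energy_matrix)
from .units import QuantConstants, fit_standard_curve

# Rhythm specs emulating absolutely-calibrated clock transcript waveforms:
# dawn genes with very high amplitude (LHY/CCA1 RNA cycles ~1000-fold in LD),
# a sequential daytime PRR wave, evening genes with lower amplitude (ELF3
# RNA ~10-fold), all damped in constant light.
RNA_SPECS = {
    "LHY":  dict(peak_phase=23.0, log_peak=np.log(300.0), log_trough=np.log(0.3)),
    "CCA1": dict(peak_phase=0.0, log_peak=np.log(250.0), log_trough=np.log(0.25)),
    "PRR7": dict(peak_phase=6.0, log_peak=np.log(80.0), log_trough=np.log(2.0)),
    "TOC1": dict(peak_phase=11.0, log_peak=np.log(60.0), log_trough=np.log(3.0)),
    "ELF3": dict(peak_phase=12.0, log_peak=np.log(40.0), log_trough=np.log(4.0)),
    "ELF4": dict(peak_phase=12.0, log_peak=np.log(50.0), log_trough=np.log(1.0)),
    "LUX":  dict(peak_phase=12.0, log_peak=np.log(70.0), log_trough=np.log(2.0)),
}
CHIP_PEAKS = {"cL": 1543.0, "cLmod": 1543.0, "cL+cLmod": 1543.0, "cEC": 48.3,
              "cT": 1543.0, "cP9": 1543.0, "cP7": 1543.0}
CONSENSUS_KD_NM = 1.44   # tightest in vitro anchor (SPR, consensus site)


def run_pipeline(seed: int = 1, outdir: str | Path = "results",
                 model_version: str = "U2019.3", n_kmers: int = 3000,
                 rna_noise_sd: float = 0.0, fit_opts: dict | None = None) -> dict:
    """Run the whole synthetic analysis; writes tables under ``outdir`` and
    returns the headline quantities as a dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    qc = QuantConstants()
    summary: dict = {"seed": seed, "model_version": model_version}

    # 1. synthetic absolute RNA + NanoLUC calibration ----------------------
    regime = ld_then_ll(1, 72)
    rna = {}
    for i, (gene, kw) in enumerate(RNA_SPECS.items()):
        spec = RhythmSpec(gene_id=gene, noise_sd=rna_noise_sd,
                          seed=seed * 1000 + i, **kw)
        rna[gene] = gen_rna_timeseries(spec, regime, sampling_interval=2.0)
    pd.concat([ts.to_frame() for ts in rna.values()]).to_csv(
        out / "rna_timeseries.csv", index=False)

    plate = gen_calibration_curve(true_intercept=2.0, true_slope=1.0,
                                  noise_sd=0.1, replicates=4,
                                  seed=seed * 1000 + 50)
    plate.to_csv(out / "calibration_plate.csv", index=False)
    cal_model = fit_standard_curve(plate)
    summary["calibration_slope"] = cal_model.slope
    summary["calibration_intercept"] = cal_model.intercept

    # 2. simple protein model ---------------------------------------------
    kinetics = pkgdata.default_kinetics()
    proteins = {}
    for gene, ts in rna.items():
        M = interpolate_rna(ts)
        proteins[gene] = simulate_protein(M, kinetics[gene], regime,
                                          grid_h=0.25)
    pd.concat([p.to_frame() for p in proteins.values()]).to_csv(
        out / "predicted_proteins.csv", index=False)
    lhycca1 = proteins["LHY"].copies_per_cell + proteins["CCA1"].copies_per_cell
    t_pred = proteins["LHY"].time_h
    summary["pred_peak_lhy_cca1"] = float(lhycca1[t_pred <= 24].max())

    # 3. rescale the circuit model to the predicted levels -----------------
    model3 = shipped_model(model_version)
    fit_regime = ld_cycles(12)
    sel = (t_pred >= 0) & (t_pred <= 24)
    targets = {
        "LHY/CCA1": (t_pred[sel], lhycca1[sel]),
        "PRR7": (t_pred[sel], proteins["PRR7"].copies_per_cell[sel]),
        "LUX": (t_pred[sel], proteins["LUX"].copies_per_cell[sel]),
    }
    fit = fit_scaling(model3, targets, fit_regime, **(fit_opts or {}))
    summary["scaling_factors"] = fit.factors
    summary["scaling_cost"] = fit.cost
    model4 = apply_scaling(model3, fit.factors)
    model5 = propagate_scaling(model4)

    # 4. Kd extraction + ChIP-peak recalibration ---------------------------
    records = [chip_recalibrate(r, CHIP_PEAKS.get(r.regulator, 1.0))
               for r in extract_kd(model5, qc)]
    kd_table = pd.DataFrame([{
        "regulator": r.regulator, "target": r.target, "parameter": r.parameter,
        "kd_copies_per_cell": r.kd_copies, "kd_nM": r.kd_nM,
        "kd_per_chip_peak_nM": r.kd_per_peak_nM} for r in records])
    kd_table.to_csv(out / "simulated_kd.csv", index=False)
    summary["n_kd_records"] = len(records)
    summary["kd_nM_range"] = [float(kd_table.kd_nM.min()),
                              float(kd_table.kd_nM.max())]

    # 5. PBM -> energy matrix -> calibrated promoter Kd --------------------
    truth_matrix = random_energy_matrix(seed=seed + 7)
    pbm_truth = PbmTruth(matrix=truth_matrix, n_kmers=n_kmers,
                         seed=seed * 1000 + 60)
    pbm, labels = gen_pbm_dataset(pbm_truth)
    pbm.assign(bound=labels.values).to_csv(out / "pbm_escores.csv", index=False)
    ema = ema_infer(pbm, seed=seed)
    r_matrix = float(pearsonr(ema.matrix.energies.ravel(),
                              truth_matrix.energies.ravel())[0])
    accuracy = float(((ema.posterior_bound.to_numpy() >= 0.5)
                      == labels.to_numpy()).mean())
    summary["ema_matrix_pearson_r"] = r_matrix
    summary["ema_label_accuracy"] = accuracy

    consensus = truth_matrix.consensus()
    anchors = pd.DataFrame({
        "sequence": [consensus, None, None],
        "escore": [0.47, 0.30, 0.25],
        "kd_nM": [CONSENSUS_KD_NM, 30.0, 38.0],
        "assay": ["SPR", "EMSA", "EMSA"],
    })
    anchors["kd_nM"] = anchors["kd_nM"].astype(float)
    cal = calibrate_escore_kd(anchors, mode="direct")
    summary["calibration_kd_slope"] = cal.slope

    planted = [(consensus, 200, "+"), (consensus, 600, "-")]
    haplotypes = gen_promoter_set(1000, planted, n_haplotypes=6,
                                  mutation_rate=0.01, seed=seed * 1000 + 70)
    scan = scan_promoter(str(haplotypes[0].seq), ema, cal, sequence_id="hap0")
    scan.to_bed().to_csv(out / "promoter_sites.bed", sep="\t", index=False)
    found = sorted(s.position for s in scan.sites)
    summary["planted_site_positions"] = [p for _, p, _ in planted]
    summary["recovered_site_positions"] = found
    summary["sites_recovered"] = all(p in found for _, p, _ in planted)
    summary["total_kd_nM_reference"] = scan.total_kd_nM

    variants = variant_kd_effects(haplotypes, ema, cal)
    variants.to_csv(out / "haplotype_kd.csv", index=False)

    # 6. reporter-gene injection: promoter-variant Kd into the circuit -----
    finite = variants.dropna(subset=["total_kd_nM"])
    kd_try = float(finite.total_kd_nM.iloc[-1]) if len(finite) else 1.0
    m_rep = inject_reporter_gene(model5, kd_try, "cGm", qc=qc, regulator="cL")
    traj = simulate(m_rep, ld_then_ll(11, 72), record_span=96,
                    check_entrainment=False)
    base = simulate(model5, ld_then_ll(11, 72), record_span=96,
                    check_entrainment=False)
    core_dev = max(float(np.max(np.abs(traj[n] - base[n]))
                         / max(float(np.abs(base[n]).max()), 1e-12))
                   for n in model5.species)
    summary["reporter_core_max_rel_dev"] = core_dev
    summary["entrainment_error"] = entrainment_error(base)
    summary["reporter_kd_nM"] = kd_try
    pd.DataFrame({"zt": traj.zt, "native_GI_mRNA": traj["cGm"],
                  "reporter_GI_mRNA": traj["cGm_rep"]}).to_csv(
        out / "reporter_waveforms.csv", index=False)

    # 7. reports: protein table, phase plane, photoperiod comparison -------
    sim_sources = {}
    for pool, gene in (("LHY/CCA1", None), ("PRR7", "PRR7"), ("TOC1", "TOC1"),
                       ("ELF3", "ELF3"), ("LUX", "LUX")):
        entries = [(f"Sim. {model5.version}", (base.zt, combine_pools(base, pool)))]
        if gene is not None:
            entries.append(("Pred.", (proteins[gene].time_h,
                                      proteins[gene].copies_per_cell)))
        else:
            entries.append(("Pred.", (t_pred, lhycca1)))
        sim_sources[pool] = entries
    table1 = build_protein_table(sim_sources, ld_window=(0.0, 24.0),
                                 ll_window=(48.0, 72.0))
    table1.to_csv(out / "protein_table.csv", index=False)
    sim_row = table1[(table1.protein == "LHY/CCA1")
                     & (table1.source.str.startswith("Sim."))].iloc[0]
    summary["sim_peak_lhy_cca1"] = float(sim_row.peak_ld)
    summary["sim_fold_lhy_cca1"] = float(sim_row.fold_ld)
    summary["sim_ll_ld_ratio_lhy_cca1"] = float(sim_row.ll_ld_ratio)

    pp = build_phase_plane(base.zt, np.maximum(base["cT"], 1e-6),
                           base.zt, np.maximum(base["cLm"], 1e-6),
                           marker_times=(0.0, 18.0, 24.0))
    pp.to_csv(out / "phase_plane_toc1_lhy.csv", index=False)

    short = simulate(model5, ld_cycles(12, 8.0, 16.0), record_span=48,
                     check_entrainment=False, cycle_h=24.0)
    long_ = simulate(model5, ld_cycles(12, 16.0, 8.0), record_span=48,
                     check_entrainment=False, cycle_h=24.0)
    cmp_ = compare_photoperiods(short.zt, np.maximum(short["cL"], 1e-6),
                                long_.zt, np.maximum(long_["cL"], 1e-6))
    cmp_.to_csv(out / "photoperiod_comparison.csv", index=False)
    summary["photoperiod_max_abs_diff"] = float(cmp_.abs_diff.max())

    write_provenance(out / "provenance.json",
                     config={"seed": seed, "model_version": model_version,
                             "n_kmers": n_kmers, "rna_noise_sd": rna_noise_sd},
                     seeds={"master": seed})
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")
    return summary
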