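"""PBM deconvolution, Kd calibration, promoter scanning, reporter injection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clockunits.binding import (EnergyMatrix, calibrate_escore_kd, canonical_kmer,
                                ema_infer, inject_reporter_gene, revcomp,
                                scan_promoter, total_kd, variant_kd_effects)
from clockunits.clock_model import simulate
from clockunits.regimes import ld_cycles
from clockunits.synth import (PbmTruth, gen_pbm_dataset, gen_promoter_set,
                              random_energy_matrix)
from clockunits.units import QuantConstants, conc_to_copies


def make_cal(slope=-100.0, intercept=50.0):
    anchors = pd.DataFrame({"escore": [0.1, 0.4],
                            "kd_nM": [intercept + slope * 0.1,
                                      intercept + slope * 0.4]})
    return calibrate_escore_kd(anchors)


class TestEnergyMatrix:
    def test_gauge_fixes_per_position_minimum(self):
        m = random_energy_matrix(seed=1)
        assert np.allclose(m.energies.min(axis=1), 0.0)
        assert m.energy(m.consensus()) == pytest.approx(0.0)

    def test_gauge_shift_changes_no_relative_energy(self):
        m = random_energy_matrix(seed=2)
        shifted = EnergyMatrix(m.energies + np.r_[1.5, np.zeros(7)][:, None])
        kmers = ["ACGTACGT", "TTTTACGT", "GGGGCCCC"]
        d0 = np.diff([m.energy(k) for k in kmers])
        d1 = np.diff([shifted.energy(k) for k in kmers])
        assert np.allclose(d0, d1)
        assert np.allclose(shifted.gauged().energies, m.energies)

    def test_canonical_energy_is_strand_symmetric(self):
        m = random_energy_matrix(seed=3)
        for k in ["ACGTACGT", "AATTCCGG", "TGCATGCA"]:
            assert m.canonical_energy(k)[0] == m.canonical_energy(revcomp(k))[0]

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError):
            EnergyMatrix(np.zeros((4, 8)))


class TestEmaInference:
    def test_planted_matrix_recovered(self, ema_recovery):
        """EMA recovers the planted energy matrix (Pearson r >= 0.9) and the
        bound/unbound labels (accuracy >= 0.95) from overlapping E-score
        distributions, without any explicit E-score threshold."""
        assert ema_recovery["pearson_r"] >= 0.9
        assert ema_recovery["accuracy"] >= 0.95

    def test_deterministic_given_seed(self, ema_recovery):
        again = ema_infer(ema_recovery["pbm"], seed=0)
        assert np.array_equal(again.matrix.energies,
                              ema_recovery["result"].matrix.energies)

    def test_well_separated_classes_give_hard_posteriors(self):
        truth = PbmTruth(matrix=random_energy_matrix(seed=4), frac_bound=0.05,
                         n_kmers=1500, seed=5, bound_mean=0.45,
                         unbound_mean=0.05, bound_noise_sd=0.02,
                         unbound_noise_sd=0.02)
        pbm, labels = gen_pbm_dataset(truth)
        res = ema_infer(pbm, seed=0)
        post = res.posterior_bound.to_numpy()
        assert np.all((post > 0.99) | (post < 0.01))
        assert ((post >= 0.5) == labels.to_numpy()).all()

    def test_consensus_has_high_bound_prior(self, ema_recovery):
        res = ema_recovery["result"]
        e_min = res.matrix.energy(res.matrix.consensus())
        assert res.prior_bound(e_min) > 0.99

    def test_degenerate_input_rejected(self):
        pbm = pd.DataFrame({"kmer": ["ACGTACGT"] * 40, "escore": [0.1] * 40})
        with pytest.raises(ValueError):
            ema_infer(pbm)
        small = pd.DataFrame({"kmer": ["ACGTACGT", "AAAATTTT"],
                              "escore": [0.4, 0.1]})
        with pytest.raises(ValueError):
            ema_infer(small)


class TestKdCalibration:
    def test_two_anchor_line_passes_through_both(self):
        anchors = pd.DataFrame({"escore": [0.45, 0.25], "kd_nM": [1.44, 38.0]})
        cal = calibrate_escore_kd(anchors)
        assert cal.predict(0.45) == pytest.approx(1.44)
        assert cal.predict(0.25) == pytest.approx(38.0)

    def test_noisy_planted_line_slope_bias_under_5pct(self):
        slopes = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0.2, 0.5, 8)
            y = 60.0 - 120.0 * x + rng.normal(0, 2.0, 8)
            slopes.append(calibrate_escore_kd(
                pd.DataFrame({"escore": x, "kd_nM": y})).slope)
        assert abs(np.mean(slopes) - (-120.0)) / 120.0 < 0.05

    def test_slope_transfer_anchors_single_point(self):
        anchors = pd.DataFrame({"escore": [0.4], "kd_nM": [6.5]})
        cal = calibrate_escore_kd(anchors, mode="slope_transfer",
                                  donor_slope=-150.0)
        assert cal.slope == -150.0
        assert cal.predict(0.4) == pytest.approx(6.5)

    def test_errors(self):
        one = pd.DataFrame({"escore": [0.4], "kd_nM": [1.0]})
        with pytest.raises(ValueError):
            calibrate_escore_kd(one, mode="direct")
        flat = pd.DataFrame({"escore": [0.4, 0.4], "kd_nM": [1.0, 2.0]})
        with pytest.raises(ValueError):
            calibrate_escore_kd(flat)

    def test_nonpositive_prediction_flagged(self):
        anchors = pd.DataFrame({"escore": [0.3, 0.4], "kd_nM": [20.0, 2.0]})
        with pytest.warns(UserWarning, match="non-positive"):
            calibrate_escore_kd(anchors)


class TestPromoterScan:
    def test_consensus_8mer_single_site_at_zero(self, ema_recovery):
        res = ema_recovery["result"]
        scan = scan_promoter(res.matrix.consensus(), res, make_cal())
        assert len(scan.sites) == 1
        assert scan.sites[0].position == 0
        assert scan.sites[0].energy == pytest.approx(0.0)

    def test_planted_sites_recovered_in_random_promoter(self, ema_recovery):
        res = ema_recovery["result"]
        consensus = ema_recovery["truth_matrix"].consensus()
        planted = [(consensus, 50, "+"), (consensus, 220, "-")]
        [ref] = gen_promoter_set(300, planted, seed=9)
        scan = scan_promoter(str(ref.seq), res, make_cal())
        found = {s.position for s in scan.sites}
        assert {50, 220}.issubset(found)

    def test_canonical_vs_mutated_energy_contrast(self, ema_recovery):
        """A mutated binding site scores distinctly higher energy (weaker
        binding) than the canonical site in its window profile."""
        res = ema_recovery["result"]
        consensus = ema_recovery["truth_matrix"].consensus()
        mutated = ("T" if consensus[3] != "T" else "A").join(
            [consensus[:3], consensus[4:]])
        [ref_c] = gen_promoter_set(120, [(consensus, 50, "+")], seed=4)
        [ref_m] = gen_promoter_set(120, [(mutated, 50, "+")], seed=4)
        e_c = scan_promoter(str(ref_c.seq), res, make_cal()).window_energies[50]
        e_m = scan_promoter(str(ref_m.seq), res, make_cal()).window_energies[50]
        assert e_c == pytest.approx(0.0, abs=1e-9)
        assert e_m > e_c + 0.5

    def test_strand_symmetry(self, ema_recovery):
        res = ema_recovery["result"]
        consensus = ema_recovery["truth_matrix"].consensus()
        [ref] = gen_promoter_set(200, [(consensus, 70, "+")], seed=6)
        seq = str(ref.seq)
        fwd = scan_promoter(seq, res, make_cal())
        rev = scan_promoter(revcomp(seq), res, make_cal())
        n = len(seq)
        assert ({s.position for s in fwd.sites}
                == {n - 8 - s.position for s in rev.sites})
        assert np.allclose(np.nan_to_num(fwd.window_energies),
                           np.nan_to_num(rev.window_energies[::-1]))

    def test_null_site_rate_matches_exhaustive_enumeration(self, ema_recovery):
        """Site frequency in random sequence matches the bound fraction of
        the full 8-mer universe computed by brute-force enumeration."""
        res = ema_recovery["result"]
        from itertools import product
        kmers = ["".join(p) for p in product("ACGT", repeat=8)]
        E = res.matrix.energies
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        energies = np.zeros(len(kmers))
        for pos in range(8):
            col = np.array([E[pos, idx[k[pos]]] for k in kmers])
            energies += col
        p_bound = float((res.prior_bound(energies) >= 0.5).mean())
        # min-orientation scoring: a window is a site if either orientation is
        p_window = 1 - (1 - p_bound) ** 2
        rng = np.random.default_rng(12)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 30000))
        scan = scan_promoter(seq, res, make_cal())
        rate = len(scan.sites) / len(scan.window_energies)
        assert rate == pytest.approx(p_window, rel=0.2, abs=0.005)

    def test_ambiguity_codes_skipped_with_warning(self, ema_recovery):
        res = ema_recovery["result"]
        with pytest.warns(UserWarning, match="ambiguity"):
            scan = scan_promoter("ACGTNACGTACGTACG", res, make_cal())
        assert np.isnan(scan.window_energies[:5]).any()

    def test_empty_sequence_rejected(self, ema_recovery):
        with pytest.raises(ValueError):
            scan_promoter("ACGT", ema_recovery["result"], make_cal())


class TestTotalKd:
    def test_single_site_identity(self):
        assert total_kd([3.3]) == pytest.approx(3.3)

    def test_two_equal_sites_halve(self):
        assert total_kd([4.0, 4.0]) == pytest.approx(2.0)

    def test_no_sites_is_explicit_no_binding(self):
        assert total_kd([]) is None

    @given(st.lists(st.floats(min_value=1e-3, max_value=1e4), min_size=1,
                    max_size=12))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_total_never_exceeds_tightest_site_and_adding_monotone(self, kds):
        tot = total_kd(kds)
        assert tot <= min(kds) + 1e-12
        assert total_kd(kds + [10.0]) <= tot + 1e-12


class TestVariantEffects:
    def test_duplicate_haplotypes_equal_kd(self, ema_recovery):
        res = ema_recovery["result"]
        consensus = ema_recovery["truth_matrix"].consensus()
        haps = gen_promoter_set(300, [(consensus, 100, "+")],
                                n_haplotypes=3, mutation_rate=0.0, seed=2)
        out = variant_kd_effects(haps, res, make_cal())
        assert out.total_kd_nM.nunique() == 1
        assert (out.n_sites == out.n_sites.iloc[0]).all()

    def test_single_base_change_maps_through_matrix_and_calibration(self,
                                                                    ema_recovery):
        """One substitution inside the only site changes its Kd by exactly
        the energy-matrix entry difference passed through the E-score and
        calibration lines."""
        res = ema_recovery["result"]
        cal = make_cal()
        consensus = res.matrix.consensus()
        pos = 4
        base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        # pick the smallest nonzero penalty so the variant stays a bound site
        row = res.matrix.energies[pos]
        alt = int(np.argsort(row)[1])
        variant = consensus[:pos] + "ACGT"[alt] + consensus[pos + 1:]
        s0 = scan_promoter(consensus, res, cal, kd_floor_nM=None)
        s1 = scan_promoter(variant, res, cal, kd_floor_nM=None)
        assert len(s0.sites) == len(s1.sites) == 1
        d_energy = row[alt] - row[base_idx[consensus[pos]]]
        expected = cal.slope * res.escore_slope * d_energy
        assert s1.sites[0].kd_nM - s0.sites[0].kd_nM == pytest.approx(expected,
                                                                      rel=1e-9)

    def test_empty_haplotype_set_rejected(self, ema_recovery):
        with pytest.raises(ValueError):
            variant_kd_effects([], ema_recovery["result"], make_cal())


class TestReporterInjection:
    def test_native_kd_reporter_tracks_native_mrna(self, u2019):
        qc = QuantConstants()
        from clockunits.units import copies_to_conc
        native_kd_nM = float(copies_to_conc(u2019.parameters["g15"], qc))
        m = inject_reporter_gene(u2019, native_kd_nM, "cGm", qc=qc,
                                 regulator="cL")
        traj = simulate(m, ld_cycles(12), record_span=24,
                        check_entrainment=False)
        scale = traj["cGm"].max()
        assert np.max(np.abs(traj["cGm_rep"] - traj["cGm"])) / scale < 1e-5

    def test_core_trajectories_unchanged(self, u2019):
        """The reporter is integrated after the core, so the core states are
        bitwise identical with and without the injected gene."""
        m = inject_reporter_gene(u2019, 0.37, "cGm", regulator="cL")
        base = simulate(u2019, ld_cycles(12), record_span=24,
                        check_entrainment=False)
        with_rep = simulate(m, ld_cycles(12), record_span=24,
                            check_entrainment=False)
        for name in u2019.species:
            scale = max(np.abs(base[name]).max(), 1e-12)
            assert np.max(np.abs(with_rep[name] - base[name])) / scale < 1e-10

    def test_unknown_target_rejected(self, u2019):
        with pytest.raises(KeyError):
            inject_reporter_gene(u2019, 1.0, "cNOPEm")

    def test_ambiguous_regulator_requires_choice(self, u2019):
        with pytest.raises(ValueError, match="regulator"):
            inject_reporter_gene(u2019, 1.0, "cE4m")
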