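"""Clock circuit engine: model I/O, simulation, scaling, Kd extraction."""

import numpy as np
import pytest

from clockunits.clock_model import (ClockModel, KdRecord, ModelDefinitionError,
                                    apply_scaling, chip_recalibrate,
                                    combine_pools, entrainment_error,
                                    extract_kd, load_model, propagate_scaling,
                                    save_model, simulate)
from clockunits.regimes import ld_cycles, ld_then_ll
from clockunits.units import QuantConstants, copies_to_conc

REGIME = ld_cycles(12)


class TestModelIO:
    def test_round_trip_identity(self, u2019, tmp_path):
        p = tmp_path / "m.json"
        save_model(u2019, p)
        reloaded = load_model(p)
        assert reloaded.to_definition() == u2019.to_definition()
        save_model(reloaded, tmp_path / "m2.json")
        assert (tmp_path / "m.json").read_bytes() == (tmp_path / "m2.json").read_bytes()

    def test_missing_parameter_named_in_error(self, u2019):
        d = u2019.to_definition()
        del d["parameters"]["g5"]
        with pytest.raises(ModelDefinitionError, match="g5"):
            ClockModel.from_definition(d)

    def test_unknown_version_tag_rejected(self, u2019):
        d = u2019.to_definition()
        d["version"] = "X9.banana"
        with pytest.raises(ModelDefinitionError, match="version"):
            ClockModel.from_definition(d)

    def test_kd_map_covers_regulator_target_pairs(self, u2019):
        pairs = {(r["regulator"], r["target"]) for r in u2019.kd_map}
        assert ("cEC", "cE4m") in pairs and ("cL", "cTm") in pairs
        for rec in u2019.kd_map:
            assert rec["parameter"] in u2019.parameters


class TestSimulation:
    def test_entrained_cycle_periodic_below_half_percent(self, u2019, u2020):
        for model in (u2019, u2020):
            traj = simulate(model, REGIME, entrain_cycles=10, record_span=48)
            assert entrainment_error(traj) < 0.005

    def test_positivity_from_zero_initial_condition(self, u2019):
        d = u2019.to_definition()
        d["species"] = {k: 0.0 for k in d["species"]}
        m = ClockModel.from_definition(d)
        traj = simulate(m, REGIME, record_span=24, check_entrainment=False)
        for name, y in traj.states.items():
            assert np.all(y >= 0)
        assert combine_pools(traj, "LHY/CCA1").max() > 0

    def test_trajectories_deterministic(self, u2019):
        a = simulate(u2019, REGIME, record_span=24, check_entrainment=False)
        b = simulate(u2019, REGIME, record_span=24, check_entrainment=False)
        for name in u2019.species:
            assert np.array_equal(a[name], b[name])

    def test_phase_ordering_under_ld(self, u2019):
        """Dawn phasing of LHY/CCA1 (first half of the light period) and
        evening phasing of TOC1, as in the entrained plant clock."""
        traj = simulate(u2019, REGIME, record_span=24, check_entrainment=False)
        lhy = combine_pools(traj, "LHY/CCA1")
        toc1 = combine_pools(traj, "TOC1")
        assert 0 <= traj.zt[np.argmax(lhy)] <= 6
        assert 8 <= traj.zt[np.argmax(toc1)] <= 18

    def test_regime_too_short_rejected(self, u2019):
        with pytest.raises(ValueError, match="extend the regime"):
            simulate(u2019, ld_cycles(5), entrain_cycles=10, record_span=24)


class TestPools:
    def test_single_pool_is_identity(self, u2019):
        traj = simulate(u2019, REGIME, record_span=24, check_entrainment=False)
        assert np.array_equal(combine_pools(traj, "TOC1"), traj["cT"])

    def test_pool_sum_bounds_members(self, u2019):
        traj = simulate(u2019, REGIME, record_span=24, check_entrainment=False)
        lux = combine_pools(traj, "LUX")
        assert np.all(lux >= traj["cLUX"]) and np.all(lux >= traj["cEC"])

    def test_unknown_protein_rejected(self, u2019):
        traj = simulate(u2019, REGIME, record_span=24, check_entrainment=False)
        with pytest.raises(KeyError):
            combine_pools(traj, "NOTAPROTEIN")


class TestScaling:
    def test_unit_factors_leave_parameters_unchanged(self, u2019):
        m5 = propagate_scaling(apply_scaling(
            u2019, {"s_L": 1.0, "s_P7": 1.0, "s_LUX": 1.0}))
        for p, v in u2019.parameters.items():
            assert m5.parameters[p] == pytest.approx(v)

    def test_dot4_and_dot5_trajectories_identical(self, u2019):
        rng = np.random.default_rng(5)
        factors = {f: float(10 ** rng.uniform(-1, 3)) for f in
                   ("s_L", "s_P7", "s_LUX")}
        m4 = apply_scaling(u2019, factors)
        m5 = propagate_scaling(m4)
        assert m4.version.endswith(".4") and m5.version.endswith(".5")
        t4 = simulate(m4, REGIME, record_span=24, check_entrainment=False)
        t5 = simulate(m5, REGIME, record_span=24, check_entrainment=False)
        for name in u2019.species:
            scale = max(np.abs(t4[name]).max(), 1e-12)
            assert np.max(np.abs(t4[name] - t5[name])) / scale < 1e-6

    def test_scaled_parameters_multiplied_as_documented(self, u2019):
        factors = {"s_L": 3.0, "s_P7": 2.0, "s_LUX": 0.5}
        m5 = propagate_scaling(apply_scaling(u2019, factors))
        assert m5.parameters["g5"] == pytest.approx(3.0 * u2019.parameters["g5"])
        assert m5.parameters["s_L"] == 1.0

    def test_protein_scale_equivariance(self, u2019):
        """Scaling is a change of variables: the .4 proteins equal the .3
        proteins multiplied by their factors."""
        factors = {"s_L": 2.0, "s_P7": 5.0, "s_LUX": 0.5}
        t3 = simulate(u2019, REGIME, record_span=24, check_entrainment=False)
        t4 = simulate(apply_scaling(u2019, factors), REGIME, record_span=24,
                      check_entrainment=False)
        assert np.allclose(t4["cL"], 2.0 * t3["cL"], rtol=1e-5)
        assert np.allclose(t4["cP7"], 5.0 * t3["cP7"], rtol=1e-5)
        assert np.allclose(t4["cLUX"], 0.5 * t3["cLUX"], rtol=1e-5)
        assert np.allclose(t4["cLm"], t3["cLm"], rtol=1e-5)   # mRNA unscaled

    def test_non_positive_factor_rejected(self, u2019):
        with pytest.raises(ValueError):
            apply_scaling(u2019, {"s_L": -1.0})


class TestKdExtraction:
    def test_one_record_per_map_entry_with_conversion(self, u2019):
        qc = QuantConstants()
        records = extract_kd(u2019, qc)
        assert len(records) == len(u2019.kd_map)
        for r in records:
            assert r.kd_nM == pytest.approx(copies_to_conc(r.kd_copies, qc))

    def test_unfolded_factor_applied_in_dot4(self, u2019):
        m4 = apply_scaling(u2019, {"s_L": 10.0, "s_P7": 1.0, "s_LUX": 1.0})
        rec4 = {r.parameter: r for r in extract_kd(m4)}
        rec3 = {r.parameter: r for r in extract_kd(u2019)}
        assert rec4["g5"].kd_copies == pytest.approx(10 * rec3["g5"].kd_copies)
        assert rec4["g2"].kd_copies == pytest.approx(rec3["g2"].kd_copies)

    def test_zero_kd_rejected(self):
        with pytest.raises(ValueError):
            KdRecord("cL", "cTm", "g5", kd_copies=0.0, kd_nM=0.0)


class TestChipRecalibration:
    def test_identity_at_one_peak(self):
        r = KdRecord("cL", "cTm", "g5", 20979.0, 304.0)
        assert chip_recalibrate(r, 1).kd_per_peak_nM == pytest.approx(304.0)

    def test_division_rule_and_monotonicity(self):
        r = KdRecord("cL", "cTm", "g5", 20979.0, 304.0)
        out = [chip_recalibrate(r, n).kd_per_peak_nM for n in (10, 100, 1543)]
        assert out[0] == pytest.approx(30.4)
        assert out[2] == pytest.approx(304.0 / 1543)
        assert out[0] > out[1] > out[2]

    def test_published_column_ratios_back_derive_peak_counts(self):
        """The printed Kd and Kd-per-ChIP-peak columns imply ~1.5e3 peaks for
        the dawn transcription factor and ~48 for the Evening Complex."""
        from clockunits.data import table2_kd
        t = table2_kd()
        ratios = t["kd_nM"] / t["kd_per_chip_peak_nM"]
        cca1 = ratios[t.protein == "CCA1"]
        ec = ratios[t.protein == "LUX"]
        assert cca1.mean() == pytest.approx(1.5e3, rel=0.05)
        assert ec.mean() == pytest.approx(48, rel=0.05)

    def test_fractional_peaks_rejected(self):
        r = KdRecord("cL", "cTm", "g5", 100.0, 1.0)
        with pytest.raises(ValueError):
            chip_recalibrate(r, 0)
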