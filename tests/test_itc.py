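"""ITC partition isotherm: concentrations, model, integration, fit, thermo."""

import dataclasses
import math

import numpy as np
import pytest

from memprobe import itc_partition as itc
from memprobe import synthetic_data as syn
from memprobe.errors import InputValidationError, MissingDataError

# the three measured compounds: (K mM^-1, dH kJ/mol, TdS, dG, dG uncertainty)
TABLE_ROWS = {
    "nonanoic_acid": (0.36, 3.32, 27.85, -24.53, 0.48),
    "sarmentine": (1.69, 1.47, 29.77, -28.30, 0.82),
    "sorgoleone": (28.5, 1.79, 37.13, -35.34, 0.80),
}
T_EXP_K = 299.15  # 26 degC


class TestConcentrationSeries:
    def test_single_injection_naive_closed_form(self):
        sched = itc.InjectionSchedule(volumes_ul=(10.0,), discard_first=False)
        s = itc.concentration_series(1.4565, 500.0, 5.0, sched, mode="naive")
        assert s.C_L0_mM[0] == pytest.approx(5.0 * 0.010 / 1.4565, rel=1e-6)
        assert s.C_A0_uM[0] == 500.0

    def test_full_schedule_naive_final_concentration(self):
        s = itc.concentration_series(1.4565, 500.0, 5.0, itc.default_schedule(), mode="naive")
        assert s.C_L0_mM[-1] == pytest.approx(5.0 * 0.282 / 1.4565, rel=1e-6)

    def test_zero_volume_schedule_rejected(self):
        with pytest.raises(InputValidationError):
            itc.InjectionSchedule(volumes_ul=())

    @pytest.mark.parametrize("mode", ["naive", "dilution", "overfill"])
    def test_lipid_strictly_increasing(self, mode):
        s = itc.concentration_series(1.4565, 75.0, 5.0, itc.default_schedule(), mode)
        assert np.all(np.diff(s.C_L0_mM) > 0)

    def test_dilution_reduces_both_species(self):
        naive = itc.concentration_series(1.4565, 75.0, 5.0, itc.default_schedule(), "naive")
        dil = itc.concentration_series(1.4565, 75.0, 5.0, itc.default_schedule(), "dilution")
        assert np.all(np.asarray(dil.C_L0_mM) < np.asarray(naive.C_L0_mM))
        assert np.all(np.diff(dil.C_A0_uM) < 0)


class TestCumulativeHeatModel:
    def geometry(self, cl_mM, ca_uM=100.0):
        return itc.ConcentrationSeries(
            C_L0_mM=tuple(cl_mM), C_A0_uM=(ca_uM,) * len(cl_mM), mode="naive")

    def test_hand_arithmetic(self):
        # K=2 mM^-1, dH=1 kJ/mol, V=1 mL, C_A=100 uM, C_L=0.5 mM -> 5e-5 J = 50 uJ
        series = self.geometry([0.5])
        q = itc.cumulative_heat_model(2.0, 1.0, 1.0, series, heat_unit="uJ")
        assert q[0] == pytest.approx(50.0, rel=1e-12)

    def test_saturation_plateau(self):
        series = self.geometry([1e9])
        q = itc.cumulative_heat_model(1.0, 2.0, 1.0, series, heat_unit="uJ")
        plateau = 2.0e3 * 1e-3 * 100e-6 * 1e6  # dH*V*C_A in uJ
        assert q[0] == pytest.approx(plateau, rel=1e-6)

    def test_half_saturation_at_inverse_K(self):
        K = 3.7
        series = self.geometry([1.0 / K, 1e9])
        q = itc.cumulative_heat_model(K, 2.0, 1.0, series, heat_unit="uJ")
        assert q[0] == pytest.approx(q[1] / 2.0, rel=1e-6)

    def test_monotone_in_lipid_concentration(self):
        cl = np.linspace(0.01, 2.0, 50)
        q = itc.cumulative_heat_model(1.5, 1.0, 1.0, self.geometry(cl))
        assert np.all(np.diff(q) > 0)


class TestIntegratePeaks:
    def make_schedule(self, n=3, interval=100.0):
        return itc.InjectionSchedule(volumes_ul=(10.0,) * n, discard_first=False,
                                     interval_s=interval)

    def test_rectangular_pulse_area(self):
        sched = self.make_schedule(1)
        t = np.arange(0.0, 100.0, 0.1)
        p = np.where((t >= 30) & (t < 60), 2.0, 0.0)
        h = itc.integrate_peaks(t, p, sched, baseline_mode="median")
        assert h[0] == pytest.approx(60.0, rel=0.01)

    def test_pulse_on_constant_baseline(self):
        sched = self.make_schedule(1)
        t = np.arange(0.0, 100.0, 0.1)
        p = 1.0 + np.where((t >= 30) & (t < 60), 2.0, 0.0)
        h = itc.integrate_peaks(t, p, sched, baseline_mode="linear")
        assert h[0] == pytest.approx(60.0, rel=0.02)

    def test_short_trace_rejected(self):
        sched = self.make_schedule(3)
        t = np.arange(0.0, 150.0, 1.0)  # covers only 1.5 windows
        with pytest.raises(MissingDataError):
            itc.integrate_peaks(t, np.zeros_like(t), sched)

    def test_area_conservation_from_generator(self):
        spec = syn.ITCSpec(K_mM=1.69, dH_kJ_mol=1.47, C_A0_uM=75.0)
        t, p = syn.gen_itc_trace(spec)
        heats = itc.integrate_peaks(t, p, spec.schedule, baseline_mode="median")
        exp = syn.gen_itc_thermogram(spec)
        recovered = heats[spec.schedule.retained_slice]
        assert np.allclose(recovered, exp.heats, rtol=5e-3)


class TestFitPartition:
    @pytest.mark.parametrize("name", list(TABLE_ROWS))
    def test_noiseless_roundtrip(self, name):
        K, dH, *_ = TABLE_ROWS[name]
        ca = 500.0 if name == "nonanoic_acid" else 75.0
        c_syr = 1.0 if name == "sorgoleone" else 5.0
        exp = syn.gen_itc_thermogram(syn.ITCSpec(
            K_mM=K, dH_kJ_mol=dH, C_A0_uM=ca, C_syringe_mM=c_syr))
        fit = itc.fit_partition(exp)
        assert fit.converged
        assert fit.K_mM == pytest.approx(K, rel=1e-3)
        assert fit.dH_kJ_mol == pytest.approx(dH, rel=1e-3)

    def test_noisy_median_error(self):
        K, dH = 1.69, 1.47
        errs_K, errs_dH = [], []
        for seed in range(200):
            exp = syn.gen_itc_thermogram(syn.ITCSpec(
                seed=seed, K_mM=K, dH_kJ_mol=dH, C_A0_uM=75.0, noise_sd=0.02))
            fit = itc.fit_partition(exp)
            errs_K.append(abs(fit.K_mM - K) / K)
            errs_dH.append(abs(fit.dH_kJ_mol - dH) / dH)
        assert np.median(errs_K) < 0.10
        assert np.median(errs_dH) < 0.05

    def test_constant_zero_heats_flagged(self):
        sched = itc.default_schedule()
        exp = itc.TitrationExperiment(
            V_cell_ml=1.4565, C_A0_uM=75.0, C_syringe_mM=5.0,
            schedule=sched, heats=(0.0,) * 28)
        fit = itc.fit_partition(exp)
        assert not fit.converged
        assert abs(fit.dH_kJ_mol) < 1e-6

    def test_scaling_leaves_K_invariant_and_doubles_heats(self):
        base = syn.ITCSpec(K_mM=1.69, dH_kJ_mol=1.47, C_A0_uM=75.0)
        doubled = dataclasses.replace(
            base, V_cell_ml=2 * base.V_cell_ml,
            schedule=itc.InjectionSchedule(
                volumes_ul=tuple(2 * v for v in base.schedule.volumes_ul)))
        e1 = syn.gen_itc_thermogram(base)
        e2 = syn.gen_itc_thermogram(doubled)
        assert np.allclose(np.asarray(e2.heats), 2 * np.asarray(e1.heats), rtol=1e-9)
        f1, f2 = itc.fit_partition(e1), itc.fit_partition(e2)
        assert f2.K_mM == pytest.approx(f1.K_mM, rel=1e-6)


class TestDeriveThermodynamics:
    @pytest.mark.parametrize("name", list(TABLE_ROWS))
    def test_reproduces_published_free_energy(self, name):
        K, dH, tds, dg, dg_unc = TABLE_ROWS[name]
        th = itc.derive_thermodynamics(K, dH, T_EXP_K)
        assert abs(th.dG_kJ_mol - dg) < dg_unc
        assert th.TdS_kJ_mol == pytest.approx(dH - th.dG_kJ_mol, abs=1e-12)

    @pytest.mark.parametrize("name", list(TABLE_ROWS))
    def test_published_rows_self_consistent(self, name):
        _, dH, tds, dg, _ = TABLE_ROWS[name]
        assert abs((dH - tds) - dg) < 0.02

    def test_standard_state_boundary(self):
        # 55.5 * K[M^-1] = 1 -> dG = 0 exactly
        K_mM = 1.0 / 55.5 * 1e-3
        th = itc.derive_thermodynamics(K_mM, 1.0, T_EXP_K)
        assert th.dG_kJ_mol == pytest.approx(0.0, abs=1e-12)

    def test_rejects_nonpositive_K(self):
        with pytest.raises(InputValidationError):
            itc.derive_thermodynamics(-1.0, 1.0, T_EXP_K)
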