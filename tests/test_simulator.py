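"""Simulator physics and ground-truth semantics."""

import numpy as np
import pytest

from revtrig.errors import ConfigError
from revtrig.simulator import (
    EffortProgram,
    PatientModel,
    R_EXP_VALVE,
    default_validation_scenarios,
    make_validation_set,
    pmus_pulse,
    simulate,
)
from revtrig.waveform_io import VentilatorSettings


def eom_residual(rec, patient, peep):
    """|Paw - (res*V' + V/Crs + PEEP - Pmus)| on the pre-noise signals."""
    q = rec.meta["flow_clean_lpm"] / 60.0
    vol_l = np.concatenate([[0.0], np.cumsum(q[:-1])]) * rec.dt
    pred = patient.res * q + vol_l / (patient.crs / 1000.0) + peep - rec.meta["pmus"]
    return np.abs(rec.meta["paw_clean"] - pred)


class TestEquationOfMotion:
    @pytest.mark.parametrize("fixture", ["passive_vcv", "entrained_vcv", "entrained_pcv"])
    def test_residual_below_tolerance(self, fixture, request, patient):
        rec, _ = request.getfixturevalue(fixture)
        peep = 5.0
        resid = eom_residual(rec, patient, peep)
        # expiration drains through the valve: Paw = PEEP - r_exp * V',
        # which satisfies the equation of motion identically as well
        assert resid.max() < 0.1

    def test_static_pause_pressure(self):
        # slow rate so exhalation completes: Pplat = PEEP + VT/Crs = 13
        pat = PatientModel()
        vent = VentilatorSettings(mode="VCV", set_rate=12, vt_set=400, peep=5,
                                  ti=1.0, pause_s=0.3)
        rec, gt = simulate(pat, vent, EffortProgram(mode="none"), 60, seed=1)
        q = rec.meta["flow_clean_lpm"]
        paw = rec.meta["paw_clean"]
        # pause samples of breath 1: flow exactly zero inside the cycle
        s = int(gt.breaths.iloc[1].start_s * 100)
        pause = paw[s : s + 300][np.abs(q[s : s + 300]) < 1e-9]
        assert len(pause) >= 25
        assert abs(np.median(pause) - 13.0) <= 0.2

    def test_passive_vcv_delivered_volume(self, passive_vcv):
        _, gt = passive_vcv
        v = gt.breaths.v_insp_ml.to_numpy()
        assert np.all(np.abs(v - 400.0) / 400.0 < 0.02)

    def test_passive_pes_swing_closed_form(self, passive_vcv, patient):
        rec, gt = passive_vcv
        pes = rec.meta["pes_clean"]
        swings = []
        for row in gt.breaths.iloc[1:-1].itertuples():
            s = int(row.start_s * 100)
            ee = np.mean(pes[s - 20 : s - 2])
            ei = np.mean(pes[s + 110 : s + 130])  # inside the pause
            swings.append(ei - ee)
        expected = 400.0 / patient.ccw  # VT/Ccw = 2 cmH2O
        assert abs(np.median(swings) - expected) / expected < 0.05


class TestEffortPrograms:
    def test_entrained_every_breath_is_rt(self, patient):
        vent = VentilatorSettings(mode="VCV", set_rate=20, vt_set=400, peep=5,
                                  ti=1.0, pause_s=0.3)
        eff = EffortProgram(mode="entrained", ratio=1, delay_s=0.5, amp_cmh2o=10)
        _, gt = simulate(patient, vent, eff, 60, seed=2)
        assert gt.rt_count >= 18
        assert (gt.breaths.label == "RT").all()

    def test_paralyzed_no_nonmachine_events(self, passive_vcv):
        _, gt = passive_vcv
        assert (gt.breaths.trigger == "machine").all()
        assert (gt.breaths.label == "none").all()

    def test_zero_amplitude_entrainment_is_passive(self, patient):
        vent = VentilatorSettings(mode="VCV", set_rate=15, vt_set=400, peep=5,
                                  ti=1.0, pause_s=0.3)
        eff = EffortProgram(mode="entrained", ratio=1, delay_s=0.5,
                            amp_cmh2o=0.0, amp_cv=0.0)
        _, gt = simulate(patient, vent, eff, 60, seed=3)
        assert (gt.breaths.label == "none").all()

    def test_psv_without_efforts_or_noise_has_no_breaths(self):
        pat = PatientModel(noise_sd_paw=0, noise_sd_flow=0, noise_sd_pes=0)
        vent = VentilatorSettings(mode="PSV", set_rate=20, p_insp=10, peep=5)
        _, gt = simulate(pat, vent, EffortProgram(mode="none"), 60, seed=4)
        assert gt.n_breaths == 0

    def test_psv_pre_trigger_all_patient(self, psv_patient_triggered):
        _, gt = psv_patient_triggered
        assert (gt.breaths.trigger == "patient").all()
        assert gt.rt_count == 0

    def test_stacking_emerges_and_promotes_subtype(self, stacking_vcv):
        _, gt = stacking_vcv
        b = gt.breaths
        assert b.stacked.sum() > 0
        # a stacked breath follows an RT breath labeled with subtype BS
        stacked_idx = b.index[b.stacked].tolist()
        assert all(b.loc[k - 1, "rt_subtype"] == "BS" for k in stacked_idx)
        # stacked breath began before its predecessor exhaled 90%
        frac = b.loc[[k - 1 for k in stacked_idx], "v_exhaled_ml"].to_numpy() / \
            b.loc[[k - 1 for k in stacked_idx], "v_insp_ml"].to_numpy()
        assert np.all(frac < 0.9)

    def test_rt_count_nondecreasing_in_amplitude(self, patient):
        vent = VentilatorSettings(mode="VCV", set_rate=15, vt_set=400, peep=5,
                                  ti=1.0, pause_s=0.3)
        counts = []
        for amp in (2.0, 5.0, 10.0, 20.0):
            eff = EffortProgram(mode="entrained", ratio=2, delay_s=0.5,
                                amp_cmh2o=amp, amp_cv=0.0, delay_jitter_sd=0.0)
            _, gt = simulate(patient, vent, eff, 120, seed=5)
            counts.append(gt.rt_count)
        assert counts == sorted(counts)

    def test_late_ie_efforts_label_iee(self, patient):
        vent = VentilatorSettings(mode="VCV", set_rate=12, vt_set=400, peep=5,
                                  ti=1.0, pause_s=0.3)
        eff = EffortProgram(mode="late_ie", ratio=2, delay_s=1.5, amp_cmh2o=3.0,
                            dur_s=0.7)
        _, gt = simulate(patient, vent, eff, 60, seed=6)
        assert (gt.breaths.label == "IEE").sum() >= 5
        # the 1.5 s discriminator: every IEE peak is late
        iee = gt.breaths[gt.breaths.label == "IEE"]
        assert ((iee.effort_peak_s - iee.start_s) > 1.5).all()


class TestDeterminismAndScenarios:
    def test_same_seed_bit_identical(self, patient, vcv_settings):
        eff = EffortProgram(mode="entrained", ratio=2, amp_cmh2o=8)
        r1, g1 = simulate(patient, vcv_settings, eff, 30, seed=9)
        r2, g2 = simulate(patient, vcv_settings, eff, 30, seed=9)
        assert np.array_equal(r1.paw, r2.paw)
        assert np.array_equal(r1.flow, r2.flow)
        assert g1.breaths.equals(g2.breaths)

    def test_default_validation_set_strata(self):
        scen = default_validation_scenarios()
        assert len(scen) == 20
        strata = [s["stratum"] for s in scen]
        assert strata.count("none") == 4 and strata.count("psv") == 4

    def test_single_high_stratum_recording(self):
        scen = [s for s in default_validation_scenarios() if s["stratum"] == "high"][:1]
        scen[0] = dict(scen[0], duration_s=120.0)
        out = make_validation_set(scen, seed=3)
        assert len(out) == 1
        assert out[0][2].rt_per_min > 10.0

    def test_duration_too_short_rejected(self, patient, vcv_settings):
        with pytest.raises(ConfigError):
            simulate(patient, vcv_settings, EffortProgram(mode="none"), 5.0, seed=0)


def test_pmus_pulse_shape():
    # peak at rise_frac * dur, zero outside (0, dur)
    assert pmus_pulse(-0.1, 10, 1.0, 0.35) == 0.0
    assert pmus_pulse(1.0, 10, 1.0, 0.35) == 0.0
    assert pmus_pulse(0.35, 10, 1.0, 0.35) == pytest.approx(10.0)
    assert 0 < pmus_pulse(0.1, 10, 1.0, 0.35) < 10.0
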