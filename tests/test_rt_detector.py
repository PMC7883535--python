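"""Detector features, model fitting, classification behavior."""

import numpy as np
import pytest

from revtrig.errors import CapabilityError, DataError
from revtrig.reference_labeling import BreathLabel
from revtrig.rt_detector import (
    DetectionModel,
    FeatureVector,
    detect,
    detect_recording,
    extract_features,
    fit_model,
)
from revtrig.segmentation import Breath, segment
from revtrig.simulator import EffortProgram, PatientModel, simulate
from revtrig.waveform_io import VentilatorSettings, WaveformRecord, smooth


def _flat_record(n=3000):
    return WaveformRecord(100.0, paw=np.full(n, 5.0), flow=np.zeros(n))


def _breath(idx, start, ppeak=30.0, pef=40.0, vt=400.0):
    b = Breath(index=idx, start=start, insp_end=start + 100, end=start + 300,
               trigger="machine")
    b.ppeak, b.pef, b.v_insp = ppeak, pef, vt
    return b


class TestFeatureArithmetic:
    def test_d_ppeak_running_average(self):
        rec = _flat_record()
        history = [
            _breath(i, 300 * i, ppeak=p)
            for i, p in enumerate([30.1, 29.9, 30.0, 30.0])
        ]
        current = _breath(4, 1200, ppeak=27.0)
        fv = extract_features(current, history, rec, "VCV")
        assert fv.d_ppeak == pytest.approx(-3.0)
        assert not fv.low_confidence

    def test_empty_history_flags_low_confidence(self):
        fv = extract_features(_breath(0, 0), [], _flat_record(), "VCV")
        assert fv.low_confidence
        assert fv.d_ppeak == 0.0 and fv.d_pef == 0.0

    def test_passive_features_below_noise_floor(self, passive_vcv):
        rec, _ = passive_vcv
        recs = smooth(rec)
        breaths = segment(rec, mode="VCV")
        history = []
        vals = []
        for b in breaths:
            fv = extract_features(b, history, recs, "VCV")
            if history:
                vals.append(fv)
            history.append(b)
        assert vals
        from revtrig.rt_detector import GATE_D_PEF, GATE_D_PPEAK, GATE_DEFORM

        assert max(abs(f.d_ppeak) for f in vals) < GATE_D_PPEAK
        assert max(abs(f.d_pef) for f in vals) < GATE_D_PEF
        assert max(f.exp_deform for f in vals) < GATE_DEFORM

    def test_rt_breath_shows_expiratory_deformation(self, patient):
        # effort peaking in early expiration bends the expiratory flow
        vent = VentilatorSettings(mode="VCV", set_rate=15, vt_set=400, peep=5,
                                  ti=1.0, pause_s=0.3)
        eff = EffortProgram(mode="entrained", ratio=2, delay_s=0.8, amp_cmh2o=10.0,
                            amp_cv=0.0, delay_jitter_sd=0.0, dur_s=1.3)
        rec, gt = simulate(patient, vent, eff, 120, seed=31)
        recs = smooth(rec)
        breaths = segment(rec, mode="VCV")
        rt_idx = set(gt.breaths.index[gt.breaths.label == "RT"])
        history = []
        hits = 0
        n_rt = 0
        for b in breaths:
            fv = extract_features(b, history, recs, "VCV")
            if b.index in rt_idx:
                n_rt += 1
                if fv.exp_deform > 0.1 and fv.deform_window is not None:
                    hits += 1
            else:
                history.append(b)
        assert n_rt > 10
        assert hits / n_rt > 0.8

    def test_unsupported_mode_raises(self):
        with pytest.raises(CapabilityError):
            extract_features(_breath(0, 0), [], _flat_record(), "NAVA")


def _toy_training(n=300, seed=0):
    """Separable synthetic feature/label pairs for fit_model mechanics."""
    rng = np.random.default_rng(seed)
    fvs, labels = [], []
    for i in range(n):
        rt = i % 3 == 0
        fv = FeatureVector(breath_index=i, mode="VCV")
        fv.d_ppeak = float(rng.normal(-4.0 if rt else 0.0, 0.5))
        fv.exp_deform = float(abs(rng.normal(0.3 if rt else 0.01, 0.05)))
        fvs.append(fv)
        labels.append(
            BreathLabel(breath_index=i, label="RT" if rt else "none",
                        rt_subtype="insp" if rt else None)
        )
    return fvs, labels


class TestFitModel:
    def test_refit_is_deterministic(self):
        fvs, labels = _toy_training()
        m1 = fit_model(fvs, labels, seed=5)
        m2 = fit_model(fvs, labels, seed=5)
        assert np.allclose(m1.coefficients, m2.coefficients, atol=1e-9)
        assert m1.cutoff == m2.cutoff

    def test_cutoff_in_open_interval(self):
        m = fit_model(*_toy_training())
        assert 0.0 < m.cutoff < 1.0

    def test_single_class_rejected(self):
        fvs, labels = _toy_training()
        for lab in labels:
            lab.label, lab.rt_subtype = "none", None
        with pytest.raises(DataError, match="single class"):
            fit_model(fvs, labels)

    def test_too_few_breaths_rejected(self):
        fvs, labels = _toy_training(n=50)
        with pytest.raises(DataError, match="200"):
            fit_model(fvs, labels)

    def test_json_roundtrip(self, tmp_path):
        m = fit_model(*_toy_training())
        path = tmp_path / "model.json"
        m.to_json(path)
        back = DetectionModel.from_json(path)
        assert back.coefficients == m.coefficients
        assert back.cutoff == m.cutoff
        assert back.feature_list == m.feature_list


class TestDetect:
    def test_paralyzed_recording_no_rt(self, passive_vcv, default_model):
        rec, _ = passive_vcv
        _, labels = detect_recording(rec, default_model, "VCV")
        assert all(lab.label != "RT" for lab in labels)

    def test_psv_patient_triggered_no_rt(self, psv_patient_triggered, default_model):
        rec, _ = psv_patient_triggered
        _, labels = detect_recording(rec, default_model, "PSV")
        assert all(lab.label != "RT" for lab in labels)

    def test_detection_is_deterministic(self, entrained_vcv, default_model):
        rec, _ = entrained_vcv
        _, l1 = detect_recording(rec, default_model, "VCV")
        _, l2 = detect_recording(rec, default_model, "VCV")
        assert [(x.breath_index, x.label, x.rt_subtype) for x in l1] == \
               [(x.breath_index, x.label, x.rt_subtype) for x in l2]

    def test_patient_triggered_breaths_never_rt(self, stacking_vcv, default_model):
        rec, _ = stacking_vcv
        breaths, labels = detect_recording(rec, default_model, "VCV")
        for b, lab in zip(breaths, labels):
            if b.trigger == "patient":
                assert lab.label != "RT"

    def test_detects_entrained_rt(self, entrained_vcv, default_model):
        rec, gt = entrained_vcv
        _, labels = detect_recording(rec, default_model, "VCV")
        n_rt = sum(1 for lab in labels if lab.label == "RT")
        assert abs(n_rt - gt.rt_count) <= 0.2 * gt.rt_count

    def test_rt_labels_carry_subtype(self, entrained_vcv, default_model):
        rec, _ = entrained_vcv
        _, labels = detect_recording(rec, default_model, "VCV")
        for lab in labels:
            assert (lab.label == "RT") == (lab.rt_subtype is not None)

    def test_detection_rate_monotone_in_amplitude(self, patient, default_model):
        vent = VentilatorSettings(mode="VCV", set_rate=16, vt_set=400, peep=5,
                                  ti=1.0, pause_s=0.3)
        rates = []
        for amp in (2.0, 5.0, 10.0, 20.0):
            eff = EffortProgram(mode="entrained", ratio=2, delay_s=0.5,
                                amp_cmh2o=amp, amp_cv=0.0, delay_jitter_sd=0.0,
                                dur_s=1.1)
            rec, gt = simulate(patient, vent, eff, 120, seed=42)
            _, labels = detect_recording(rec, default_model, "VCV")
            n_rt = sum(1 for lab in labels if lab.label == "RT")
            rates.append(n_rt / max(gt.rt_count, 1))
        assert all(b >= a - 0.05 for a, b in zip(rates, rates[1:]))

    def test_unsupported_mode_raises(self, passive_vcv, default_model):
        rec, _ = passive_vcv
        breaths = segment(rec, mode="VCV")
        with pytest.raises(CapabilityError):
            detect(rec, breaths, default_model, "APRV")
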