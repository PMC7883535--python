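"""Pes effort detection and the RT / IEE / patient-trigger timing rules."""

import numpy as np
import pytest

from revtrig.errors import CapabilityError, DataError
from revtrig.reference_labeling import (
    BreathLabel,
    EffortEvent,
    detect_pes_efforts,
    label_recording,
    label_reference,
    rt_rate,
)
from revtrig.segmentation import Breath, detect_breaths
from revtrig.simulator import EffortProgram, PatientModel, simulate
from revtrig.waveform_io import VentilatorSettings, WaveformRecord


class TestDetectPesEfforts:
    def test_passive_recording_yields_no_events(self, passive_vcv):
        rec, _ = passive_vcv
        breaths = detect_breaths(rec)
        assert detect_pes_efforts(rec, breaths) == []

    def test_event_count_and_amplitude_recovery(self, patient):
        vent = VentilatorSettings(mode="VCV", set_rate=16, vt_set=400, peep=5,
                                  ti=1.0, pause_s=0.3)
        eff = EffortProgram(mode="entrained", ratio=2, delay_s=0.5, amp_cmh2o=10.0,
                            amp_cv=0.0, delay_jitter_sd=0.0, dur_s=1.1)
        rec, gt = simulate(patient, vent, eff, 240, seed=21)
        breaths = detect_breaths(rec)
        events = detect_pes_efforts(rec, breaths)
        true_n = int(gt.breaths.effort_amp.notna().sum())
        assert true_n >= 30
        assert len(events) == true_n
        amps = np.array([e.amp for e in events])
        assert np.all(np.abs(amps - 10.0) / 10.0 < 0.15)

    def test_cardiac_oscillations_rejected_by_duration(self):
        # cardiac-only Pes: 1.5 cmH2O sinusoid at 80/min on a passive breath train
        pat = PatientModel(cardiac_amp=1.5, cardiac_rate=80.0)
        vent = VentilatorSettings(mode="VCV", set_rate=14, vt_set=400, peep=5,
                                  ti=1.0, pause_s=0.3)
        rec, _ = simulate(pat, vent, EffortProgram(mode="none"), 120, seed=22)
        breaths = detect_breaths(rec)
        assert detect_pes_efforts(rec, breaths) == []

    def test_missing_pes_raises_capability_error(self, passive_vcv):
        rec, _ = passive_vcv
        from dataclasses import replace
        blind = replace(rec, pes=None)
        with pytest.raises(CapabilityError, match="Paw/flow"):
            detect_pes_efforts(blind, detect_breaths(blind))

    def test_event_onset_precedes_peak(self, entrained_vcv):
        rec, _ = entrained_vcv
        events = detect_pes_efforts(rec, detect_breaths(rec))
        assert events
        assert all(e.onset_s < e.peak_s and e.amp > 0 for e in events)


def _machine_breath(start_s=0.0, rate=100.0):
    """One machine breath 0..4 s (insufflation 1.3 s incl. pause) on a
    minimal waveform; used to exercise the timing rules in isolation."""
    n = 400
    paw = np.full(n, 5.0)
    flow = np.zeros(n)
    flow[0:100] = 24.0
    flow[130:350] = -15.0
    rec = WaveformRecord(rate, paw=paw, flow=flow)
    b = Breath(index=0, start=0, insp_end=130, end=400, trigger="machine")
    return rec, b


def _ev(onset, peak, amp=5.0, offset=None):
    return EffortEvent(onset_s=onset, peak_s=peak, amp=amp,
                       breath_index=0, offset_s=offset if offset else peak + 0.3)


class TestTimingRules:
    """Strict boundary semantics of the event definitions."""

    @pytest.mark.parametrize(
        "onset,peak,expected",
        [
            (0.30, 1.00, "RT"),     # canonical reverse triggering
            (0.11, 1.49, "RT"),     # just inside both strict bounds
            (0.05, 1.00, "none"),   # onset not more than 0.1 s after start
            (0.10, 1.00, "none"),   # exactly 0.1 s: strict inequality
            (0.30, 1.50, "none"),   # peak exactly 1.5 s: strict inequality
            (0.30, 1.60, "IEE"),    # peak beyond 1.5 s, no trigger
            (1.70, 2.10, "IEE"),    # late expiratory effort
        ],
    )
    def test_machine_breath_event_classes(self, onset, peak, expected):
        rec, b = _machine_breath()
        labels = label_reference([_ev(onset, peak)], [b], rec)
        assert labels[0].label == expected

    def test_rt_subtype_from_peak_timing(self):
        rec, b = _machine_breath()
        # peak during constant flow -> insp; during pause -> pause;
        # at exhalation onset -> exp1; later -> exp
        for peak, sub in [(0.8, "insp"), (1.15, "pause"), (1.4, "exp1"), (1.49, "exp1")]:
            lab = label_reference([_ev(0.3, peak)], [b], rec)[0]
            assert (lab.label, lab.rt_subtype) == ("RT", sub)
        # a pause exists in this waveform at 1.0-1.3 s; exp starts 1.3 s
        lab = label_reference([_ev(1.2, 1.45)], [b], rec)[0]
        assert lab.rt_subtype == "exp1"

    def test_patient_breath_keeps_patient_label(self):
        rec, b = _machine_breath()
        b.trigger = "patient"
        labels = label_reference([], [b], rec)
        assert labels[0].label == "patient_trigger"

    def test_patient_breath_with_late_effort_is_iee(self):
        rec, b = _machine_breath()
        b.trigger = "patient"
        labels = label_reference([_ev(1.8, 2.2)], [b], rec)
        assert labels[0].label == "IEE"

    def test_first_classifiable_event_wins(self):
        rec, b = _machine_breath()
        # an indeterminate early event does not mask a later RT event
        labels = label_reference([_ev(0.08, 0.5), _ev(0.6, 1.2)], [b], rec)
        assert labels[0].label == "none"
        # but among classifiable events the first decides
        labels = label_reference([_ev(0.3, 1.0), _ev(1.8, 2.2)], [b], rec)
        assert labels[0].label == "RT"

    def test_auto_triggered_breath_can_be_rt(self):
        rec, b = _machine_breath()
        b.trigger = "auto"
        labels = label_reference([_ev(0.3, 1.0)], [b], rec)
        assert labels[0].label == "RT"


class TestRtRate:
    def test_paper_scale_fraction(self):
        labels = [
            BreathLabel(breath_index=i, label="RT" if i < 1073 else "none",
                        rt_subtype="insp" if i < 1073 else None)
            for i in range(4509)
        ]
        assert rt_rate(labels) == pytest.approx(1073 / 4509)
        assert round(100 * rt_rate(labels), 1) == 23.8

    def test_degenerate_rates(self):
        none = [BreathLabel(breath_index=0, label="none")]
        assert rt_rate(none) == 0.0
        allrt = [BreathLabel(breath_index=0, label="RT", rt_subtype="insp")]
        assert rt_rate(allrt) == 1.0
        with pytest.raises(DataError):
            rt_rate([])


class TestEndToEndAgreement:
    def test_reference_matches_ground_truth(self, entrained_vcv, entrained_pcv,
                                            stacking_vcv, psv_patient_triggered):
        """Reference labels agree with GroundTruth classes >= 97% for
        efforts of at least 3 cmH2O (and all passive breaths)."""
        ok = n = 0
        for (rec, gt), mode in [(entrained_vcv, "VCV"), (entrained_pcv, "PCV"),
                                (stacking_vcv, "VCV"), (psv_patient_triggered, "PSV")]:
            _, _, labels = label_recording(rec, mode)
            truth = gt.breaths.label.tolist()
            amps = gt.breaths.effort_amp.fillna(np.inf).tolist()
            assert len(labels) == len(truth)
            for lab, t, a in zip(labels, truth, amps):
                if a >= 3.0:
                    ok += lab.label == t
                    n += 1
        assert n > 100
        assert ok / n >= 0.97

    def test_no_rt_on_patient_triggered_or_paralyzed(self, passive_vcv,
                                                     psv_patient_triggered):
        for (rec, _), mode in [(passive_vcv, "VCV"), (psv_patient_triggered, "PSV")]:
            _, _, labels = label_recording(rec, mode)
            assert all(lab.label != "RT" for lab in labels)
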