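"""Shared fixtures: short seeded simulated recordings and the packaged model.

Session-scoped so the simulator runs once per recording per test session.
"""

import pytest

from revtrig.rt_detector import load_default_model
from revtrig.simulator import EffortProgram, PatientModel, simulate
from revtrig.waveform_io import VentilatorSettings


@pytest.fixture(scope="session")
def patient():
    return PatientModel()


@pytest.fixture(scope="session")
def vcv_settings():
    return VentilatorSettings(
        mode="VCV", set_rate=15, vt_set=400.0, peep=5.0, ti=1.0, pause_s=0.3
    )


@pytest.fixture(scope="session")
def passive_vcv(patient, vcv_settings):
    """120 s passive (paralyzed analogue) VCV recording."""
    return simulate(patient, vcv_settings, EffortProgram(mode="none"), 120.0, seed=101)


@pytest.fixture(scope="session")
def entrained_vcv(patient, vcv_settings):
    """120 s VCV with 1:2 entrained reverse-triggering efforts (amp 10)."""
    eff = EffortProgram(mode="entrained", ratio=2, delay_s=0.5, amp_cmh2o=10.0,
                        amp_cv=0.2, dur_s=1.1)
    return simulate(patient, vcv_settings, eff, 120.0, seed=102)


@pytest.fixture(scope="session")
def entrained_pcv(patient):
    """120 s PCV with 1:2 entrained efforts."""
    vent = VentilatorSettings(mode="PCV", set_rate=16, p_insp=8.0, peep=5.0,
                              ti=1.0, pause_s=0.0)
    eff = EffortProgram(mode="entrained", ratio=2, delay_s=0.5, amp_cmh2o=10.0,
                        amp_cv=0.2, dur_s=1.1)
    return simulate(patient, vent, eff, 120.0, seed=103)


@pytest.fixture(scope="session")
def stacking_vcv(patient):
    """120 s VCV with strong 1:1 entrained efforts producing breath stacking."""
    vent = VentilatorSettings(mode="VCV", set_rate=15, vt_set=400.0, peep=5.0,
                              ti=1.0, pause_s=0.3)
    eff = EffortProgram(mode="entrained", ratio=1, delay_s=0.7, amp_cmh2o=14.0,
                        amp_cv=0.3, dur_s=1.5)
    return simulate(patient, vent, eff, 120.0, seed=104)


@pytest.fixture(scope="session")
def psv_patient_triggered(patient):
    """120 s PSV, every breath patient-triggered."""
    vent = VentilatorSettings(mode="PSV", set_rate=20, p_insp=10.0, peep=5.0)
    eff = EffortProgram(mode="pre_trigger", amp_cmh2o=9.0, amp_cv=0.2, dur_s=0.9)
    return simulate(patient, vent, eff, 120.0, seed=105)


@pytest.fixture(scope="session")
def default_model():
    return load_default_model()
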