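"""Patient–ventilator simulator producing labeled synthetic recordings.

The respiratory system is a passive single compartment obeying the
equation of motion

    Paw = res * V'  +  V / Crs  +  PEEP  -  Pmus

with compliance Crs (mL/cmH2O), resistance res (cmH2O.s/L) and muscular
pressure Pmus (cmH2O, inspiratory positive).  Esophageal pressure follows
the chest-wall relaxation relation

    Pes = Pes_baseline + V / Ccw - Pmus + cardiac artifact + noise.

The ventilator side implements VCV (constant-flow insufflation of a set
tidal volume, optional end-inspiratory pause), PCV and PSV (first-order
approach to a pressure target, PSV cycling at a fraction of peak
inspiratory flow).  During exhalation the circuit drains through an
expiratory valve of resistance ``r_exp_valve`` toward the PEEP reservoir;
when a patient effort demands inspiratory flow the valve closes (demand
behavior) and the airway pressure dips below PEEP by the unbalanced
muscular pressure, which can trip the pressure trigger — breath stacking
therefore *emerges* whenever an effort is strong enough to cross the
trigger threshold before exhalation completes; it is never scripted.

Patient efforts are piecewise raised-cosine Pmus pulses arranged by an
:class:`EffortProgram`: entrained to machine insufflations (reverse
triggering), leading the machine schedule (patient triggering), or late
and weak (ineffective efforts).  Every simulated breath carries a ground
truth record (trigger type, true effort timing and amplitude, event
class, stacking flag).

Integration is explicit Euler on the canonical 100 Hz grid; the system
time constant (res*Crs ~ 0.5 s) is resolved by two orders of magnitude.
Signals at each sample are computed from the pre-update volume, so the
stored waveforms satisfy the equation of motion exactly before noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, SimulationError
from .waveform_io import CANONICAL_RATE_HZ, VentilatorSettings, WaveformRecord

logger = logging.getLogger("revtrig")

#: expiratory-valve resistance between airway and PEEP reservoir (cmH2O.s/L)
R_EXP_VALVE = 3.0

#: trigger refractory period after cycling to exhalation (s)
TRIGGER_REFRACTORY_S = 0.2

#: Pmus level above which a triggered insufflation counts as patient- (not
#: auto-) triggered in the ground truth (cmH2O)
AUTO_TRIGGER_PMUS_FLOOR = 0.5

#: timing rules for event classes (s after machine insufflation onset)
RT_ONSET_MIN_S = 0.1
RT_PEAK_MAX_S = 1.5

#: exhalation completeness fraction shared with the analysis side
COMPLETENESS_FRAC = 0.90


@dataclass
class PatientModel:
    """Passive mechanics and measurement-noise description of one patient.

    crs / ccw are respiratory-system and chest-wall compliance in
    mL/cmH2O (ccw >= crs because the lung adds elastance in series);
    res is airway resistance in cmH2O.s/L.  Noise SDs are per-channel
    white Gaussian; the cardiac artifact is a sinusoid on Pes.
    """

    crs: float = 50.0
    res: float = 10.0
    ccw: float = 200.0
    pes_baseline: float = 5.0
    noise_sd_paw: float = 0.2
    noise_sd_flow: float = 0.3
    noise_sd_pes: float = 0.2
    cardiac_amp: float = 0.5
    cardiac_rate: float = 80.0

    def __post_init__(self) -> None:
        if self.crs <= 0 or self.res <= 0:
            raise ConfigError("crs and res must be positive")
        if self.ccw < self.crs:
            raise ConfigError("ccw must be >= crs")
        for name in ("noise_sd_paw", "noise_sd_flow", "noise_sd_pes"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class EffortProgram:
    """Parameterized train of respiratory-muscle efforts.

    mode:
      * ``none`` — fully passive (paralysis analogue).
      * ``entrained`` — one effort per ``ratio`` machine insufflations,
        starting ``delay_s`` (jittered) after insufflation onset: the
        reverse-triggering pattern.
      * ``pre_trigger`` — efforts at the intrinsic rate, leading the
        machine: every breath is patient-triggered (PSV analogue).
      * ``late_ie`` — weak efforts whose peak falls beyond the 1.5 s
        discriminator: ineffective efforts during expiration.
      * ``mixed`` — entrained efforts plus sparse late weak efforts.

    Amplitudes are drawn Normal(amp_cmh2o, amp_cv * amp_cmh2o) truncated
    at zero; each effort is a raised cosine rising over
    ``rise_frac * dur_s`` and decaying over the remainder, so the true
    peak Pmus occurs ``rise_frac * dur_s`` after effort onset.
    """

    mode: str = "none"
    ratio: int = 1
    delay_s: float = 0.5
    delay_jitter_sd: float = 0.05
    amp_cmh2o: float = 10.0
    amp_cv: float = 0.2
    dur_s: float = 1.0
    rise_frac: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "entrained", "pre_trigger", "late_ie", "mixed"):
            raise ConfigError(f"unknown effort mode {self.mode!r}")
        if self.amp_cmh2o < 0:
            raise ConfigError("amp_cmh2o must be >= 0")
        if not 0 < self.rise_frac < 1:
            raise ConfigError("rise_frac must lie in (0, 1)")
        if self.dur_s <= 0:
            raise ConfigError("dur_s must be positive")
        if self.ratio < 1:
            raise ConfigError("ratio must be an integer >= 1")


@dataclass
class GroundTruth:
    """Per-breath truth table of a simulated recording."""

    breaths: pd.DataFrame
    duration_s: float

    @property
    def n_breaths(self) -> int:
        return len(self.breaths)

    @property
    def rt_count(self) -> int:
        return int((self.breaths["label"] == "RT").sum())

    @property
    def rt_rate(self) -> float:
        """Fraction of all breaths labeled RT."""
        if self.n_breaths == 0:
            raise DataError("rt_rate undefined for zero breaths")
        return self.rt_count / self.n_breaths

    @property
    def rt_per_min(self) -> float:
        return self.rt_count / (self.duration_s / 60.0)


def pmus_pulse(tau: float, amp: float, dur: float, rise_frac: float) -> float:
    """Raised-cosine effort pulse evaluated ``tau`` s after its onset."""
    if tau <= 0.0 or tau >= dur:
        return 0.0
    t_rise = rise_frac * dur
    if tau < t_rise:
        return 0.5 * amp * (1.0 - math.cos(math.pi * tau / t_rise))
    return 0.5 * amp * (1.0 + math.cos(math.pi * (tau - t_rise) / (dur - t_rise)))


class _Effort:
    """One scheduled effort with bookkeeping for ground-truth assembly."""

    __slots__ = ("onset", "amp", "dur", "rise_frac", "triggered_breath")

    def __init__(self, onset: float, amp: float, dur: float, rise_frac: float):
        self.onset = onset
        self.amp = amp
        self.dur = dur
        self.rise_frac = rise_frac
        self.triggered_breath: int | None = None

    @property
    def peak_t(self) -> float:
        return self.onset + self.rise_frac * self.dur

    @property
    def end(self) -> float:
        return self.onset + self.dur


def simulate(
    patient: PatientModel,
    vent: VentilatorSettings,
    effort: EffortProgram,
    duration_s: float,
    seed: int,
    r_exp_valve: float = R_EXP_VALVE,
) -> tuple[WaveformRecord, GroundTruth]:
    """Simulate ``duration_s`` seconds of ventilation; return the noisy
    recording and its ground truth.

    The returned record's ``meta`` carries the pre-noise signals
    (``paw_clean``, ``flow_clean_lpm``, ``pes_clean``) and the true
    ``pmus`` trace so that tests can verify the equation of motion
    directly.
    """
    if duration_s < 10:
        raise ConfigError("duration_s must be >= 10")
    rng = np.random.default_rng(seed)
    dt = 1.0 / CANONICAL_RATE_HZ
    n = int(round(duration_s * CANONICAL_RATE_HZ))

    noise_paw = rng.normal(0.0, patient.noise_sd_paw, n) if patient.noise_sd_paw else np.zeros(n)
    noise_flow = rng.normal(0.0, patient.noise_sd_flow, n) if patient.noise_sd_flow else np.zeros(n)
    noise_pes = rng.normal(0.0, patient.noise_sd_pes, n) if patient.noise_sd_pes else np.zeros(n)

    crs_l = patient.crs / 1000.0  # L/cmH2O
    res = patient.res
    peep = vent.peep
    # machine backup schedule exists only in the controlled modes
    intrinsic = 60.0 / vent.set_rate if vent.set_rate > 0 else 3.0
    period = intrinsic if vent.mode in ("VCV", "PCV") else math.inf

    # pre-scheduled efforts (intrinsic-rhythm mode)
    efforts: list[_Effort] = []
    if effort.mode == "pre_trigger":
        p_int = intrinsic
        if vent.mode != "PSV":
            p_int *= 0.9  # patient rhythm leads the machine backup rate
        t = max(effort.delay_s, 0.2)
        while t < duration_s:
            amp = max(0.0, rng.normal(effort.amp_cmh2o, effort.amp_cv * effort.amp_cmh2o))
            jit = rng.normal(0.0, effort.delay_jitter_sd)
            if amp > 0.05:
                efforts.append(_Effort(t + jit, amp, effort.dur_s, effort.rise_frac))
            t += p_int
        efforts.sort(key=lambda e: e.onset)

    paw = np.empty(n)
    flow_lps = np.empty(n)
    pmus_tr = np.empty(n)

    n_ti = max(1, int(round(vent.ti / dt)))
    n_pause = int(round(vent.pause_s / dt)) if vent.mode == "VCV" else 0
    vcv_flow = (vent.vt_set / 1000.0) / vent.ti if vent.mode == "VCV" else 0.0

    # state
    vol = 0.0  # L above the passive end-expiratory volume
    phase = "EXP"
    phase_k = 10**9  # samples completed in current phase (EXP pre-armed)
    next_due = 0.0 if vent.mode in ("VCV", "PCV") else math.inf
    machine_count = 0
    peak_insp_flow = 0.0
    breaths: list[dict] = []
    active: list[_Effort] = []
    eff_ptr = 0
    paw_buf: list[float] = []

    def start_insufflation(t: float, trig: str, tr_effort: _Effort | None):
        nonlocal phase, phase_k, machine_count, peak_insp_flow, next_due
        if breaths:
            breaths[-1]["end_t"] = t
            breaths[-1]["v_next0"] = vol * 1000.0
        breaths.append(
            {
                "start_t": t,
                "trigger": trig,
                "v0": vol * 1000.0,
                "insp_flow_end_t": None,
                "exp_start_t": None,
                "vei": None,
                "end_t": None,
                "v_next0": None,
            }
        )
        if tr_effort is not None:
            tr_effort.triggered_breath = len(breaths) - 1
        phase, phase_k = "INSP", 0
        peak_insp_flow = 0.0
        next_due = t + period
        if trig == "machine":
            machine_count += 1
            if effort.mode in ("entrained", "mixed", "late_ie") and (
                machine_count - 1
            ) % effort.ratio == 0:
                amp = max(0.0, rng.normal(effort.amp_cmh2o, effort.amp_cv * effort.amp_cmh2o))
                delay = max(0.05, effort.delay_s + rng.normal(0.0, effort.delay_jitter_sd))
                if amp > 0.05:  # a zero-amplitude pulse is no contraction
                    efforts.append(_Effort(t + delay, amp, effort.dur_s, effort.rise_frac))
            if effort.mode == "mixed" and machine_count % 5 == 0:
                # sparse late weak efforts on top of the entrained train
                amp = max(0.0, rng.normal(3.0, 0.9))
                efforts.append(_Effort(t + 1.6, amp, 0.7, effort.rise_frac))

    for i in range(n):
        t = i * dt

        while eff_ptr < len(efforts) and efforts[eff_ptr].onset <= t:
            active.append(efforts[eff_ptr])
            eff_ptr += 1
        if active:
            active = [e for e in active if e.end > t]
        pmus = 0.0
        for e in active:
            pmus += pmus_pulse(t - e.onset, e.amp, e.dur, e.rise_frac)

        if phase == "INSP":
            t_in = phase_k * dt
            if vent.mode == "VCV":
                q = vcv_flow
                p = res * q + vol / crs_l + peep - pmus
            else:
                target = peep + vent.p_insp * (
                    1.0 - math.exp(-t_in / max(vent.rise_time_s, 1e-3))
                )
                q = (target - vol / crs_l - peep + pmus) / res
                p = target
                if q > peak_insp_flow:
                    peak_insp_flow = q
        elif phase == "PAUSE":
            q = 0.0
            p = vol / crs_l + peep - pmus
        else:  # EXP: drain through the valve; inspiratory demand closes it
            q = (pmus - vol / crs_l) / (res + r_exp_valve)
            if q > 0.0:
                q = 0.0
                p = vol / crs_l + peep - pmus
            else:
                p = peep - r_exp_valve * q

        paw[i] = p
        flow_lps[i] = q
        pmus_tr[i] = pmus
        vol += q * dt
        phase_k += 1

        if vol < -0.25:
            raise SimulationError(
                f"non-physical volume {vol * 1000:.0f} mL at t={t:.2f} s "
                f"(patient={patient}, vent={vent}, effort={effort})"
            )

        # phase transitions and trigger logic
        if phase == "INSP":
            cycle = False
            if vent.mode in ("VCV", "PCV"):
                cycle = phase_k >= n_ti
            else:  # PSV
                cycle = (
                    phase_k * dt > 0.25
                    and peak_insp_flow > 0
                    and q < vent.psv_cycle_frac * peak_insp_flow
                ) or phase_k * dt > 3.0
            if cycle:
                breaths[-1]["insp_flow_end_t"] = (i + 1) * dt
                breaths[-1]["vei"] = vol * 1000.0
                if vent.mode == "VCV" and n_pause > 0:
                    phase, phase_k = "PAUSE", 0
                else:
                    breaths[-1]["exp_start_t"] = (i + 1) * dt
                    phase, phase_k = "EXP", 0
                    paw_buf.clear()
        elif phase == "PAUSE":
            if phase_k >= n_pause:
                breaths[-1]["exp_start_t"] = (i + 1) * dt
                phase, phase_k = "EXP", 0
                paw_buf.clear()
        else:  # EXP: evaluate the pressure trigger on smoothed sensed Paw
            sensed = p + noise_paw[i]
            paw_buf.append(sensed)
            if len(paw_buf) > 8:
                paw_buf.pop(0)
            if phase_k * dt > TRIGGER_REFRACTORY_S:
                smoothed = sorted(paw_buf)[len(paw_buf) // 2]
                if smoothed < peep - vent.trigger_paw_drop:
                    trig = "patient" if pmus > AUTO_TRIGGER_PMUS_FLOOR else "auto"
                    tr_eff = None
                    if trig == "patient":
                        for e in active:
                            if e.triggered_breath is None and e.onset < t:
                                tr_eff = e
                                break
                    start_insufflation(t, trig, tr_eff)
                elif t >= next_due:
                    start_insufflation(t, "machine", None)

    if breaths:
        breaths[-1]["end_t"] = n * dt
        breaths[-1]["v_next0"] = vol * 1000.0
        for b in breaths:
            if b["vei"] is None:  # recording ended mid-insufflation
                b["vei"] = b["v_next0"]
            if b["insp_flow_end_t"] is None:
                b["insp_flow_end_t"] = b["end_t"]
            if b["exp_start_t"] is None:
                b["exp_start_t"] = b["end_t"]
    elif vent.mode == "PSV":
        logger.warning(
            "PSV simulation produced zero insufflations (no efforts, no auto-trigger)"
        )

    gt = _assemble_ground_truth(breaths, efforts, duration_s)

    # pre-update volume trace matching the stored signals
    vol_pre_ml = np.concatenate([[0.0], np.cumsum(flow_lps[:-1])]) * dt * 1000.0
    pes_clean = patient.pes_baseline + vol_pre_ml / patient.ccw - pmus_tr
    tgrid = np.arange(n) * dt
    cardiac = patient.cardiac_amp * np.sin(2 * np.pi * patient.cardiac_rate / 60.0 * tgrid)

    record = WaveformRecord(
        sampling_rate_hz=CANONICAL_RATE_HZ,
        paw=paw + noise_paw,
        flow=flow_lps * 60.0 + noise_flow,
        pes=pes_clean + cardiac + noise_pes,
        meta={
            "paw_clean": paw,
            "flow_clean_lpm": flow_lps * 60.0,
            "pes_clean": pes_clean,
            "pmus": pmus_tr,
            "vent_mode": vent.mode,
            "seed": seed,
        },
    )
    return record, gt


def _assemble_ground_truth(
    breaths: list[dict], efforts: list[_Effort], duration_s: float
) -> GroundTruth:
    rows = []
    for k, b in enumerate(breaths):
        start, end = b["start_t"], b["end_t"]
        v_insp = (b["vei"] or 0.0) - b["v0"]
        exhaled = (b["vei"] or 0.0) - (b["v_next0"] if b["v_next0"] is not None else b["v0"])
        nxt = breaths[k + 1] if k + 1 < len(breaths) else None
        # this breath is stacked if it began before its predecessor exhaled
        stacked = False
        if k > 0:
            prev = breaths[k - 1]
            prev_vi = (prev["vei"] or 0.0) - prev["v0"]
            prev_exh = (prev["vei"] or 0.0) - b["v0"]
            stacked = prev_vi > 0 and prev_exh < COMPLETENESS_FRAC * prev_vi

        own = [e for e in efforts if start < e.onset < end and e.triggered_breath != k]
        label, subtype = "none", None
        onset_s = peak_s = amp = math.nan
        if b["trigger"] == "patient":
            label = "patient_trigger"
            trig_eff = next((e for e in efforts if e.triggered_breath == k), None)
            if trig_eff is not None:
                onset_s, peak_s, amp = trig_eff.onset, trig_eff.peak_t, trig_eff.amp
            # a late non-triggering effort within a triggered breath is IEE
            for e in own:
                if e.triggered_breath is None and e.peak_t > start + RT_PEAK_MAX_S:
                    label = "IEE"
                    onset_s, peak_s, amp = e.onset, e.peak_t, e.amp
                    break
        else:  # machine- or auto-triggered insufflation
            for e in own:
                rel_on = e.onset - start
                rel_pk = e.peak_t - start
                if rel_on > RT_ONSET_MIN_S and rel_pk < RT_PEAK_MAX_S:
                    label = "RT"
                    onset_s, peak_s, amp = e.onset, e.peak_t, e.amp
                    if e.triggered_breath == k + 1:
                        subtype = "BS"
                    elif e.peak_t < b["insp_flow_end_t"]:
                        subtype = "insp"
                    elif e.peak_t < b["exp_start_t"]:
                        subtype = "pause"
                    elif e.peak_t < b["exp_start_t"] + 0.2:
                        subtype = "exp1"
                    else:
                        subtype = "exp"
                    break
                if e.triggered_breath is None and rel_pk > RT_PEAK_MAX_S:
                    label = "IEE"
                    onset_s, peak_s, amp = e.onset, e.peak_t, e.amp
                    break
        # successor stacking promotes the RT subtype to BS
        if label == "RT" and nxt is not None and v_insp > 0:
            if ((b["vei"] or 0.0) - nxt["v0"]) < COMPLETENESS_FRAC * v_insp:
                subtype = "BS"
        rows.append(
            {
                "index": k,
                "start_s": start,
                "end_s": end,
                "trigger": b["trigger"],
                "label": label,
                "rt_subtype": subtype,
                "stacked": stacked,
                "effort_onset_s": onset_s,
                "effort_peak_s": peak_s,
                "effort_amp": amp,
                "v_insp_ml": v_insp,
                "v_exhaled_ml": exhaled,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "index", "start_s", "end_s", "trigger", "label", "rt_subtype", "stacked",
            "effort_onset_s", "effort_peak_s", "effort_amp", "v_insp_ml", "v_exhaled_ml",
        ],
    )
    return GroundTruth(breaths=df, duration_s=duration_s)


# -- scenario suites ---------------------------------------------------------


def _sub_seed(seed: int, i: int) -> int:
    return int((seed * 100003 + 7919 * i + 13) % (2**31 - 1))


def default_validation_scenarios() -> list[dict]:
    """Twenty 10-min scenarios in five strata of four recordings each:
    no RT (paralyzed), low (<4 RT/min), moderate (4–10 RT/min),
    high (>10 RT/min) and PSV (all patient-triggered, control)."""
    scen: list[dict] = []

    def vent(mode, rate, **kw):
        base = dict(mode=mode, set_rate=rate, vt_set=400.0, p_insp=8.0, peep=5.0,
                    ti=1.0, pause_s=0.3, trigger_paw_drop=2.0)
        if mode != "VCV":
            base["pause_s"] = 0.0
        base.update(kw)
        return base

    modes = ["VCV", "PCV", "VCV", "PCV"]
    for j, m in enumerate(modes):
        scen.append(dict(name=f"paralyzed_{j}", stratum="none", vent=vent(m, 18 + j),
                         effort=dict(mode="none"), duration_s=600.0))
    for j, m in enumerate(modes):
        scen.append(dict(
            name=f"low_{j}", stratum="low", vent=vent(m, 20),
            effort=dict(mode="entrained", ratio=6, delay_s=0.4 + 0.1 * j,
                        amp_cmh2o=8.0, amp_cv=0.25, dur_s=1.0),
            duration_s=600.0))
    for j, m in enumerate(modes):
        scen.append(dict(
            name=f"moderate_{j}", stratum="moderate", vent=vent(m, 16),
            effort=dict(mode="entrained", ratio=2, delay_s=0.35 + 0.1 * j,
                        amp_cmh2o=9.0, amp_cv=0.25, dur_s=1.0),
            duration_s=600.0))
    for j, m in enumerate(modes):
        scen.append(dict(
            name=f"high_{j}", stratum="high", vent=vent(m, 15 + j),
            effort=dict(mode="entrained", ratio=1, delay_s=0.4 + 0.1 * j,
                        amp_cmh2o=12.0, amp_cv=0.35, dur_s=1.4),
            duration_s=600.0))
    for j in range(4):
        scen.append(dict(
            name=f"psv_{j}", stratum="psv",
            vent=dict(mode="PSV", set_rate=20 + j, p_insp=10.0, peep=5.0,
                      trigger_paw_drop=2.0, psv_cycle_frac=0.25),
            effort=dict(mode="pre_trigger", amp_cmh2o=9.0, amp_cv=0.2, dur_s=0.9),
            duration_s=600.0))
    return scen


def default_training_scenarios() -> list[dict]:
    """Training suite: 5-min recordings spanning passive breaths, RT of
    graded amplitude/delay in both controlled modes, ineffective efforts
    and pressure support."""
    scen: list[dict] = []

    def add(name, mode, eff, rate=16, dur=300.0):
        if mode == "PSV":
            vent = dict(mode="PSV", set_rate=rate, p_insp=10.0, peep=5.0,
                        trigger_paw_drop=2.0, psv_cycle_frac=0.25)
        else:
            vent = dict(mode=mode, set_rate=rate, vt_set=400.0, p_insp=8.0, peep=5.0,
                        ti=1.0, pause_s=0.3 if mode == "VCV" else 0.0,
                        trigger_paw_drop=2.0)
        scen.append(dict(name=name, stratum="train", vent=vent, effort=eff, duration_s=dur))

    add("passive_vcv", "VCV", dict(mode="none"))
    add("passive_pcv", "PCV", dict(mode="none"))
    for amp in (4.0, 8.0, 15.0, 25.0):
        add(f"rt_vcv_a{int(amp)}", "VCV",
            dict(mode="entrained", ratio=2, delay_s=0.4, amp_cmh2o=amp, amp_cv=0.25, dur_s=1.1))
        add(f"rt_pcv_a{int(amp)}", "PCV",
            dict(mode="entrained", ratio=2, delay_s=0.5, amp_cmh2o=amp, amp_cv=0.25, dur_s=1.1))
    add("rt_vcv_late", "VCV",
        dict(mode="entrained", ratio=3, delay_s=0.8, amp_cmh2o=10.0, amp_cv=0.25, dur_s=1.3))
    add("iee_vcv", "VCV",
        dict(mode="late_ie", ratio=2, delay_s=1.5, amp_cmh2o=3.0, amp_cv=0.2, dur_s=0.7),
        rate=12)
    add("mixed_vcv", "VCV",
        dict(mode="mixed", ratio=2, delay_s=0.6, amp_cmh2o=13.0, amp_cv=0.35, dur_s=1.6))
    add("mixed_pcv", "PCV",
        dict(mode="mixed", ratio=2, delay_s=0.6, amp_cmh2o=13.0, amp_cv=0.35, dur_s=1.6))
    add("psv_train", "PSV", dict(mode="pre_trigger", amp_cmh2o=9.0, amp_cv=0.2, dur_s=0.9))
    return scen


def run_scenario(scenario: dict, seed: int) -> tuple[WaveformRecord, GroundTruth]:
    """Instantiate and run one scenario dictionary."""
    try:
        patient = PatientModel(**scenario.get("patient", {}))
        vent = VentilatorSettings(**scenario["vent"])
        eff = EffortProgram(**scenario.get("effort", {"mode": "none"}))
        duration = float(scenario.get("duration_s", 600.0))
    except KeyError as exc:
        raise ConfigError(f"scenario missing key {exc}") from exc
    except TypeError as exc:
        raise ConfigError(f"invalid scenario parameter: {exc}") from exc
    return simulate(patient, vent, eff, duration, seed)


def make_validation_set(
    config: Sequence[dict] | None = None, seed: int = 0
) -> list[tuple[dict, WaveformRecord, GroundTruth]]:
    """Run a scenario suite (default: the 20-recording stratified
    validation mix) with fixed per-scenario sub-seeds."""
    scenarios = list(config) if config is not None else default_validation_scenarios()
    if not scenarios:
        raise ConfigError("scenario list is empty")
    out = []
    for i, sc in enumerate(scenarios):
        rec, gt = run_scenario(sc, _sub_seed(seed, i))
        out.append((sc, rec, gt))
    return out
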