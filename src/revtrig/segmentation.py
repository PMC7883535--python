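"""Breath segmentation, trigger classification and per-breath mechanics.

A breath is an insufflation followed by an expiration, even if short and
incomplete; a cycle runs from one insufflation onset to the next, so
breaths tile the recording (half-open sample intervals).  A second
insufflation arriving before the previous volume is fully exhaled is a
separate, stacked breath.

Detection thresholds (onset flow, sustain time, cycling, pre-trigger
window, exhalation completeness) are module constants exposed here; the
defaults sit above the smoothing-residual noise of typical adult
recordings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DataError
from .waveform_io import WaveformRecord, integrate_volume, smooth

#: insufflation onset: flow must exceed this (L/min) ...
ONSET_FLOW_LPM = 3.0
#: ... for at least this long (ms)
ONSET_SUSTAIN_MS = 80.0
#: expiration evidence / cycling: flow below this (L/min) ends insufflation
EXP_FLOW_LPM = -3.0
#: minimum insufflation length before cycling is searched (s)
MIN_INSP_S = 0.15
#: zero-flow pause criterion for plateau pressure: |flow| < 2 L/min ...
PAUSE_FLOW_LPM = 2.0
#: ... sustained at least this long (ms)
PAUSE_MIN_MS = 100.0
#: exhalation is "complete" when this fraction of inspired volume returned
COMPLETENESS_FRAC = 0.90
#: window before onset searched for triggering evidence (s)
PRE_TRIGGER_WINDOW_S = 0.3
#: Pes drop qualifying a patient trigger (cmH2O, strict >)
PES_TRIGGER_DROP = 2.0
#: Paw dip below the local expiratory baseline qualifying a patient
#: trigger when Pes is unavailable (cmH2O, strict >)
PAW_TRIGGER_DIP = 0.3
#: EAdi excess above baseline qualifying a patient trigger (uV, strict >)
EADI_TRIGGER_UV = 0.5


@dataclass
class Breath:
    """One insufflation-to-next-insufflation cycle.

    ``start``/``insp_end``/``end`` are 0-based sample indices with
    half-open convention; ``insp_end`` marks the transition to
    expiration (the end-inspiratory pause, when present, belongs to the
    insufflation).  ``pef`` is the magnitude of the most negative
    expiratory flow (L/min); volumes are mL.
    """

    index: int
    start: int
    insp_end: int
    end: int
    trigger: str = "machine"
    stacked: bool = False
    ppeak: float | None = None
    pplat: float | None = None
    pef: float | None = None
    v_insp: float | None = None
    v_exp_at_next: float | None = None

    def start_s(self, rate_hz: float) -> float:
        return self.start / rate_hz

    def duration_s(self, rate_hz: float) -> float:
        return (self.end - self.start) / rate_hz


def detect_breaths(record: WaveformRecord) -> list[Breath]:
    """Partition a recording into breaths from the flow signal.

    An insufflation onset is a rising crossing of the onset-flow
    threshold sustained for :data:`ONSET_SUSTAIN_MS`; between two onsets
    the flow must show expiratory evidence (a crossing below
    :data:`EXP_FLOW_LPM`), which rejects within-insufflation flow
    oscillations while keeping stacked insufflations as separate
    breaths.  The final partial cycle is closed at the recording end.
    """
    if record.duration_s < 2.0:
        raise DataError("recording shorter than 2 s")
    rec = smooth(record)
    flow = rec.flow
    rate = rec.sampling_rate_hz
    n = len(flow)
    sustain = max(1, int(round(ONSET_SUSTAIN_MS / 1000.0 * rate)))

    above = flow > ONSET_FLOW_LPM
    quiet_n = max(1, int(round(0.10 * rate)))  # 100 ms of near-zero flow
    onsets: list[int] = []
    i = 0
    armed = True  # first onset needs no prior expiration
    quiet_run = 0
    while i < n:
        rising = above[i] and (i == 0 or not above[i - 1])
        if rising and armed:
            j = min(n, i + sustain)
            if j - i >= sustain and np.all(above[i:j]):
                onsets.append(i)
                armed = False
                quiet_run = 0
                i += sustain
                continue
        if not armed:
            # re-arm on expiratory flow, or on sustained near-zero flow
            # (closed demand valve during an effort, or an end-insp pause)
            if flow[i] < EXP_FLOW_LPM:
                armed = True
            else:
                quiet_run = quiet_run + 1 if abs(flow[i]) < 1.0 else 0
                if quiet_run >= quiet_n:
                    armed = True
        i += 1

    breaths: list[Breath] = []
    min_insp = int(round(MIN_INSP_S * rate))
    for k, start in enumerate(onsets):
        end = onsets[k + 1] if k + 1 < len(onsets) else n
        seg = flow[start + min_insp : end]
        below = np.nonzero(seg < EXP_FLOW_LPM)[0]
        insp_end = start + min_insp + int(below[0]) if below.size else end
        breaths.append(Breath(index=k, start=start, insp_end=insp_end, end=end))
    return breaths


def breath_mechanics(breath: Breath, record: WaveformRecord) -> Breath:
    """Fill ppeak, pplat, pef and volumes in place (returns the breath).

    Plateau pressure is the mean Paw over the last zero-flow pause
    (|flow| < 2 L/min for >= 100 ms) within the insufflation and is
    absent when no such pause exists (pressure modes without pause).
    Volume is re-zeroed at the insufflation onset, so stacking tests use
    within-cycle volume only.
    """
    paw, flow = record.paw, record.flow
    rate = record.sampling_rate_hz
    s, ie, e = breath.start, breath.insp_end, breath.end
    breath.ppeak = float(np.max(paw[s:ie])) if ie > s else float(paw[s])

    breath.pplat = None
    if ie - s > 2:
        quiet = np.abs(flow[s:ie]) < PAUSE_FLOW_LPM
        min_len = max(1, int(round(PAUSE_MIN_MS / 1000.0 * rate)))
        run_start, best = None, None
        for j in range(len(quiet) + 1):
            if j < len(quiet) and quiet[j]:
                if run_start is None:
                    run_start = j
            else:
                if run_start is not None and j - run_start >= min_len:
                    best = (run_start, j)
                run_start = None
        # skip the onset ramp: a pause beginning at the very first samples
        # of the insufflation is not an end-inspiratory pause
        if best is not None and best[0] > min_len:
            breath.pplat = float(np.mean(paw[s + best[0] : s + best[1]]))

    breath.pef = float(max(0.0, np.max(-flow[ie:e]))) if e > ie else 0.0

    vol = integrate_volume(record, s, e)
    rel_ie = min(ie - s, len(vol) - 1)
    breath.v_insp = float(vol[rel_ie])
    breath.v_exp_at_next = float(breath.v_insp - vol[-1])
    return breath


def classify_trigger(
    breath: Breath,
    record: WaveformRecord,
    prev_breath: Breath | None,
    mode: str = "VCV",
    efforts: Sequence | None = None,
    peep_cmh2o: float | None = None,
) -> str:
    """Classify the breath's trigger as machine, patient or auto.

    With Pes available, a patient trigger requires a qualifying
    inspiratory effort (Pes drop > 2 cmH2O below baseline, or
    EAdi > 0.5 uV above baseline together with a Paw drop > 0.3 cmH2O)
    that begins before the insufflation onset and is still present in
    the pre-trigger window.  ``efforts`` may carry pre-detected Pes
    effort events (objects with ``onset_s``/``peak_s``/``offset_s``);
    they take precedence over the local-window heuristic.  Without Pes,
    a pre-onset Paw dip > 0.3 cmH2O below the local expiratory baseline
    — or below the recording-wide end-expiratory pressure
    ``peep_cmh2o`` when supplied, which stays valid when a strong
    ongoing effort depresses the local baseline itself (stacking) — is
    the criterion.  In PSV, a breath with no patient evidence is
    auto-triggered; in the controlled modes it is machine-triggered.
    """
    rate = record.sampling_rate_hz
    t_start = breath.start / rate
    pre = int(round(PRE_TRIGGER_WINDOW_S * rate))

    is_patient = False
    if efforts is not None:
        for ev in efforts:
            offset = getattr(ev, "offset_s", ev.peak_s)
            if ev.onset_s < t_start and offset >= t_start - PRE_TRIGGER_WINDOW_S:
                is_patient = True
                break
    elif record.pes is not None:
        lo = max(0, breath.start - pre)
        base_lo = max(0, breath.start - int(1.2 * rate))
        base_hi = max(base_lo + 1, breath.start - int(0.6 * rate))
        baseline = float(np.median(record.pes[base_lo:base_hi]))
        drop = baseline - float(np.min(record.pes[lo : breath.start + 1]))
        is_patient = drop > PES_TRIGGER_DROP
        if not is_patient and record.eadi is not None:
            eadi_base = float(np.median(record.eadi[base_lo:base_hi]))
            eadi_exc = float(np.max(record.eadi[lo : breath.start + 1])) - eadi_base
            paw_dip = _paw_predip(breath, record, prev_breath)
            is_patient = eadi_exc > EADI_TRIGGER_UV and paw_dip > PAW_TRIGGER_DIP
    else:
        is_patient = _paw_predip(breath, record, prev_breath) > PAW_TRIGGER_DIP
        if not is_patient and peep_cmh2o is not None:
            is_patient = (peep_cmh2o - _paw_premin(breath, record)) > PAW_TRIGGER_DIP

    if is_patient:
        return "patient"
    return "auto" if mode == "PSV" else "machine"


def _paw_premin(breath: Breath, record: WaveformRecord) -> float:
    """Minimum 50 ms-averaged Paw in the final 150 ms before onset."""
    rate = record.sampling_rate_hz
    s = breath.start
    w_lo = max(0, s - int(0.15 * rate))
    w_hi = min(len(record.paw), s + int(0.03 * rate))
    seg = record.paw[w_lo:w_hi]
    if len(seg) < 2:
        return float("inf")
    k = max(1, int(round(0.05 * rate)))
    kernel = np.ones(k) / k
    return float(np.min(np.convolve(seg, kernel, mode="valid")))


def estimate_peep(breaths: list[Breath], record: WaveformRecord) -> float | None:
    """Recording-wide end-expiratory airway pressure: the median of the
    per-breath pre-onset Paw medians (robust to efforts and stacking)."""
    rate = record.sampling_rate_hz
    vals = []
    for b in breaths:
        hi = max(0, b.start - int(0.05 * rate))
        lo = max(0, b.start - int(0.25 * rate))
        if hi - lo >= 3:
            vals.append(float(np.median(record.paw[lo:hi])))
    return float(np.median(vals)) if len(vals) >= 3 else None


def _paw_predip(breath: Breath, record: WaveformRecord, prev_breath: Breath | None) -> float:
    """Paw dip below the local expiratory baseline just before onset.

    Baseline: median Paw over the last 500 ms of the preceding
    expiration excluding the final 100 ms (robust to oscillations); dip
    measured on a 50 ms-averaged Paw in the final 150 ms before onset.
    """
    rate = record.sampling_rate_hz
    s = breath.start
    b_hi = max(0, s - int(0.10 * rate))
    b_lo = max(0, s - int(0.60 * rate))
    if prev_breath is not None:
        b_lo = max(b_lo, prev_breath.insp_end)
    if b_hi - b_lo < 3:
        return 0.0
    baseline = float(np.median(record.paw[b_lo:b_hi]))
    w_lo = max(0, s - int(0.15 * rate))
    w_hi = min(len(record.paw), s + int(0.03 * rate))
    if w_hi - w_lo < 2:
        return 0.0
    seg = record.paw[w_lo:w_hi]
    k = max(1, int(round(0.05 * rate)))
    kernel = np.ones(k) / k
    seg_mean = np.convolve(seg, kernel, mode="valid")
    return baseline - float(np.min(seg_mean))


def detect_stacking(breaths: list[Breath], record: WaveformRecord) -> list[Breath]:
    """Flag breaths that began before their predecessor finished exhaling.

    ``stacked`` is true when, at this breath's onset, the preceding
    breath had returned less than :data:`COMPLETENESS_FRAC` of its
    inspired volume.  The first breath is never stacked.
    """
    for k, b in enumerate(breaths):
        if k == 0:
            b.stacked = False
            continue
        prev = breaths[k - 1]
        if prev.v_insp is None or prev.v_exp_at_next is None:
            prev = breath_mechanics(prev, record)
        b.stacked = bool(
            prev.v_insp > 0 and prev.v_exp_at_next < COMPLETENESS_FRAC * prev.v_insp
        )
    return breaths


def segment(
    record: WaveformRecord,
    mode: str = "VCV",
    efforts: Sequence | None = None,
) -> list[Breath]:
    """Full segmentation pipeline: smooth, detect breaths, compute
    mechanics, classify triggers and flag stacking."""
    rec = smooth(record)
    breaths = detect_breaths(record)
    for b in breaths:
        breath_mechanics(b, rec)
    peep_est = None if rec.pes is not None or efforts is not None else estimate_peep(breaths, rec)
    prev = None
    for b in breaths:
        b.trigger = classify_trigger(
            b, rec, prev, mode=mode, efforts=efforts, peep_cmh2o=peep_est
        )
        prev = b
    detect_stacking(breaths, rec)
    return breaths
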