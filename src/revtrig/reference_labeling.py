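"""Gold-standard breath labeling from esophageal pressure.

Inspiratory efforts appear as negative Pes deflections below the
end-expiratory baseline.  Event timing then classifies each breath:

* reverse triggering (RT): on a machine- (or auto-) triggered breath, an
  effort whose onset falls strictly more than 0.1 s after the
  insufflation onset and whose maximal deflection peaks strictly less
  than 1.5 s after it;
* ineffective effort during expiration (IEE): a non-triggering effort
  peaking strictly more than 1.5 s after the machine insufflation onset,
  or a late non-triggering effort within a patient-triggered breath;
* patient trigger: a qualifying effort beginning before the insufflation.

Efforts with onset in (0, 0.1] s after the insufflation onset are
indeterminate (neither RT nor patient trigger under the strict
definitions) and leave the breath unlabeled.

Because Pes of a passive insufflation *rises* by V/Ccw, the detector
regresses Pes on within-breath volume over effort-free samples and
subtracts this chest-wall component before measuring deflections, so
event amplitudes approximate the true muscular pressure rather than the
volume-attenuated raw Pes swing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CapabilityError, DataError
from .segmentation import (
    Breath,
    PAUSE_FLOW_LPM,
    classify_trigger,
    detect_breaths,
    detect_stacking,
    breath_mechanics,
)
from .waveform_io import WaveformRecord, integrate_volume, smooth

#: minimum deflection amplitude qualifying as an effort (cmH2O)
MIN_EFFORT_CMH2O = 1.0
#: minimum time the deflection must stay above 60% of its peak (s);
#: rejects cardiac oscillations, which are narrower at any amplitude
MIN_EFFORT_DUR_S = 0.25
#: minimum full width at 30% of peak (s); a cardiac lobe is bounded by
#: the cardiac half-period (~0.35-0.45 s at 70-90/min) at every level,
#: while real efforts (>= ~0.5 s) are wider
MIN_EFFORT_WIDTH_S = 0.40
#: candidate region threshold on the deflection signal (cmH2O)
REGION_THRESHOLD = 0.5
#: rolling window of the end-expiratory Pes baseline (s)
BASELINE_WINDOW_S = 10.0
#: RT timing rules (s after machine insufflation onset; strict inequalities)
RT_ONSET_MIN_S = 0.1
RT_PEAK_MAX_S = 1.5


@dataclass
class EffortEvent:
    """One detected respiratory-muscle contraction."""

    onset_s: float
    peak_s: float
    amp: float
    breath_index: int
    offset_s: float = float("nan")

    def __post_init__(self) -> None:
        if not self.onset_s < self.peak_s:
            raise DataError("effort onset must precede its peak")
        if not self.amp > 0:
            raise DataError("effort amplitude must be positive")


@dataclass
class BreathLabel:
    """Event label of one breath from one source (reference/automatic)."""

    breath_index: int
    label: str  # none | RT | IEE | patient_trigger
    rt_subtype: str | None = None  # insp | pause | exp1 | exp | BS
    source: str = "reference"
    trigger: str = "machine"
    start_s: float = float("nan")

    def __post_init__(self) -> None:
        if (self.label == "RT") != (self.rt_subtype is not None):
            raise DataError("rt_subtype present iff label == RT")


def _rolling_quantile(x: np.ndarray, win: int, q: float = 0.5, step: int = 25) -> np.ndarray:
    """Centered rolling quantile evaluated on a decimated grid and
    linearly interpolated (the baseline varies on the multi-second
    scale, far slower than the decimation step)."""
    n = len(x)
    half = win // 2
    idx = np.arange(0, n, step)
    vals = np.array([np.quantile(x[max(0, i - half) : min(n, i + half + 1)], q) for i in idx])
    return np.interp(np.arange(n), idx, vals)


def detect_pes_efforts(
    record: WaveformRecord,
    breaths: list[Breath],
    min_effort_cmh2o: float = MIN_EFFORT_CMH2O,
) -> list[EffortEvent]:
    """Detect inspiratory efforts as negative Pes deflections.

    The deflection is measured against a rolling-median end-expiratory
    baseline plus the chest-wall recoil component V(t)/Ccw, with 1/Ccw
    estimated by least squares of Pes on within-breath volume over
    effort-free samples.  Events must exceed ``min_effort_cmh2o`` and
    stay above 60% of their peak for at least
    :data:`MIN_EFFORT_DUR_S` (cardiac rejection).  Each event is
    assigned to the breath containing its onset.
    """
    if record.pes is None:
        raise CapabilityError(
            "no esophageal pressure channel: use the Paw/flow-only detector instead"
        )
    rec = smooth(record)
    pes = rec.pes
    rate = rec.sampling_rate_hz
    n = len(pes)

    # continuous volume above the running end-expiratory level: unlike
    # per-breath re-zeroing this keeps the retained volume of stacked
    # breaths, which the chest-wall correction must see; the rolling
    # minimum removes integration drift
    vol = integrate_volume(rec, 0, n)
    vol = vol - _rolling_quantile(vol, int(15.0 * rate) | 1, q=0.0)

    win = max(3, int(round(BASELINE_WINDOW_S * rate)) | 1)
    pad = int(round(0.3 * rate))

    def fit_slope(free: np.ndarray) -> float | None:
        # refuse degenerate fits (too few samples or no volume spread)
        if free.sum() < max(5 * rate, 0.05 * n) or np.ptp(vol[free]) < 50:
            return None
        v, p = vol[free], pes[free]
        vc = v - v.mean()
        denom = float(vc @ vc)
        if denom <= 0:
            return None
        return max(0.0, float(vc @ (p - p.mean())) / denom)

    # iterate: remove the chest-wall component slope*V from Pes, estimate
    # the end-expiratory baseline as an upper rolling quantile (efforts
    # only deflect downward), mask candidate efforts, refit the slope on
    # effort-free samples
    slope = fit_slope(np.ones(n, dtype=bool)) or 0.0
    defl = np.zeros(n)
    for _ in range(3):
        pes_corr = pes - slope * vol
        base = _rolling_quantile(pes_corr, win)
        defl = base - pes_corr
        mask = defl > REGION_THRESHOLD
        if mask.any():
            idx = np.flatnonzero(mask)
            grow = np.zeros(n, dtype=bool)
            for i in idx:
                grow[max(0, i - pad) : min(n, i + pad)] = True
            mask = grow
        refit = fit_slope(~mask)
        if refit is None:  # keep the current slope rather than degrade
            break
        slope = refit

    # contiguous candidate regions, merged across sub-0.2 s gaps
    above = defl > REGION_THRESHOLD
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(n)
    regions: list[list[int]] = []
    gap = int(round(0.1 * rate))
    for s, e in zip(starts, ends):
        if regions and s - regions[-1][1] < gap:
            regions[-1][1] = e
        else:
            regions.append([s, e])

    min_dur = int(round(MIN_EFFORT_DUR_S * rate))
    events: list[EffortEvent] = []
    breath_starts = np.array([b.start for b in breaths]) if breaths else np.array([])
    for s, e in regions:
        seg = defl[s:e]
        amp = float(np.max(seg))
        if amp < min_effort_cmh2o:
            continue
        # the deflection must hold 60% of its peak for a contiguous
        # stretch: cardiac oscillations are narrow at any amplitude
        strong = seg > 0.6 * amp
        run = best_run = 0
        for v in strong:
            run = run + 1 if v else 0
            best_run = max(best_run, run)
        if best_run < min_dur:
            continue
        peak_local = int(np.argmax(seg))
        lo = peak_local
        while lo > 0 and seg[lo - 1] > 0.3 * amp:
            lo -= 1
        hi = peak_local
        while hi < len(seg) - 1 and seg[hi + 1] > 0.3 * amp:
            hi += 1
        if (hi - lo) / rate < MIN_EFFORT_WIDTH_S:
            continue
        peak_i = s + int(np.argmax(seg))
        floor = max(0.1 * amp, 0.15)
        i = s
        while i > 0 and defl[i - 1] > floor:
            i -= 1
        j = e
        while j < n and defl[j] > floor:
            j += 1
        onset_i = min(i, peak_i - 1)  # strict onset < peak even for edge regions
        if breath_starts.size:
            k = int(np.searchsorted(breath_starts, onset_i, side="right") - 1)
            k = max(k, 0)
        else:
            k = 0
        events.append(
            EffortEvent(
                onset_s=onset_i / rate,
                peak_s=peak_i / rate,
                amp=amp,
                breath_index=k,
                offset_s=j / rate,
            )
        )
    return events


def _pause_start_s(breath: Breath, record: WaveformRecord) -> float:
    """Time of the end-inspiratory pause start (insufflation end if none)."""
    rate = record.sampling_rate_hz
    s, ie = breath.start, breath.insp_end
    lead = int(round(0.15 * rate))
    quiet = np.abs(record.flow[s + lead : ie]) < PAUSE_FLOW_LPM
    min_len = int(round(0.1 * rate))
    run = 0
    for j, q in enumerate(quiet):
        run = run + 1 if q else 0
        if run >= min_len:
            return (s + lead + j - run + 1) / rate
    return ie / rate


def label_reference(
    efforts: list[EffortEvent],
    breaths: list[Breath],
    record: WaveformRecord,
) -> list[BreathLabel]:
    """Apply the timing rules to produce one reference label per breath.

    Requires trigger types on the breaths.  Among multiple non-triggering
    efforts in one cycle the first classifiable one sets the label; an RT
    breath whose successor is stacked carries subtype BS.
    """
    rate = record.sampling_rate_hz
    labels: list[BreathLabel] = []
    for k, b in enumerate(breaths):
        start_t = b.start / rate
        end_t = b.end / rate
        nxt = breaths[k + 1] if k + 1 < len(breaths) else None
        nxt_start_t = nxt.start / rate if nxt else float("inf")
        own = sorted(
            (ev for ev in efforts if start_t < ev.onset_s < end_t),
            key=lambda ev: ev.onset_s,
        )

        def triggered_next(ev: EffortEvent) -> bool:
            off = ev.offset_s if np.isfinite(ev.offset_s) else ev.peak_s
            return (
                nxt is not None
                and nxt.trigger == "patient"
                and ev.onset_s < nxt_start_t <= off
            )

        label, subtype = "none", None
        if b.trigger == "patient":
            label = "patient_trigger"
            for ev in own:
                if ev.peak_s > start_t + RT_PEAK_MAX_S and not triggered_next(ev):
                    label, subtype = "IEE", None
                    break
        else:
            for ev in own:
                rel_on = ev.onset_s - start_t
                rel_pk = ev.peak_s - start_t
                if rel_on > RT_ONSET_MIN_S and rel_pk < RT_PEAK_MAX_S:
                    label = "RT"
                    subtype = _rt_subtype(b, nxt, ev, record)
                    break
                if rel_pk > RT_PEAK_MAX_S and not triggered_next(ev):
                    label = "IEE"
                    break
                # onset in (0, 0.1] s: indeterminate, look no further
                break
        labels.append(
            BreathLabel(
                breath_index=k,
                label=label,
                rt_subtype=subtype,
                source="reference",
                trigger=b.trigger,
                start_s=start_t,
            )
        )
    return labels


def _rt_subtype(
    breath: Breath, nxt: Breath | None, ev: EffortEvent, record: WaveformRecord
) -> str:
    if nxt is not None and nxt.stacked:
        return "BS"
    rate = record.sampling_rate_hz
    pause_t = _pause_start_s(breath, record)
    exp_t = breath.insp_end / rate
    if ev.peak_s < pause_t:
        return "insp"
    if ev.peak_s < exp_t:
        return "pause"
    if ev.peak_s < exp_t + 0.2:
        return "exp1"
    return "exp"


def rt_rate(labels: list[BreathLabel]) -> float:
    """Rate of RT: (number of RT breaths) / (number of breaths), in [0, 1]."""
    if not labels:
        raise DataError("rt_rate undefined for zero breaths")
    n_rt = sum(1 for lab in labels if lab.label == "RT")
    return n_rt / len(labels)


def label_recording(record: WaveformRecord, mode: str) -> tuple[list[Breath], list[EffortEvent], list[BreathLabel]]:
    """Full reference pipeline: segment, detect Pes efforts, classify
    triggers using the detected efforts, flag stacking, label."""
    rec = smooth(record)
    breaths = detect_breaths(record)
    for b in breaths:
        breath_mechanics(b, rec)
    efforts = detect_pes_efforts(record, breaths)
    prev = None
    for b in breaths:
        b.trigger = classify_trigger(b, rec, prev, mode=mode, efforts=efforts)
        prev = b
    detect_stacking(breaths, rec)
    labels = label_reference(efforts, breaths, rec)
    return breaths, efforts, labels
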