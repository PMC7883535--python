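"""Muscular-pressure (Pmus) quantification from esophageal pressure.

During a purely passive breath the esophageal pressure follows the
chest-wall relaxation curve

    Pcw(t) = Pes_ee + V(t) / Ccw

where Pes_ee is the end-expiratory Pes baseline and Ccw the chest-wall
compliance.  Any inspiratory muscle activity pulls Pes below this curve,
so the muscular pressure of a breath is

    Pmus(t) = Pcw(t) - Pes(t),      pmus_peak = max Pmus over the cycle,

with the search window extended into early expiration, where reverse
triggering efforts often peak.  Ccw itself is measured on passive breaths
of the same recording as the median ratio of inspired volume to the
passive Pes swing.

An artifact screen invalidates (never raises on) breaths whose Pes shows
non-physiological behavior: an instantaneous step (single-sample jump
beyond what any muscular swing produces) or an unexplained end-to-end
baseline shift above 5 cmH2O.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .segmentation import Breath
from .waveform_io import WaveformRecord, integrate_volume, smooth

#: artifact screen: a single-sample Pes jump above this (cmH2O) is a
#: non-physiological step — the fastest muscular swings in these data
#: stay below ~1.5 cmH2O per 10 ms sample, a sensor step is instantaneous
ARTIFACT_JUMP_CMH2O = 3.0
#: artifact screen: end-to-end baseline shift above this (cmH2O)
ARTIFACT_BASELINE_SHIFT = 5.0
#: Pmus search window margin beyond the 1.5 s RT bound (s)
PMUS_WINDOW_MARGIN_S = 0.5
#: end-expiratory baseline window before breath onset (s)
BASELINE_PRE_S = 0.30
BASELINE_GAP_S = 0.05


@dataclass
class PmusResult:
    """Peak muscular pressure of one breath."""

    breath_index: int
    pmus_peak: float
    event_class: str = "none"
    valid: bool = True
    reason: str = ""


def _pes_baseline(pes: np.ndarray, start: int, rate: float) -> float:
    hi = max(0, start - int(BASELINE_GAP_S * rate))
    lo = max(0, start - int((BASELINE_PRE_S + BASELINE_GAP_S) * rate))
    if hi - lo < 3:
        hi = min(len(pes), start + int(0.05 * rate) + 3)
        lo = start
    return float(np.median(pes[lo:hi]))


def estimate_ccw(record: WaveformRecord, passive_breaths: list[Breath]) -> float:
    """Chest-wall compliance (mL/cmH2O) from passive breaths.

    For each passive (machine-triggered, effort-free) breath the ratio
    dV/dPes between end-expiration and end-insufflation estimates Ccw;
    the median over breaths is returned.  At least 3 passive breaths are
    required — otherwise a :class:`~revtrig.errors.DataError` instructs
    the caller to supply Ccw from an independent measurement.
    """
    if record.pes is None:
        raise DataError("Ccw estimation requires the Pes channel")
    if len(passive_breaths) < 3:
        raise DataError(
            "fewer than 3 passive breaths available: supply chest-wall "
            "compliance manually"
        )
    rec = smooth(record)
    pes = rec.pes
    rate = rec.sampling_rate_hz
    ratios = []
    for b in passive_breaths:
        # integrate the raw flow from slightly before the detected onset:
        # median smoothing shifts the sharp insufflation edge and onset
        # detection lags the true start by a sample or two, each worth
        # ~1% of VT; pre-onset flow is ~0 so the pad is harmless
        pad = min(3, b.start)
        vol = integrate_volume(record, b.start - pad, b.end)
        rel_ie = min(b.insp_end - b.start + pad, len(vol) - 1)
        dv = float(vol[rel_ie])
        if dv <= 0:
            continue
        # average Pes over the final 250 ms of insufflation (pause when
        # present): cardiac oscillations average toward zero
        w = int(0.25 * rate)
        ie = b.start + rel_ie
        pes_ei = float(np.mean(pes[max(b.start, ie - w) : ie]))
        pes_ee = _pes_baseline(pes, b.start, rate)
        dp = pes_ei - pes_ee
        if dp > 0.1:
            ratios.append(dv / dp)
    if len(ratios) < 3:
        raise DataError("passive Pes swings too small or noisy to estimate Ccw")
    return float(np.median(ratios))


def compute_pmus(
    record: WaveformRecord, breath: Breath, ccw: float, event_class: str = "none"
) -> PmusResult:
    """Peak Pmus of one breath against the chest-wall relaxation curve."""
    if record.pes is None:
        raise DataError("Pmus computation requires the Pes channel")
    if ccw <= 0:
        raise DataError("ccw must be positive")
    rec = smooth(record)
    pes = rec.pes
    rate = rec.sampling_rate_hz
    s, e = breath.start, breath.end

    vol = integrate_volume(record, s, e)
    pes_ee = _pes_baseline(pes, s, rate)
    pcw = pes_ee + vol / ccw
    pmus_t = pcw - pes[s:e]

    w_end = min(e - s, int((1.5 + PMUS_WINDOW_MARGIN_S) * rate))
    # short boxcar before the max: the peak of a noisy trace is biased up
    k = max(1, int(0.12 * rate))
    pmus_s = np.convolve(pmus_t, np.ones(k) / k, mode="same")
    peak = float(np.max(pmus_s[:w_end])) if w_end > 0 else 0.0
    peak = max(0.0, peak)  # inspiratory effort magnitude; raw trace may go negative

    valid, reason = _artifact_screen(pes[s:e], pmus_t, rate)
    return PmusResult(
        breath_index=breath.index,
        pmus_peak=peak,
        event_class=event_class,
        valid=valid,
        reason=reason,
    )


def _artifact_screen(pes_seg: np.ndarray, pmus_t: np.ndarray, rate: float) -> tuple[bool, str]:
    jumps = np.abs(np.diff(pes_seg))
    if np.any(jumps > ARTIFACT_JUMP_CMH2O):
        return False, f"Pes step > {ARTIFACT_JUMP_CMH2O:g} cmH2O within one sample"
    # baseline shift is only assessable when the breath ends effort-free
    tail = int(0.3 * rate)
    if len(pmus_t) > 2 * tail and float(np.median(np.abs(pmus_t[-tail:]))) < 1.0:
        shift = abs(float(np.median(pes_seg[-tail:])) - float(np.median(pes_seg[:tail])))
        # the chest-wall component across one cycle is bounded by VT/Ccw;
        # a larger end-to-end shift indicates sensor drift
        if shift > ARTIFACT_BASELINE_SHIFT:
            return False, f"baseline shift {shift:.1f} cmH2O across breath"
    return True, ""


def summarize_efforts(
    results: list[PmusResult], labels: list, duration_min: float
) -> pd.DataFrame:
    """Per-class effort burden table.

    Classes: RT with breath stacking (``RT_BS``), RT without
    (``RT_noBS``), patient-triggered and IEE.  Columns: n, median, IQR
    bounds, range, within-class coefficient of variation, events/min and
    the median-Pmus x rate product (cmH2O/min).
    """
    valid = {r.breath_index: r for r in results if r.valid}
    if not valid:
        raise DataError("no valid Pmus results to summarize")
    if duration_min <= 0:
        raise DataError("duration_min must be positive")

    def cls_of(lab) -> str | None:
        if lab.label == "RT":
            return "RT_BS" if lab.rt_subtype == "BS" else "RT_noBS"
        if lab.label == "patient_trigger":
            return "patient_trigger"
        if lab.label == "IEE":
            return "IEE"
        return None

    rows = []
    for lab in labels:
        r = valid.get(lab.breath_index)
        c = cls_of(lab)
        if r is not None and c is not None:
            rows.append({"event_class": c, "pmus": r.pmus_peak})
    if not rows:
        raise DataError("no labeled valid efforts to summarize")
    df = pd.DataFrame(rows)

    out = []
    for c, grp in df.groupby("event_class"):
        x = grp["pmus"].to_numpy()
        med = float(np.median(x))
        n = len(x)
        cv = float(np.std(x, ddof=1) / np.mean(x)) if n > 1 and np.mean(x) > 0 else np.nan
        rate_per_min = n / duration_min
        out.append(
            {
                "event_class": c,
                "n": n,
                "median": med,
                "q25": float(np.percentile(x, 25)),
                "q75": float(np.percentile(x, 75)),
                "min": float(np.min(x)),
                "max": float(np.max(x)),
                "cv": cv,
                "events_per_min": rate_per_min,
                "median_x_rate": med * rate_per_min,
            }
        )
    return pd.DataFrame(out).set_index("event_class")
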