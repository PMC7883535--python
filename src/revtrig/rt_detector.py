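"""Automated reverse-triggering detection from airway pressure and flow.

The detector realizes the two-waveform strategy: a reverse-triggering
effort deforms the airway signals differently depending on the
ventilation mode and on where in the cycle the effort falls.

* During constant-flow (VCV) insufflation the effort shows mainly on
  Paw: the peak pressure drops relative to the running average of the
  most recent undeformed breaths (dPpeak), the plateau drops (dPplat),
  and their difference (dPpp) separates resistive from muscular change.
* During pressure-controlled insufflation (PCV/PSV) the effort shows on
  flow: excess inspiratory flow above the breath's own exponential
  decay envelope (insp_flow_deform).
* In expiration (any mode) the effort bends the expiratory flow away
  from its fitted monotone decay envelope (exp_deform) and reduces the
  peak expiratory flow relative to the running average (dPEF).

A logistic regression on the standardized features yields an RT
probability; the classification cutoff is the Youden-optimal point of
the training ROC.  Machine-triggered breaths in VCV/PCV and
auto-triggered breaths in PSV are evaluated; a patient-triggered breath
is never labeled RT.  A minimum-deformation gate (floors calibrated to
the passive noise level of the signals) suppresses false positives,
which matters more than catching the weakest efforts: very weak efforts
(a few cmH2O) may not deform Paw or flow visibly at all and are then
undetectable from airway signals alone, by design.

The packaged default model is trained on the seeded synthetic training
suite; ``fit_model`` retrains on any labeled data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve

from .errors import CapabilityError, ConfigError, DataError
from .reference_labeling import BreathLabel, RT_PEAK_MAX_S
from .segmentation import Breath, PAUSE_FLOW_LPM
from .waveform_io import WaveformRecord, smooth

#: number of recent undeformed breaths in the running averages
HISTORY_N = 4
#: deformation gate floors (passive-noise scale of each feature)
GATE_D_PPEAK = 0.3    # cmH2O
GATE_D_PEF = 2.0      # L/min
GATE_DEFORM = 0.06    # dimensionless envelope residual
GATE_PAW_DIP = 0.5    # cmH2O below the within-insufflation running max
#: expiratory window searched for deformation (s after expiration onset)
EXP_SEARCH_S = 1.5
#: exp1 subtype window at the very onset of exhalation (s)
EXP1_WINDOW_S = 0.2

SUPPORTED_MODES = ("VCV", "PCV", "PSV")

#: ordered model features
FEATURE_LIST = [
    "d_ppeak",
    "d_pplat",
    "has_pplat",
    "d_ppp",
    "d_pef",
    "d_vt",
    "paw_insp_deform",
    "exp_deform",
    "insp_flow_deform",
    "is_pcv",
    "is_psv",
]


@dataclass
class FeatureVector:
    """Per-breath detector features (see module docstring)."""

    breath_index: int
    mode: str
    d_ppeak: float = 0.0
    d_pplat: float | None = None
    d_ppp: float | None = None
    d_pef: float = 0.0
    d_vt: float = 0.0
    paw_insp_deform: float = 0.0
    exp_deform: float = 0.0
    insp_flow_deform: float = 0.0
    deform_time_s: float = float("nan")
    deform_window: str | None = None  # insp | pause | exp1 | exp
    low_confidence: bool = False

    def as_row(self) -> list[float]:
        return [
            self.d_ppeak,
            self.d_pplat if self.d_pplat is not None else 0.0,
            1.0 if self.d_pplat is not None else 0.0,
            self.d_ppp if self.d_ppp is not None else 0.0,
            self.d_pef,
            self.d_vt,
            self.paw_insp_deform,
            self.exp_deform,
            self.insp_flow_deform,
            1.0 if self.mode == "PCV" else 0.0,
            1.0 if self.mode == "PSV" else 0.0,
        ]


@dataclass
class DetectionModel:
    """Serializable logistic detection model."""

    feature_list: list[str]
    coefficients: list[float]
    intercept: float
    scaler_mean: list[float]
    scaler_scale: list[float]
    cutoff: float
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff < 1.0:
            raise ConfigError("cutoff must lie strictly in (0, 1)")
        if len(self.coefficients) != len(self.feature_list):
            raise ConfigError("coefficient count must match feature_list")

    def probability(self, fv: FeatureVector) -> float:
        x = np.asarray(fv.as_row())
        z = (x - np.asarray(self.scaler_mean)) / np.asarray(self.scaler_scale)
        t = float(np.dot(z, self.coefficients) + self.intercept)
        return 1.0 / (1.0 + np.exp(-t))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "feature_list": self.feature_list,
                    "coefficients": self.coefficients,
                    "intercept": self.intercept,
                    "scaler_mean": self.scaler_mean,
                    "scaler_scale": self.scaler_scale,
                    "cutoff": self.cutoff,
                    "training_meta": self.training_meta,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "DetectionModel":
        path = Path(path)
        if not path.exists():
            raise DataError(f"model file not found: {path}")
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(f"invalid model file {path.name}: {exc}") from exc


# -- envelope fits -----------------------------------------------------------


def _exp_envelope(t: np.ndarray, y: np.ndarray, fit_mask: np.ndarray) -> np.ndarray | None:
    """Least-squares exponential decay A*exp(-t/tau) through the masked
    samples of a positive signal; None when the fit is unusable."""
    yy = y[fit_mask]
    tt = t[fit_mask]
    good = yy > 1e-3
    if good.sum() < 4:
        return None
    coef = np.polyfit(tt[good], np.log(yy[good]), 1)
    if coef[0] >= 0:  # not a decay
        return None
    return np.exp(np.polyval(coef, t))


def _monotone_dip(x: np.ndarray) -> tuple[float, int]:
    """Largest drop of ``x`` below its running maximum, with its index."""
    if len(x) == 0:
        return 0.0, 0
    d = np.maximum.accumulate(x) - x
    j = int(np.argmax(d))
    return float(d[j]), j


def _monotone_rise(x: np.ndarray) -> tuple[float, int]:
    """Largest rise of ``x`` above its running minimum, with its index."""
    if len(x) == 0:
        return 0.0, 0
    d = x - np.minimum.accumulate(x)
    j = int(np.argmax(d))
    return float(d[j]), j


def _expiratory_deformation(
    breath: Breath, record: WaveformRecord
) -> tuple[float, float]:
    """Largest relative positive deviation of expiratory flow from its
    monotone decay envelope in the first 1.5 s of expiration, and its
    time (s from insufflation onset).

    Two complementary signatures are combined: the deficit below a
    fitted exponential decay envelope (an effort brakes or reverses the
    expiratory flow) and the rise of the flow magnitude above its
    running minimum (flow rebounding after the effort passes — a decay
    is monotone when passive)."""
    rate = record.sampling_rate_hz
    ie, e = breath.insp_end, breath.end
    if e - ie < int(0.25 * rate):
        return 0.0, float("nan")
    m = -record.flow[ie:e]  # expiratory magnitude, positive
    search = min(e - ie, int(EXP_SEARCH_S * rate))
    scale = max(float(np.max(m[:search])), 10.0)
    # the smoothed transition into expiration is not deformation
    skip = min(int(0.08 * rate), max(search - 2, 0))

    best, best_j = 0.0, skip
    # envelope deficit
    t = np.arange(e - ie) / rate
    head = int(0.15 * rate)
    tail = int(0.30 * rate)
    if e - ie >= skip + head + tail:
        fit_mask = np.zeros(e - ie, dtype=bool)
        fit_mask[skip : skip + head] = True
        fit_mask[-tail:] = True
        env = _exp_envelope(t, np.maximum(m, 1e-3), fit_mask)
        if env is not None:
            resid = (env[skip:search] - m[skip:search]) / scale
            j = int(np.argmax(resid))
            if resid[j] > best:
                best, best_j = float(resid[j]), skip + j
    # rebound above the running minimum
    rise, j = _monotone_rise(m[skip:search])
    if rise / scale > best:
        best, best_j = rise / scale, skip + j
    return best, (ie - breath.start + best_j) / rate


def _inspiratory_flow_deformation(
    breath: Breath, record: WaveformRecord
) -> tuple[float, float]:
    """PCV/PSV: relative rise of post-peak inspiratory flow above its
    running minimum (a passive decelerating-flow breath is monotone
    after the peak; an effort adds a bump), and its time from onset."""
    rate = record.sampling_rate_hz
    s, ie = breath.start, breath.insp_end
    fl = record.flow[s:ie]
    if len(fl) < int(0.35 * rate):
        return 0.0, float("nan")
    # anchor at the pressurization peak (first ~0.3 s): an effort bump
    # later in the insufflation may exceed it and must not become the
    # reference itself
    early = max(int(0.3 * rate), 2)
    pk = int(np.argmax(fl[:early]))
    post = fl[pk:]
    if len(post) < int(0.15 * rate):
        return 0.0, float("nan")
    scale = max(float(fl[pk]), 10.0)
    rise, j = _monotone_rise(post)
    return rise / scale, (pk + j) / rate


def _paw_insp_deformation(
    breath: Breath, record: WaveformRecord
) -> tuple[float, float, str]:
    """VCV: Paw drop below its running maximum within the constant-flow
    phase, and within the end-inspiratory pause, each taken separately
    (the resistive Ppeak->Pplat step at pause onset is not deformation).
    Returns (dip cmH2O, time from onset, window name)."""
    rate = record.sampling_rate_hz
    s, ie = breath.start, breath.insp_end
    pw = _pause_window(breath, record)
    flow_end = pw[0] if pw is not None else ie
    # skip the pressurization ramp at the very start
    lead = int(0.15 * rate)
    best, best_j, win = 0.0, s, "insp"
    if flow_end - (s + lead) > int(0.1 * rate):
        dip, j = _monotone_dip(record.paw[s + lead : flow_end])
        if dip > best:
            best, best_j, win = dip, s + lead + j, "insp"
    if pw is not None and pw[1] - pw[0] > int(0.08 * rate):
        skip = int(0.05 * rate)  # settle after the valve closes
        dip, j = _monotone_dip(record.paw[pw[0] + skip : pw[1]])
        if dip > best:
            best, best_j, win = dip, pw[0] + skip + j, "pause"
    return best, (best_j - s) / rate, win


def _pause_window(breath: Breath, record: WaveformRecord) -> tuple[int, int] | None:
    rate = record.sampling_rate_hz
    s, ie = breath.start, breath.insp_end
    lead = int(0.15 * rate)
    quiet = np.abs(record.flow[s + lead : ie]) < PAUSE_FLOW_LPM
    min_len = int(0.1 * rate)
    run = 0
    for j, qt in enumerate(quiet):
        run = run + 1 if qt else 0
        if run >= min_len:
            k0 = s + lead + j - run + 1
            while j + 1 < len(quiet) and quiet[j + 1]:
                j += 1
            return k0, s + lead + j + 1
    return None


# -- feature extraction ------------------------------------------------------


def extract_features(
    breath: Breath,
    history: list[Breath],
    record: WaveformRecord,
    mode: str,
) -> FeatureVector:
    """Compute the detector features of one breath.

    ``history`` holds the most recent undeformed evaluated breaths of
    the same mode (oldest first); with an empty history the
    delta-features are 0 and the vector is flagged low-confidence.
    """
    if mode not in SUPPORTED_MODES:
        raise CapabilityError(f"unsupported mode {mode!r}; supported: {SUPPORTED_MODES}")
    hist = history[-HISTORY_N:]
    fv = FeatureVector(breath_index=breath.index, mode=mode)
    fv.low_confidence = not hist

    if hist:
        fv.d_ppeak = float(breath.ppeak - np.mean([h.ppeak for h in hist]))
        pefs = [h.pef for h in hist if h.pef is not None]
        if pefs and breath.pef is not None:
            fv.d_pef = float(breath.pef - np.mean(pefs))
        vts = [h.v_insp for h in hist if h.v_insp is not None]
        if vts and breath.v_insp is not None:
            fv.d_vt = float(breath.v_insp - np.mean(vts))
        pplats = [h.pplat for h in hist if h.pplat is not None]
        if breath.pplat is not None and pplats:
            fv.d_pplat = float(breath.pplat - np.mean(pplats))
            fv.d_ppp = fv.d_ppeak - fv.d_pplat

    candidates: list[tuple[float, float, str]] = []
    rate = record.sampling_rate_hz
    exp_start = (breath.insp_end - breath.start) / rate

    exp_d, exp_t = _expiratory_deformation(breath, record)
    fv.exp_deform = exp_d
    if np.isfinite(exp_t):
        window = "exp1" if exp_t < exp_start + EXP1_WINDOW_S else "exp"
        candidates.append((exp_d, exp_t, window))

    insp_d, insp_t = _inspiratory_flow_deformation(breath, record)
    if mode in ("PCV", "PSV"):
        fv.insp_flow_deform = insp_d
        if np.isfinite(insp_t):
            candidates.append((insp_d, insp_t, "insp"))

    paw_d, paw_t, paw_win = _paw_insp_deformation(breath, record)
    if mode == "VCV":
        fv.paw_insp_deform = paw_d
        if paw_d > 0:
            # normalize the cmH2O dip to the dimensionless residual scale
            candidates.append((paw_d / 5.0, paw_t, paw_win))

    if candidates:
        best = max(candidates, key=lambda c: c[0])
        if best[0] > 0:
            fv.deform_time_s, fv.deform_window = best[1], best[2]
    return fv


# -- model fitting -----------------------------------------------------------


def fit_model(
    features: list[FeatureVector],
    labels: list[BreathLabel],
    seed: int = 0,
    training_meta: dict | None = None,
) -> DetectionModel:
    """Fit the logistic detector on standardized features.

    ``labels`` must align with ``features`` breath-for-breath; the
    positive class is ``label == "RT"``.  The probability cutoff is the
    Youden-optimal (max sensitivity + specificity - 1) point of the
    training ROC.
    """
    if len(features) != len(labels):
        raise DataError("features and labels must align")
    if len(features) < 200:
        raise DataError(f"need >= 200 labeled breaths to train, got {len(features)}")
    X = np.asarray([fv.as_row() for fv in features], dtype=float)
    y = np.asarray([lab.label == "RT" for lab in labels], dtype=int)
    if len(np.unique(y)) < 2:
        raise DataError("training set contains a single class")

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale < 1e-9] = 1.0
    Z = (X - mean) / scale

    clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000, random_state=seed)
    clf.fit(Z, y)
    prob = clf.predict_proba(Z)[:, 1]
    fpr, tpr, thr = roc_curve(y, prob)
    youden = tpr - fpr
    best = int(np.argmax(youden))
    cutoff = float(np.clip(thr[best], 1e-6, 1 - 1e-6))

    meta = {"seed": seed, "n_train": int(len(y)), "n_pos": int(y.sum())}
    if training_meta:
        meta.update(training_meta)
    return DetectionModel(
        feature_list=list(FEATURE_LIST),
        coefficients=[float(c) for c in clf.coef_[0]],
        intercept=float(clf.intercept_[0]),
        scaler_mean=[float(v) for v in mean],
        scaler_scale=[float(v) for v in scale],
        cutoff=cutoff,
        training_meta=meta,
    )


# -- detection ---------------------------------------------------------------


def _passes_gate(fv: FeatureVector) -> bool:
    """Minimum-deformation gate: at least one feature must clear its
    passive-noise floor before a breath may be called RT."""
    return (
        abs(fv.d_ppeak) >= GATE_D_PPEAK
        or abs(fv.d_pef) >= GATE_D_PEF
        or fv.exp_deform >= GATE_DEFORM
        or fv.insp_flow_deform >= GATE_DEFORM
        or fv.paw_insp_deform >= GATE_PAW_DIP
    )


def detect(
    record: WaveformRecord,
    breaths: list[Breath],
    model: DetectionModel,
    mode: str,
) -> list[BreathLabel]:
    """Label every breath automatically using airway pressure and flow.

    Machine-triggered breaths (VCV/PCV) and auto-triggered breaths (PSV)
    are evaluated; patient-triggered breaths are structurally never RT.
    The running history excludes breaths already labeled RT so that
    deformed breaths do not contaminate the baseline averages.
    """
    if mode not in SUPPORTED_MODES:
        raise CapabilityError(f"unsupported mode {mode!r}; supported: {SUPPORTED_MODES}")
    rec = smooth(record)
    labels: list[BreathLabel] = []
    history: list[Breath] = []
    eval_trigger = "auto" if mode == "PSV" else "machine"
    for k, b in enumerate(breaths):
        start_s = b.start / rec.sampling_rate_hz
        if b.trigger != eval_trigger:
            labels.append(
                BreathLabel(
                    breath_index=k, label="none", source="automatic",
                    trigger=b.trigger, start_s=start_s,
                )
            )
            continue
        fv = extract_features(b, history, rec, mode)
        prob = model.probability(fv)
        is_rt = (
            prob > model.cutoff
            and _passes_gate(fv)
            and fv.deform_window is not None
        )
        subtype = None
        if is_rt:
            nxt = breaths[k + 1] if k + 1 < len(breaths) else None
            if nxt is not None and nxt.stacked:
                subtype = "BS"
            else:
                subtype = _gate_subtype(fv, b, rec)
        labels.append(
            BreathLabel(
                breath_index=k,
                label="RT" if is_rt else "none",
                rt_subtype=subtype,
                source="automatic",
                trigger=b.trigger,
                start_s=start_s,
            )
        )
        if not is_rt:
            history.append(b)
            if len(history) > HISTORY_N:
                history.pop(0)
    return labels


def _gate_subtype(fv: FeatureVector, breath: Breath, record: WaveformRecord) -> str:
    """Subtype from the dominant deformation window, respecting the
    1.5 s bound (strict) for expiratory subtypes."""
    if fv.deform_window in ("exp", "exp1"):
        if fv.deform_time_s < RT_PEAK_MAX_S:
            return fv.deform_window
        return "exp"  # deformation beyond the bound: keep exp (peak may lag onset)
    return fv.deform_window or "insp"


def detect_recording(
    record: WaveformRecord, model: DetectionModel, mode: str
) -> tuple[list[Breath], list[BreathLabel]]:
    """Full automatic pipeline on airway pressure and flow only.

    Esophageal/EAdi channels are stripped before segmentation so the
    detector provably never uses them (trigger classification falls back
    to the Paw pre-dip criterion).
    """
    from dataclasses import replace as _replace

    from .segmentation import segment

    blind = _replace(record, pes=None, eadi=None)
    breaths = segment(blind, mode=mode)
    labels = detect(blind, breaths, model, mode)
    return breaths, labels


# -- training on the synthetic suite ----------------------------------------


def features_for_breaths(
    record: WaveformRecord,
    breaths: list[Breath],
    mode: str,
    rt_flags: list[bool],
) -> tuple[list[FeatureVector], list[int]]:
    """Features of every evaluated breath, maintaining the same
    undeformed-history policy as :func:`detect` but driven by known RT
    flags (training uses the reference labels for history exclusion)."""
    rec = smooth(record)
    eval_trigger = "auto" if mode == "PSV" else "machine"
    history: list[Breath] = []
    fvs: list[FeatureVector] = []
    idxs: list[int] = []
    for k, b in enumerate(breaths):
        if b.trigger != eval_trigger:
            continue
        fvs.append(extract_features(b, history, rec, mode))
        idxs.append(k)
        if not rt_flags[k]:
            history.append(b)
            if len(history) > HISTORY_N:
                history.pop(0)
    return fvs, idxs


def build_training_data(seed: int = 0) -> tuple[list[FeatureVector], list[BreathLabel]]:
    """Run the default training scenario suite and return aligned
    (features, reference labels) for every evaluated breath."""
    from .reference_labeling import label_recording
    from .simulator import _sub_seed, default_training_scenarios, run_scenario

    scenarios = default_training_scenarios()
    all_fvs: list[FeatureVector] = []
    all_labels: list[BreathLabel] = []
    for i, sc in enumerate(scenarios):
        rec, _gt = run_scenario(sc, _sub_seed(seed, 1000 + i))
        mode = sc["vent"]["mode"]
        breaths, _efforts, ref = label_recording(rec, mode)
        rt_flags = [lab.label == "RT" for lab in ref]
        # features are computed blind to Pes, exactly as at detection time
        from dataclasses import replace as _replace

        blind = _replace(rec, pes=None, eadi=None)
        fvs, idxs = features_for_breaths(blind, breaths, mode, rt_flags)
        all_fvs.extend(fvs)
        all_labels.extend(ref[k] for k in idxs)
    return all_fvs, all_labels


def train_default_model(seed: int = 0) -> DetectionModel:
    """Train the packaged model on the seeded synthetic training suite."""
    from .simulator import default_training_scenarios

    fvs, labels = build_training_data(seed)
    meta = {"scenario_config_hash": scenario_config_hash(default_training_scenarios())}
    return fit_model(fvs, labels, seed=seed, training_meta=meta)


# -- packaged default model --------------------------------------------------


def default_model_path() -> Path:
    return Path(str(resources.files("revtrig") / "data" / "default_model.json"))


def load_default_model() -> DetectionModel:
    """The model shipped with the package (trained on the seeded
    synthetic training suite)."""
    return DetectionModel.from_json(default_model_path())


def scenario_config_hash(scenarios: list[dict]) -> str:
    return hashlib.sha256(json.dumps(scenarios, sort_keys=True).encode()).hexdigest()[:12]
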