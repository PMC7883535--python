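# Methods

This note documents the models, detection rules, parameter defaults and
numerical choices behind `revtrig`, and what the synthetic experiments do
and do not demonstrate.

## Event definitions

A *breath* is an insufflation followed by an expiration, even if short and
incomplete; a cycle runs from one insufflation onset to the next, so breaths
tile a recording without overlap (half-open sample intervals). A second
insufflation beginning before the preceding breath has returned 90% of its
inspired volume is a separate, *stacked* breath.

With esophageal pressure (Pes) available, breath-level event classes follow
strict timing rules relative to the insufflation onset of a machine- (or
auto-) triggered breath:

| class | rule |
|---|---|
| reverse triggering (RT) | effort onset **> 0.1 s** after onset AND maximal Pes deflection **< 1.5 s** after onset |
| ineffective effort (IEE) | non-triggering effort with peak deflection **> 1.5 s** after onset; also late non-triggering efforts within patient-triggered breaths |
| patient trigger | qualifying effort (Pes drop **> 2 cmH₂O** below baseline, or EAdi **> 0.5 µV** above baseline with a Paw drop **> 0.3 cmH₂O**) beginning before the insufflation onset |

All inequalities are strict. Efforts with onset in (0, 0.1] s are
indeterminate: they are counted as breaths but assigned no event class,
since they satisfy neither the RT rule (onset too early) nor the
patient-trigger rule (onset after the insufflation). An effort peaking
exactly at 1.5 s is likewise neither RT nor IEE. An RT breath whose
successor is stacked carries the subtype `BS`; otherwise the subtype follows
the deflection-peak phase: `insp` (within the flow phase), `pause` (within
the end-inspiratory pause), `exp1` (first 200 ms of expiration), `exp`
(later, within 1.5 s of onset).

## Simulator

The respiratory system is a passive single compartment:

```
Paw = res·V̇ + V/Crs + PEEP − Pmus          (airway)
Pes = Pes_baseline + V/Ccw − Pmus + cardiac + noise   (esophageal)
```

Integration is explicit Euler on the canonical 100 Hz grid; signals are
computed from the pre-update volume, so the stored pre-noise waveforms
satisfy the equation of motion to machine precision (the test tolerance is
0.1 cmH₂O). The system time constant (res·Crs ≈ 0.5 s) is resolved by two
orders of magnitude, so no higher-order scheme is needed.

**Ventilator logic.** VCV delivers a constant flow `vt_set/ti` with an
optional end-inspiratory pause; PCV/PSV apply a first-order pressure target
with rise time `rise_time_s`; PSV cycles when inspiratory flow falls below
`psv_cycle_frac` (default 0.25) of its peak. During expiration the circuit
drains through an expiratory valve (resistance 3 cmH₂O·s/L) toward the PEEP
reservoir; when a patient effort demands inspiratory flow, the valve closes
(demand behavior) and Paw dips below PEEP by the unbalanced muscular
pressure. The pressure trigger fires when the median-smoothed sensed Paw
falls more than `trigger_paw_drop` (default 2 cmH₂O) below set PEEP, with a
200 ms refractory period after cycling. Set PEEP is used as the trigger
reference rather than a running estimate, which would lag during fast
exhalation. Breath stacking is therefore *emergent*: a second insufflation
occurs exactly when an effort is strong enough to cross the trigger
threshold against the remaining elastic recoil (`Pmus > V/Crs +
trigger_paw_drop`), never by scripting — which also reproduces the clinical
observation that stacking selects the strongest efforts.

**Efforts** are raised-cosine Pmus pulses (rise over `rise_frac·dur`,
default peak at 35% of duration). Programs: `entrained` (one effort per
`ratio` machine insufflations, onset `delay_s` after insufflation onset —
the RT pattern), `pre_trigger` (intrinsic rhythm leading the machine —
patient triggering / PSV), `late_ie` (weak efforts peaking beyond 1.5 s —
IEE), `mixed`, `none`. Amplitudes are Normal(amp, cv·amp) truncated at zero.

**Default patient**: Crs 50 mL/cmH₂O, res 10 cmH₂O·s/L, Ccw 200 mL/cmH₂O,
Pes baseline 5 cmH₂O; Gaussian channel noise SD 0.2 cmH₂O (Paw), 0.3 L/min
(flow), 0.2 cmH₂O (Pes); cardiac artifact 0.5 cmH₂O at 80/min on Pes.
These are typical passively ventilated adult ICU values; the noise and
cardiac levels are the scale at which expert visual reading remains easy, so
the reference labels can act as a gold standard.

**Validation suite**: 20 recordings of 10 min in five strata of four — no RT
(paralysis analogue), low (<4 RT/min), moderate (4–10 RT/min), high
(>10 RT/min; amplitude CV 0.35 so that a subset of efforts stacks), and PSV
(fully patient-triggered). Effort amplitudes 8–13 cmH₂O mean, delays
0.35–0.8 s — inside the 1.3–36.8 cmH₂O range of reported RT efforts.
Per-recording sub-seeds derive deterministically from the suite seed. The
training suite (separate seeds, 5-min recordings) spans passive VCV/PCV,
entrained efforts of 4–25 cmH₂O in both controlled modes, late ineffective
efforts, stacking and PSV.

**What the simulator does not emulate** — and hence what passing tests do
not show about real recordings: leaks and tube compensation, two-compartment
/ pendelluft mechanics, expiratory muscle activity, varying intrinsic
respiratory drive (entrainment is imposed, not a coupled oscillator),
ventilator-specific trigger/cycling firmware, secretions and condensate
artifacts, EAdi synthesis. Real Pes also carries peristalsis and posture
artifacts far richer than a sinusoid plus white noise.

## Segmentation (Paw + flow only)

Insufflation onset: smoothed flow (80 ms moving median) rising above
3 L/min sustained ≥ 80 ms; between onsets the flow must show either
expiratory evidence (< −3 L/min) or ≥ 100 ms of near-zero flow (closed
demand valve or pause), which keeps stacked insufflations as separate
breaths while rejecting within-insufflation flow oscillations. Insufflation
end: first flow < −3 L/min after a 150 ms minimum (the pause belongs to the
insufflation). Plateau pressure: mean Paw over the last |flow| < 2 L/min run
of ≥ 100 ms inside the insufflation; absent without a pause. PEF is the
magnitude of the most negative expiratory flow. Volume is re-zeroed at every
onset; exhaled volume at the next onset below 90% of inspired volume flags
the successor as stacked.

Without Pes, a patient trigger is a pre-onset Paw dip > 0.3 cmH₂O below
either the local expiratory baseline (median of the last 500 ms of
expiration excluding the final 100 ms) or the recording-wide end-expiratory
pressure (median of per-breath pre-onset medians). The second reference is
needed for stacked breaths, where the ongoing effort depresses the local
baseline itself.

## Reference labeling from Pes

Efforts are negative deflections of Pes measured against a baseline that
accounts for the chest wall: a passive insufflation *raises* Pes by V/Ccw,
so the detector (i) integrates a continuous, drift-corrected volume signal
(rolling-minimum subtraction over 15 s — per-breath re-zeroing would discard
the retained volume of stacked breaths), (ii) regresses Pes on volume over
effort-free samples to estimate 1/Ccw, iterating mask-and-refit three
times, and (iii) measures deflections of `Pes − V·slope` below its rolling
median (10 s window). Events require amplitude ≥ 1 cmH₂O, a contiguous
≥ 0.25 s above 60% of peak, and a full width ≥ 0.4 s at 30% of peak; the
duration rules reject cardiac oscillations, whose lobes are bounded by the
cardiac half-period at every level. Among several non-triggering efforts in
one cycle the first classifiable one sets the breath label (one label per
breath, matching a breath-level confusion matrix); an effort that triggers
the next breath is never an IEE.

## Automatic detection (the Paw/flow classifier)

Evaluated breaths: machine-triggered in VCV/PCV, auto-triggered in PSV.
Patient-triggered breaths are structurally never RT. Features per breath:

- `d_ppeak`, `d_pplat`, `d_ppp = d_ppeak − d_pplat`, `d_pef`, `d_vt` —
  current value minus the running mean of the 4 most recent *undeformed*
  breaths (breaths already labeled RT are excluded so deformation does not
  contaminate the baseline); zero and flagged low-confidence with empty
  history;
- `paw_insp_deform` (VCV) — Paw drop below its running maximum within the
  constant-flow phase and, separately, within the pause (the resistive
  Ppeak→Pplat step at pause onset is not deformation): a passive
  constant-flow insufflation has monotonically rising Paw, an inspiratory
  effort bends it down;
- `insp_flow_deform` (PCV/PSV) — rise of post-peak inspiratory flow above
  its running minimum, anchored at the early pressurization peak (first
  0.3 s) so that an effort bump larger than that peak cannot become its own
  reference: passive decelerating flow is monotone after the peak;
- `exp_deform` — the larger of (a) the deficit of expiratory flow magnitude
  below a fitted exponential decay envelope (least squares on the first
  150 ms and last 300 ms of expiration) and (b) its rise above the running
  minimum, both within the first 1.5 s of expiration, skipping the first
  80 ms (smoothing ramp); an effort brakes, reverses, or rebounds the decay;
- mode indicators.

The deformation features are deliberately history-free: recordings with
1:1 entrainment (RT rates up to >90% of breaths) contain almost no
undeformed history, and stacked breaths have sub-300-ms expirations.

A logistic regression on standardized features gives the RT probability;
the cutoff maximizes Youden's J (sensitivity + specificity − 1) on the
training ROC. A breath is labeled RT only if, additionally, at least one
deformation feature clears its passive-noise floor (|ΔPpeak| ≥ 0.3 cmH₂O,
|ΔPEF| ≥ 2 L/min, flow deformations ≥ 0.06, Paw dip ≥ 0.5 cmH₂O — floors
set at ~1.5× the maxima measured on seeded passive runs) and a deformation
window is identified. The gate encodes the design priority of avoiding
false positives; its corollary is the intended failure mode that efforts of
~2 cmH₂O or less, which deform neither Paw nor flow visibly, go undetected.
Subtypes follow the dominant deformation window, with `BS` when the
successor is stacked.

The packaged model is trained on the synthetic training suite (seed 0,
1084 evaluated breaths); `fit_model` retrains on any aligned
feature/label set with ≥ 200 breaths of both classes.

## Pmus quantification

`Pmus(t) = Pes_ee + V(t)/Ccw − Pes(t)` with Pes_ee the median Pes over the
300 ms ending 50 ms before the onset; the peak is taken over the cycle up
to 2.0 s from onset (1.5 s RT bound + 0.5 s margin, since RT efforts often
peak in early expiration) after a 120 ms boxcar (the raw max of a noisy
trace is biased upward). Negative instantaneous Pmus is floored at zero for
the peak. Ccw comes from passive breaths (≥ 3 required) as the median
ΔV/ΔPes between end-expiration and end-insufflation, integrating raw
(unsmoothed) flow from 3 samples before the detected onset — median
smoothing and onset-detection lag each bias the volume by ~1% otherwise.
The artifact screen invalidates (never raises on) breaths with a
single-sample Pes step > 3 cmH₂O (≈300 cmH₂O/s — an instantaneous sensor
step; the fastest simulated muscular swings stay below half that) or an
unexplained end-to-end baseline shift > 5 cmH₂O, assessed only when the
breath ends effort-free.

## Agreement statistics

The RT/not-RT dichotomy (subtypes collapsed) gives the 2×2 matrix and the
standard rates; Cohen's kappa uses margin-based expected agreement with the
Fleiss-style large-sample standard error `SE = sqrt(p_o(1−p_o)/(n(1−p_e)²))`
and z = 1.96 for the 95% CI. The sample-size planner inverts the same
expression under equal rater margins at the assumed prevalence; for a
planned kappa of 0.85, half-width 0.02, prevalence 20%, it returns 4286
breaths. Reported percentages are rounded half-up to one decimal; full
precision is always retained alongside.

## Problem sizes

The shipped experiments use 10-min validation recordings (≈3 800 breaths
across the 20-recording suite), 5-min training recordings, and 2-min
recordings for the parameter-recovery grid (amplitudes 5–35 cmH₂O × delays
0.2–0.8 s); these sizes give stable breath-level statistics while keeping a
full pipeline run in the low minutes on one core.

## Known limitations

- Supported modes are VCV, PCV and PSV only; other modes raise a capability
  error rather than guessing.
- The detector's Δ-features assume a reasonably stable ventilator setting
  within a recording; a settings change mid-recording contaminates the
  running averages for the next few breaths.
- Double triggering (a single patient effort triggering two insufflations)
  is not distinguished from RT-driven stacking beyond the trigger-type rule.
- The reference labeler's Ccw regression needs some effort-free,
  volume-varying samples; recordings with continuous maximal effort would
  degrade the chest-wall correction (it then falls back toward the raw
  deflection).
- All performance figures quoted in the acceptance outputs are measured on
  synthetic recordings; they characterize the algorithm under the
  simulator's assumptions, not its clinical accuracy on any real dataset.
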