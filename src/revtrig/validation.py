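"""Breath-level agreement statistics between reference and automatic labels.

The comparison is the RT / not-RT dichotomy (subtypes collapsed):

* true positive  — RT by both reference and automatic detection,
* true negative  — not RT by both,
* false positive — RT by automatic detection only,
* false negative — RT by reference only.

Derived metrics use the standard formulas; chance-corrected agreement is
Cohen's kappa, kappa = (p_o - p_e) / (1 - p_e), with the expected
agreement p_e taken from the row/column margins.  The 95% CI uses the
Fleiss-style large-sample standard error

    SE = sqrt( p_o (1 - p_o) / ( n (1 - p_e)^2 ) )

with the normal z = 1.96; the same expression, inverted for n, drives
the kappa-based sample-size planner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DataError

Z95 = 1.959963984540054


@dataclass
class ConfusionSummary:
    """2x2 breath-level agreement matrix with derived metrics."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None
    accuracy: float | None = None
    prevalence: float | None = None
    kappa: float | None = None
    kappa_ci: tuple[float, float] | None = None

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict:
        d = {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "total": self.total,
        }
        for k in ("sensitivity", "specificity", "ppv", "npv", "accuracy",
                  "prevalence", "kappa"):
            v = getattr(self, k)
            d[k] = v
            if v is not None and k != "kappa":
                d[k + "_pct"] = round_half_up(100.0 * v, 1)
        if self.kappa is not None:
            d["kappa_x100"] = round_half_up(100.0 * self.kappa, 1)
        if self.kappa_ci is not None:
            d["kappa_ci"] = list(self.kappa_ci)
        return d


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal rounding with ties away from zero (presentation rounding)."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def build_confusion(reference: list, automatic: list) -> ConfusionSummary:
    """Tally the 2x2 matrix from two index-aligned label lists.

    Labels are objects with ``breath_index`` and ``label`` (``RT`` is
    the positive class; subtypes are collapsed).  The two lists must
    cover identical breath-index sets.
    """
    ref = {lab.breath_index: lab.label == "RT" for lab in reference}
    aut = {lab.breath_index: lab.label == "RT" for lab in automatic}
    if set(ref) != set(aut):
        offenders = sorted(set(ref) ^ set(aut))
        raise DataError(f"label sets cover different breaths: {offenders[:10]}")
    tp = fp = fn = tn = 0
    for k, r in ref.items():
        a = aut[k]
        if r and a:
            tp += 1
        elif r and not a:
            fn += 1
        elif a and not r:
            fp += 1
        else:
            tn += 1
    return ConfusionSummary(tp=tp, fp=fp, fn=fn, tn=tn)


def compute_metrics(cs: ConfusionSummary) -> ConfusionSummary:
    """Fill the standard diagnostic rates; undefined ratios stay None."""
    if cs.total == 0:
        raise DataError("empty confusion matrix")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    cs.sensitivity = ratio(cs.tp, cs.tp + cs.fn)
    cs.specificity = ratio(cs.tn, cs.tn + cs.fp)
    cs.ppv = ratio(cs.tp, cs.tp + cs.fp)
    cs.npv = ratio(cs.tn, cs.tn + cs.fn)
    cs.accuracy = (cs.tp + cs.tn) / cs.total
    cs.prevalence = (cs.tp + cs.fn) / cs.total
    return cs


def _po_pe(tp: int, fp: int, fn: int, tn: int) -> tuple[float, float]:
    n = tp + fp + fn + tn
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / n**2
    return po, pe


def cohen_kappa(cs: ConfusionSummary) -> ConfusionSummary:
    """Cohen's kappa with a 95% large-sample CI; None when margins are
    degenerate (p_e = 1)."""
    if cs.total == 0:
        raise DataError("empty confusion matrix")
    po, pe = _po_pe(cs.tp, cs.fp, cs.fn, cs.tn)
    if pe >= 1.0 - 1e-12:
        cs.kappa = None
        cs.kappa_ci = None
        return cs
    kappa = (po - pe) / (1.0 - pe)
    se = math.sqrt(po * (1.0 - po) / (cs.total * (1.0 - pe) ** 2))
    cs.kappa = kappa
    cs.kappa_ci = (max(-1.0, kappa - Z95 * se), min(1.0, kappa + Z95 * se))
    return cs


def kappa_ci_half_width(kappa0: float, prevalence: float, n: int) -> float:
    """Half-width of the 95% kappa CI under equal margins at the given
    prevalence (the planning model of :func:`kappa_sample_size`)."""
    pe = prevalence**2 + (1.0 - prevalence) ** 2
    po = kappa0 * (1.0 - pe) + pe
    se = math.sqrt(po * (1.0 - po) / (n * (1.0 - pe) ** 2))
    return Z95 * se


def kappa_sample_size(
    kappa0: float,
    half_width: float,
    prevalence: float,
    alpha: float = 0.05,
) -> int:
    """Smallest number of breaths giving a kappa CI half-width at most
    ``half_width``, assuming both raters share ``prevalence`` margins."""
    if not 0.0 < kappa0 < 1.0:
        raise DataError("kappa0 must lie in (0, 1)")
    if not 0.0 < prevalence < 1.0:
        raise DataError("prevalence must lie in (0, 1)")
    if half_width <= 0:
        raise DataError("half_width must be positive")
    if not 0.0 < alpha < 1.0:
        raise DataError("alpha must lie in (0, 1)")
    from scipy.stats import norm

    z = float(norm.ppf(1.0 - alpha / 2.0))
    pe = prevalence**2 + (1.0 - prevalence) ** 2
    po = kappa0 * (1.0 - pe) + pe
    if po >= 1.0:
        raise DataError("planning inputs give perfect expected agreement")
    n = po * (1.0 - po) / ((half_width / z) ** 2 * (1.0 - pe) ** 2)
    return int(math.ceil(n))


def agreement_report(
    reference: list, automatic: list, per_recording: dict | None = None
) -> dict:
    """Complete JSON-serializable agreement report: counts, rates
    (fraction and 1-decimal percent), kappa (raw and x100), and the
    breath-by-breath discrepancy listing used for adjudication."""
    cs = cohen_kappa(compute_metrics(build_confusion(reference, automatic)))
    ref_by_idx = {lab.breath_index: lab for lab in reference}
    discrepancies = []
    for lab in automatic:
        r = ref_by_idx[lab.breath_index]
        if (r.label == "RT") != (lab.label == "RT"):
            discrepancies.append(
                {
                    "breath_index": lab.breath_index,
                    "start_s": r.start_s,
                    "reference": r.label,
                    "automatic": lab.label,
                }
            )
    n_rt_ref = sum(1 for lab in reference if lab.label == "RT")
    report = {
        "confusion": cs.as_dict(),
        "rt_rate_reference_pct": round_half_up(100.0 * n_rt_ref / max(len(reference), 1), 1),
        "n_breaths": len(reference),
        "discrepancies": discrepancies,
    }
    if per_recording:
        report["per_recording"] = per_recording
    return report
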