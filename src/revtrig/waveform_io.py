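"""Waveform and annotation I/O for ventilator recordings.

A recording holds uniformly sampled airway pressure (Paw, cmH2O) and flow
(L/min), optionally esophageal pressure (Pes, cmH2O) and diaphragm
electrical activity (EAdi, uV).  All analysis in this package runs on the
canonical 100 Hz grid; recordings at other rates are linearly resampled on
load.  Flow follows the convention inspiration positive / expiration
negative, so "peak expiratory flow" is the magnitude of the flow minimum.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .errors import DataError, FormatError

logger = logging.getLogger("revtrig")

#: canonical sampling rate of all internal computations (samples/s)
CANONICAL_RATE_HZ = 100.0

#: default moving-median smoothing window applied before any detection (ms)
DEFAULT_SMOOTH_MS = 80.0

#: canonical waveform CSV column names
WAVEFORM_COLUMNS = {
    "time": "time_s",
    "paw": "paw_cmh2o",
    "flow": "flow_lpm",
    "pes": "pes_cmh2o",
    "eadi": "eadi_uv",
}

#: canonical label CSV column order
LABEL_COLUMNS = ["breath_index", "start_s", "trigger", "label", "rt_subtype", "source"]


@dataclass
class WaveformRecord:
    """Uniformly sampled multi-channel ventilator recording.

    Parameters
    ----------
    sampling_rate_hz
        Sampling rate, samples per second; sampling is uniform by
        construction (time is derived from the rate, never stored
        per sample).
    paw
        Airway pressure, cmH2O.
    flow
        Flow at the airway opening, L/min, inspiration positive.
    pes
        Optional esophageal pressure, cmH2O.
    eadi
        Optional diaphragm electrical activity, uV.
    t0
        Time of the first sample, s.
    meta
        Free-form provenance mapping.
    """

    sampling_rate_hz: float
    paw: np.ndarray
    flow: np.ndarray
    pes: np.ndarray | None = None
    eadi: np.ndarray | None = None
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise DataError("sampling_rate_hz must be positive")
        self.paw = np.asarray(self.paw, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        if self.pes is not None:
            self.pes = np.asarray(self.pes, dtype=float)
        if self.eadi is not None:
            self.eadi = np.asarray(self.eadi, dtype=float)
        n = len(self.paw)
        if n < 2:
            raise DataError("record needs at least 2 samples")
        for name in ("flow", "pes", "eadi"):
            ch = getattr(self, name)
            if ch is not None and len(ch) != n:
                raise DataError(f"channel {name!r} length {len(ch)} != paw length {n}")

    # -- derived quantities -------------------------------------------------

    def __len__(self) -> int:
        return len(self.paw)

    @property
    def dt(self) -> float:
        """Sample interval, s."""
        return 1.0 / self.sampling_rate_hz

    @property
    def duration_s(self) -> float:
        return len(self) * self.dt

    def time(self) -> np.ndarray:
        """Per-sample times in s, derived from the rate."""
        return self.t0 + np.arange(len(self)) / self.sampling_rate_hz

    def channels(self) -> dict[str, np.ndarray]:
        out = {"paw": self.paw, "flow": self.flow}
        if self.pes is not None:
            out["pes"] = self.pes
        if self.eadi is not None:
            out["eadi"] = self.eadi
        return out


@dataclass
class VentilatorSettings:
    """Ventilator configuration of a recording.

    mode is one of ``VCV`` (volume-controlled), ``PCV``
    (pressure-controlled) or ``PSV`` (pressure support).  ``vt_set`` (mL)
    and ``ti``/``pause_s`` (s) apply to VCV; ``p_insp`` (cmH2O above PEEP)
    to PCV/PSV; ``set_rate`` (breaths/min) to VCV/PCV.  ``trigger_paw_drop``
    is the pressure-trigger sensitivity below PEEP (cmH2O);
    ``psv_cycle_frac`` the fraction of peak inspiratory flow at which PSV
    cycles to exhalation.
    """

    mode: str = "VCV"
    set_rate: float = 20.0
    vt_set: float = 400.0
    p_insp: float = 12.0
    peep: float = 5.0
    ti: float = 1.0
    pause_s: float = 0.3
    trigger_paw_drop: float = 2.0
    psv_cycle_frac: float = 0.25
    rise_time_s: float = 0.1

    def __post_init__(self) -> None:
        if self.mode not in ("VCV", "PCV", "PSV"):
            raise DataError(f"unsupported ventilator mode {self.mode!r}")
        if self.mode in ("VCV", "PCV") and self.set_rate <= 0:
            raise DataError("set_rate must be positive in VCV/PCV")
        if not 0 < self.psv_cycle_frac < 1:
            raise DataError("psv_cycle_frac must lie in (0, 1)")
        if self.trigger_paw_drop <= 0:
            raise DataError("trigger_paw_drop must be positive")
        if self.mode == "VCV" and self.pause_s < 0:
            raise DataError("pause_s must be >= 0")


# -- reading and writing ----------------------------------------------------


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") > first_line.count(",") else ","


def read_waveform(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sampling_rate_hz: float = CANONICAL_RATE_HZ,
) -> WaveformRecord:
    """Read a delimited-text waveform file into a :class:`WaveformRecord`.

    ``schema`` maps logical channel names (``paw``, ``flow``, optionally
    ``pes``, ``eadi``, ``time``) to column names in the file; by default
    the canonical column names are used.  Rows with a non-numeric value in
    a mandatory channel (paw, flow) are dropped with a logged warning.
    Recordings sampled at a rate other than the canonical 100 Hz are
    linearly resampled onto the canonical grid.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"waveform file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    sep = _sniff_delimiter(first)
    df = pd.read_csv(path, sep=sep)

    colmap = dict(WAVEFORM_COLUMNS)
    if schema:
        colmap.update(schema)
    for ch in ("paw", "flow"):
        if colmap[ch] not in df.columns:
            raise FormatError(
                f"mandatory column {colmap[ch]!r} (channel {ch!r}) missing from {path.name}"
            )

    def numeric(col: str) -> pd.Series:
        return pd.to_numeric(df[col], errors="coerce")

    paw = numeric(colmap["paw"])
    flow = numeric(colmap["flow"])
    usable = paw.notna() & flow.notna()
    n_bad = int((~usable).sum())
    if n_bad:
        logger.warning("%s: dropped %d rows with non-numeric paw/flow", path.name, n_bad)
    if int(usable.sum()) < 2:
        raise DataError(f"{path.name}: fewer than 2 usable rows")

    channels: dict[str, np.ndarray] = {
        "paw": paw[usable].to_numpy(),
        "flow": flow[usable].to_numpy(),
    }
    for ch in ("pes", "eadi"):
        if colmap[ch] in df.columns:
            channels[ch] = numeric(colmap[ch])[usable].to_numpy()

    record = WaveformRecord(
        sampling_rate_hz=sampling_rate_hz,
        paw=channels["paw"],
        flow=channels["flow"],
        pes=channels.get("pes"),
        eadi=channels.get("eadi"),
        meta={"source": str(path)},
    )
    if sampling_rate_hz != CANONICAL_RATE_HZ:
        record = resample(record, CANONICAL_RATE_HZ)
    return record


def write_waveform(record: WaveformRecord, path: str | Path) -> None:
    """Write a record to the canonical waveform CSV (UTF-8, '.' decimal)."""
    cols: dict[str, np.ndarray] = {"time_s": record.time()}
    for ch, arr in record.channels().items():
        cols[WAVEFORM_COLUMNS[ch]] = arr
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols.keys())
        arrays = list(cols.values())
        for i in range(len(record)):
            writer.writerow(f"{a[i]:.8g}" for a in arrays)


def resample(record: WaveformRecord, rate_hz: float) -> WaveformRecord:
    """Linearly resample every channel onto a uniform ``rate_hz`` grid."""
    t_old = record.time()
    n_new = max(2, int(round(record.duration_s * rate_hz)))
    t_new = record.t0 + np.arange(n_new) / rate_hz
    t_new = t_new[t_new <= t_old[-1] + 1e-12]

    def interp(ch: np.ndarray | None) -> np.ndarray | None:
        if ch is None:
            return None
        return np.interp(t_new, t_old, ch)

    return WaveformRecord(
        sampling_rate_hz=rate_hz,
        paw=interp(record.paw),
        flow=interp(record.flow),
        pes=interp(record.pes),
        eadi=interp(record.eadi),
        t0=record.t0,
        meta=dict(record.meta),
    )


# -- smoothing and integration ----------------------------------------------


def _median_window_samples(window_ms: float, rate_hz: float) -> int:
    w = int(round(window_ms * rate_hz / 1000.0))
    if w < 1:
        w = 1
    if w % 2 == 0:
        w += 1
    return w


def smooth(record: WaveformRecord, window_ms: float = DEFAULT_SMOOTH_MS) -> WaveformRecord:
    """Centered moving-median smoothing of every channel.

    The window is ``round(window_ms * rate / 1000)`` samples, forced odd
    (minimum 1); edges use shrunken windows so the length is unchanged.
    A 0 ms window returns the record unchanged.  The median suppresses
    isolated valve/cardiac spikes without blunting genuine 0.1 s-scale
    deflections.
    """
    if window_ms < 0:
        raise DataError("window_ms must be >= 0")
    if window_ms == 0:
        return record
    w = _median_window_samples(window_ms, record.sampling_rate_hz)
    if w == 1:
        return record

    def med(ch: np.ndarray | None) -> np.ndarray | None:
        if ch is None:
            return None
        return (
            pd.Series(ch).rolling(window=w, center=True, min_periods=1).median().to_numpy()
        )

    return replace(record, paw=med(record.paw), flow=med(record.flow),
                   pes=med(record.pes), eadi=med(record.eadi))


def integrate_volume(record: WaveformRecord, start: int, end: int) -> np.ndarray:
    """Cumulative volume (mL) from the flow channel over ``[start, end)``.

    Trapezoidal integration of flow converted L/min -> L/s, zeroed at
    ``start``.  Indices are 0-based, half-open.
    """
    n = len(record)
    if not (0 <= start < end <= n):
        raise DataError(f"integration interval [{start}, {end}) out of range for length {n}")
    flow_lps = record.flow[start:end] / 60.0
    vol_ml = cumulative_trapezoid(flow_lps, dx=record.dt, initial=0.0) * 1000.0
    return vol_ml


# -- label tables ------------------------------------------------------------


def write_labels(labels: pd.DataFrame | list, path: str | Path) -> None:
    """Write a breath-label table to the canonical label CSV."""
    df = _labels_frame(labels)
    df.to_csv(path, index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a breath-label CSV; validates the canonical columns."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"label file not found: {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise DataError(f"{path.name}: empty label file")
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing label columns {missing}")
    df["rt_subtype"] = df["rt_subtype"].where(df["rt_subtype"].notna(), None)
    return df[LABEL_COLUMNS]


def _labels_frame(labels) -> pd.DataFrame:
    if isinstance(labels, pd.DataFrame):
        return labels[LABEL_COLUMNS]
    rows = []
    for lab in labels:
        rows.append(
            {
                "breath_index": lab.breath_index,
                "start_s": lab.start_s,
                "trigger": lab.trigger,
                "label": lab.label,
                "rt_subtype": lab.rt_subtype,
                "source": lab.source,
            }
        )
    return pd.DataFrame(rows, columns=LABEL_COLUMNS)


def roundtrip_equal(a: WaveformRecord, b: WaveformRecord, sig: int = 6) -> bool:
    """True when all shared channels agree to ``sig`` significant digits."""
    for name, ch in a.channels().items():
        other = b.channels().get(name)
        if other is None or len(other) != len(ch):
            return False
        scale = np.maximum(np.abs(ch), 1e-30)
        if np.any(np.abs(ch - other) / scale > 10 ** (1 - sig)):
            return False
    return True
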