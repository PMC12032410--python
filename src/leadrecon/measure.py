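"""Open ECG measurement: R detection, delineation, and amplitude/interval markers.

This module is the package's stand-in for a commercial ECG measurement
system.  It produces, per record:

* global intervals — RR, QT, PR, QRS duration (ms), medians over beats;
* per-lead amplitudes — R, S, T and mid-ST-segment (STM) in microvolts,
  referenced to the median of the PR segment, medians over beats.

Detection runs on a designated lead (default II); delineation runs on the
across-lead L2 magnitude of the independent leads, where every wave appears
as a positive bump.  Onsets and offsets are located as crossings of 4.4 % of
the local wave peak above baseline — the level a Gaussian wave reaches 2.5
standard deviations from its center — and T end uses the classical tangent
method (steepest post-peak slope extrapolated to baseline).  Search windows
rate-adapt for short RR intervals.  The module is fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .leads import INDEPENDENT_LEADS, LEADS_12, MultiLeadSignal
from .synth import FIDUCIAL_NAMES, GroundTruthFiducials

#: fraction of a wave's peak (above baseline) marking onset/offset; equals
#: exp(-2.5^2 / 2), i.e. a Gaussian wave 2.5 sigma from its center.
EDGE_FRACTION = float(np.exp(-2.5 ** 2 / 2))

#: reference beat span (ms) below 0.9*RR of which search windows compress
RATE_ADAPT_SPAN_MS = 560.0

AMPLITUDE_MARKERS = ("R", "S", "T", "STM")
INTERVAL_MARKERS = ("RR", "QT", "PR", "QRS")
#: precordial leads reported in the evaluation tables
REPORT_LEADS = ("V1", "V2", "V3", "V6")


class MeasurementError(RuntimeError):
    pass


class NoBeatsDetected(MeasurementError):
    pass


def detect_r_peaks(signal: MultiLeadSignal, lead: str = "II",
                   magnitude_fallback: bool = True) -> np.ndarray:
    """R-peak sample indices from a band-pass + squared-derivative envelope.

    Detection runs on the designated lead.  If no QRS-like activity clears
    the noise gate there — e.g. a subject whose R vector is nearly orthogonal
    to that lead — and ``magnitude_fallback`` is on, detection retries on the
    across-lead L2 magnitude, where the QRS loop is never silent.

    Strictly increasing, refractory >= 200 ms.  Raises
    :class:`NoBeatsDetected` on flat or beat-free input.
    """
    if signal.duration < 2.0:
        raise MeasurementError(
            f"need at least 2 s of signal, got {signal.duration:.2f} s")
    try:
        return _detect_r_on(signal.lead(lead).astype(float),
                            signal.sampling_rate)
    except NoBeatsDetected:
        if not magnitude_fallback or signal.n_leads < 2:
            raise
        return _detect_r_on(_magnitude(signal), signal.sampling_rate)


def _detect_r_on(x: np.ndarray, fs: float) -> np.ndarray:
    if np.ptp(x) < 1e-9:
        raise NoBeatsDetected("signal is flat; no beats detected")
    nyq = fs / 2.0
    b, a = sps.butter(2, [5.0 / nyq, 40.0 / nyq], btype="band")
    filt = sps.filtfilt(b, a, x)
    env = np.convolve(np.gradient(filt) ** 2,
                      np.ones(int(0.10 * fs)) / int(0.10 * fs), mode="same")
    if env.max() <= 0:
        raise NoBeatsDetected("no QRS-like activity found; no beats detected")
    locs, _ = sps.find_peaks(env, height=0.25 * env.max(), distance=int(0.2 * fs))
    if locs.size == 0:
        raise NoBeatsDetected("no beats detected")
    # refine on the raw lead: extremum of |x - local median| within +-40 ms
    half = int(0.04 * fs)
    refined, prominences = [], []
    for p in locs:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        seg = np.abs(x[lo:hi] - np.median(x[lo:hi]))
        refined.append(lo + int(np.argmax(seg)))
        prominences.append(seg.max())
    # QRS-vs-noise gate: raw peak amplitudes must clear the robust noise
    # floor estimated from the first difference (wander-insensitive)
    noise_scale = 1.4826 * np.median(np.abs(np.diff(x))) / np.sqrt(2.0)
    if np.median(prominences) < 5.0 * max(noise_scale, 1e-9):
        raise NoBeatsDetected("no QRS-like activity found; no beats detected")
    refined = np.unique(refined)
    keep = [int(refined[0])]
    for r in refined[1:]:
        if r - keep[-1] >= int(0.2 * fs):
            keep.append(int(r))
    return np.asarray(keep, dtype=int)


@dataclass(frozen=True)
class Delineation:
    fiducials: GroundTruthFiducials
    skipped_beats: int


def _magnitude(signal: MultiLeadSignal) -> np.ndarray:
    names = [l for l in INDEPENDENT_LEADS if l in signal.lead_names]
    if not names:
        names = list(signal.lead_names)
    rows = np.stack([signal.lead(l) for l in names])
    return np.sqrt((rows ** 2).sum(axis=0))


def _first_below(m: np.ndarray, start: int, stop: int, step: int,
                 thr: float) -> Optional[int]:
    for i in range(start, stop, step):
        if m[i] <= thr:
            return i
    return None


def delineate(signal: MultiLeadSignal, r_peaks: np.ndarray) -> Delineation:
    """Per-beat fiducials around given R peaks.

    Beats too close to the record edge, or whose landmark search fails or
    comes out unordered, are skipped and counted in ``skipped_beats``.
    """
    fs = signal.sampling_rate
    ms = fs / 1000.0                      # samples per ms
    m = _magnitude(signal)
    n = m.size
    r_peaks = np.asarray(r_peaks, dtype=int)
    rr_med_ms = (np.median(np.diff(r_peaks)) / ms if r_peaks.size > 1
                 else 60000.0 / 70.0)
    k = min(1.0, 0.9 * rr_med_ms / RATE_ADAPT_SPAN_MS)

    def w(offset_ms: float) -> int:
        return int(round(offset_ms * k * ms))

    rows, skipped = [], 0
    for r in r_peaks:
        if r + w(-260) < 0 or r + w(410) >= n:
            skipped += 1
            continue
        try:
            r = r + w(-10) + int(np.argmax(m[r + w(-10):r + w(10) + 1]))
            base = float(np.median(m[r + w(-80):r + w(-48)]))

            # QRS onset from the Q-side bump (window ends short of the R
            # shoulder, which would otherwise dominate the local maximum)
            q_lo, q_hi = r + w(-45), r + w(-21)
            tq = q_lo + int(np.argmax(m[q_lo:q_hi]))
            thr = base + EDGE_FRACTION * (m[tq] - base)
            onset = _first_below(m, tq, r + w(-90), -1, thr)

            # S peak and QRS offset (J point)
            s_lo, s_hi = r + w(16), r + w(45)
            ts = s_lo + int(np.argmax(m[s_lo:s_hi]))
            thr = base + EDGE_FRACTION * (m[ts] - base)
            j = _first_below(m, ts, r + w(95), 1, thr)

            # P wave
            p_lo, p_hi = r + w(-200), r + w(-80)
            tp = p_lo + int(np.argmax(m[p_lo:p_hi]))
            thr = base + EDGE_FRACTION * (m[tp] - base)
            p_on = _first_below(m, tp, r + w(-260), -1, thr)

            # T wave
            t_lo, t_hi = j + w(60), j + w(300)
            tt = t_lo + int(np.argmax(m[t_lo:t_hi]))
            thr = base + EDGE_FRACTION * (m[tt] - base)
            t_on = _first_below(m, tt, j, -1, thr)
            # tangent method for T end
            seg = m[tt:tt + w(150)]
            slope = np.gradient(seg)
            im = int(np.argmin(slope))
            if slope[im] >= 0:
                raise MeasurementError("no descending T slope")
            t_end = tt + im + (seg[im] - base) / (-slope[im])
            t_end = int(round(t_end))

            st_mid = int(np.floor((j + t_on) / 2.0 + 0.5))  # shift-invariant
            row = [p_on, onset, r, ts, j, st_mid, t_on, tt, t_end]
        except (MeasurementError, ValueError, TypeError, IndexError):
            skipped += 1
            continue
        if any(v is None for v in row) or row[-1] >= n or row[0] < 0:
            skipped += 1
            continue
        if not all(b > a for a, b in zip(row, row[1:])):
            skipped += 1
            continue
        rows.append(row)
    fid = GroundTruthFiducials(
        np.array(rows, dtype=int).reshape(-1, len(FIDUCIAL_NAMES)), n)
    return Delineation(fiducials=fid, skipped_beats=skipped)


def measure_markers(signal: MultiLeadSignal, fiducials: GroundTruthFiducials,
                    leads: Optional[Sequence[str]] = None) -> dict:
    """Marker dictionary for one record.

    Amplitudes per lead (uV), baseline = median of the PR segment; intervals
    (ms) from the fiducial columns; everything medianed across beats.
    Missing markers are NaN (flagged via ``n_beats == 0``), never silent zeros.
    """
    leads = list(leads) if leads is not None else [
        l for l in LEADS_12 if l in signal.lead_names]
    fs = signal.sampling_rate
    out = {"n_beats": int(fiducials.n_beats)}
    per_ms = 1000.0 / fs
    if fiducials.n_beats == 0:
        for name in INTERVAL_MARKERS:
            out[f"{name}_ms"] = math.nan
        for lead in leads:
            for mk in AMPLITUDE_MARKERS:
                out[f"{mk}_{lead}"] = math.nan
        return out

    f = fiducials
    r = f.column("r_peak")
    out["RR_ms"] = float(np.median(np.diff(r)) * per_ms) if r.size > 1 else math.nan
    out["QT_ms"] = float(np.median(f.column("t_end") - f.column("qrs_onset")) * per_ms)
    out["PR_ms"] = float(np.median(f.column("qrs_onset") - f.column("p_onset")) * per_ms)
    out["QRS_ms"] = float(np.median(f.column("qrs_offset") - f.column("qrs_onset")) * per_ms)

    for lead in leads:
        x = signal.lead(lead)
        rv, sv, tv, stv = [], [], [], []
        for b in range(f.n_beats):
            p_on, qon = f.beats[b, 0], f.beats[b, 1]
            qoff, st_mid, t_pk = f.beats[b, 4], f.beats[b, 5], f.beats[b, 7]
            # PR segment: past the P wave, short of QRS onset
            seg_lo = p_on + int(0.6 * (qon - p_on))
            baseline = float(np.median(x[seg_lo:max(seg_lo + 2, qon - 1)]))
            qrs = x[qon:qoff + 1]
            rv.append(qrs.max() - baseline)
            sv.append(baseline - qrs.min())
            tv.append(x[t_pk] - baseline)
            stv.append(x[st_mid] - baseline)
        out[f"R_{lead}"] = float(np.median(rv))
        out[f"S_{lead}"] = float(np.median(sv))
        out[f"T_{lead}"] = float(np.median(tv))
        out[f"STM_{lead}"] = float(np.median(stv))
    return out


class MarkerTable:
    """Per-record markers as a DataFrame keyed by record id.

    Columns: ``n_beats``, the four intervals (``RR_ms`` ...), and
    ``<marker>_<lead>`` amplitude columns in microvolts.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.name != "record_id":
            if "record_id" in frame.columns:
                frame = frame.set_index("record_id")
            else:
                raise MeasurementError("marker table needs a record_id key")
        self.frame = frame

    @classmethod
    def from_rows(cls, record_ids: Sequence[str], rows: Sequence[dict]) -> "MarkerTable":
        frame = pd.DataFrame(list(rows), index=pd.Index(record_ids, name="record_id"))
        return cls(frame)

    def amplitude(self, marker: str, lead: str) -> pd.Series:
        return self.frame[f"{marker}_{lead}"]

    def interval(self, name: str) -> pd.Series:
        return self.frame[f"{name}_ms"]

    def feature(self, feature: str, lead: Optional[str] = None) -> pd.Series:
        if feature in INTERVAL_MARKERS:
            return self.interval(feature)
        return self.amplitude(feature, lead)

    def has(self, feature: str, lead: Optional[str] = None) -> bool:
        col = f"{feature}_ms" if feature in INTERVAL_MARKERS else f"{feature}_{lead}"
        return col in self.frame.columns

    def write_csv(self, path):
        self.frame.to_csv(path)

    @classmethod
    def read_csv(cls, path) -> "MarkerTable":
        return cls(pd.read_csv(path, index_col="record_id"))

    def __len__(self):
        return len(self.frame)


def measure_record(signal: MultiLeadSignal, detection_lead: str = "II",
                   leads: Optional[Sequence[str]] = None) -> dict:
    """Detect, delineate and measure one record; returns a marker row."""
    peaks = detect_r_peaks(signal, lead=detection_lead)
    delin = delineate(signal, peaks)
    row = measure_markers(signal, delin.fiducials, leads=leads)
    row["skipped_beats"] = delin.skipped_beats
    return row


def measure_cohort(signals: Sequence[MultiLeadSignal],
                   record_ids: Sequence[str],
                   detection_lead: str = "II",
                   leads: Optional[Sequence[str]] = None) -> MarkerTable:
    """Measure many records; records where detection fails get NaN rows."""
    rows = []
    for sig in signals:
        try:
            rows.append(measure_record(sig, detection_lead, leads))
        except MeasurementError:
            rows.append({"n_beats": 0})
    return MarkerTable.from_rows(list(record_ids), rows)
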