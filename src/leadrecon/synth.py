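"""Synthetic 12-lead ECG cohorts from a 3-D cardiac dipole model.

The heart's net electrical activity is modelled as a time-varying 3-D dipole
vector ``D(t)``; each lead is a fixed linear projection of that vector.  Within
a beat the dipole is a sum of Gaussian bumps (P, Q, R, S, T waves), each with a
per-axis amplitude vector, plus an explicit ST-segment plateau so ST-level
measurement has a nonzero target.  Per-subject variability enters through

* a shared habitus factor ``global_scale`` (log-normal) multiplying every
  amplitude — the only deliberately *shared* factor across dipole axes,
* independent per-axis log-normal scale factors, which decouple amplitudes
  seen by lead I (x axis) from those seen by the near-orthogonal precordial
  leads (z axis), emulating the weak inter-lead amplitude correlation of real
  normal ECGs,
* a random rotation of the electrical axis (azimuth in the frontal plane,
  elevation toward the z axis),
* heart rate, beat-to-beat RR jitter, additive white noise and sinusoidal
  baseline wander.

Ground-truth fiducials are computed from the known wave timing (never
re-detected), so the measurement module can be validated against them.

Geometry convention: x = leftward (lead I direction), y = inferior, z =
anterior.  Leads I and II lie in the frontal (x, y) plane; V3's projection row
is dominated by z, i.e. nearly orthogonal to lead I.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .leads import (INDEPENDENT_LEADS, MultiLeadSignal, assemble_12_lead)

WAVES = ("P", "Q", "R", "S", "T")

#: Fixed map from dipole (x, y, z) to the 8 independent leads (Dower-like
#: geometry).  Rows I and II are frontal-plane (zero z); V3 is nearly
#: orthogonal to lead I.  Exact values are configuration, not science.
DEFAULT_PROJECTION = np.array([
    [1.00, 0.00, 0.00],   # I
    [0.50, 0.866, 0.00],  # II
    [-0.50, 0.10, 0.70],  # V1
    [-0.20, 0.10, 0.90],  # V2
    [0.00, 0.05, 1.00],   # V3
    [0.30, 0.10, 0.80],   # V4
    [0.70, 0.10, 0.40],   # V5
    [0.90, 0.05, 0.10],   # V6
])

#: Lead whose projection row is nearest to orthogonal to lead I's row.
NEAR_ORTHOGONAL_LEAD = "V3"

#: Baseline per-axis wave amplitudes in uV (before subject variability).
DEFAULT_WAVE_AMPLITUDES = {
    "P": (60.0, 40.0, 20.0),
    "Q": (-80.0, -40.0, -20.0),
    "R": (900.0, 700.0, 800.0),
    "S": (-150.0, -100.0, -250.0),
    "T": (250.0, 150.0, 200.0),
}


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class DipoleModel:
    """Wave timing template and lead projection geometry.

    Wave centers/widths are in ms from beat onset for a reference beat; for
    short RR intervals the whole template is compressed by
    ``min(1, 0.9 * RR / span)`` where ``span`` is the template's T-end time,
    a crude analogue of physiologic QT rate adaptation.
    """

    wave_centers_ms: dict = field(default_factory=lambda: {
        "P": 80.0, "Q": 188.0, "R": 212.0, "S": 238.0, "T": 470.0})
    wave_widths_ms: dict = field(default_factory=lambda: {
        "P": 15.0, "Q": 6.0, "R": 8.0, "S": 6.0, "T": 45.0})
    #: ST plateau level per dipole axis, uV (before subject variability).
    st_level: tuple = (20.0, 10.0, 40.0)
    #: Fraction of the J->T-onset span used for each raised-cosine ramp.
    st_ramp_fraction: float = 0.3
    projection_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_PROJECTION.copy())

    def __post_init__(self):
        object.__setattr__(self, "projection_matrix",
                           np.asarray(self.projection_matrix, dtype=float))
        order = [self.wave_centers_ms[w] for w in WAVES if w in self.wave_centers_ms]
        if any(b <= a for a, b in zip(order, order[1:])):
            raise SynthError(f"wave centers must be ordered P<Q<R<S<T, got {order}")
        if self.projection_matrix.shape != (8, 3):
            raise SynthError("projection matrix must be 8x3")

    # -- template fiducial times (ms from beat onset, compression factor 1) --
    def fiducial_times_ms(self) -> dict:
        c, s = self.wave_centers_ms, self.wave_widths_ms
        j = c["S"] + 2.5 * s["S"]
        t_on = c["T"] - 2.5 * s["T"]
        return {
            "p_onset": c["P"] - 2.5 * s["P"],
            "qrs_onset": c["Q"] - 2.5 * s["Q"],
            "r_peak": c["R"],
            "s_peak": c["S"],
            "qrs_offset": j,
            "st_mid": (j + t_on) / 2.0,
            "t_onset": t_on,
            "t_peak": c["T"],
            # tangent-method T end for a Gaussian: peak + 2 sigma
            "t_end": c["T"] + 2.0 * s["T"],
        }

    @property
    def template_span_ms(self) -> float:
        return self.fiducial_times_ms()["t_end"]

    def compression(self, rr_ms: float) -> float:
        return min(1.0, 0.9 * rr_ms / self.template_span_ms)


FIDUCIAL_NAMES = ("p_onset", "qrs_onset", "r_peak", "s_peak", "qrs_offset",
                  "st_mid", "t_onset", "t_peak", "t_end")


@dataclass(frozen=True)
class SubjectParams:
    """Everything subject-specific that shapes one record."""

    heart_rate: float                 # bpm
    rr_jitter_sd: float               # ms
    axis_azimuth: float               # degrees, rotation in the frontal plane
    axis_elevation: float             # degrees, rotation toward z
    wave_amplitudes: dict             # wave -> (x, y, z) uV, subject-specific
    st_level: tuple                   # (x, y, z) uV, subject-specific
    global_scale: float               # unitless habitus factor
    noise_sd: float                   # uV
    baseline_wander_amp: float        # uV
    baseline_wander_freq: float       # Hz
    subject_id: str = "rec_0000"

    def __post_init__(self):
        if not (30.0 < self.heart_rate < 200.0):
            raise SynthError(f"heart rate {self.heart_rate} outside (30, 200) bpm")
        if self.global_scale <= 0:
            raise SynthError("global_scale must be > 0")
        if min(self.noise_sd, self.baseline_wander_amp, self.rr_jitter_sd) < 0:
            raise SynthError("noise levels must be >= 0")

    def rotation(self) -> np.ndarray:
        """Axis rotation: azimuth about z (x<->y), then elevation about y (x<->z)."""
        az = math.radians(self.axis_azimuth)
        el = math.radians(self.axis_elevation)
        rz = np.array([[math.cos(az), -math.sin(az), 0.0],
                       [math.sin(az), math.cos(az), 0.0],
                       [0.0, 0.0, 1.0]])
        ry = np.array([[math.cos(el), 0.0, math.sin(el)],
                       [0.0, 1.0, 0.0],
                       [-math.sin(el), 0.0, math.cos(el)]])
        return ry @ rz

    def effective_amplitude(self, wave: str) -> np.ndarray:
        """Rotated, habitus-scaled amplitude vector for one wave (uV)."""
        return self.global_scale * (self.rotation() @ np.asarray(self.wave_amplitudes[wave]))

    def effective_st(self) -> np.ndarray:
        return self.global_scale * (self.rotation() @ np.asarray(self.st_level))


@dataclass(frozen=True)
class GroundTruthFiducials:
    """Per-beat fiducial sample indices, strictly increasing within a beat.

    ``beats`` has shape (n_beats, 9) with columns :data:`FIDUCIAL_NAMES`.
    """

    beats: np.ndarray
    n_samples: int

    def __post_init__(self):
        beats = np.asarray(self.beats, dtype=int).reshape(-1, len(FIDUCIAL_NAMES))
        object.__setattr__(self, "beats", beats)
        if beats.size:
            if not (np.diff(beats, axis=1) > 0).all():
                raise SynthError("fiducials must be strictly increasing within a beat")
            if beats.min() < 0 or beats.max() >= self.n_samples:
                raise SynthError("fiducial index out of record bounds")

    @property
    def n_beats(self) -> int:
        return self.beats.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.beats[:, FIDUCIAL_NAMES.index(name)]


@dataclass(frozen=True)
class SyntheticRecord:
    signal: MultiLeadSignal           # 12 leads, canonical order
    params: SubjectParams
    fiducials: GroundTruthFiducials

    @property
    def record_id(self) -> str:
        return self.params.subject_id

    def independent(self) -> MultiLeadSignal:
        return self.signal.subset(INDEPENDENT_LEADS)


@dataclass(frozen=True)
class PopulationConfig:
    """Sampling distributions for :func:`sample_subject`."""

    hr_mean: float = 70.0
    hr_sd: float = 10.0
    hr_range: tuple = (45.0, 120.0)
    rr_jitter_sd: float = 15.0        # ms, same for every subject
    #: frontal-plane (azimuth) electrical-axis spread; the classical
    #: inter-subject axis variation lives in this plane
    axis_sd_deg: float = 25.0
    #: anterior-posterior (elevation) spread; kept small because a large
    #: shared rotation toward z would itself couple limb and precordial
    #: amplitudes, masking the role of the explicit shared scale factor
    elevation_sd_deg: float = 8.0
    #: sigma of log global_scale; the shared-factor weight controlling how
    #: much amplitude correlation exists across dipole axes.
    shared_scale_sd: float = 0.25
    #: sigma of log per-axis scale factors (independent across x, y, z).
    axis_scale_sd: float = 0.35
    #: sigma of log per-wave multipliers (shared across axes within a wave).
    wave_jitter_sd: float = 0.10
    noise_sd: float = 10.0            # uV
    baseline_wander_amp: float = 30.0  # uV
    baseline_wander_freq: float = 0.25  # Hz

    def __post_init__(self):
        if self.hr_sd < 0 or self.hr_range[0] >= self.hr_range[1]:
            raise SynthError("invalid heart-rate distribution")
        for name in ("shared_scale_sd", "axis_scale_sd", "wave_jitter_sd"):
            if getattr(self, name) < 0:
                raise SynthError(f"{name} must be >= 0")


def noise_free(config: PopulationConfig) -> PopulationConfig:
    """Copy of ``config`` with additive noise and baseline wander off."""
    return replace(config, noise_sd=0.0, baseline_wander_amp=0.0)


def sample_subject(config: PopulationConfig, rng: np.random.Generator,
                   subject_id: str = "rec_0000",
                   model: Optional[DipoleModel] = None) -> SubjectParams:
    """Draw one subject's parameters; deterministic given the rng state."""
    model = model or DipoleModel()
    lo, hi = config.hr_range
    hr = float(np.clip(config.hr_mean, lo + 1e-9, hi - 1e-9))
    if config.hr_sd > 0:
        for _ in range(1000):
            hr = config.hr_mean + config.hr_sd * rng.standard_normal()
            if lo < hr < hi:
                break
        else:
            raise SynthError("heart-rate truncation rejected 1000 draws; check config")
    az = config.axis_sd_deg * rng.standard_normal()
    el = config.elevation_sd_deg * rng.standard_normal()
    g = math.exp(config.shared_scale_sd * rng.standard_normal())
    axis_scale = np.exp(config.axis_scale_sd * rng.standard_normal(3))
    wave_mult = np.exp(config.wave_jitter_sd * rng.standard_normal(len(WAVES)))
    amps = {w: tuple(np.asarray(DEFAULT_WAVE_AMPLITUDES[w]) * axis_scale * m)
            for w, m in zip(WAVES, wave_mult)}
    st_mult = math.exp(config.wave_jitter_sd * rng.standard_normal())
    st = tuple(np.asarray(model.st_level) * axis_scale * st_mult)
    return SubjectParams(
        heart_rate=hr, rr_jitter_sd=config.rr_jitter_sd,
        axis_azimuth=az, axis_elevation=el,
        wave_amplitudes=amps, st_level=st, global_scale=g,
        noise_sd=config.noise_sd,
        baseline_wander_amp=config.baseline_wander_amp,
        baseline_wander_freq=config.baseline_wander_freq,
        subject_id=subject_id)


def _beat_schedule(params: SubjectParams, duration_ms: float,
                   rng: np.random.Generator):
    """Beat onset times and RR intervals (ms); first onset at 40 ms."""
    mean_rr = 60000.0 / params.heart_rate
    onsets, rrs = [], []
    t = 100.0
    while t < duration_ms:
        rr = mean_rr
        if params.rr_jitter_sd > 0:
            rr = max(300.0, mean_rr + params.rr_jitter_sd * rng.standard_normal())
        onsets.append(t)
        rrs.append(rr)
        t += rr
    return np.array(onsets), np.array(rrs)


def dipole_trajectory(params: SubjectParams, model: DipoleModel,
                      t_ms: np.ndarray, onsets: np.ndarray,
                      rrs: np.ndarray) -> np.ndarray:
    """Noise-free dipole D(t), shape (3, len(t_ms)); exact analytic evaluation."""
    d = np.zeros((3, t_ms.size))
    fid = model.fiducial_times_ms()
    for onset, rr in zip(onsets, rrs):
        k = model.compression(rr)
        for w in WAVES:
            if w not in params.wave_amplitudes:
                continue
            c = onset + k * model.wave_centers_ms[w]
            s = k * model.wave_widths_ms[w]
            amp = params.effective_amplitude(w)
            lo = np.searchsorted(t_ms, c - 6 * s)
            hi = np.searchsorted(t_ms, c + 6 * s)
            if hi > lo:
                bump = np.exp(-0.5 * ((t_ms[lo:hi] - c) / s) ** 2)
                d[:, lo:hi] += amp[:, None] * bump[None, :]
        # ST plateau with raised-cosine ramps between J and T onset
        j = onset + k * fid["qrs_offset"]
        t_on = onset + k * fid["t_onset"]
        span = t_on - j
        if span > 0:
            ramp = model.st_ramp_fraction * span
            lo = np.searchsorted(t_ms, j)
            hi = np.searchsorted(t_ms, t_on)
            if hi > lo:
                tt = t_ms[lo:hi]
                w_env = np.ones(hi - lo)
                up = tt < j + ramp
                w_env[up] = 0.5 * (1 - np.cos(np.pi * (tt[up] - j) / ramp))
                down = tt > t_on - ramp
                w_env[down] = 0.5 * (1 - np.cos(np.pi * (t_on - tt[down]) / ramp))
                d[:, lo:hi] += params.effective_st()[:, None] * w_env[None, :]
    return d


def generate_record(params: SubjectParams, model: Optional[DipoleModel] = None,
                    duration: float = 10.0, fs: float = 500.0,
                    rng: Optional[np.random.Generator] = None) -> SyntheticRecord:
    """Simulate one 12-lead record with ground-truth fiducials.

    Noise and baseline wander are added to the 8 independent leads; the four
    limb leads are then *derived*, so the Einthoven/Goldberger identities hold
    exactly in every record.
    """
    model = model or DipoleModel()
    rng = rng if rng is not None else np.random.default_rng(0)
    if fs <= 0:
        raise SynthError(f"sampling rate must be > 0, got {fs}")
    n_float = duration * fs
    n = int(round(n_float))
    if abs(n_float - n) > 1e-9:
        raise SynthError(f"duration*fs = {n_float} is not an integral sample count")
    t_ms = np.arange(n) * (1000.0 / fs)
    onsets, rrs = _beat_schedule(params, duration * 1000.0, rng)
    d = dipole_trajectory(params, model, t_ms, onsets, rrs)
    independent = model.projection_matrix @ d      # (8, n) uV
    if params.baseline_wander_amp > 0:
        phases = rng.uniform(0, 2 * np.pi, size=8)
        wander = params.baseline_wander_amp * np.sin(
            2 * np.pi * params.baseline_wander_freq * (t_ms[None, :] / 1000.0)
            + phases[:, None])
        independent = independent + wander
    if params.noise_sd > 0:
        independent = independent + params.noise_sd * rng.standard_normal((8, n))
    signal = assemble_12_lead(
        MultiLeadSignal(independent, fs, INDEPENDENT_LEADS))

    fid_t = model.fiducial_times_ms()
    rows = []
    for onset, rr in zip(onsets, rrs):
        k = model.compression(rr)
        times = {name: onset + k * fid_t[name] for name in FIDUCIAL_NAMES}
        # edge margin: leave room after T end for tangent/search windows
        if times["p_onset"] < 10.0 or times["t_end"] + 62.0 * k > t_ms[-1]:
            continue  # edge beat: skipped, by design
        rows.append([int(round(times[name] * fs / 1000.0)) for name in FIDUCIAL_NAMES])
    fiducials = GroundTruthFiducials(
        np.array(rows, dtype=int).reshape(-1, len(FIDUCIAL_NAMES)), n)
    return SyntheticRecord(signal=signal, params=params, fiducials=fiducials)


def generate_cohort(n: int, config: Optional[PopulationConfig] = None,
                    seed: int = 17, duration: float = 10.0, fs: float = 500.0,
                    model: Optional[DipoleModel] = None) -> list:
    """Simulate ``n`` subjects; fully reproducible given ``seed``."""
    if n < 1:
        raise SynthError(f"cohort size must be >= 1, got {n}")
    config = config or PopulationConfig()
    model = model or DipoleModel()
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        params = sample_subject(config, rng, subject_id=f"rec_{i:04d}", model=model)
        records.append(generate_record(params, model, duration, fs, rng))
    return records


def split_cohort(records: Sequence, fractions=(0.8, 0.1, 0.1), seed: int = 17):
    """Shuffle then split into (train, validation, test).

    train = floor(f0*n), validation = floor(f1*n), test = remainder.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise SynthError(f"fractions {fractions} do not sum to 1")
    n = len(records)
    if n < 3:
        raise SynthError(f"need at least 3 records to split, got {n}")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(math.floor(fractions[0] * n))
    n_val = int(math.floor(fractions[1] * n))
    shuffled = [records[i] for i in order]
    return (shuffled[:n_train], shuffled[n_train:n_train + n_val],
            shuffled[n_train + n_val:])


# ---------------------------------------------------------------------------
# Analytic (closed-form) marker oracles for validating the measurement module
# ---------------------------------------------------------------------------

def analytic_lead_value(record: SyntheticRecord, lead: str,
                        sample_indices: np.ndarray,
                        model: Optional[DipoleModel] = None) -> np.ndarray:
    """Noise-free analytic amplitude of ``lead`` at given samples (uV)."""
    model = model or DipoleModel()
    fs = record.signal.sampling_rate
    t_ms = np.atleast_1d(sample_indices) * (1000.0 / fs)
    # rebuild the deterministic beat schedule from the fiducials
    onsets, rrs = _recover_schedule(record, model)
    d = dipole_trajectory(record.params, model, t_ms, onsets, rrs)
    row = model.projection_matrix[list(INDEPENDENT_LEADS).index(lead)]
    return row @ d


def _recover_schedule(record: SyntheticRecord, model: DipoleModel):
    """Beat onsets/RRs (ms) back-computed from ground-truth R-peak times."""
    fs = record.signal.sampling_rate
    r_ms = record.fiducials.column("r_peak") * (1000.0 / fs)
    if r_ms.size == 0:
        return np.array([]), np.array([])
    rrs = np.diff(r_ms)
    rrs = np.append(rrs, rrs[-1] if rrs.size else 60000.0 / record.params.heart_rate)
    # onset = r_peak - compression * template r time; compression depends on rr
    c_r = model.wave_centers_ms["R"]
    onsets = np.array([r - model.compression(rr) * c_r for r, rr in zip(r_ms, rrs)])
    return onsets, rrs


def analytic_markers(record: SyntheticRecord, leads: Sequence[str] = INDEPENDENT_LEADS,
                     model: Optional[DipoleModel] = None) -> dict:
    """Closed-form amplitude markers (uV) per lead and interval markers (ms).

    Amplitudes are extrema of the analytic noise-free waveform over the same
    ground-truth windows the measurement module uses (R: max over QRS window,
    S: -min over QRS window, T: value at T peak, STM: value at ST midpoint),
    medianed over beats.  Intervals come straight from the fiducial timing.
    """
    model = model or DipoleModel()
    fid = record.fiducials
    fs = record.signal.sampling_rate
    out = {"per_lead": {}, "intervals": {}}
    for lead in leads:
        r_vals, s_vals, t_vals, stm_vals = [], [], [], []
        for b in range(fid.n_beats):
            qon, qoff = fid.beats[b, 1], fid.beats[b, 4]
            window = np.arange(qon, qoff + 1)
            y = analytic_lead_value(record, lead, window, model)
            r_vals.append(y.max())
            s_vals.append(-y.min())
            t_vals.append(float(analytic_lead_value(
                record, lead, np.array([fid.beats[b, 7]]), model)[0]))
            stm_vals.append(float(analytic_lead_value(
                record, lead, np.array([fid.beats[b, 5]]), model)[0]))
        out["per_lead"][lead] = {
            "R": float(np.median(r_vals)), "S": float(np.median(s_vals)),
            "T": float(np.median(t_vals)), "STM": float(np.median(stm_vals))}
    ms = 1000.0 / fs
    r = fid.column("r_peak")
    out["intervals"] = {
        "RR": float(np.median(np.diff(r)) * ms) if r.size > 1 else float("nan"),
        "QT": float(np.median(fid.column("t_end") - fid.column("qrs_onset")) * ms),
        "PR": float(np.median(fid.column("qrs_onset") - fid.column("p_onset")) * ms),
        "QRS": float(np.median(fid.column("qrs_offset") - fid.column("qrs_onset")) * ms),
    }
    return out
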