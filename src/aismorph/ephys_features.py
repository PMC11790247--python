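"""Current-clamp feature extraction from step protocols.

Extracts the standard excitability parameters from families of voltage
sweeps recorded under incrementing current steps: resting membrane
potential, input resistance, AP threshold / amplitude / half-width /
maximum rise, rheobase, per-step firing rates and the maximum slope of the
f–I curve.

Definitions
-----------
* AP detection: voltage peaks above 0 mV whose preceding depolarization
  reaches the dV/dt criterion (default 20 mV/ms), with ≥1 ms refractory
  separation; peaks too close to the sweep end to carry a complete
  repolarization are excluded and flagged.
* threshold: membrane potential at the first sample where dV/dt reaches the
  criterion on the rising phase; amplitude = peak − threshold;
  half-width = width at threshold + amplitude/2 with linear interpolation
  between samples; max rise = maximal dV/dt between threshold and peak.
* waveform-analysis selection: the first AP fired at least 30 ms after the
  start of the current injection.
* passive properties: RMP is the mean pre-step voltage; input resistance is
  the steady-state deflection of a hyperpolarizing (−100 pA) step divided
  by the injected current.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FeatureFailure

DVDT_CRITERION = 20.0          # mV/ms
MIN_FIRST_AP_LATENCY_MS = 30.0


@dataclass
class Sweep:
    current_pa: float
    time_ms: np.ndarray
    voltage_mv: np.ndarray

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.voltage_mv = np.asarray(self.voltage_mv, dtype=float)
        if self.time_ms.shape != self.voltage_mv.shape:
            raise ValueError("time and voltage must align")

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])


@dataclass
class SweepSet:
    sweeps: list
    step_onset_ms: float
    step_duration_ms: float
    sample_rate_khz: float

    def __post_init__(self) -> None:
        currents = [s.current_pa for s in self.sweeps]
        if any(b <= a for a, b in zip(currents, currents[1:])):
            raise ValueError("sweep currents must be strictly increasing")

    def currents(self) -> np.ndarray:
        return np.array([s.current_pa for s in self.sweeps])


@dataclass
class APFeatures:
    threshold: float     # mV
    amplitude: float     # mV
    half_width: float    # ms
    max_rise: float      # mV/ms
    time: float          # ms, peak time
    flags: tuple = ()


@dataclass
class PassiveProperties:
    rmp: float               # mV
    input_resistance: float  # MΩ
    flags: tuple = ()


@dataclass
class SpikeDetection:
    peak_times_ms: np.ndarray
    peak_indices: np.ndarray
    excluded_truncated: int = 0
    flags: tuple = ()


def detect_aps(sweep: Sweep, dvdt_criterion: float = DVDT_CRITERION,
               refractory_ms: float = 1.0) -> SpikeDetection:
    """Detect AP peaks above 0 mV with a dV/dt take-off criterion."""
    from scipy.signal import find_peaks

    v = sweep.voltage_mv
    dt = sweep.dt_ms
    distance = max(1, int(round(refractory_ms / dt)))
    peaks, _ = find_peaks(v, height=0.0, distance=distance)

    dvdt = np.gradient(v, dt)
    kept, flags, truncated = [], [], 0
    guard = int(round(1.0 / dt))  # need ~1 ms of repolarization after peak
    for p in peaks:
        lo = max(0, p - int(round(5.0 / dt)))
        if dvdt[lo:p + 1].max() < dvdt_criterion:
            continue
        if p >= v.size - guard or v[p:].min() > 0:
            truncated += 1
            continue
        kept.append(p)
    if truncated:
        flags.append("truncated-ap-excluded")
    idx = np.asarray(kept, dtype=int)
    return SpikeDetection(sweep.time_ms[idx] if idx.size else np.empty(0),
                          idx, truncated, tuple(flags))


def ap_features(sweep: Sweep, peak_index: int,
                dvdt_criterion: float = DVDT_CRITERION) -> APFeatures:
    """Waveform features of a single AP given its peak sample index."""
    v = sweep.voltage_mv
    dt = sweep.dt_ms
    dvdt = np.gradient(v, dt)

    lo = max(0, peak_index - int(round(5.0 / dt)))
    rising = np.flatnonzero(dvdt[lo:peak_index + 1] >= dvdt_criterion)
    if rising.size == 0:
        raise FeatureFailure("dV/dt never reaches the threshold criterion")
    thr_idx = lo + int(rising[0])
    threshold = float(v[thr_idx])
    peak = float(v[peak_index])
    amplitude = peak - threshold
    if amplitude <= 0:
        raise FeatureFailure("non-positive AP amplitude")
    max_rise = float(dvdt[thr_idx:peak_index + 1].max())

    half_level = threshold + amplitude / 2
    t_up = _crossing_before(v, sweep.time_ms, peak_index, half_level)
    t_down = _crossing_after(v, sweep.time_ms, peak_index, half_level)
    if t_up is None or t_down is None:
        raise FeatureFailure("half-amplitude level not crossed on both sides")
    return APFeatures(threshold, amplitude, float(t_down - t_up), max_rise,
                      float(sweep.time_ms[peak_index]))


def _crossing_before(v, t, peak_index, level):
    for i in range(peak_index, 0, -1):
        if v[i - 1] <= level <= v[i]:
            f = (level - v[i - 1]) / (v[i] - v[i - 1])
            return t[i - 1] + f * (t[i] - t[i - 1])
    return None


def _crossing_after(v, t, peak_index, level):
    for i in range(peak_index, v.size - 1):
        if v[i] >= level >= v[i + 1]:
            f = (v[i] - level) / (v[i] - v[i + 1])
            return t[i] + f * (t[i + 1] - t[i])
    return None


def first_ap_for_waveform(sweep: Sweep, detection: SpikeDetection,
                          step_onset_ms: float,
                          min_latency_ms: float = MIN_FIRST_AP_LATENCY_MS):
    """Index of the first AP fired ≥ ``min_latency_ms`` after step onset,
    or None if the sweep contributes no waveform features."""
    for i, t in enumerate(detection.peak_times_ms):
        if t >= step_onset_ms + min_latency_ms:
            return int(detection.peak_indices[i])
    return None


def rheobase(sweeps: SweepSet, dvdt_criterion: float = DVDT_CRITERION):
    """Smallest injected current eliciting ≥1 AP during the step.

    Returns ``(current_pa, flags)``; ``current_pa`` is NaN with flag
    ``not-reached`` when no sweep spikes, and the result is flagged
    ``at-minimum-tested`` when the lowest sweep already spikes.
    """
    spiking = []
    for s in sweeps.sweeps:
        det = detect_aps(s, dvdt_criterion)
        in_step = [t for t in det.peak_times_ms
                   if sweeps.step_onset_ms <= t
                   <= sweeps.step_onset_ms + sweeps.step_duration_ms + 2.0]
        spiking.append(len(in_step) > 0)
    if not any(spiking):
        return float("nan"), ("not-reached",)
    first = int(np.argmax(spiking))
    flags = ("at-minimum-tested",) if first == 0 else ()
    return float(sweeps.sweeps[first].current_pa), flags


def fi_curve_max_slope(sweeps: SweepSet,
                       dvdt_criterion: float = DVDT_CRITERION):
    """f–I table (firing rate per step) and the maximum finite-difference
    slope f'(max) between consecutive steps, in Hz/pA."""
    if len(sweeps.sweeps) < 2:
        raise ValueError("f-I slope undefined for a single sweep")
    rows = []
    dur_s = sweeps.step_duration_ms / 1000.0
    for s in sweeps.sweeps:
        det = detect_aps(s, dvdt_criterion)
        n = sum(sweeps.step_onset_ms <= t
                <= sweeps.step_onset_ms + sweeps.step_duration_ms + 2.0
                for t in det.peak_times_ms)
        rows.append({"current_pa": s.current_pa, "n_spikes": n,
                     "rate_hz": n / dur_s})
    table = pd.DataFrame(rows)
    di = np.diff(table["current_pa"].to_numpy())
    df_ = np.diff(table["rate_hz"].to_numpy())
    return table, float(np.max(df_ / di))


def passive_properties(sweeps: SweepSet,
                       test_current_pa: float = -100.0) -> PassiveProperties:
    """RMP and input resistance from a hyperpolarizing test step."""
    currents = sweeps.currents()
    neg = np.flatnonzero(currents < 0)
    if neg.size == 0:
        raise ValueError("no hyperpolarizing sweep for passive properties")
    pick = neg[int(np.argmin(np.abs(currents[neg] - test_current_pa)))]
    s = sweeps.sweeps[pick]

    pre = s.voltage_mv[s.time_ms < sweeps.step_onset_ms]
    rmp = float(pre.mean())
    t_end = sweeps.step_onset_ms + sweeps.step_duration_ms
    steady = s.voltage_mv[(s.time_ms >= t_end - 0.25 * sweeps.step_duration_ms)
                          & (s.time_ms < t_end)]
    deflection = float(steady.mean()) - rmp       # mV
    rin = deflection / (s.current_pa * 1e-3)      # mV / nA = MΩ
    flags = ("implausible-rin",) if rin <= 1.0 else ()
    return PassiveProperties(rmp, rin, flags)
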