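"""Current-clamp analysis: spike detection, F-I curves, rheobase,
action-potential threshold/amplitude, rebound-spike counting."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import FitError
from .simulator import Trace

__all__ = [
    "FICurve",
    "detect_spikes",
    "ap_threshold",
    "ap_amplitude",
    "fi_curve",
    "rebound_spikes",
    "SPIKE_PEAK_CUTOFF",
    "THRESHOLD_DVDT",
]

#: A local maximum counts as an action potential only if its peak is
#: depolarized relative to this level (mV).
SPIKE_PEAK_CUTOFF = -10.0

#: AP threshold: voltage where the rate of rise first exceeds 2 V/s.
THRESHOLD_DVDT = 2.0  # mV/ms

#: Minimum separation between detected spike peaks (ms).
MIN_SPIKE_SEPARATION = 2.0

#: Window after stimulus offset in which rebound spikes are counted (ms).
REBOUND_WINDOW = 500.0


@dataclass
class FICurve:
    I_applied: np.ndarray
    spike_count: np.ndarray
    rheobase: float = None  # pA, or None if no step evoked a spike

    def __post_init__(self) -> None:
        self.I_applied = np.asarray(self.I_applied, dtype=float)
        self.spike_count = np.asarray(self.spike_count, dtype=int)
        if np.any(self.spike_count < 0):
            raise ValueError("spike counts must be non-negative")
        if self.rheobase is not None and self.rheobase not in self.I_applied:
            raise ValueError("rheobase must be a member of the tested grid")

    def count_at(self, I: float) -> int:
        idx = np.nonzero(np.isclose(self.I_applied, I))[0]
        if idx.size == 0:
            raise KeyError(f"{I} pA not in the tested grid")
        return int(self.spike_count[idx[0]])


def detect_spikes(trace: Trace, window=None) -> np.ndarray:
    """Times (ms) of action-potential peaks inside ``window``.

    Local maxima exceeding ``SPIKE_PEAK_CUTOFF`` separated by at least
    ``MIN_SPIKE_SEPARATION`` ms.
    """
    dt = trace.dt or 1.0
    distance = max(1, int(round(MIN_SPIKE_SEPARATION / dt)))
    idx, _ = find_peaks(trace.y, height=SPIKE_PEAK_CUTOFF, distance=distance)
    times = trace.t[idx]
    if window is not None:
        t0, t1 = window
        times = times[(times >= t0) & (times <= t1)]
    return times


def ap_threshold(trace: Trace, spike_time: float, lookback: float = 10.0) -> float:
    """Voltage at the first sample before the peak where dV/dt (central
    differences) exceeds 2 V/s, searched within ``lookback`` ms."""
    dt = trace.dt
    dvdt = np.gradient(trace.y, dt)
    peak_idx = int(np.argmin(np.abs(trace.t - spike_time)))
    start = max(0, peak_idx - int(round(lookback / dt)))
    above = np.nonzero(dvdt[start:peak_idx] > THRESHOLD_DVDT)[0]
    if above.size == 0:
        raise FitError("rate of rise never exceeds 2 V/s before the peak")
    return float(trace.y[start + above[0]])


def ap_amplitude(trace: Trace, spike_time: float) -> float:
    """Spike amplitude (mV) measured from threshold to peak."""
    peak_idx = int(np.argmin(np.abs(trace.t - spike_time)))
    return float(trace.y[peak_idx]) - ap_threshold(trace, spike_time)


def fi_curve(traces) -> FICurve:
    """Spike counts during the stimulus window per current step.

    Rheobase is the smallest depolarizing step evoking >= 1 spike."""
    amps, counts = [], []
    for tr in traces:
        amps.append(float(tr.meta["step_pA"]))
        window = tr.meta.get("stim_window")
        counts.append(len(detect_spikes(tr, window)))
    amps = np.asarray(amps)
    counts = np.asarray(counts)
    order = np.argsort(amps)
    amps, counts = amps[order], counts[order]
    firing = (counts >= 1) & (amps > 0)
    rheobase = float(amps[firing][0]) if firing.any() else None
    return FICurve(I_applied=amps, spike_count=counts, rheobase=rheobase)


def rebound_spikes(trace: Trace, offset_time: float = None,
                   window: float = REBOUND_WINDOW) -> int:
    """Number of spikes in ``(offset, offset + window]`` after the end of
    a hyperpolarizing step."""
    if offset_time is None:
        offset_time = trace.meta["stim_window"][1]
    times = detect_spikes(trace)
    return int(np.sum((times > offset_time) & (times <= offset_time + window)))
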