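"""Command-waveform builders for every clamp experiment.

A :class:`StepProtocol` is a piecewise-constant voltage command: a
holding level, an ordered list of segments, and 100-ms pre/post pads at
the holding level for baseline/offset analysis.  Exactly one segment may
vary across sweeps, either in level or in duration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Segment",
    "StepProtocol",
    "CurrentStepProtocol",
    "total_activation",
    "total_inactivation",
    "slow_time_course",
    "fast_protocols",
    "fi_protocol",
    "leak_template_protocol",
    "PROTOCOL_BUILDERS",
]

# Sampling-grid and padding defaults for simulated traces (not stated for
# the simulations; 20 kHz resolves the fast transient).
DT_DEFAULT = 0.05
PAD_DEFAULT = 100.0

# Duration grids for the duration-varying protocols; the source methods
# state ranges only.
SLOW_DURATIONS = (0.0, 50.0, 100.0, 250.0, 500.0, 1000.0, 2000.0, 4000.0, 8000.0)
FAST_DURATIONS = (0.0, 10.0, 25.0, 50.0, 100.0, 150.0, 200.0, 250.0)


@dataclass(frozen=True)
class Segment:
    """One protocol segment; ``level`` or ``duration`` may be a tuple of
    per-sweep values (at most one varying segment per protocol)."""

    level: object  # mV, float or tuple of floats
    duration: object  # ms, float or tuple of floats

    @property
    def varies(self) -> bool:
        return isinstance(self.level, tuple) or isinstance(self.duration, tuple)


@dataclass(frozen=True)
class StepProtocol:
    segments: tuple
    label: str = ""
    holding: float = -70.0
    pre_pad: float = PAD_DEFAULT
    post_pad: float = PAD_DEFAULT
    test_segment: int = -1  # index into ``segments`` analysed as the test pulse

    def __post_init__(self) -> None:
        n_vary = sum(1 for s in self.segments if s.varies)
        if n_vary > 1:
            raise ValueError("at most one segment may vary across sweeps")
        for s in self.segments:
            durs = s.duration if isinstance(s.duration, tuple) else (s.duration,)
            if any(d < 0 for d in durs):
                raise ValueError("segment durations must be non-negative")

    @property
    def n_sweeps(self) -> int:
        for s in self.segments:
            if isinstance(s.level, tuple):
                return len(s.level)
            if isinstance(s.duration, tuple):
                return len(s.duration)
        return 1

    def sweep_segments(self, sweep: int):
        """Fully resolved ``(level, duration)`` list for one sweep,
        including the holding-level pads."""
        if not 0 <= sweep < self.n_sweeps:
            raise IndexError(f"sweep {sweep} out of range")
        out = [(self.holding, self.pre_pad)]
        for s in self.segments:
            level = s.level[sweep] if isinstance(s.level, tuple) else s.level
            dur = s.duration[sweep] if isinstance(s.duration, tuple) else s.duration
            out.append((float(level), float(dur)))
        out.append((self.holding, self.post_pad))
        return out

    def segment_times(self, sweep: int):
        """Absolute ``(t_start, duration, level)`` per segment (pads included)."""
        t = 0.0
        out = []
        for level, dur in self.sweep_segments(sweep):
            out.append((t, dur, level))
            t += dur
        return out

    def total_duration(self, sweep: int) -> float:
        return sum(d for _, d in self.sweep_segments(sweep))

    def command(self, sweep: int, t) -> np.ndarray:
        """Command voltage sampled at times ``t`` (ms)."""
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.holding)
        for t0, dur, level in self.segment_times(sweep):
            out[(t >= t0) & (t < t0 + dur)] = level
        return out

    def test_window(self, sweep: int):
        """(t_start, t_end) of the designated test segment, absolute ms."""
        times = self.segment_times(sweep)
        # +1 offset: segment_times includes the pre-pad at index 0
        idx = self.test_segment if self.test_segment >= 0 else len(self.segments) + self.test_segment
        t0, dur, _ = times[idx + 1]
        return t0, t0 + dur

    def sweep_levels(self):
        """Varying levels (one per sweep) of the level-varying segment."""
        for s in self.segments:
            if isinstance(s.level, tuple):
                return np.asarray(s.level, dtype=float)
        raise ValueError(f"protocol {self.label!r} has no level-varying segment")

    def sweep_durations(self):
        """Varying durations (one per sweep) of the duration-varying segment."""
        for s in self.segments:
            if isinstance(s.duration, tuple):
                return np.asarray(s.duration, dtype=float)
        raise ValueError(f"protocol {self.label!r} has no duration-varying segment")

    def to_json(self) -> str:
        return json.dumps(
            {
                "label": self.label,
                "holding": self.holding,
                "pre_pad": self.pre_pad,
                "post_pad": self.post_pad,
                "test_segment": self.test_segment,
                "segments": [
                    {"level": s.level, "duration": s.duration} for s in self.segments
                ],
            },
            default=list,
        )


@dataclass(frozen=True)
class CurrentStepProtocol:
    """Current-clamp step family; amplitudes are relative to the holding
    current (baseline 0 pA)."""

    steps: tuple
    duration: float = 500.0
    pre: float = 100.0
    post: float = 500.0
    baseline: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("pulse duration must be positive")

    @property
    def n_sweeps(self) -> int:
        return len(self.steps)

    def total_duration(self) -> float:
        return self.pre + self.duration + self.post

    def applied(self, sweep: int, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.baseline)
        on = (t >= self.pre) & (t < self.pre + self.duration)
        out[on] = self.baseline + self.steps[sweep]
        return out


def _levels(lo: float, hi: float, step: float):
    return tuple(float(v) for v in np.arange(lo, hi + step / 2, step))


def total_activation() -> StepProtocol:
    """Hold -100 mV for 5 s, then 1-s test pulses -70..+40 mV (12 sweeps)."""
    return StepProtocol(
        segments=(
            Segment(level=-100.0, duration=5000.0),
            Segment(level=_levels(-70, 40, 10), duration=1000.0),
        ),
        label="total-activation",
        test_segment=1,
    )


def total_inactivation() -> StepProtocol:
    """10-s prepulses -100..-10 mV, then a 1-s test pulse at 0 mV (10 sweeps)."""
    return StepProtocol(
        segments=(
            Segment(level=_levels(-100, -10, 10), duration=10000.0),
            Segment(level=0.0, duration=1000.0),
        ),
        label="total-inactivation",
        test_segment=1,
    )


def slow_time_course():
    """(inactivation-rate, recovery) protocols for the slow transient.

    Rate of inactivation: remove inactivation at -100 mV (5 s), condition
    at -10 mV for 0-8 s, test at 0 mV (1 s).  Recovery: inactivate at
    -10 mV (10 s), recover at -100 mV for 0-8 s, test at 0 mV (1 s).
    """
    inact_rate = StepProtocol(
        segments=(
            Segment(level=-100.0, duration=5000.0),
            Segment(level=-10.0, duration=SLOW_DURATIONS),
            Segment(level=0.0, duration=1000.0),
        ),
        label="slow-inactivation-rate",
        test_segment=2,
    )
    recovery = StepProtocol(
        segments=(
            Segment(level=-10.0, duration=10000.0),
            Segment(level=-100.0, duration=SLOW_DURATIONS),
            Segment(level=0.0, duration=1000.0),
        ),
        label="slow-recovery",
        test_segment=2,
    )
    return inact_rate, recovery


def fast_protocols():
    """(activation A, activation B, inactivation, inactivation-rate,
    recovery) protocols for the fast transient.

    A/B differ only in the 200-ms conditioning level (-100 vs -30 mV);
    subtracting B from A isolates the fast component.
    """
    test_levels = _levels(-70, 40, 10)
    act_a = StepProtocol(
        segments=(
            Segment(level=-100.0, duration=200.0),
            Segment(level=test_levels, duration=150.0),
        ),
        label="fast-activation-A",
        test_segment=1,
    )
    act_b = StepProtocol(
        segments=(
            Segment(level=-30.0, duration=200.0),
            Segment(level=test_levels, duration=150.0),
        ),
        label="fast-activation-B",
        test_segment=1,
    )
    inact = StepProtocol(
        segments=(
            Segment(level=_levels(-100, -20, 10), duration=200.0),
            Segment(level=-10.0, duration=150.0),
        ),
        label="fast-inactivation",
        test_segment=1,
    )
    inact_rate = StepProtocol(
        segments=(
            Segment(level=-100.0, duration=300.0),
            Segment(level=-30.0, duration=FAST_DURATIONS),
            Segment(level=0.0, duration=100.0),
        ),
        label="fast-inactivation-rate",
        test_segment=2,
    )
    recovery = StepProtocol(
        segments=(
            Segment(level=0.0, duration=300.0),
            Segment(level=-100.0, duration=FAST_DURATIONS),
            Segment(level=0.0, duration=100.0),
        ),
        label="fast-recovery",
        test_segment=2,
    )
    return act_a, act_b, inact, inact_rate, recovery


def fi_protocol(experimental: bool = False) -> CurrentStepProtocol:
    """500-ms current-step family.

    ``experimental=True`` returns the slice-recording grid
    (-25..-5 pA by 5, 2..28 pA by 2); otherwise the simulation grid
    (-30..0 pA by 10, 2..28 pA by 2).
    """
    if experimental:
        hyper = tuple(float(v) for v in range(-25, 0, 5))
    else:
        hyper = tuple(float(v) for v in range(-30, 1, 10))
    depol = tuple(float(v) for v in range(2, 29, 2))
    return CurrentStepProtocol(
        steps=hyper + depol,
        duration=500.0,
        pre=100.0,
        post=500.0,
        label="fi-experimental" if experimental else "fi-simulation",
    )


def leak_template_protocol(n_sweeps: int = 1, dV: float = -5.0, duration: float = 20.0) -> StepProtocol:
    """-5 mV test pulse from holding, used for the leak/Cm template."""
    level = -70.0 + dV
    return StepProtocol(
        segments=(Segment(level=(level,) * n_sweeps if n_sweeps > 1 else level, duration=duration),),
        label="leak-template",
        test_segment=0,
        pre_pad=20.0,
        post_pad=20.0,
    )


PROTOCOL_BUILDERS = {
    "total-activation": total_activation,
    "total-inactivation": total_inactivation,
    "slow-inactivation-rate": lambda: slow_time_course()[0],
    "slow-recovery": lambda: slow_time_course()[1],
    "fast-activation-A": lambda: fast_protocols()[0],
    "fast-activation-B": lambda: fast_protocols()[1],
    "fast-inactivation": lambda: fast_protocols()[2],
    "fast-inactivation-rate": lambda: fast_protocols()[3],
    "fast-recovery": lambda: fast_protocols()[4],
    "leak-template": leak_template_protocol,
}
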