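"""Clamp simulation front-end and trace container/IO.

Voltage clamp is ideal (command followed exactly, no series resistance);
the recorded signal is the summed voltage-gated ionic current, outward
positive.  Current clamp integrates the membrane equation from rest.
Traces serialize to CSV (``t_ms, value, sweep``) plus a JSON sidecar of
protocol metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._engine import CompiledModel
from .errors import GridMismatchError
from .neuron import NeuronModel, resting_potential
from .protocols import CurrentStepProtocol, StepProtocol

__all__ = [
    "Trace",
    "run_voltage_clamp",
    "run_current_clamp",
    "run_clamp_to_waveform",
    "write_traces",
    "read_traces",
]

DT_OUTPUT = 0.05  # ms


@dataclass
class Trace:
    """Uniformly sampled time series (pA under clamp, mV under current clamp)."""

    t: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape:
            raise GridMismatchError("t and y must have the same shape")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise GridMismatchError("time grid must be uniform and increasing")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 0.0

    def window(self, t0: float, t1: float) -> "Trace":
        sel = (self.t >= t0 - 1e-9) & (self.t < t1 - 1e-9)
        return Trace(self.t[sel], self.y[sel], dict(self.meta))

    def same_grid(self, other: "Trace") -> bool:
        return self.t.shape == other.t.shape and np.allclose(self.t, other.t, atol=1e-9)


def _vc_meta(protocol: StepProtocol, sweep: int, dt: float) -> dict:
    return {
        "kind": "vc",
        "label": protocol.label,
        "sweep": sweep,
        "holding": protocol.holding,
        "dt": dt,
        "segments": [list(s) for s in protocol.segment_times(sweep)],
        "test_window": list(protocol.test_window(sweep)),
    }


def run_voltage_clamp(
    model: NeuronModel,
    protocol: StepProtocol,
    dt: float = DT_OUTPUT,
    per_channel: bool = False,
):
    """Simulate an ideal voltage-clamp protocol; one current Trace per sweep.

    Segment responses are propagated analytically (gate relaxation in
    closed form), so the result is independent of ``dt`` up to sampling.
    """
    cm = CompiledModel(model)
    traces = []
    for sweep in range(protocol.n_sweeps):
        segs = protocol.sweep_segments(sweep)
        out = cm.voltage_clamp_sweep(segs, dt, init_V=protocol.holding,
                                     per_channel=per_channel)
        meta = _vc_meta(protocol, sweep, dt)
        if per_channel:
            t, I, comps = out
            meta["components"] = {k: v for k, v in comps.items()}
        else:
            t, I = out
        traces.append(Trace(t, I, meta))
    return traces


def run_current_clamp(
    model: NeuronModel,
    protocol: CurrentStepProtocol,
    dt: float = DT_OUTPUT,
    dt_int: float = 0.005,
    V0: float = None,
):
    """Integrate the membrane equation under a current-step family.

    Starts from the model's resting potential (or ``V0``); returns one
    membrane-voltage Trace per sweep, sampled every ``dt`` ms.
    """
    cm = CompiledModel(model)
    if V0 is None:
        V0 = resting_potential(model)
    B = protocol.n_sweeps
    amps = np.asarray(protocol.steps, dtype=float) + protocol.baseline
    record_every = max(1, int(round(dt / dt_int)))
    seg = lambda a, d: (a, int(round(d / dt_int)))
    applied = [
        seg(np.zeros(B) + protocol.baseline, protocol.pre),
        seg(amps, protocol.duration),
        seg(np.zeros(B) + protocol.baseline, protocol.post),
    ]
    t, Vrec = cm.current_clamp(V0, applied, dt_int, record_every)
    traces = []
    for sweep in range(B):
        meta = {
            "kind": "cc",
            "label": protocol.label,
            "sweep": sweep,
            "dt": dt,
            "step_pA": float(protocol.steps[sweep]),
            "stim_window": [protocol.pre, protocol.pre + protocol.duration],
        }
        traces.append(Trace(t, Vrec[sweep], meta))
    return traces


def run_clamp_to_waveform(model: NeuronModel, voltage_trace: Trace) -> Trace:
    """Clamp the membrane to a recorded voltage trajectory and return the
    total ionic current (leak and holding included), for consistency
    checks against the current-clamp path."""
    cm = CompiledModel(model)
    I = cm.clamp_to_waveform(voltage_trace.t, voltage_trace.y)
    meta = dict(voltage_trace.meta)
    meta["kind"] = "vc-waveform"
    return Trace(voltage_trace.t, I, meta)


# ---------------------------------------------------------------------------
# IO


def write_traces(traces, path) -> None:
    """Write traces as CSV (t_ms, value, sweep) + JSON metadata sidecar."""
    path = Path(path)
    frames = []
    metas = {}
    for tr in traces:
        sweep = int(tr.meta.get("sweep", len(frames)))
        frames.append(pd.DataFrame({"t_ms": tr.t, "value": tr.y, "sweep": sweep}))
        metas[str(sweep)] = {k: v for k, v in tr.meta.items() if k != "components"}
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(metas, indent=1))


def read_traces(path):
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    metas = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    traces = []
    for sweep, grp in df.groupby("sweep"):
        meta = metas.get(str(int(sweep)), {"sweep": int(sweep)})
        traces.append(Trace(grp["t_ms"].to_numpy(), grp["value"].to_numpy(), meta))
    return traces
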