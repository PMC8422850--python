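"""Voltage-clamp trace analysis.

Leak/capacitance subtraction (scaled-template and P/N), peak extraction,
conversion of peak currents to normalized conductance via the GHK
driving force, and Boltzmann / single-exponential curve fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from ._engine import ghk_drive
from .errors import FitError, GridMismatchError
from .gating import VT_DEFAULT
from .simulator import Trace

__all__ = [
    "IVCurve",
    "BoltzmannFit",
    "ExpFit",
    "offline_leak_subtract",
    "pn_subtract",
    "peak_current",
    "normalized_ghk_conductance",
    "fit_boltzmann",
    "fit_exponential",
    "voltage_subtraction_isolate",
    "activation_curve",
    "SLOW_PEAK_WINDOW",
]

#: Analysis reversal potential for K+ permeability conversion (mV).  This
#: is the analysis-pipeline constant and is deliberately distinct from the
#: model K+ reversal of -92 mV; the two are never unified.
EREV_ANALYSIS = -94.0

#: Peak-search window (ms after test-pulse onset) for the slow-recovery
#: protocol, chosen to skip the early fast-transient contamination.
SLOW_PEAK_WINDOW = (70.0, 150.0)


@dataclass
class IVCurve:
    """Per-sweep peak current (pA or pA/pF) against test/prepulse voltage."""

    V: np.ndarray
    peak: np.ndarray
    window: tuple = None

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.peak = np.asarray(self.peak, dtype=float)
        if self.V.shape != self.peak.shape:
            raise GridMismatchError("one peak per sweep required")


@dataclass
class BoltzmannFit:
    V50: float
    k: float
    gmax: float
    residual: float

    def __call__(self, V):
        return self.gmax * expit(-(np.asarray(V, dtype=float) - self.V50) / self.k)


@dataclass
class ExpFit:
    tau: float
    amplitude: float
    offset: float
    residual: float

    def __call__(self, t):
        return self.amplitude * np.exp(-np.asarray(t, dtype=float) / self.tau) + self.offset


# ---------------------------------------------------------------------------
# subtraction


def _template_parts(template: Trace, step_duration_key: str = "test_window"):
    """Split a -5 mV template response into (baseline, transient, plateau).

    The plateau is the mean of the last quarter of the step; the
    transient is the remainder of the in-step response."""
    t0, t1 = template.meta["test_window"]
    sel = (template.t >= t0 - 1e-9) & (template.t < t1 - 1e-9)
    base_sel = template.t < t0 - 1e-9
    baseline = float(np.mean(template.y[base_sel])) if base_sel.any() else 0.0
    step = template.y[sel] - baseline
    n = len(step)
    plateau = float(np.mean(step[int(0.75 * n):]))
    transient = step - plateau
    return transient, plateau


def offline_leak_subtract(trace: Trace, template: Trace, dV_template: float = -5.0) -> Trace:
    """Scaled-template leak and capacitive-transient subtraction.

    The averaged response to -5 mV pulses is decomposed into a steady
    leak plateau and an onset transient.  Per protocol segment, the
    plateau is scaled by (segment level - holding)/dV and subtracted;
    the transient is scaled by the voltage jump at each segment edge.
    Requires segment metadata on ``trace``.
    """
    if "segments" not in trace.meta:
        raise GridMismatchError("trace lacks protocol segment metadata")
    transient, plateau = _template_parts(template)
    holding = trace.meta.get("holding", -70.0)
    y = trace.y.copy()
    prev_level = holding
    for t0, dur, level in trace.meta["segments"]:
        if dur <= 0:
            prev_level = level
            continue
        sel = np.nonzero((trace.t >= t0 - 1e-9) & (trace.t < t0 + dur - 1e-9))[0]
        y[sel] -= plateau * (level - holding) / dV_template
        edge_scale = (level - prev_level) / dV_template
        if edge_scale != 0.0 and sel.size:
            m = min(len(transient), sel.size)
            y[sel[:m]] -= transient[:m] * edge_scale
        prev_level = level
    meta = dict(trace.meta)
    meta["leak_subtracted"] = True
    return Trace(trace.t, y, meta)


def pn_subtract(main: Trace, subsweeps, n: int = -5) -> Trace:
    """P/N online leak subtraction.

    ``subsweeps`` are |n| responses to the command scaled by 1/n around
    the holding level (n < 0: inverted sub-pulses).  Each sweep is
    baseline-corrected on its pre-pulse window, then the sub-responses
    are summed and combined with the main sweep so that any linear
    (leak) component cancels.
    """
    if n == 0:
        raise ValueError("n must be nonzero")
    if len(subsweeps) < abs(n):
        raise GridMismatchError(f"need {abs(n)} subsweeps, got {len(subsweeps)}")
    for s in subsweeps:
        if not main.same_grid(s):
            raise GridMismatchError("subsweep grid does not match main sweep")

    def _debase(tr: Trace) -> np.ndarray:
        segs = tr.meta.get("segments")
        if segs:
            t0 = segs[0][0] + segs[0][1]  # end of pre-pad
            base = float(np.mean(tr.y[tr.t < t0 - 1e-9])) if np.any(tr.t < t0 - 1e-9) else 0.0
        else:
            base = float(np.mean(tr.y[: max(1, len(tr.y) // 50)]))
        return tr.y - base

    total_sub = np.sum([_debase(s) for s in subsweeps[: abs(n)]], axis=0)
    sign = -1.0 if n > 0 else 1.0
    y = _debase(main) + sign * total_sub
    meta = dict(main.meta)
    meta["pn_subtracted"] = n
    return Trace(main.t, y, meta)


def voltage_subtraction_isolate(traceA: Trace, traceB: Trace) -> Trace:
    """Pointwise A - B (fast-component isolation by prepulse subtraction)."""
    if not traceA.same_grid(traceB):
        raise GridMismatchError("traces are on different grids")
    meta = dict(traceA.meta)
    meta["isolated"] = "A-B"
    return Trace(traceA.t, traceA.y - traceB.y, meta)


# ---------------------------------------------------------------------------
# peaks and curves


def peak_current(trace: Trace, window=None) -> float:
    """Maximum current inside ``window`` (absolute ms); defaults to the
    trace's test-pulse window from metadata, else the whole trace."""
    if window is None:
        window = trace.meta.get("test_window")
    if window is None:
        sel = slice(None)
    else:
        t0, t1 = window
        sel = (trace.t >= t0 - 1e-9) & (trace.t < t1 - 1e-9)
        if not np.any(sel):
            raise ValueError("empty peak-search window")
    return float(np.max(trace.y[sel]))


def normalized_ghk_conductance(iv: IVCurve, Erev: float = EREV_ANALYSIS,
                               VT: float = VT_DEFAULT) -> IVCurve:
    """Convert peak currents to normalized permeability.

    Each peak is divided by the GHK driving force at its test potential
    (points at the reversal are dropped), then the curve is normalized to
    its maximum."""
    keep = np.abs(iv.V - Erev) > 1e-9
    V = iv.V[keep]
    g = iv.peak[keep] / ghk_drive(V, Erev, VT)
    gmax = np.max(np.abs(g))
    if gmax == 0:
        raise ValueError("all-zero peak currents")
    return IVCurve(V=V, peak=g / np.max(g), window=iv.window)


def _multistart_lsq(residual, starts, bounds=None):
    best = None
    for x0 in starts:
        try:
            res = least_squares(residual, x0, bounds=bounds or (-np.inf, np.inf))
        except ValueError:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError("least-squares fit did not converge from any start")
    return best


def fit_boltzmann(V, g) -> BoltzmannFit:
    """Least-squares Boltzmann fit ``gmax / (1 + exp((V - V50)/k))``.

    Multi-start trust-region least squares; raises ``FitError`` for
    degenerate (flat or non-converging) inputs.
    """
    V = np.asarray(V, dtype=float)
    g = np.asarray(g, dtype=float)
    if len(V) < 4:
        raise FitError("need at least 4 points to fit a Boltzmann")
    if np.ptp(g) < 1e-3:
        raise FitError("input curve is flat; Boltzmann parameters unidentifiable")

    gmax0 = float(np.max(g))
    # crude midpoint estimate from the half-maximum crossing
    order = np.argsort(V)
    Vs, gs = V[order], g[order]
    half = gmax0 / 2
    cross = np.nonzero(np.diff(np.sign(gs - half)))[0]
    V50_0 = float(Vs[cross[0]]) if cross.size else float(np.median(Vs))
    rising = gs[-1] > gs[0]
    k0 = -8.0 if rising else 8.0

    def residual(p):
        V50, k, gmax = p
        return gmax * expit(-(V - V50) / k) - g

    starts = [
        (V50_0, k0, gmax0),
        (V50_0 - 10.0, 2 * k0, gmax0),
        (V50_0 + 10.0, 0.5 * k0, 1.2 * gmax0),
    ]
    best = _multistart_lsq(residual, starts)
    V50, k, gmax = best.x
    fit = BoltzmannFit(V50=float(V50), k=float(k), gmax=float(gmax),
                       residual=float(np.sum(best.fun**2)))
    if abs(fit.k) > 1e3 or not np.isfinite(fit.V50):
        raise FitError("degenerate Boltzmann fit (unbounded slope)")
    return fit


def fit_exponential(t, y) -> ExpFit:
    """Fit ``y = a * exp(-t / tau) + c`` with tau > 0 enforced."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 4:
        raise FitError("need at least 4 points to fit an exponential")
    if np.ptp(y) < 1e-6:
        raise FitError("input curve is flat; exponential fit is degenerate")

    c0 = float(y[np.argmax(t)])
    a0 = float(y[np.argmin(t)] - c0) or 1.0
    span = float(np.ptp(t)) or 1.0

    def residual(p):
        log_tau, a, c = p
        return a * np.exp(-t / np.exp(log_tau)) + c - y

    starts = [
        (np.log(span / 3), a0, c0),
        (np.log(span), a0, c0),
        (np.log(span / 10), a0, c0),
    ]
    best = _multistart_lsq(residual, starts)
    log_tau, a, c = best.x
    return ExpFit(tau=float(np.exp(log_tau)), amplitude=float(a), offset=float(c),
                  residual=float(np.sum(best.fun**2)))


# ---------------------------------------------------------------------------
# convenience pipeline pieces


def activation_curve(traces, window=None) -> IVCurve:
    """Peaks of each sweep's test pulse against its test level."""
    V, peaks = [], []
    for tr in traces:
        tw = tr.meta.get("test_window")
        if window is not None and tw is not None:
            t0 = tw[0]
            w = (t0 + window[0], t0 + window[1])
        else:
            w = tw
        peaks.append(peak_current(tr, w))
        t0, dur, level = _segment_for_window(tr)
        V.append(level)
    return IVCurve(V=np.array(V), peak=np.array(peaks), window=window)


def _segment_for_window(tr: Trace):
    """Segment record matching the trace's test window."""
    tw = tr.meta.get("test_window")
    if tw is None:
        raise GridMismatchError("trace lacks a test window")
    for t0, dur, level in tr.meta["segments"]:
        if abs(t0 - tw[0]) < 1e-9:
            return t0, dur, level
    raise GridMismatchError("no segment matches the test window")
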