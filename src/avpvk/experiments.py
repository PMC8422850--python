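"""In-silico study orchestration.

Reproduces the modelling experiments end to end: voltage-clamp panel
fits per component and stage, the current-clamp F-I comparison, rheobase
action-potential metrics, and the conductance-swap suite (hybrid models
with individual or multiple conductances substituted between stages).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import vc_analysis as va
from .cc_analysis import FICurve, ap_amplitude, ap_threshold, detect_spikes, fi_curve, rebound_spikes
from .neuron import NeuronModel, calibrate, isolate, preset, swap
from .protocols import (
    Segment,
    StepProtocol,
    fast_protocols,
    fi_protocol,
    total_activation,
    total_inactivation,
)
from .simulator import run_current_clamp, run_voltage_clamp

__all__ = [
    "reproduce_vc_panels",
    "swap_suite",
    "rheobase_ap_comparison",
    "SwapResult",
    "HYBRID_SWAPS",
    "calibrated_preset",
    "run_all",
]

#: Hybrid definitions: channels of the diestrous base replaced by their
#: proestrous counterparts (the two non-hybrid models are included for
#: comparison).
HYBRID_SWAPS = {
    "di full": (),
    "pro full": None,  # sentinel: the plain proestrous model
    "di+proK": ("slow", "fast", "resid"),
    "di+proSlow": ("slow",),
    "di+proFast": ("fast",),
    "di+proResid": ("resid",),
    "di+proCaT": ("CaT",),
    "di+proNaP": ("NaP",),
    "di+proH": ("h",),
    "di+proInward": ("CaT", "NaP", "h"),
}

_REBOUND_STEP = -30.0


def calibrated_preset(stage: str) -> NeuronModel:
    """Stage preset after leak/holding calibration (-70 mV rest, 1 GOhm)."""
    return calibrate(preset(stage))


def _inactivation_curve(traces, protocol: StepProtocol):
    peaks = np.array([va.peak_current(tr) for tr in traces])
    V = protocol.sweep_levels()
    return va.IVCurve(V=V, peak=peaks / np.max(peaks))


def _long_inactivation_protocol(test_level: float) -> StepProtocol:
    """10-s prepulse inactivation family with a 1-s test pulse."""
    levels = tuple(float(v) for v in np.arange(-100.0, -9.9, 10.0))
    return StepProtocol(
        segments=(
            Segment(level=levels, duration=10000.0),
            Segment(level=test_level, duration=1000.0),
        ),
        label=f"inactivation-10s-{test_level:g}",
        test_segment=1,
    )


def reproduce_vc_panels(stage: str, model: NeuronModel = None) -> pd.DataFrame:
    """Run the per-component clamp protocols and analysis chain.

    Returns a tidy frame of recovered Boltzmann parameters per component:
    activation V50/k (GHK-converted peaks) and inactivation V50/k (both
    the published protocol and a fully-equilibrated 10-s prepulse
    variant).
    """
    base = model if model is not None else preset(stage)
    rows = []

    def add(component, measure, value):
        rows.append({"stage": stage, "component": component,
                     "measure": measure, "value": float(value)})

    # slow: drug-isolated recordings use the long total-current protocols
    slow = isolate(base, "slow")
    act = run_voltage_clamp(slow, total_activation())
    norm = va.normalized_ghk_conductance(va.activation_curve(act))
    fit = va.fit_boltzmann(norm.V, norm.peak)
    add("slow", "act_V50", fit.V50)
    add("slow", "act_k", fit.k)

    inact_proto = total_inactivation()
    inact = run_voltage_clamp(slow, inact_proto)
    curve = _inactivation_curve(inact, inact_proto)
    fit = va.fit_boltzmann(curve.V, curve.peak)
    add("slow", "inact_V50", fit.V50)
    add("slow", "inact_k", fit.k)

    # fast: voltage-subtraction (protocol A - protocol B).  The isolated
    # fast channel is used: with the tabulated (slow) residual
    # inactivation gate, the residual component is not steady between the
    # -100 and -30 mV conditioning levels and would leak into A - B.
    fast_only = isolate(base, "fast")
    act_a, act_b, inact_fast, _, _ = fast_protocols()
    A = run_voltage_clamp(fast_only, act_a)
    B = run_voltage_clamp(fast_only, act_b)
    isolated = [va.voltage_subtraction_isolate(a, b) for a, b in zip(A, B)]
    norm = va.normalized_ghk_conductance(va.activation_curve(isolated))
    fit = va.fit_boltzmann(norm.V, norm.peak)
    add("fast", "act_V50", fit.V50)
    add("fast", "act_k", fit.k)

    inact_traces = run_voltage_clamp(fast_only, inact_fast)
    curve = _inactivation_curve(inact_traces, inact_fast)
    fit = va.fit_boltzmann(curve.V, curve.peak)
    add("fast", "inact_V50", fit.V50)
    add("fast", "inact_k", fit.k)

    long_proto = _long_inactivation_protocol(test_level=-10.0)
    long_traces = run_voltage_clamp(fast_only, long_proto)
    curve = _inactivation_curve(long_traces, long_proto)
    fit = va.fit_boltzmann(curve.V, curve.peak)
    add("fast", "inact10s_V50", fit.V50)
    add("fast", "inact10s_k", fit.k)

    # residual: activation from the protocol-B response (fast inactivated)
    resid_only = isolate(base, "resid")
    Bres = run_voltage_clamp(resid_only, act_b)
    norm = va.normalized_ghk_conductance(va.activation_curve(Bres))
    fit = va.fit_boltzmann(norm.V, norm.peak)
    add("resid", "act_V50", fit.V50)
    add("resid", "act_k", fit.k)

    return pd.DataFrame(rows)


@dataclass
class SwapResult:
    name: str
    model: NeuronModel
    fi: FICurve
    rebound: int
    traces: list = None

    @property
    def total_spikes(self) -> int:
        return int(np.sum(self.fi.spike_count[self.fi.I_applied > 0]))


def _fi_and_rebound(model: NeuronModel, dt_int: float, keep_traces: bool = False) -> tuple:
    proto = fi_protocol(experimental=False)
    traces = run_current_clamp(model, proto, dt_int=dt_int)
    fi = fi_curve(traces)
    rebound_trace = traces[int(np.argmin(np.abs(np.array(proto.steps) - _REBOUND_STEP)))]
    n_rebound = rebound_spikes(rebound_trace)
    return fi, n_rebound, (traces if keep_traces else None)


def swap_suite(di: NeuronModel = None, pro: NeuronModel = None,
               dt_int: float = 0.005, keep_traces: bool = False) -> dict:
    """Run the full hybrid-model comparison.

    Every hybrid is re-calibrated before testing (baseline potential and
    input resistance are identical across models by construction), then
    run through the simulation F-I grid and the -30 pA rebound test.
    Returns ``{name: SwapResult}``.
    """
    di = di if di is not None else calibrated_preset("diestrus")
    pro = pro if pro is not None else calibrated_preset("proestrus")
    results = {}
    for name, channels in HYBRID_SWAPS.items():
        if channels is None:
            model = pro
        elif not channels:
            model = di
        else:
            model = swap(di, pro, channels)
        fi, reb, traces = _fi_and_rebound(model, dt_int, keep_traces)
        results[name] = SwapResult(name=name, model=model, fi=fi, rebound=reb,
                                   traces=traces)
    return results


def swap_suite_table(results: dict) -> pd.DataFrame:
    """Tidy (hybrid, metric, value) table of a swap-suite run."""
    rows = []
    for name, res in results.items():
        rows.append({"hybrid": name, "metric": "rheobase_pA",
                     "value": np.nan if res.fi.rheobase is None else res.fi.rheobase})
        rows.append({"hybrid": name, "metric": "rebound_spikes", "value": res.rebound})
        rows.append({"hybrid": name, "metric": "total_spikes", "value": res.total_spikes})
        for I, n in zip(res.fi.I_applied, res.fi.spike_count):
            rows.append({"hybrid": name, "metric": f"spikes@{I:g}pA", "value": n})
    return pd.DataFrame(rows)


def rheobase_ap_comparison(di: NeuronModel = None, pro: NeuronModel = None,
                           dt_int: float = 0.005) -> pd.DataFrame:
    """Rheobase action-potential threshold and amplitude per stage."""
    rows = []
    for stage, model in (("diestrus", di), ("proestrus", pro)):
        model = model if model is not None else calibrated_preset(stage)
        proto = fi_protocol(experimental=False)
        traces = run_current_clamp(model, proto, dt_int=dt_int)
        fi = fi_curve(traces)
        if fi.rheobase is None:
            rows.append({"stage": stage, "rheobase_pA": np.nan,
                         "threshold_mV": np.nan, "amplitude_mV": np.nan})
            continue
        idx = int(np.nonzero(np.isclose(fi.I_applied, fi.rheobase))[0][0])
        trace = traces[int(np.argmin(np.abs(np.array(proto.steps) - fi.rheobase)))]
        spikes = detect_spikes(trace, trace.meta["stim_window"])
        rows.append({
            "stage": stage,
            "rheobase_pA": fi.rheobase,
            "threshold_mV": ap_threshold(trace, spikes[0]),
            "amplitude_mV": ap_amplitude(trace, spikes[0]),
        })
    return pd.DataFrame(rows)


def run_all(outdir, dt_int: float = 0.005) -> None:
    """Run every study and persist tidy CSV/JSON results under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panels = pd.concat([reproduce_vc_panels(s) for s in ("diestrus", "proestrus")],
                       ignore_index=True)
    panels.to_csv(outdir / "vc_panels.csv", index=False)

    di = calibrated_preset("diestrus")
    pro = calibrated_preset("proestrus")
    results = swap_suite(di, pro, dt_int=dt_int)
    swap_suite_table(results).to_csv(outdir / "swap_suite.csv", index=False)
    rheobase_ap_comparison(di, pro, dt_int=dt_int).to_csv(
        outdir / "rheobase_ap.csv", index=False)

    manifest = {
        name: {"label": res.model.label, "g_leak": res.model.g_leak,
               "Ihold": res.model.Ihold,
               "gbar": {c.name: c.gbar for c in res.model.conductances}}
        for name, res in results.items()
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
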