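"""Synthetic whole-cell recording generator.

Wraps the ideal clamp simulator in an in-silico "rig": per-cell
lognormal conductance scatter anchored to the stage presets, passive
properties drawn around the population means, linear leak current,
capacitive transients at step edges, additive Gaussian noise, and
multiplicative per-component drug suppression (TEA / 4-AP conditions).
All cells satisfy the recording inclusion criteria by construction
(Rs < 20 MOhm, Rinput > 500 MOhm, Cm 8-30 pF, Ihold -60..10 pA).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import InvalidSpecError
from .neuron import NeuronModel, preset
from .protocols import StepProtocol, leak_template_protocol
from .simulator import Trace, run_voltage_clamp

__all__ = [
    "SyntheticCell",
    "DrugCondition",
    "RecordingBundle",
    "sample_cell",
    "record",
    "apply_drug",
    "calibrate_drug",
    "TEA_DEFAULT",
    "FOURAP_DEFAULT",
    "population_peak_ratio",
]

#: Population means for passive-property sampling (Rs MOhm, Rinput MOhm,
#: Cm pF, Ihold pA) and their sampling SDs.
PASSIVE_MEANS = {"Rs": 15.8, "Rinput": 1000.0, "Cm": 17.62, "Ihold": -20.0}
PASSIVE_SDS = {"Rs": 1.5, "Rinput": 120.0, "Cm": 2.0, "Ihold": 8.0}
PASSIVE_BOUNDS = {
    "Rs": (1.0, 20.0),
    "Rinput": (500.0, 2500.0),
    "Cm": (8.0, 30.0),
    "Ihold": (-60.0, 10.0),
}

SIGMA_LOG_DEFAULT = 0.25

#: Default per-component suppression factors; starting points for
#: calibration against the printed population peak ratios, not
#: measurements.
TEA_DEFAULT = {"slow": 0.15, "resid": 0.35, "fast": 0.80}
FOURAP_DEFAULT = {"fast": 0.10, "slow": 0.85, "resid": 0.95}


@dataclass(frozen=True)
class DrugCondition:
    """Multiplicative gbar suppression per component; factors in [0, 1]."""

    name: str
    suppression: dict

    def __post_init__(self) -> None:
        for comp, f in self.suppression.items():
            if not 0.0 <= f <= 1.0:
                raise InvalidSpecError(f"suppression factor for {comp} outside [0, 1]")


@dataclass
class SyntheticCell:
    """One simulated cell: a base model plus its rig-level parameters."""

    base: NeuronModel
    gbar_multipliers: dict
    Rs: float  # MOhm
    Rinput: float  # MOhm
    Cm: float  # pF
    Ihold: float  # pA
    seed: int = None

    def __post_init__(self) -> None:
        for name, f in self.gbar_multipliers.items():
            if f <= 0:
                raise InvalidSpecError(f"gbar multiplier for {name} must be positive")
        for key in ("Rs", "Rinput", "Cm", "Ihold"):
            lo, hi = PASSIVE_BOUNDS[key]
            if not lo <= getattr(self, key) <= hi:
                raise InvalidSpecError(f"{key}={getattr(self, key)} outside plausibility bounds")

    @property
    def model(self) -> NeuronModel:
        return self.base.scaled(self.gbar_multipliers)

    @property
    def g_leak_pipette(self) -> float:
        """Leak conductance implied by the cell's input resistance (nS)."""
        return 1e3 / self.Rinput


@dataclass
class RecordingBundle:
    """Sweeps plus the auxiliary recordings the analysis chain needs."""

    sweeps: list
    template: Trace = None  # averaged -5 mV pulse response
    pn_subsweeps: list = None  # per main sweep: list of P/N sub-responses


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def sample_cell(stage: str, seed: int = None, sigma_log: float = SIGMA_LOG_DEFAULT,
                base: NeuronModel = None) -> SyntheticCell:
    """Draw one synthetic cell around the stage preset.

    Conductance multipliers are lognormal with median 1 (``sigma_log`` the
    SD of the underlying normal); passive properties are truncated
    normals around the population means.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    model = base if base is not None else preset(stage)
    multipliers = {
        name: float(np.exp(rng.normal(0.0, sigma_log))) for name in model.channel_names
    }
    passive = {
        key: _truncated_normal(rng, PASSIVE_MEANS[key], PASSIVE_SDS[key], *PASSIVE_BOUNDS[key])
        for key in ("Rs", "Rinput", "Cm", "Ihold")
    }
    return SyntheticCell(base=model, gbar_multipliers=multipliers, seed=seed, **passive)


def apply_drug(cell: SyntheticCell, condition: DrugCondition) -> SyntheticCell:
    """Scale the named components' gbar multipliers by the drug factors."""
    mult = dict(cell.gbar_multipliers)
    for comp, f in condition.suppression.items():
        if comp not in mult:
            raise KeyError(f"unknown component {comp!r}")
        mult[comp] = mult[comp] * f
    return dataclasses.replace(cell, gbar_multipliers=mult)


def _artifact_trace(cell: SyntheticCell, trace: Trace) -> np.ndarray:
    """Linear leak plus capacitive edge transients for one clamp sweep."""
    g_leak = cell.g_leak_pipette  # nS
    E_leak = trace.meta.get("holding", -70.0)
    V = np.full(len(trace.t), trace.meta.get("holding", -70.0))
    for t0, dur, level in trace.meta["segments"]:
        V[(trace.t >= t0 - 1e-9) & (trace.t < t0 + dur - 1e-9)] = level
    artifact = g_leak * (V - E_leak)
    tau_c = cell.Rs * cell.Cm * 1e-3  # ms
    prev = trace.meta.get("holding", -70.0)
    for t0, dur, level in trace.meta["segments"]:
        if dur <= 0:
            prev = level
            continue
        dV = level - prev
        if dV != 0.0:
            sel = (trace.t >= t0 - 1e-9) & (trace.t < t0 + dur - 1e-9)
            tl = trace.t[sel] - t0
            # peak dV/Rs in pA: mV / MOhm = nA
            artifact[sel] += 1e3 * dV / cell.Rs * np.exp(-tl / tau_c)
        prev = level
    return artifact


def record(cell: SyntheticCell, protocol: StepProtocol, noise_sd: float = 5.0,
           artifacts: bool = True, seed: int = None, pn: int = None) -> RecordingBundle:
    """Simulate a clamp recording of ``cell`` through the in-silico rig.

    Adds (optionally) the linear leak current, capacitive transients at
    step edges, and white Gaussian noise; also emits the averaged -5 mV
    template response and, if ``pn`` is given, the P/N sub-sweep
    responses needed for online subtraction.
    """
    rng = np.random.default_rng(seed)
    model = cell.model
    sweeps = run_voltage_clamp(model, protocol)
    out = []
    for tr in sweeps:
        y = tr.y.copy()
        if artifacts:
            y = y + _artifact_trace(cell, tr)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=len(y))
        out.append(Trace(tr.t, y, dict(tr.meta)))

    # -5 mV template, averaged over 100 repeats -> noise shrinks 10x
    template_proto = leak_template_protocol()
    tmpl = run_voltage_clamp(model, template_proto)[0]
    ty = tmpl.y.copy()
    if artifacts:
        ty = ty + _artifact_trace(cell, tmpl)
    if noise_sd > 0:
        ty = ty + rng.normal(0.0, noise_sd / np.sqrt(100.0), size=len(ty))
    template = Trace(tmpl.t, ty, dict(tmpl.meta))

    pn_subs = None
    if pn:
        pn_subs = []
        for sweep in range(protocol.n_sweeps):
            subs = []
            scaled_segments = [
                (protocol.holding + (level - protocol.holding) / pn, dur)
                for level, dur in protocol.sweep_segments(sweep)
            ]
            from ._engine import CompiledModel

            cm = CompiledModel(model)
            t, I = cm.voltage_clamp_sweep(scaled_segments, out[sweep].dt,
                                          init_V=protocol.holding)
            meta = dict(out[sweep].meta)
            meta["pn_scale"] = pn
            for _ in range(abs(pn)):
                y = I.copy()
                if artifacts:
                    sub_meta = dict(meta)
                    sub_meta["segments"] = [
                        [t0, dur, protocol.holding + (level - protocol.holding) / pn]
                        for t0, dur, level in meta["segments"]
                    ]
                    y = y + _artifact_trace(cell, Trace(t, I, sub_meta))
                if noise_sd > 0:
                    y = y + rng.normal(0.0, noise_sd, size=len(y))
                subs.append(Trace(t, y, meta))
            pn_subs.append(subs)

    return RecordingBundle(sweeps=out, template=template, pn_subsweeps=pn_subs)


# ---------------------------------------------------------------------------
# drug-condition calibration against the printed population ratios


def population_peak_ratio(condition: DrugCondition, stage: str = "diestrus",
                          n_cells: int = 200, sigma_log: float = SIGMA_LOG_DEFAULT,
                          seed: int = 0, test_level: float = 40.0) -> float:
    """Mean peak total-K current at the +40 mV test pulse of drug-treated
    cells over untreated cells (independent populations, paired seeds are
    deliberately not used)."""
    from .protocols import Segment

    proto = StepProtocol(
        segments=(
            Segment(level=-100.0, duration=5000.0),
            Segment(level=(test_level,), duration=1000.0),
        ),
        label="plus40-probe",
        test_segment=1,
    )
    blocked = {"NaP": 0.0, "CaT": 0.0, "nat": 0.0, "h": 0.0}  # TTX/Cd/Ni analogue
    peaks_ctrl, peaks_drug = [], []
    for i in range(n_cells):
        ctrl = sample_cell(stage, seed=1_000_000 * (seed + 1) + i, sigma_log=sigma_log)
        drug = sample_cell(stage, seed=2_000_000 * (seed + 1) + i, sigma_log=sigma_log)
        drug = apply_drug(drug, condition)
        for cell, sink in ((ctrl, peaks_ctrl), (drug, peaks_drug)):
            sweep = run_voltage_clamp(cell.model.scaled(blocked), proto, dt=0.2)[0]
            sink.append(np.max(sweep.y[(sweep.t >= sweep.meta["test_window"][0])]))
    return float(np.mean(peaks_drug) / np.mean(peaks_ctrl))


def calibrate_drug(condition: DrugCondition, target_ratio: float,
                   stage: str = "diestrus", n_cells: int = 200, seed: int = 0,
                   max_iter: int = 8, tol: float = 0.01) -> DrugCondition:
    """Scale the block depth of a drug condition so the population peak
    ratio at +40 mV matches ``target_ratio``.

    The suppression factors move along ``f(lam) = 1 - lam * (1 - f0)``;
    ``lam`` is adjusted by secant iteration on the measured ratio.
    """
    base = {k: v for k, v in condition.suppression.items()}

    def with_lam(lam: float) -> DrugCondition:
        supp = {k: float(np.clip(1.0 - lam * (1.0 - f), 0.0, 1.0)) for k, f in base.items()}
        return DrugCondition(name=condition.name, suppression=supp)

    lam0, lam1 = 1.0, None
    r0 = population_peak_ratio(with_lam(lam0), stage, n_cells, seed=seed)
    if abs(r0 - target_ratio) <= tol:
        return with_lam(lam0)
    # linear model: ratio(0) = 1 -> initial secant through (0, 1)
    lam1 = lam0 * (1.0 - target_ratio) / max(1.0 - r0, 1e-9)
    for _ in range(max_iter):
        lam1 = float(np.clip(lam1, 0.0, 1.0 / max(1.0 - min(base.values()), 1e-9)))
        r1 = population_peak_ratio(with_lam(lam1), stage, n_cells, seed=seed)
        if abs(r1 - target_ratio) <= tol:
            return with_lam(lam1)
        if abs(r1 - r0) < 1e-9:
            break
        lam0, lam1, r0 = lam1, lam1 + (target_ratio - r1) * (lam1 - lam0) / (r1 - r0), r1
    return with_lam(lam1)
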