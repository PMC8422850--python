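"""Single-compartment neuron models.

A :class:`NeuronModel` bundles the membrane capacitance, a set of
Hodgkin-Huxley conductances, a three-state Markov transient-sodium
channel, an Ohmic leak, and a holding current.  Stage presets
(``diestrus`` / ``proestrus``) ship as YAML files under
``avpvk/presets/`` and carry the published parameter values verbatim.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from scipy.special import expit

from .errors import CalibrationError, DegenerateError, InvalidSpecError
from .gating import (
    VT_DEFAULT,
    DrivingForce,
    DrivingLaw,
    GatingSpec,
    SignConvention,
    TauForm,
    TauSpec,
    driving,
    steady_state,
)

__all__ = [
    "RateSpec",
    "MarkovNaTSpec",
    "ConductanceSpec",
    "NeuronModel",
    "ModelState",
    "preset",
    "markov_rates",
    "markov_steady_state",
    "steady_state_model",
    "steady_ionic_current",
    "resting_potential",
    "calibrate",
    "measure_input_resistance",
    "swap",
    "isolate",
    "STAGES",
]

STAGES = ("diestrus", "proestrus")


@dataclass(frozen=True)
class RateSpec:
    """Sigmoidal transition rate ``r / (1 + exp((V + s) / k))`` in 1/ms."""

    s: float
    k: float
    r: float

    def __call__(self, V):
        out = self.r * expit(-(np.asarray(V, dtype=float) + self.s) / self.k)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class MarkovNaTSpec:
    """Three-state (closed/open/inactivated) transient Na+ channel.

    Transitions: C -> O at ``alpha``, O -> C at ``beta``, O -> I at
    ``r1``, I -> C at ``r3``.  Current is
    ``gbar * O**open_exponent * (V - E)``.
    """

    gbar: float
    E: float
    alpha: RateSpec
    beta: RateSpec
    r1: RateSpec
    r3: RateSpec
    open_exponent: int = 3

    def __post_init__(self) -> None:
        if self.gbar < 0:
            raise InvalidSpecError("NaT gbar must be non-negative")
        if self.open_exponent < 1:
            raise InvalidSpecError("open exponent must be >= 1")


@dataclass(frozen=True)
class ConductanceSpec:
    """One Hodgkin-Huxley conductance.

    ``inactivation`` is a tuple of ``(GatingSpec, weight)`` pairs; the
    channel's inactivation term is the weighted sum of its gates
    (empty tuple = non-inactivating).
    """

    name: str
    gbar: float
    df: DrivingForce
    m: GatingSpec
    r: int = 1
    inactivation: tuple = ()

    def __post_init__(self) -> None:
        if self.gbar < 0:
            raise InvalidSpecError(f"{self.name}: gbar must be non-negative")
        if self.r < 1:
            raise InvalidSpecError(f"{self.name}: activation exponent r must be >= 1")
        if self.inactivation:
            total = sum(w for _, w in self.inactivation)
            if abs(total - 1.0) > 1e-9:
                raise InvalidSpecError(
                    f"{self.name}: inactivation weights must sum to 1, got {total}"
                )


@dataclass(frozen=True)
class NeuronModel:
    Cm: float
    conductances: tuple
    nat: MarkovNaTSpec
    g_leak: float
    E_leak: float
    Ihold: float = 0.0
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.Cm <= 0:
            raise InvalidSpecError("Cm must be positive")
        if self.g_leak < 0:
            raise InvalidSpecError("g_leak must be non-negative")
        names = [c.name for c in self.conductances]
        if len(names) != len(set(names)):
            raise InvalidSpecError("duplicate conductance names")

    @property
    def channel_names(self) -> tuple:
        return tuple(c.name for c in self.conductances)

    def channel(self, name: str) -> ConductanceSpec:
        for c in self.conductances:
            if c.name == name:
                return c
        raise KeyError(f"unknown channel {name!r}")

    def replace(self, **kwargs) -> "NeuronModel":
        return dataclasses.replace(self, **kwargs)

    def with_channel(self, spec: ConductanceSpec) -> "NeuronModel":
        """Return a copy with the same-named conductance replaced."""
        self.channel(spec.name)  # raises on unknown name
        new = tuple(spec if c.name == spec.name else c for c in self.conductances)
        return self.replace(conductances=new)

    def scaled(self, multipliers: dict) -> "NeuronModel":
        """Return a copy with per-channel gbar multiplied (``nat`` allowed)."""
        model = self
        for name, f in multipliers.items():
            if name == "nat":
                model = model.replace(nat=dataclasses.replace(model.nat, gbar=model.nat.gbar * f))
            else:
                c = model.channel(name)
                model = model.with_channel(dataclasses.replace(c, gbar=c.gbar * f))
        return model


@dataclass
class ModelState:
    """Full dynamical state: V, HH gates per channel, Markov occupancies."""

    V: float
    gates: dict  # name -> (m, [h, ...])
    markov: tuple  # (C, O, I)


# ---------------------------------------------------------------------------
# presets


def _parse_tau(d: dict) -> TauSpec:
    form = TauForm[d["form"]]
    kwargs = {k: float(v) for k, v in d.items() if k != "form"}
    return TauSpec(form=form, **kwargs)


def _parse_gate(d: dict) -> GatingSpec:
    conv = SignConvention[d.get("sign_convention", "V_MINUS_V50")]
    return GatingSpec(
        V50=float(d["V50"]), K=float(d["K"]), tau=_parse_tau(d["tau"]), sign_convention=conv
    )


def _load_yaml(name: str) -> dict:
    with resources.files("avpvk.presets").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def _parse_nat(d: dict) -> MarkovNaTSpec:
    rates = {k: RateSpec(**{kk: float(vv) for kk, vv in v.items()}) for k, v in d["rates"].items()}
    return MarkovNaTSpec(
        gbar=float(d["gbar_nS"]),
        E=float(d["E_mV"]),
        alpha=rates["alpha"],
        beta=rates["beta"],
        r1=rates["r1"],
        r3=rates["r3"],
        open_exponent=int(d.get("open_exponent", 3)),
    )


def preset(stage: str) -> NeuronModel:
    """Build the fully parameterized model for ``diestrus`` or ``proestrus``."""
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}, got {stage!r}")
    doc = _load_yaml(f"{stage}.yaml")
    VT = float(doc.get("VT_mV", VT_DEFAULT))
    conductances = []
    for cd in doc["conductances"]:
        df = DrivingForce(
            law=DrivingLaw[cd["law"]],
            E=float(cd["E_mV"]),
            VT=VT,
            c_scale=float(cd.get("c_out_mM", 1.0)),
        )
        inact = tuple(
            (_parse_gate(hd), float(hd.get("weight", 1.0))) for hd in cd.get("h", [])
        )
        conductances.append(
            ConductanceSpec(
                name=cd["name"],
                gbar=float(cd["gbar_nS"]),
                df=df,
                m=_parse_gate(cd["m"]),
                r=int(cd.get("r", 1)),
                inactivation=inact,
            )
        )
    nat = _parse_nat(_load_yaml("nat.yaml"))
    return NeuronModel(
        Cm=float(doc["Cm_pF"]),
        conductances=tuple(conductances),
        nat=nat,
        g_leak=float(doc["leak"]["g_nS"]),
        E_leak=float(doc["leak"]["E_mV"]),
        Ihold=float(doc.get("Ihold_pA", 0.0)),
        label=doc["label"],
    )


# ---------------------------------------------------------------------------
# Markov channel


def markov_rates(spec: MarkovNaTSpec, V):
    """Evaluate (alpha, beta, r1, r3) in 1/ms at voltage ``V``."""
    return spec.alpha(V), spec.beta(V), spec.r1(V), spec.r3(V)


def markov_matrix(spec: MarkovNaTSpec, V: float):
    """Rate matrix / affine term of the reduced (C, O) system at fixed V.

    With I = 1 - C - O:  d[C,O]/dt = M @ [C,O] + b.
    """
    a, b_, r1, r3 = markov_rates(spec, V)
    M = np.array([[-(a + r3), b_ - r3], [a, -(b_ + r1)]])
    b = np.array([r3, 0.0])
    return M, b


def markov_steady_state(spec: MarkovNaTSpec, V: float):
    """Stationary (C, O, I) occupancies at fixed voltage."""
    M, b = markov_matrix(spec, V)
    try:
        x = np.linalg.solve(M, -b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rates keep M regular
        raise DegenerateError(f"singular Markov rate matrix at V={V}") from exc
    C, O = float(x[0]), float(x[1])
    return C, O, 1.0 - C - O


def steady_state_model(model: NeuronModel, V: float) -> ModelState:
    """Fixed-point state at voltage ``V``: HH gates at their steady states,
    Markov occupancies at the stationary distribution."""
    gates = {}
    for c in model.conductances:
        m = steady_state(c.m, V)
        hs = [steady_state(g, V) for g, _ in c.inactivation]
        gates[c.name] = (m, hs)
    return ModelState(V=float(V), gates=gates, markov=markov_steady_state(model.nat, V))


# ---------------------------------------------------------------------------
# whole-cell current bookkeeping


def steady_ionic_current(model: NeuronModel, V: float) -> float:
    """Total steady-state ionic current (pA, outward positive) at ``V``,
    including NaT and leak but not the holding current."""
    state = steady_state_model(model, V)
    total = 0.0
    for c in model.conductances:
        m, hs = state.gates[c.name]
        H = sum(w * h for (_, w), h in zip(c.inactivation, hs)) if c.inactivation else 1.0
        total += c.gbar * m**c.r * H * driving(c.df, V)
    _, O, _ = state.markov
    total += model.nat.gbar * O**model.nat.open_exponent * (V - model.nat.E)
    total += model.g_leak * (V - model.E_leak)
    return float(total)


def resting_potential(model: NeuronModel, lo: float = -110.0, hi: float = -40.0) -> float:
    """Zero of the steady net membrane current (ionic minus holding)."""
    from scipy.optimize import brentq

    f = lambda V: steady_ionic_current(model, V) - model.Ihold
    grid = np.linspace(lo, hi, 141)
    vals = np.array([f(v) for v in grid])
    sign = np.sign(vals)
    idx = np.where(np.diff(sign) != 0)[0]
    if len(idx) == 0:
        raise CalibrationError("no resting potential found in search window")
    i = idx[0]
    return float(brentq(f, grid[i], grid[i + 1], xtol=1e-9))


def measure_input_resistance(
    model: NeuronModel,
    step_pA: float = -5.0,
    duration: float = 500.0,
    dt_int: float = 0.01,
) -> float:
    """Input resistance (GOhm) from the steady deflection to a small step.

    Simulates a ``step_pA`` current step of ``duration`` ms from rest and
    reports mean(V over the last 10% of the step) minus rest, divided by
    the step amplitude.  mV / pA = GOhm.
    """
    from .protocols import CurrentStepProtocol
    from .simulator import run_current_clamp

    proto = CurrentStepProtocol(
        steps=(step_pA,), duration=duration, pre=50.0, post=0.0, label="rin-probe"
    )
    trace = run_current_clamp(model, proto, dt=0.05, dt_int=dt_int)[0]
    t0 = 50.0
    rest = float(np.mean(trace.y[trace.t < t0]))
    tail = trace.y[(trace.t >= t0 + 0.9 * duration) & (trace.t < t0 + duration)]
    dV = float(np.mean(tail)) - rest
    return dV / step_pA


def calibrate(
    model: NeuronModel,
    V_target: float = -70.0,
    Rin_target: float = 1.0,
    max_iter: int = 25,
    rel_tol: float = 1e-3,
    dt_int: float = 0.01,
) -> NeuronModel:
    """Adjust ``g_leak`` and ``Ihold`` so the model rests at ``V_target``
    (within 50 uV by construction) and its measured input resistance
    equals ``Rin_target`` GOhm.

    Fixed-point iteration: the holding current is set to balance the
    steady ionic current at ``V_target`` exactly; the leak conductance is
    corrected by the slope-conductance mismatch ``1/R_target - 1/R_meas``
    (nS, with R in GOhm) until the measured resistance converges.
    """
    m = model
    for _ in range(max_iter):
        m = m.replace(Ihold=steady_ionic_current(m, V_target))
        R = measure_input_resistance(m, dt_int=dt_int)
        if abs(R - Rin_target) <= rel_tol * Rin_target:
            return m
        g_new = m.g_leak + (1.0 / Rin_target - 1.0 / R)
        if g_new < 0:
            raise CalibrationError(
                f"calibration requires negative leak (g_leak -> {g_new:.3f} nS)"
            )
        m = m.replace(g_leak=g_new)
    raise CalibrationError(f"input resistance did not converge within {max_iter} iterations")


def swap(base: NeuronModel, donor: NeuronModel, channel_names, recalibrate: bool = True) -> NeuronModel:
    """Hybrid model: the named conductances of ``base`` replaced by the
    donor's, then re-calibrated.  An empty name set returns ``base``."""
    names = set(channel_names)
    if not names:
        return base
    hybrid = base
    for name in sorted(names):
        donor.channel(name)  # raise early on unknown name
        hybrid = hybrid.with_channel(donor.channel(name))
    hybrid = hybrid.replace(label="hybrid")
    if recalibrate:
        hybrid = calibrate(hybrid)
    return hybrid


def isolate(model: NeuronModel, name: str) -> NeuronModel:
    """Copy of ``model`` with every voltage-gated conductance except
    ``name`` (and NaT) zeroed; used to simulate drug/voltage-isolated
    component recordings."""
    new = []
    for c in model.conductances:
        new.append(c if c.name == name else dataclasses.replace(c, gbar=0.0))
    if name != "nat":
        model.channel(name)
    nat = dataclasses.replace(model.nat, gbar=model.nat.gbar if name == "nat" else 0.0)
    return model.replace(conductances=tuple(new), nat=nat, label=f"{model.label}:{name}")
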