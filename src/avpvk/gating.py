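"""Voltage-dependent gating primitives.

Steady-state (Boltzmann) activation/inactivation functions, their
voltage-dependent time constants, and the two driving-force laws (Ohmic
and Goldman-Hodgkin-Katz) used to compose single-channel currents.

Conventions
-----------
* Voltages in mV, times in ms, conductances in nS, currents in pA
  (nS x mV = pA), so no unit conversions appear downstream.
* Outward current is positive.
* Steady state is ``1 / (1 + exp(x / K))`` with ``x = V - V50`` (the
  default) or ``x = V + V50``; a negative slope factor K yields an
  activation curve, a positive K an inactivation curve.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import InvalidSpecError

__all__ = [
    "SignConvention",
    "TauForm",
    "DrivingLaw",
    "GatingSpec",
    "TauSpec",
    "DrivingForce",
    "steady_state",
    "time_constant",
    "driving",
    "channel_current",
    "VT_DEFAULT",
    "nernst",
]

#: Thermal voltage kT/q at the 31 degC recording temperature (304.15 K), mV.
VT_DEFAULT = 26.21

# Faraday constant / gas constant, for Nernst potentials.
_R = 8.314462618  # J / (mol K)
_F = 96485.33212  # C / mol


def nernst(c_out: float, c_in: float, T_kelvin: float, z: int = 1) -> float:
    """Nernst equilibrium potential in mV for ion concentrations in mM."""
    if c_out <= 0 or c_in <= 0:
        raise ValueError("concentrations must be positive")
    return 1e3 * _R * T_kelvin / (z * _F) * math.log(c_out / c_in)


class SignConvention(enum.Enum):
    V_MINUS_V50 = "V_MINUS_V50"
    V_PLUS_V50 = "V_PLUS_V50"


class TauForm(enum.Enum):
    CONSTANT = "CONSTANT"
    SINGLE_SIGMOID = "SINGLE_SIGMOID"
    DOUBLE_SIGMOID = "DOUBLE_SIGMOID"
    BELL = "BELL"


class DrivingLaw(enum.Enum):
    OHMIC = "OHMIC"
    GHK = "GHK"


@dataclass(frozen=True)
class TauSpec:
    """Voltage-dependent time constant of one gating variable.

    Forms (V in mV, result in ms):

    * ``CONSTANT``        -> ``fixed_value``
    * ``SINGLE_SIGMOID``  -> ``A + B / (1 + exp((V - C) / D))``
    * ``DOUBLE_SIGMOID``  -> ``A + [B/(1+exp((V-C)/D))] * [E/(1+exp((V-F)/G))]``
    * ``BELL``            -> ``E / (exp((A+V)/B) + exp((C+V)/D)) + F``
    """

    form: TauForm
    A: float = 0.0
    B: float = 0.0
    C: float = 0.0
    D: float = 1.0
    E: float = 1.0
    F: float = 0.0
    G: float = 1.0
    fixed_value: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, v_lo: float = -120.0, v_hi: float = 60.0) -> None:
        """Raise ``InvalidSpecError`` unless tau > 0 over [v_lo, v_hi] mV."""
        grid = np.linspace(v_lo, v_hi, 361)
        tau = time_constant(self, grid)
        if not np.all(np.isfinite(tau)) or np.any(tau <= 0.0):
            raise InvalidSpecError(
                f"time constant not strictly positive on [{v_lo}, {v_hi}] mV: {self}"
            )


@dataclass(frozen=True)
class GatingSpec:
    """Steady state + kinetics of one Hodgkin-Huxley gating variable."""

    V50: float
    K: float
    tau: TauSpec
    sign_convention: SignConvention = SignConvention.V_MINUS_V50

    def __post_init__(self) -> None:
        if self.K == 0:
            raise InvalidSpecError("slope factor K must be nonzero")

    @property
    def signed_v50(self) -> float:
        """Offset ``s`` such that the sigmoid argument is ``(V + s) / K``."""
        if self.sign_convention is SignConvention.V_MINUS_V50:
            return -self.V50
        return self.V50

    @property
    def midpoint(self) -> float:
        """Membrane voltage at which the steady state equals 0.5."""
        return -self.signed_v50

    @property
    def is_activation(self) -> bool:
        return self.K < 0


@dataclass(frozen=True)
class DrivingForce:
    """Driving-force law of one channel: Ohmic or GHK, zero at ``E``.

    ``c_scale`` multiplies the GHK driving force; it represents the
    external ion concentration (mM) of the GHK current equation written
    in concentration form, with the internal concentration implied by
    ``E``.  It does not move the reversal potential.
    """

    law: DrivingLaw
    E: float
    VT: float = VT_DEFAULT
    c_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.VT <= 0:
            raise InvalidSpecError("thermal voltage VT must be positive")
        if self.c_scale <= 0:
            raise InvalidSpecError("GHK concentration scale must be positive")


def steady_state(spec: GatingSpec, V):
    """Steady-state activation/inactivation fraction at voltage ``V`` (mV).

    Returns ``1 / (1 + exp((V + s) / K))`` with ``s = -V50`` under the
    ``V_MINUS_V50`` convention and ``s = +V50`` under ``V_PLUS_V50``.
    Output is strictly inside (0, 1) for finite V.
    """
    x = (np.asarray(V, dtype=float) + spec.signed_v50) / spec.K
    out = expit(-x)
    return out if out.ndim else float(out)


def time_constant(spec: TauSpec, V):
    """Evaluate the time constant (ms) of ``spec`` at voltage ``V`` (mV)."""
    V = np.asarray(V, dtype=float)
    if spec.form is TauForm.CONSTANT:
        tau = np.full(V.shape, float(spec.fixed_value))
    elif spec.form is TauForm.SINGLE_SIGMOID:
        tau = spec.A + spec.B * expit(-(V - spec.C) / spec.D)
    elif spec.form is TauForm.DOUBLE_SIGMOID:
        tau = spec.A + (spec.B * expit(-(V - spec.C) / spec.D)) * (
            spec.E * expit(-(V - spec.F) / spec.G)
        )
    elif spec.form is TauForm.BELL:
        tau = (
            spec.E
            / (np.exp((spec.A + V) / spec.B) + np.exp((spec.C + V) / spec.D))
            + spec.F
        )
    else:  # pragma: no cover - enum is closed
        raise InvalidSpecError(f"unknown tau form {spec.form}")
    return tau if tau.ndim else float(tau)


def driving(df: DrivingForce, V):
    """Driving force in mV-equivalents so that gbar (nS) x driving = pA.

    ``OHMIC`` returns ``V - E``.  ``GHK`` returns
    ``(V/VT) * (exp((V - E)/VT) - 1) / (exp(V/VT) - 1)`` — the
    thermal-voltage-scaled prefactor of the GHK current equation — with
    the removable singularity at V = 0 evaluated as its limit
    ``exp(-E/VT) - 1``.  Both laws vanish exactly at ``V = E`` and share
    the sign of ``V - E``.  The GHK output is treated as mV-equivalent so
    that gbar (nS) x driving x gates composes to pA; this keeps the
    published maximal conductances on the scale of the measured current
    densities.
    """
    V = np.asarray(V, dtype=float)
    if df.law is DrivingLaw.OHMIC:
        out = V - df.E
        return out if out.ndim else float(out)
    num = np.expm1((V - df.E) / df.VT)
    den = np.expm1(V / df.VT)
    limit = np.expm1(-df.E / df.VT)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = df.c_scale * np.where(
            np.abs(V) < 1e-9, limit, (V / df.VT) * num / np.where(den == 0, 1.0, den)
        )
    return out if out.ndim else float(out)


def channel_current(cs, V, gate_values) -> float:
    """Instantaneous current (pA) of one channel from explicit gate values.

    ``gate_values`` maps are ``(m, [h_1, h_2, ...])``; the inactivation
    term is the weighted sum of the h values using the channel's weights
    (1.0 when the channel carries no inactivation gate).
    """
    m, h_values = gate_values
    if not 0.0 <= m <= 1.0 or any(not 0.0 <= h <= 1.0 for h in h_values):
        raise ValueError("gate values must lie in [0, 1]")
    if cs.inactivation:
        weights = [w for _, w in cs.inactivation]
        H = sum(w * h for w, h in zip(weights, h_values))
    else:
        H = 1.0
    return cs.gbar * m**cs.r * H * driving(cs.df, V)
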