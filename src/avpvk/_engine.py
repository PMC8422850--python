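"""Vectorized numerical core.

``CompiledModel`` flattens a :class:`~avpvk.neuron.NeuronModel` into
plain arrays so that

* voltage-clamp responses to piecewise-constant commands are propagated
  *analytically* per segment (Hodgkin-Huxley gates relax exponentially
  and the reduced Markov system is linear with constant coefficients at
  fixed voltage), and
* current-clamp sweeps are integrated with a fixed-step scheme
  (Rush-Larsen exponential updates for HH gates, implicit Euler for the
  Markov occupancies, midpoint rule for the membrane voltage) batched
  across sweeps.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .errors import DegenerateError, IntegrationError
from .gating import DrivingLaw, SignConvention, TauForm
from .neuron import NeuronModel

try:  # optional acceleration; the numpy path is the reference
    from ._cc_numba import cc_loop as _numba_cc_loop
except Exception:  # pragma: no cover - numba present in supported envs
    _numba_cc_loop = None

__all__ = ["CompiledModel", "ghk_drive"]

_LAW_OHMIC = 0
_LAW_GHK = 1

_FORM_CODE = {
    TauForm.CONSTANT: 0,
    TauForm.SINGLE_SIGMOID: 1,
    TauForm.DOUBLE_SIGMOID: 2,
    TauForm.BELL: 3,
}


def ghk_drive(V, E: float, VT: float):
    """GHK driving force ``(V/VT) * expm1((V-E)/VT) / expm1(V/VT)``,
    removable singularity at V=0 (limit ``expm1(-E/VT)``)."""
    V = np.asarray(V, dtype=float)
    num = np.expm1((V - E) / VT)
    den = np.expm1(V / VT)
    limit = np.expm1(-E / VT)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            np.abs(V) < 1e-9, limit, (V / VT) * num / np.where(den == 0.0, 1.0, den)
        )
    return out


class CompiledModel:
    """Array-flattened neuron model (see module docstring)."""

    def __init__(self, model: NeuronModel):
        self.model = model
        self.Cm = model.Cm
        self.Ihold = model.Ihold
        self.g_leak = model.g_leak
        self.E_leak = model.E_leak

        sv50, K = [], []
        tA, tB, tC, tD, tE, tF, tG, form = [], [], [], [], [], [], [], []

        def add_gate(g):
            sv50.append(g.signed_v50)
            K.append(g.K)
            ts = g.tau
            code = _FORM_CODE[ts.form]
            form.append(code)
            if ts.form is TauForm.CONSTANT:
                tA.append(ts.fixed_value)
                tB.append(0.0)
                tC.append(0.0)
                tD.append(1.0)
                tE.append(1.0)
                tF.append(0.0)
                tG.append(1.0)
            else:
                tA.append(ts.A)
                tB.append(ts.B)
                tC.append(ts.C)
                tD.append(ts.D)
                tE.append(ts.E)
                tF.append(ts.F)
                tG.append(ts.G)
            return len(sv50) - 1

        chans = []
        for c in model.conductances:
            m_idx = add_gate(c.m)
            h_idx = [add_gate(g) for g, _ in c.inactivation]
            h_w = [w for _, w in c.inactivation]
            chans.append(
                dict(
                    name=c.name,
                    gbar=c.gbar,
                    E=c.df.E,
                    VT=c.df.VT,
                    law=_LAW_OHMIC if c.df.law is DrivingLaw.OHMIC else _LAW_GHK,
                    c_scale=c.df.c_scale,
                    r=c.r,
                    m_idx=m_idx,
                    h_idx=h_idx,
                    h_w=h_w,
                )
            )
        self.channels = chans
        self.n_gates = len(sv50)
        self.sv50 = np.asarray(sv50)[:, None]
        self.K = np.asarray(K)[:, None]
        self.tA = np.asarray(tA)[:, None]
        self.tB = np.asarray(tB)[:, None]
        self.tC = np.asarray(tC)[:, None]
        self.tD = np.asarray(tD)[:, None]
        self.tE = np.asarray(tE)[:, None]
        self.tF = np.asarray(tF)[:, None]
        self.tG = np.asarray(tG)[:, None]
        form = np.asarray(form)
        self.is_double = (form == _FORM_CODE[TauForm.DOUBLE_SIGMOID])[:, None]
        self.bell_rows = np.where(form == _FORM_CODE[TauForm.BELL])[0]

        # flat per-channel arrays for the compiled current-clamp loop
        self._gbar = np.array([c["gbar"] for c in chans])
        self._law = np.array([c["law"] for c in chans], dtype=np.int64)
        self._E = np.array([c["E"] for c in chans])
        self._VTc = np.array([c["VT"] for c in chans])
        self._cscale = np.array([c["c_scale"] for c in chans])
        self._rexp = np.array([c["r"] for c in chans], dtype=np.int64)
        self._m_idx = np.array([c["m_idx"] for c in chans], dtype=np.int64)
        self._h1 = np.array(
            [c["h_idx"][0] if c["h_idx"] else -1 for c in chans], dtype=np.int64
        )
        self._h2 = np.array(
            [c["h_idx"][1] if len(c["h_idx"]) > 1 else -1 for c in chans], dtype=np.int64
        )
        self._w1 = np.array([c["h_w"][0] if c["h_w"] else 0.0 for c in chans])
        self._w2 = np.array([c["h_w"][1] if len(c["h_w"]) > 1 else 0.0 for c in chans])

        nat = model.nat
        self.nat = nat
        self.ns = np.array([nat.alpha.s, nat.beta.s, nat.r1.s, nat.r3.s])[:, None]
        self.nk = np.array([nat.alpha.k, nat.beta.k, nat.r1.k, nat.r3.k])[:, None]
        self.nr = np.array([nat.alpha.r, nat.beta.r, nat.r1.r, nat.r3.r])[:, None]
        self.gnat = nat.gbar
        self.Enat = nat.E
        self.oexp = nat.open_exponent

    # -- elementary evaluations (V is a 1-D array over sweeps) --------------

    def gates_inf(self, V: np.ndarray) -> np.ndarray:
        return expit(-(V[None, :] + self.sv50) / self.K)

    def gates_tau(self, V: np.ndarray) -> np.ndarray:
        Vb = V[None, :]
        second = np.where(self.is_double, self.tE * expit(-(Vb - self.tF) / self.tG), 1.0)
        tau = self.tA + self.tB * expit(-(Vb - self.tC) / self.tD) * second
        for i in self.bell_rows:
            tau[i] = (
                self.tE[i, 0]
                / (
                    np.exp((self.tA[i, 0] + V) / self.tB[i, 0])
                    + np.exp((self.tC[i, 0] + V) / self.tD[i, 0])
                )
                + self.tF[i, 0]
            )
        return tau

    def nat_rates(self, V: np.ndarray) -> np.ndarray:
        """(alpha, beta, r1, r3) stacked, shape (4, B)."""
        return self.nr * expit(-(V[None, :] + self.ns) / self.nk)

    def markov_steady(self, V: float):
        a, b_, r1, r3 = self.nat_rates(np.array([float(V)]))[:, 0]
        M = np.array([[-(a + r3), b_ - r3], [a, -(b_ + r1)]])
        b = np.array([r3, 0.0])
        try:
            return np.linalg.solve(M, -b)
        except np.linalg.LinAlgError as exc:
            raise DegenerateError(f"singular Markov rate matrix at V={V}") from exc

    def _drive(self, ch: dict, V):
        if ch["law"] == _LAW_OHMIC:
            return np.asarray(V, dtype=float) - ch["E"]
        return ch["c_scale"] * ghk_drive(V, ch["E"], ch["VT"])

    def channel_current_matrix(self, V: float, gates: np.ndarray, O: np.ndarray) -> dict:
        """Per-channel currents at constant command ``V``; gate/occupancy
        arrays have a trailing time axis."""
        out = {}
        for ch in self.channels:
            m = gates[ch["m_idx"]]
            mr = m if ch["r"] == 1 else m ** ch["r"]
            if ch["h_idx"]:
                H = sum(w * gates[i] for w, i in zip(ch["h_w"], ch["h_idx"]))
            else:
                H = 1.0
            out[ch["name"]] = ch["gbar"] * mr * H * float(self._drive(ch, V))
        out["nat"] = self.gnat * O**self.oexp * (V - self.Enat)
        return out

    def ionic_current(self, V: np.ndarray, gates: np.ndarray, O: np.ndarray,
                      include_leak: bool = True) -> np.ndarray:
        """Summed ionic current (pA, outward positive) at voltages ``V`` (B,)."""
        total = np.zeros_like(V)
        for ch in self.channels:
            if ch["gbar"] == 0.0:
                continue
            m = gates[ch["m_idx"]]
            mr = m if ch["r"] == 1 else m ** ch["r"]
            if ch["h_idx"]:
                H = sum(w * gates[i] for w, i in zip(ch["h_w"], ch["h_idx"]))
            else:
                H = 1.0
            total += ch["gbar"] * mr * H * self._drive(ch, V)
        if self.gnat:
            total += self.gnat * O**self.oexp * (V - self.Enat)
        if include_leak:
            total += self.g_leak * (V - self.E_leak)
        return total

    # -- voltage clamp: analytic per-segment propagation --------------------

    def _markov_segment(self, V: float, x0: np.ndarray, tl: np.ndarray):
        """Solve the reduced (C, O) system at fixed V for local times tl.

        Returns occupancies with shape (2, len(tl)).  Exact for the
        piecewise-constant command (eigen decomposition of the 2x2 rate
        matrix)."""
        a, b_, r1, r3 = self.nat_rates(np.array([float(V)]))[:, 0]
        M = np.array([[-(a + r3), b_ - r3], [a, -(b_ + r1)]])
        b = np.array([r3, 0.0])
        xss = np.linalg.solve(M, -b)
        w, P = np.linalg.eig(M)
        try:
            c = np.linalg.solve(P, x0 - xss)
        except np.linalg.LinAlgError:  # defective matrix: substep instead
            return self._markov_substep(M, b, x0, tl)
        Y = (P @ (c[:, None] * np.exp(w[:, None] * tl[None, :]))).real
        return xss[:, None] + Y

    @staticmethod
    def _markov_substep(M, b, x0, tl, dt=1e-3):  # pragma: no cover - fallback
        out = np.empty((2, len(tl)))
        x = x0.copy()
        t = 0.0
        A = np.eye(2) - dt * M
        j = 0
        order = np.argsort(tl)
        for j in order:
            while t < tl[j]:
                x = np.linalg.solve(A, x + dt * b)
                t += dt
            out[:, j] = x
        return out

    def voltage_clamp_sweep(self, segments, dt: float, init_V: float,
                            per_channel: bool = False):
        """Ideal-clamp response to one sweep of (level, duration) segments.

        State starts at the steady state of ``init_V``.  Returns
        ``(t, I_total)`` or ``(t, I_total, components)``; the recorded
        current excludes leak and holding (ideal clamp, artifacts are a
        synthetic-data concern).
        """
        total = sum(d for _, d in segments)
        n = int(round(total / dt))
        t = np.arange(n) * dt
        I = np.empty(n)
        comps = {} if per_channel else None

        gates = self.gates_inf(np.array([init_V]))[:, 0]
        x = self.markov_steady(init_V)

        t0 = 0.0
        for level, dur in segments:
            if dur <= 0:
                continue
            idx = np.nonzero((t >= t0 - 1e-9) & (t < t0 + dur - 1e-9))[0]
            Varr = np.array([float(level)])
            inf = self.gates_inf(Varr)[:, 0]
            tau = self.gates_tau(Varr)[:, 0]
            if idx.size:
                tl = t[idx] - t0
                decay = np.exp(-tl[None, :] / tau[:, None])
                G = inf[:, None] + (gates - inf)[:, None] * decay
                occ = self._markov_segment(level, x, tl)
                cur = self.channel_current_matrix(level, G, occ[1])
                I[idx] = sum(cur.values())
                if per_channel:
                    for k, v in cur.items():
                        comps.setdefault(k, np.empty(n))[idx] = v
            # advance state to the segment end (exact)
            gates = inf + (gates - inf) * np.exp(-dur / tau)
            x = self._markov_segment(level, x, np.array([dur]))[:, 0]
            t0 += dur

        if not np.all(np.isfinite(I)):
            raise IntegrationError("non-finite clamp current")
        if per_channel:
            return t, I, comps
        return t, I

    # -- current clamp: fixed-step batched integration ----------------------

    def current_clamp(self, V0: float, applied_segments, dt: float,
                      record_every: int, use_numba: bool = True,
                      track_bounds: bool = False):
        """Integrate the membrane equation for a batch of sweeps.

        ``applied_segments`` is a list of ``(amplitudes (B,), n_steps)``
        pairs of piecewise-constant applied current (pA, on top of the
        holding current).  Returns ``(t_rec, V_rec)`` with ``V_rec`` of
        shape (B, n_recorded).  The numba and numpy code paths implement
        the same scheme; ``use_numba=False`` forces the reference path.
        """
        if track_bounds:
            use_numba = False
        if use_numba and _numba_cc_loop is not None:
            return self._current_clamp_numba(V0, applied_segments, dt, record_every)
        B = len(applied_segments[0][0])
        n_total = sum(n for _, n in applied_segments)
        n_rec = (n_total + record_every - 1) // record_every

        V = np.full(B, float(V0))
        gates = np.repeat(self.gates_inf(np.array([V0])), B, axis=1)
        x = self.markov_steady(V0)
        C = np.full(B, x[0])
        O = np.full(B, x[1])

        V_rec = np.empty((B, n_rec))
        t_rec = np.arange(n_rec) * (dt * record_every)

        drive_pA = self.Ihold
        step = 0
        rec = 0
        bounds = {
            "gate_min": np.inf, "gate_max": -np.inf,
            "occ_min": np.inf, "occ_max": -np.inf,
            "conservation_err": 0.0,
        }
        for amps, n_steps in applied_segments:
            amps = np.asarray(amps, dtype=float)
            for _ in range(n_steps):
                if step % record_every == 0:
                    V_rec[:, rec] = V
                    rec += 1
                inf = self.gates_inf(V)
                tau = self.gates_tau(V)
                gates += (inf - gates) * (-np.expm1(-dt / tau))
                a, b_, r1, r3 = self.nat_rates(V)
                A11 = 1.0 + dt * (a + r3)
                A12 = -dt * (b_ - r3)
                A21 = -dt * a
                A22 = 1.0 + dt * (b_ + r1)
                det = A11 * A22 - A12 * A21
                rhs1 = C + dt * r3
                rhs2 = O
                C = (rhs1 * A22 - A12 * rhs2) / det
                O = (A11 * rhs2 - A21 * rhs1) / det
                I1 = self.ionic_current(V, gates, O)
                Vh = V + (0.5 * dt / self.Cm) * (amps + drive_pA - I1)
                I2 = self.ionic_current(Vh, gates, O)
                V = V + (dt / self.Cm) * (amps + drive_pA - I2)
                step += 1
                if track_bounds:
                    bounds["gate_min"] = min(bounds["gate_min"], float(gates.min()))
                    bounds["gate_max"] = max(bounds["gate_max"], float(gates.max()))
                    occ = np.concatenate([C, O, 1.0 - C - O])
                    bounds["occ_min"] = min(bounds["occ_min"], float(occ.min()))
                    bounds["occ_max"] = max(bounds["occ_max"], float(occ.max()))
                    bounds["conservation_err"] = max(
                        bounds["conservation_err"],
                        float(np.max(np.abs(C + O + (1.0 - C - O) - 1.0))),
                    )
                if step % 4000 == 0 and not np.all(np.isfinite(V)):
                    raise IntegrationError("membrane potential diverged")
        if not np.all(np.isfinite(V_rec)):
            raise IntegrationError("membrane potential diverged")
        if track_bounds:
            return t_rec, V_rec, bounds
        return t_rec, V_rec

    def _current_clamp_numba(self, V0: float, applied_segments, dt: float,
                             record_every: int):
        B = len(applied_segments[0][0])
        n_total = sum(n for _, n in applied_segments)
        n_rec = (n_total + record_every - 1) // record_every

        V = np.full(B, float(V0))
        gates = np.repeat(self.gates_inf(np.array([V0])), B, axis=1).T.copy()
        x = self.markov_steady(V0)
        C = np.full(B, x[0])
        O = np.full(B, x[1])
        amps_seg = np.stack([np.asarray(a, dtype=float) for a, _ in applied_segments])
        nsteps_seg = np.array([n for _, n in applied_segments], dtype=np.int64)
        V_rec = np.empty((B, n_rec))
        form_bell = self.bell_rows
        is_bell = np.zeros(self.n_gates, dtype=np.bool_)
        is_bell[form_bell] = True
        _numba_cc_loop(
            V, gates, C, O, amps_seg, nsteps_seg, float(dt), int(record_every),
            self.sv50.ravel(), self.K.ravel(),
            self.tA.ravel(), self.tB.ravel(), self.tC.ravel(), self.tD.ravel(),
            self.tE.ravel(), self.tF.ravel(), self.tG.ravel(),
            self.is_double.ravel(), is_bell,
            self.ns.ravel(), self.nk.ravel(), self.nr.ravel(),
            self._gbar, self._law, self._E, self._VTc, self._cscale, self._rexp,
            self._m_idx, self._h1, self._h2, self._w1, self._w2,
            float(self.gnat), float(self.Enat), int(self.oexp),
            float(self.g_leak), float(self.E_leak), float(self.Cm),
            float(self.Ihold), V_rec,
        )
        if not np.all(np.isfinite(V_rec)):
            raise IntegrationError("membrane potential diverged")
        t_rec = np.arange(n_rec) * (dt * record_every)
        return t_rec, V_rec

    def clamp_to_waveform(self, t: np.ndarray, V: np.ndarray):
        """Ionic current while the voltage follows a sampled waveform.

        Gates advance by Rush-Larsen / implicit-Euler steps treating V as
        constant over each sample interval; the returned current is
        evaluated at the sample's voltage with the entering state.
        """
        n = len(t)
        dt = float(t[1] - t[0])
        gates = self.gates_inf(V[:1])[:, 0][:, None]
        x = self.markov_steady(V[0])
        C = np.array([x[0]])
        O = np.array([x[1]])
        I = np.empty(n)
        for i in range(n):
            Vi = V[i : i + 1]
            I[i] = self.ionic_current(Vi, gates, O)[0]
            inf = self.gates_inf(Vi)
            tau = self.gates_tau(Vi)
            gates += (inf - gates) * (-np.expm1(-dt / tau))
            a, b_, r1, r3 = self.nat_rates(Vi)
            A11 = 1.0 + dt * (a + r3)
            A12 = -dt * (b_ - r3)
            A21 = -dt * a
            A22 = 1.0 + dt * (b_ + r1)
            det = A11 * A22 - A12 * A21
            rhs1 = C + dt * r3
            rhs2 = O
            C = (rhs1 * A22 - A12 * rhs2) / det
            O = (A11 * rhs2 - A21 * rhs1) / det
        return I
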