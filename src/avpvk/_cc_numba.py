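"""Numba-accelerated current-clamp inner loop.

Same scheme as the numpy path in ``_engine.CompiledModel.current_clamp``
(Rush-Larsen gate updates, implicit-Euler Markov occupancies, midpoint
voltage update); kept in lockstep by the simulator regression tests.
Import of this module fails cleanly when numba is unavailable.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["cc_loop"]


@njit(cache=True, fastmath=False)
def _drive(V, law, E, VT, cs):
    if law == 0:
        return V - E
    if abs(V) < 1e-9:
        return cs * math.expm1(-E / VT)
    return cs * (V / VT) * math.expm1((V - E) / VT) / math.expm1(V / VT)


@njit(cache=True, fastmath=False)
def _ionic(V, gates_b, O,
           gbar, law, Echan, VTchan, cscale, rexp, m_idx, h1_idx, h2_idx, h1_w, h2_w,
           gnat, Enat, oexp, gleak, Eleak):
    total = gleak * (V - Eleak)
    for c in range(gbar.shape[0]):
        g = gbar[c]
        if g == 0.0:
            continue
        m = gates_b[m_idx[c]]
        mr = m
        for _ in range(rexp[c] - 1):
            mr *= m
        H = 1.0
        if h1_idx[c] >= 0:
            H = h1_w[c] * gates_b[h1_idx[c]]
            if h2_idx[c] >= 0:
                H += h2_w[c] * gates_b[h2_idx[c]]
        total += g * mr * H * _drive(V, law[c], Echan[c], VTchan[c], cscale[c])
    if gnat > 0.0:
        total += gnat * O**oexp * (V - Enat)
    return total


@njit(cache=True, fastmath=False)
def cc_loop(V, gates, C, O, amps_seg, nsteps_seg, dt, record_every,
            sv50, K, tA, tB, tC, tD, tE, tF, tG, is_double, is_bell,
            ns, nk, nr,
            gbar, law, Echan, VTchan, cscale, rexp, m_idx, h1_idx, h2_idx, h1_w, h2_w,
            gnat, Enat, oexp, gleak, Eleak, Cm, Ihold, V_rec):
    B = V.shape[0]
    n_g = sv50.shape[0]
    step = 0
    rec = 0
    for seg in range(nsteps_seg.shape[0]):
        n_steps = nsteps_seg[seg]
        for _ in range(n_steps):
            if step % record_every == 0:
                for b in range(B):
                    V_rec[b, rec] = V[b]
                rec += 1
            for b in range(B):
                Vb = V[b]
                # HH gates: exact exponential relaxation at frozen V
                for g in range(n_g):
                    inf = 1.0 / (1.0 + math.exp((Vb + sv50[g]) / K[g]))
                    if is_bell[g]:
                        tau = tE[g] / (
                            math.exp((tA[g] + Vb) / tB[g])
                            + math.exp((tC[g] + Vb) / tD[g])
                        ) + tF[g]
                    else:
                        arg = (Vb - tC[g]) / tD[g]
                        if arg > 500.0:
                            s1 = 0.0
                        else:
                            s1 = tB[g] / (1.0 + math.exp(arg))
                        if is_double[g]:
                            arg2 = (Vb - tF[g]) / tG[g]
                            if arg2 > 500.0:
                                s1 = 0.0
                            else:
                                s1 *= tE[g] / (1.0 + math.exp(arg2))
                        tau = tA[g] + s1
                    gates[b, g] += (inf - gates[b, g]) * -math.expm1(-dt / tau)
                # Markov occupancies: implicit Euler on the reduced system
                a = nr[0] / (1.0 + math.exp((Vb + ns[0]) / nk[0]))
                bb = nr[1] / (1.0 + math.exp((Vb + ns[1]) / nk[1]))
                r1 = nr[2] / (1.0 + math.exp((Vb + ns[2]) / nk[2]))
                r3 = nr[3] / (1.0 + math.exp((Vb + ns[3]) / nk[3]))
                A11 = 1.0 + dt * (a + r3)
                A12 = -dt * (bb - r3)
                A21 = -dt * a
                A22 = 1.0 + dt * (bb + r1)
                det = A11 * A22 - A12 * A21
                rhs1 = C[b] + dt * r3
                rhs2 = O[b]
                C[b] = (rhs1 * A22 - A12 * rhs2) / det
                O[b] = (A11 * rhs2 - A21 * rhs1) / det
                # membrane voltage: midpoint rule at frozen gates
                I1 = _ionic(Vb, gates[b], O[b], gbar, law, Echan, VTchan, cscale,
                            rexp, m_idx, h1_idx, h2_idx, h1_w, h2_w,
                            gnat, Enat, oexp, gleak, Eleak)
                Vh = Vb + (0.5 * dt / Cm) * (amps_seg[seg, b] + Ihold - I1)
                I2 = _ionic(Vh, gates[b], O[b], gbar, law, Echan, VTchan, cscale,
                            rexp, m_idx, h1_idx, h2_idx, h1_w, h2_w,
                            gnat, Enat, oexp, gleak, Eleak)
                V[b] = Vb + (dt / Cm) * (amps_seg[seg, b] + Ihold - I2)
            step += 1
    return rec
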