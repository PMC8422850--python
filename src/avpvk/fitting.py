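"""Maximal-conductance optimization against target clamp traces.

Only gbar values are fitted; every kinetic parameter (V50, k, tau) stays
fixed, preserving the voltage sensitivity of the subcomponents.  The
optimizer is a seeded global-best particle swarm with reflecting bounds.
Because clamp currents are linear in the maximal conductances at fixed
kinetics, per-channel unit-conductance traces are precomputed once and
the swarm objective reduces to a quadratic form.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import GridMismatchError
from .neuron import NeuronModel
from .protocols import StepProtocol
from .simulator import Trace, run_voltage_clamp

__all__ = ["FitProblem", "sse", "pso_gbar", "PSOResult"]

# Swarm hyperparameters (constriction-style defaults); configurable per call.
SWARM_SIZE = 30
ITERATIONS = 200
INERTIA = 0.729
COGNITIVE = 1.49
SOCIAL = 1.49

#: Objective window relative to the test-pulse onset (ms); the late trace
#: is excluded by default because model/data error grows there.
OBJECTIVE_WINDOW = (0.0, 250.0)


@dataclass
class FitProblem:
    model: NeuronModel
    protocol: StepProtocol
    target: list  # Trace per sweep
    free: tuple  # channel names whose gbar is optimized
    bounds: dict = None  # name -> (lo, hi); default (0, 3 * current gbar)
    objective_window: tuple = OBJECTIVE_WINDOW

    def __post_init__(self) -> None:
        if len(self.target) != self.protocol.n_sweeps:
            raise GridMismatchError("one target trace per protocol sweep required")
        for name in self.free:
            self.model.channel(name)
        if self.bounds is None:
            self.bounds = {}
        for name in self.free:
            if name not in self.bounds:
                g0 = self.model.channel(name).gbar
                self.bounds[name] = (0.0, 3.0 * g0 if g0 > 0 else 100.0)
        for name, (lo, hi) in self.bounds.items():
            if not (0 <= lo < hi):
                raise ValueError(f"invalid bounds for {name}: {(lo, hi)}")

    def _sample_mask(self, trace: Trace):
        if self.objective_window is None:
            return np.ones(len(trace.t), dtype=bool)
        t0, _ = trace.meta["test_window"]
        w0, w1 = self.objective_window
        return (trace.t >= t0 + w0 - 1e-9) & (trace.t < t0 + w1 - 1e-9)

    def with_gbar(self, gbar: dict) -> NeuronModel:
        model = self.model
        for name, g in gbar.items():
            c = model.channel(name)
            model = model.with_channel(dataclasses.replace(c, gbar=float(g)))
        return model


def sse(model: NeuronModel, target, protocol: StepProtocol,
        objective_window=OBJECTIVE_WINDOW) -> float:
    """Sum-of-squares error between a fresh clamp simulation of ``model``
    and the target traces, equal weighting across samples."""
    problem = FitProblem(model=model, protocol=protocol, target=list(target),
                         free=(), objective_window=objective_window)
    sim = run_voltage_clamp(model, protocol)
    total = 0.0
    for s, tgt in zip(sim, target):
        if not s.same_grid(tgt):
            raise GridMismatchError("simulation and target grids differ")
        mask = problem._sample_mask(s)
        total += float(np.sum((s.y[mask] - tgt.y[mask]) ** 2))
    return total


@dataclass
class PSOResult:
    gbar: dict
    sse_initial: float
    sse_final: float
    history: np.ndarray  # global-best SSE per iteration (non-increasing)
    seed: int = None


def _linear_objective(problem: FitProblem):
    """Precompute the quadratic SSE objective.

    The clamp current is ``sum_c gbar_c * u_c(t) + fixed(t)`` where the
    unit traces ``u_c`` do not depend on any gbar; the SSE then evaluates
    without re-simulation.
    """
    free = list(problem.free)
    zeroed = problem.with_gbar({n: 0.0 for n in free})
    fixed = run_voltage_clamp(zeroed, problem.protocol)
    unit = {}
    for name in free:
        only = problem.with_gbar({n: (1.0 if n == name else 0.0) for n in free})
        # subtract the fixed background to leave the unit-gbar contribution
        sims = run_voltage_clamp(only, problem.protocol)
        unit[name] = [Trace(s.t, s.y - f.y, s.meta) for s, f in zip(sims, fixed)]

    masks = [problem._sample_mask(tr) for tr in problem.target]
    A = np.concatenate(
        [
            np.stack([unit[name][i].y[m] for name in free], axis=1)
            for i, m in enumerate(masks)
        ]
    )
    base = np.concatenate([f.y[m] for f, m in zip(fixed, masks)])
    y = np.concatenate([tgt.y[m] for tgt, m in zip(problem.target, masks)])
    resid0 = base - y

    def objective(G: np.ndarray) -> np.ndarray:
        # G: (n_particles, n_free) -> SSE per particle
        r = G @ A.T + resid0[None, :]
        return np.einsum("ij,ij->i", r, r)

    return objective


def pso_gbar(problem: FitProblem, swarm: int = SWARM_SIZE, iters: int = ITERATIONS,
             seed: int = None, init: dict = None) -> PSOResult:
    """Fit the free gbar values by global-best particle swarm optimization.

    Deterministic under a fixed ``seed``; the returned history of
    global-best SSE values is non-increasing and the final SSE never
    exceeds the initial one.  ``init`` seeds one particle (defaults to
    the model's current gbar values).
    """
    if swarm < 1:
        raise ValueError("swarm size must be >= 1")
    free = list(problem.free)
    if not free:
        raise ValueError("no free parameters to optimize")
    rng = np.random.default_rng(seed)
    lo = np.array([problem.bounds[n][0] for n in free])
    hi = np.array([problem.bounds[n][1] for n in free])

    objective = _linear_objective(problem)

    X = lo + (hi - lo) * rng.random((swarm, len(free)))
    x0 = np.array([
        (init or {}).get(n, problem.model.channel(n).gbar) for n in free
    ])
    X[0] = np.clip(x0, lo, hi)
    Vel = 0.1 * (hi - lo) * (rng.random((swarm, len(free))) - 0.5)

    fitness = objective(X)
    pbest_x = X.copy()
    pbest_f = fitness.copy()
    g_idx = int(np.argmin(pbest_f))
    gbest_x = pbest_x[g_idx].copy()
    gbest_f = float(pbest_f[g_idx])
    sse_initial = float(fitness[0])

    history = np.empty(max(iters, 0))
    for it in range(iters):
        r1 = rng.random((swarm, len(free)))
        r2 = rng.random((swarm, len(free)))
        Vel = (
            INERTIA * Vel
            + COGNITIVE * r1 * (pbest_x - X)
            + SOCIAL * r2 * (gbest_x[None, :] - X)
        )
        X = X + Vel
        # reflecting bounds
        over = X > hi
        under = X < lo
        X = np.where(over, 2 * hi - X, X)
        X = np.where(under, 2 * lo - X, X)
        X = np.clip(X, lo, hi)
        Vel = np.where(over | under, -Vel, Vel)

        fitness = objective(X)
        improved = fitness < pbest_f
        pbest_x[improved] = X[improved]
        pbest_f[improved] = fitness[improved]
        g_idx = int(np.argmin(pbest_f))
        if pbest_f[g_idx] < gbest_f:
            gbest_f = float(pbest_f[g_idx])
            gbest_x = pbest_x[g_idx].copy()
        history[it] = gbest_f

    return PSOResult(
        gbar={n: float(v) for n, v in zip(free, gbest_x)},
        sse_initial=sse_initial,
        sse_final=float(gbest_f),
        history=history,
        seed=seed,
    )
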