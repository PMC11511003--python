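"""Boolean-to-continuous conversion and cyclic-attractor resolution.

Synchronous Boolean updating can manufacture cyclic attractors that are
artifacts of discrete time rather than genuine oscillations.  To tell
the two apart, the network is embedded in a continuous dynamical
system: each node becomes a concentration ``x_i in [0, 1]`` obeying

    dx_i/dt = sigma_h(omega_i(x)) - gamma_i * x_i

where ``omega_i`` is the fuzzy-logic reading of the node's Boolean rule
(NOT -> 1 - x, AND -> min, OR -> max), and ``sigma_h`` is a logistic
gain of steepness ``h`` normalized so that ``sigma_h(0) = 0`` and
``sigma_h(1) = 1``.  On Boolean corner states ``omega_i`` coincides
with the Boolean rule, so for ``gamma = 1`` every Boolean fixed point
corresponds to a continuous steady state at the same corner.  A cyclic
attractor whose states all flow to one continuous steady state is an
artifact; its thresholded "shadow" identifies the cell type it
actually represents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .attractors import Attractor, AttractorSet
from .grn import CellTypeProfile, classify_state
from .network import BooleanNetwork


@dataclass(frozen=True)
class ContinuousParams:
    h: float = 10.0  # sigmoid gain (dimensionless)
    gamma: float = 1.0  # first-order decay rate (1/time)
    tol: float = 1e-6  # steady-state residual threshold on max |dx/dt|
    t_max: float = 100.0  # integration horizon (time units)

    def __post_init__(self):
        if self.h <= 0 or self.gamma <= 0:
            raise ValueError("h and gamma must be positive")


@dataclass(frozen=True)
class SteadyState:
    x: np.ndarray
    residual: float

    def shadow(self) -> tuple[int, ...]:
        """Thresholded Boolean state (x_i > 0.5)."""
        return tuple(int(v > 0.5) for v in self.x)


@dataclass(frozen=True)
class Trajectory:
    t: np.ndarray
    x: np.ndarray  # shape (len(t), n)
    steady_state: SteadyState | None


@dataclass(frozen=True)
class ContinuousSystem:
    """The ODE counterpart of a Boolean network."""

    net: BooleanNetwork
    params: ContinuousParams

    def omega(self, x: Sequence[float]) -> np.ndarray:
        """Fuzzy-logic input functions evaluated at ``x``."""
        env = dict(zip(self.net.nodes, x))
        out = np.empty(self.net.n)
        for i, name in enumerate(self.net.nodes):
            if name in self.net.clamps:
                out[i] = float(self.net.clamps[name])
            else:
                out[i] = self.net.rules[name].fuzzy(env)
        return out

    def sigma(self, w: np.ndarray) -> np.ndarray:
        h = self.params.h
        lo = 1.0 / (1.0 + np.exp(h / 2.0))
        hi = 1.0 / (1.0 + np.exp(-h / 2.0))
        return (1.0 / (1.0 + np.exp(-h * (w - 0.5))) - lo) / (hi - lo)

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        # clip guards tiny integrator overshoots outside the unit cube
        xc = np.clip(x, 0.0, 1.0)
        return self.sigma(self.omega(xc)) - self.params.gamma * x


def continuize(
    net: BooleanNetwork, h: float = 10.0, gamma: float = 1.0, **kwargs
) -> ContinuousSystem:
    """Build the continuous system for a Boolean network."""
    return ContinuousSystem(net=net, params=ContinuousParams(h=h, gamma=gamma, **kwargs))


def integrate(
    system: ContinuousSystem,
    x0: Sequence[float],
    t_max: float | None = None,
    tol: float | None = None,
) -> Trajectory:
    """Integrate from ``x0``; declare a steady state when the residual
    ``max |dx/dt|`` stays below ``tol``.

    Non-convergence within ``t_max`` is reported as a trajectory with
    ``steady_state=None``, not raised.
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (system.net.n,) or (x0 < 0).any() or (x0 > 1).any():
        raise ValueError("x0 must lie in the unit hypercube of the network")
    t_max = system.params.t_max if t_max is None else t_max
    tol = system.params.tol if tol is None else tol
    sol = solve_ivp(
        system.rhs,
        (0.0, t_max),
        x0,
        method="LSODA",
        rtol=1e-8,
        atol=1e-10,
        dense_output=False,
    )
    x = sol.y.T
    residuals = np.abs([system.rhs(0.0, row) for row in x]).max(axis=1)
    steady = None
    # sustained window: residual below tol at the end of the trajectory
    # and over the trailing 5% of the time span
    tail = sol.t >= sol.t[-1] - 0.05 * t_max
    if residuals[-1] < tol and np.all(residuals[tail] < tol):
        steady = SteadyState(x=x[-1], residual=float(residuals[-1]))
    return Trajectory(t=sol.t, x=x, steady_state=steady)


@dataclass(frozen=True)
class CycleResolution:
    """Continuous fate of one cyclic attractor."""

    cycle: Attractor
    steady_states: tuple[SteadyState | None, ...]  # one per cycle state
    converged: bool  # every start point reached a steady state
    common_shadow: tuple[int, ...] | None  # shared thresholded state
    profile_label: str | None  # cell type the shadow matches


def resolve_cyclic_attractors(
    net: BooleanNetwork,
    attractors: AttractorSet,
    params: ContinuousParams | None = None,
    profiles: list[CellTypeProfile] | None = None,
    jitter: float = 0.01,
) -> list[CycleResolution]:
    """Integrate the continuous system from every state of every cyclic
    attractor (corner embedding, plus a jittered replicate to separate
    knife-edge from robust convergence) and report the common fate.

    Networks with only fixed points give an empty report.
    """
    params = params or ContinuousParams()
    system = ContinuousSystem(net=net, params=params)
    rng = np.random.default_rng(0)
    out = []
    for cyc in attractors.cycles:
        states = []
        for code in cyc.states:
            corner = np.array(attractors.decode(code), dtype=float)
            starts = [corner]
            if jitter:
                bumped = corner + rng.uniform(-jitter, jitter, size=net.n)
                starts.append(np.clip(bumped, 0.0, 1.0))
            best: SteadyState | None = None
            for x0 in starts:
                traj = integrate(system, x0)
                if traj.steady_state is None:
                    best = None
                    break
                if best is None:
                    best = traj.steady_state
                elif best.shadow() != traj.steady_state.shadow():
                    best = None  # knife-edge: corner and jitter disagree
                    break
            states.append(best)
        converged = all(s is not None for s in states)
        shadows = {s.shadow() for s in states if s is not None}
        common = shadows.pop() if converged and len(shadows) == 1 else None
        label = None
        if common is not None:
            label = classify_state(dict(zip(net.nodes, common)), profiles)
        out.append(
            CycleResolution(
                cycle=cyc,
                steady_states=tuple(states),
                converged=converged,
                common_shadow=common,
                profile_label=label,
            )
        )
    return out
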