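"""ODE assembly, steady-state solving and stability classification.

Each dynamic pool M_i obeys a mass balance

    dM_i/dt = sum_j f_j - sum_k f_k

over the saturating rate laws of its producing (j) and consuming (k)
reactions; fixed pools enter the rate laws as constants and acquire no
equation.  A steady state is located by a root solve in log-concentration
space (which enforces positivity) from the basal state, falling back to
integration towards quasi-stationarity followed by a root polish.  Stability
is read off the eigenvalues of the analytic Jacobian: a state is stable iff
every eigenvalue has negative real part.

When no positive steady state exists (a consuming capacity smaller than the
incoming flux), the trajectory diverges; the solver then reports the
accumulating pools instead of a converged state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .network import PathwayModel

#: absolute residual tolerance for convergence, mM / model-time
RESIDUAL_TOL = 1e-8
#: relative tolerance of the trajectory integrator
INTEGRATION_RTOL = 1e-9
#: a pool is diagnosed "accumulating" past this fold-change over basal
ACCUMULATION_FOLD = 1e3


class SteadyStateError(RuntimeError):
    """The solver could not converge nor produce a divergence diagnosis."""


@dataclass
class SteadyState:
    """A (possibly non-converged) fixed-point solve of a pathway model."""

    concentrations: dict[str, float]
    residual_norm: float
    stable: bool
    eigenvalues: list[complex]
    converged: bool = True
    accumulating: list[str] = field(default_factory=list)


class ODESystem:
    """Derivative/Jacobian evaluator compiled from a :class:`PathwayModel`."""

    def __init__(self, model: PathwayModel):
        self.model = model
        self.pool_order: list[str] = model.dynamic_pools
        self._index = {n: i for i, n in enumerate(self.pool_order)}
        self._fixed = model.fixed_state()
        self.n = len(self.pool_order)
        # per-reaction: (reaction, effective law, [(state index, stoich sign)])
        self._terms: list[tuple] = []
        for r in model.reactions.values():
            law = r.effective_law()
            contrib: list[tuple[int, float]] = []
            for pool, st in r.substrates:
                if pool in self._index:
                    contrib.append((self._index[pool], -float(st)))
            for pool, st in r.products:
                if pool in self._index:
                    contrib.append((self._index[pool], +float(st)))
            self._terms.append((r, law, contrib))

    # -- state helpers ------------------------------------------------------

    def concentration_dict(self, y: np.ndarray) -> dict[str, float]:
        conc = dict(self._fixed)
        for name, i in self._index.items():
            conc[name] = y[i]
        return conc

    def state_vector(self, conc: dict[str, float]) -> np.ndarray:
        return np.array([conc[n] for n in self.pool_order], dtype=float)

    def basal_vector(self) -> np.ndarray:
        return self.state_vector(self.model.basal_state())

    # -- evaluation ---------------------------------------------------------

    def rates(self, y: np.ndarray) -> dict[str, float]:
        conc = self.concentration_dict(y)
        return {r.id: law.rate(conc) for r, law, _ in self._terms}

    def rhs(self, y: np.ndarray) -> np.ndarray:
        conc = self.concentration_dict(y)
        dydt = np.zeros(self.n)
        for _, law, contrib in self._terms:
            v = law.rate(conc)
            for i, s in contrib:
                dydt[i] += s * v
        return dydt

    def jacobian(self, y: np.ndarray) -> np.ndarray:
        """Analytic Jacobian d(dy/dt)/dy at the state ``y``."""
        conc = self.concentration_dict(y)
        J = np.zeros((self.n, self.n))
        for _, law, contrib in self._terms:
            _, grad = law.rate_and_gradient(conc)
            for pool, dv in grad.items():
                j = self._index.get(pool)
                if j is None:
                    continue  # fixed pool: no state column
                for i, s in contrib:
                    J[i, j] += s * dv
        return J


def assemble_odes(model: PathwayModel) -> ODESystem:
    """Compile the model's mass balances into a derivative evaluator."""
    return ODESystem(model)


def classify_stability(eigenvalues) -> str:
    """"stable" iff every eigenvalue real part is strictly negative."""
    eigs = list(eigenvalues)
    if not eigs:
        raise ValueError("empty eigenvalue list")
    return "stable" if max(np.real(e) for e in eigs) < 0 else "unstable"


def _try_root(system: ODESystem, y0: np.ndarray,
              maxfev: int | None = None) -> np.ndarray | None:
    """Root solve in log space; returns the state or None.

    ``maxfev`` caps the function-evaluation budget (used by scan probes that
    must fail fast on infeasible candidates).
    """
    u0 = np.log(y0)

    # clip keeps intermediate iterates finite; a converged root is unaffected
    def fun(u):
        return system.rhs(np.exp(np.clip(u, -60.0, 60.0)))

    def jac(u):
        y = np.exp(np.clip(u, -60.0, 60.0))
        return system.jacobian(y) * y[None, :]

    options = {"maxfev": maxfev} if maxfev else {}
    sol = root(fun, u0, jac=jac, method="hybr", tol=1e-12, options=options)
    y = np.exp(np.clip(sol.x, -60.0, 60.0))
    if np.all(np.isfinite(y)) and np.linalg.norm(system.rhs(y)) < RESIDUAL_TOL:
        return y
    return None


def _diagnose_accumulation(system: ODESystem, y0: np.ndarray,
                           horizon: float = 1e4) -> tuple[np.ndarray, list[str]]:
    """Integrate towards quasi-stationarity; return endpoint + accumulating pools.

    A pool is accumulating if it exceeds ``ACCUMULATION_FOLD`` times its basal
    value within the horizon, or grows monotonically over the final decade of
    the horizon.
    """
    basal = system.basal_vector()
    cap = ACCUMULATION_FOLD * np.maximum(basal, 1e-12)

    # saturating laws bound every flux, so divergent pools grow at most
    # linearly in time: the full horizon can be integrated without overflow
    t_tail = np.geomspace(horizon / 10.0, horizon, 12)
    sol = solve_ivp(
        lambda t, y: system.rhs(y), (0.0, horizon), y0,
        method="LSODA", jac=lambda t, y: system.jacobian(y),
        rtol=INTEGRATION_RTOL, atol=1e-12, t_eval=t_tail,
    )
    y_end = sol.y[:, -1]
    acc: list[str] = []
    for i in range(system.n):
        tail = sol.y[i, :]
        if len(tail) < 3:
            continue
        growing = bool(np.all(np.diff(tail) > 0))
        # a pool relaxing towards a (large but finite) steady state also rises
        # monotonically, so demand sustained relative growth over the final
        # decade of the horizon, or a cap exceedance that is still growing
        sustained = growing and tail[-1] / max(tail[0], 1e-300) > 1.5
        capped = growing and y_end[i] > cap[i]
        if sustained or capped:
            acc.append(system.pool_order[i])
    return y_end, acc


def find_steady_state(model: PathwayModel, init: dict[str, float] | None = None
                      ) -> SteadyState:
    """Locate the steady state reached from ``init`` (default: basal state).

    Returns a converged :class:`SteadyState` with eigenvalues and a stability
    flag, or a non-converged result carrying the accumulating-pool diagnosis
    when the model has no positive fixed point.
    """
    system = assemble_odes(model)
    y0 = system.basal_vector() if init is None else system.state_vector(init)
    if np.any(y0 <= 0):
        raise ValueError("initial concentrations must be positive")

    y = _try_root(system, y0)
    if y is None:
        y_end, acc = _diagnose_accumulation(system, y0)
        if acc:
            res = float(np.linalg.norm(system.rhs(y_end)))
            return SteadyState(
                concentrations=system.concentration_dict(y_end),
                residual_norm=res, stable=False, eigenvalues=[],
                converged=False, accumulating=acc,
            )
        y = _try_root(system, y_end)
        if y is None:
            res = float(np.linalg.norm(system.rhs(y_end)))
            if res < 1e-6:  # quasi-stationary but below polish tolerance
                y = y_end
            else:
                raise SteadyStateError(
                    f"no steady state found and no accumulating pool detected "
                    f"(residual {res:.3g})"
                )

    J = system.jacobian(y)
    eigs = np.linalg.eigvals(J)
    stable = classify_stability(eigs) == "stable"
    return SteadyState(
        concentrations=system.concentration_dict(y),
        residual_norm=float(np.linalg.norm(system.rhs(y))),
        stable=stable,
        eigenvalues=[complex(e) for e in eigs],
        converged=True,
    )


def jacobian(model: PathwayModel, state: dict[str, float]) -> np.ndarray:
    """Analytic Jacobian of the model's ODE right-hand side at ``state``."""
    system = assemble_odes(model)
    return system.jacobian(system.state_vector(state))
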