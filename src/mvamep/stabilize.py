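"""Minimal-intervention Vmax scan that restores homeostasis.

Line-personalized models can lose their stable steady state: when a
consuming capacity falls below the incoming flux, the early MEP
intermediates (DXP, CDP-MEP, MEcPP or combinations) accumulate without
bound.  Biologically this signals post-transcriptional regulation that the
transcript-proportionality assumption misses.  The stabilization procedure
emulates such regulation with the smallest possible change: it scans
multipliers on the saturation rate constants of the reactions consuming the
accumulating pools (the DXR, MDS and HDS steps) over 1-D, 2-D and 3-D grids
of log2-spaced factors, pools every stable candidate, and picks the one with
the minimum normalized Euclidean distance to the original parameter values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np

from .network import PathwayModel
from .odes import (
    _diagnose_accumulation,
    _try_root,
    assemble_odes,
    find_steady_state,
)

#: default scan targets: consumers of DXP, CDP-MEP and MEcPP
DEFAULT_TARGETS = ("r11", "r14", "r15")
#: log2 grid exponents per scanned axis
GRID_EXPONENTS = tuple(range(-3, 7))


@dataclass
class Candidate:
    """One multiplier vector from the scan (reaction id -> V multiplier)."""

    multipliers: dict[str, float]
    scanned_axes: tuple[str, ...]
    stable: bool

    def normalized_distance(self) -> float:
        logs = [np.log2(m) for m in self.multipliers.values()]
        return float(np.linalg.norm(logs) / np.sqrt(len(self.scanned_axes)))

    def n_changed(self) -> int:
        return sum(1 for m in self.multipliers.values() if m != 1.0)


@dataclass
class StabilizationResult:
    scanned_parameters: tuple[str, ...]
    candidates: list[Candidate]
    chosen: Candidate
    normalized_distance: float
    max_eigenvalue_real: float
    already_stable: bool = False

    def to_dict(self) -> dict:
        return {
            "scanned_parameters": list(self.scanned_parameters),
            "chosen_multipliers": self.chosen.multipliers,
            "normalized_distance": self.normalized_distance,
            "max_eigenvalue_real": self.max_eigenvalue_real,
            "already_stable": self.already_stable,
            "n_candidates": len(self.candidates),
        }


class NoStableCandidateError(RuntimeError):
    """The scan grid contained no stabilizing multiplier vector."""


def apply_multipliers(model: PathwayModel, multipliers: dict[str, float]
                      ) -> PathwayModel:
    out = model.copy()
    for rid, m in multipliers.items():
        r = out.reactions[rid]
        r.law = r.law.with_V(r.law.V * m)
    return out


def _quick_stable(model: PathwayModel) -> bool:
    """Fast stability probe: capped root solve + eigenvalue check."""
    system = assemble_odes(model)
    y = _try_root(system, system.basal_vector(), maxfev=300)
    if y is None or np.any(y <= 0):
        return False
    return np.max(np.real(np.linalg.eigvals(system.jacobian(y)))) < 0


def detect_accumulation(model: PathwayModel) -> list[str]:
    """Pools that accumulate; empty iff a stable steady state is found."""
    ss = find_steady_state(model)
    if ss.converged and ss.stable:
        return []
    if ss.accumulating:
        return ss.accumulating
    # converged but unstable fixed point: diagnose by integration; fall back
    # to the pools loading the dominant unstable eigendirection
    system = assemble_odes(model)
    _, acc = _diagnose_accumulation(system, system.basal_vector())
    if acc:
        return acc
    J = system.jacobian(system.state_vector(ss.concentrations))
    w, v = np.linalg.eig(J)
    k = int(np.argmax(np.real(w)))
    load = np.abs(np.real(v[:, k]))
    return [system.pool_order[int(np.argmax(load))]]


def scan_stabilizing_vmax(model: PathwayModel,
                          targets: tuple[str, ...] = DEFAULT_TARGETS,
                          exponents: tuple[int, ...] = GRID_EXPONENTS
                          ) -> list[Candidate]:
    """All stable multiplier vectors on 1-D/2-D/3-D subsets of the targets.

    An already-stable model short-circuits to the identity candidate.  An
    unstable model with no stable grid point returns an empty list (the
    caller must treat this as an explicit no-candidate status, never
    silently).
    """
    if _quick_stable(model) or not detect_accumulation(model):
        return [Candidate(multipliers={t: 1.0 for t in targets},
                          scanned_axes=tuple(targets), stable=True)]

    candidates: list[Candidate] = []
    for dim in range(1, min(3, len(targets)) + 1):
        for axes in combinations(targets, dim):
            for ks in product(exponents, repeat=dim):
                mult = {a: float(2.0 ** k) for a, k in zip(axes, ks)}
                if all(m == 1.0 for m in mult.values()):
                    continue  # identity re-test is redundant: model is unstable
                if _quick_stable(apply_multipliers(model, mult)):
                    candidates.append(Candidate(
                        multipliers=mult, scanned_axes=axes, stable=True))
    return candidates


def select_minimal_change(candidates: list[Candidate], model: PathwayModel
                          ) -> StabilizationResult:
    """Pick the stable candidate closest (normalized log2 distance) to basal.

    Ties broken by fewest changed parameters, then lexicographically by the
    (reaction, multiplier) items.
    """
    stable = [c for c in candidates if c.stable]
    if not stable:
        raise NoStableCandidateError("no stable candidate on the scan grid")

    def key(c: Candidate):
        return (c.normalized_distance(), c.n_changed(),
                tuple(sorted(c.multipliers.items())))

    chosen = min(stable, key=key)
    ss = find_steady_state(apply_multipliers(model, chosen.multipliers))
    if not (ss.converged and ss.stable):
        raise NoStableCandidateError(
            "chosen candidate failed full stability verification"
        )
    max_re = max(e.real for e in ss.eigenvalues)
    identity = all(m == 1.0 for m in chosen.multipliers.values())
    return StabilizationResult(
        scanned_parameters=tuple(sorted({a for c in stable for a in c.scanned_axes})),
        candidates=stable,
        chosen=chosen,
        normalized_distance=0.0 if identity else chosen.normalized_distance(),
        max_eigenvalue_real=float(max_re),
        already_stable=identity,
    )


def stabilize(model: PathwayModel,
              targets: tuple[str, ...] = DEFAULT_TARGETS
              ) -> tuple[StabilizationResult, PathwayModel]:
    """Scan, select and apply; returns the result and the stabilized model."""
    candidates = scan_stabilizing_vmax(model, targets)
    result = select_minimal_change(candidates, model)
    return result, apply_multipliers(model, result.chosen.multipliers)


def escalate_to_stability(model: PathwayModel,
                          axes: tuple[str, ...] = DEFAULT_TARGETS,
                          max_doublings: int = 4) -> PathwayModel | None:
    """Double the consumer capacities on ``axes`` until the model is stable.

    A cheap directed top-up for models whose deficit exceeds an
    already-chosen stabilization (e.g. a line deeper than its type median,
    or a hormone dose raising the pathway input flux): each step doubles the
    V of every axis at once, emulating stronger post-transcriptional
    upregulation of the same consumers.  Returns the stabilized model, or
    None if ``max_doublings`` does not suffice.
    """
    current = model
    for _ in range(max_doublings + 1):
        if _quick_stable(current):
            return current
        current = apply_multipliers(current, {a: 2.0 for a in axes})
    return None
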