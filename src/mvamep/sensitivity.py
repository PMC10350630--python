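"""Logarithmic steady-state sensitivity analysis.

The log-sensitivity of a steady-state variable X to a parameter p is

    S(X, p) = (dX / X) / (dp / p) = d log X / d log p .

Entries are computed by re-solving the steady state at log-centered
perturbations p * (1 + delta)^(+/-1) rather than by local linearization, so
they reflect the full nonlinear steady-state response.  Per-parameter and
per-metabolite aggregates compress the matrix for cross-model comparison:

    S'_j = ||column j||_2 / n      (n metabolites)
    S'_i = ||row i||_2 / m         (m parameters)

i.e. the Euclidean norm of the sensitivity vector normalized by the number
of components, which makes the indices comparable between variants whose
models differ in size.  Entries whose perturbed re-solve loses stability are
flagged (NaN) and excluded from the aggregates with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import PathwayModel
from .odes import SteadyState, _try_root, assemble_odes

#: relative perturbation for the re-solve, centered in log space
DEFAULT_DELTA = 0.01


def parameter_labels(model: PathwayModel) -> list[tuple[str, str, str | None]]:
    """Enumerate (reaction, kind, pool) for every V and K of the model."""
    labels: list[tuple[str, str, str | None]] = []
    for rid, r in model.reactions.items():
        labels.append((rid, "V", None))
        for pool in r.law.substrate_K:
            labels.append((rid, "K", pool))
    return labels


def _label_str(label: tuple[str, str, str | None]) -> str:
    rid, kind, pool = label
    return f"{rid}.V" if kind == "V" else f"{rid}.K.{pool}"


def perturbed_model(model: PathwayModel, label: tuple[str, str, str | None],
                    factor: float) -> PathwayModel:
    """Copy of the model with one kinetic constant multiplied by ``factor``."""
    rid, kind, pool = label
    out = model.copy()
    r = out.reactions[rid]
    if kind == "V":
        r.law = r.law.with_V(r.law.V * factor)
    else:
        K = dict(r.law.substrate_K)
        K[pool] = K[pool] * factor
        r.law = type(r.law)(V=r.law.V, substrate_K=K,
                            inhibitor_K=dict(r.law.inhibitor_K))
    return out


def _resolve(model: PathwayModel, init: np.ndarray) -> np.ndarray | None:
    system = assemble_odes(model)
    y = _try_root(system, init)
    if y is None or np.any(y <= 0):
        return None
    if np.max(np.real(np.linalg.eigvals(system.jacobian(y)))) >= 0:
        return None
    return y


@dataclass
class SensitivityMatrix:
    """Log-sensitivities (metabolite x parameter) with aggregate indices."""

    entries: pd.DataFrame
    per_parameter_index: pd.Series
    per_metabolite_index: pd.Series

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    @property
    def m(self) -> int:
        return self.entries.shape[1]

    def count_above(self, threshold: float = 1.0) -> int:
        return int((self.entries.abs() > threshold).sum().sum())


def aggregate_sensitivities(entries: pd.DataFrame
                            ) -> tuple[pd.Series, pd.Series]:
    """Per-parameter and per-metabolite norm-over-count indices."""
    n, m = entries.shape
    if entries.isna().any().any():
        warnings.warn("flagged sensitivity entries excluded from aggregates")
    col = np.sqrt((entries ** 2).sum(axis=0, skipna=True)) / n
    row = np.sqrt((entries ** 2).sum(axis=1, skipna=True)) / m
    return col, row


def log_sensitivities(model: PathwayModel, ss: SteadyState,
                      delta: float = DEFAULT_DELTA) -> SensitivityMatrix:
    """Full log-sensitivity matrix of the steady state, by perturb-and-re-solve."""
    if not (ss.converged and ss.stable):
        raise ValueError("sensitivities require a stable, converged steady state")
    system = assemble_odes(model)
    y0 = system.state_vector(ss.concentrations)
    pools = system.pool_order
    labels = parameter_labels(model)
    factor = 1.0 + delta
    span = 2.0 * np.log(factor)

    cols: dict[str, np.ndarray] = {}
    for label in labels:
        up = _resolve(perturbed_model(model, label, factor), y0)
        dn = _resolve(perturbed_model(model, label, 1.0 / factor), y0)
        if up is None or dn is None:
            cols[_label_str(label)] = np.full(len(pools), np.nan)
            continue
        cols[_label_str(label)] = (np.log(up) - np.log(dn)) / span

    entries = pd.DataFrame(cols, index=pools)
    per_param, per_met = aggregate_sensitivities(entries)
    return SensitivityMatrix(entries=entries, per_parameter_index=per_param,
                             per_metabolite_index=per_met)


def eigenvalue_sensitivities(model: PathwayModel, ss: SteadyState,
                             delta: float = DEFAULT_DELTA) -> pd.DataFrame:
    """Log-sensitivity of each eigenvalue modulus to each parameter.

    Eigenvalues are tracked by descending real part; a column is flagged
    (NaN) when the base spectrum is near-degenerate, where tracking by order
    is unreliable (eigenvalue crossing under perturbation).
    """
    if not (ss.converged and ss.stable):
        raise ValueError("eigenvalue sensitivities require a stable steady state")
    system = assemble_odes(model)
    y0 = system.state_vector(ss.concentrations)

    def spectrum(m: PathwayModel, y: np.ndarray) -> np.ndarray | None:
        yy = _resolve(m, y)
        if yy is None:
            return None
        eigs = np.linalg.eigvals(assemble_odes(m).jacobian(yy))
        order = np.argsort(-np.real(eigs))
        return eigs[order]

    base = np.sort(-np.real(np.array(ss.eigenvalues)))
    gaps = np.diff(base) / np.maximum(np.abs(base[:-1]), 1e-30)
    degenerate = bool(np.any(np.abs(gaps) < 1e-9))

    labels = parameter_labels(model)
    factor = 1.0 + delta
    span = 2.0 * np.log(factor)
    n_eig = len(ss.eigenvalues)
    cols: dict[str, np.ndarray] = {}
    for label in labels:
        if degenerate:
            cols[_label_str(label)] = np.full(n_eig, np.nan)
            continue
        up = spectrum(perturbed_model(model, label, factor), y0)
        dn = spectrum(perturbed_model(model, label, 1.0 / factor), y0)
        if up is None or dn is None:
            cols[_label_str(label)] = np.full(n_eig, np.nan)
            continue
        cols[_label_str(label)] = (np.log(np.abs(up)) - np.log(np.abs(dn))) / span
    index = [f"eig{i+1}" for i in range(n_eig)]
    return pd.DataFrame(cols, index=index)
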