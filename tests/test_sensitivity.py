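"""Log-sensitivities: planted power laws, step-size robustness, aggregates."""

import numpy as np
import pandas as pd
import pytest

from mvamep.odes import find_steady_state
from mvamep.sensitivity import (
    aggregate_sensitivities,
    eigenvalue_sensitivities,
    log_sensitivities,
    parameter_labels,
)


def test_planted_power_law_exponents_recovered(linear_toy):
    """M* = c K / (V - c): exact log-sensitivities are K: +1, and
    V: -V/(V-c) (the planted power-law exponent in V at the fixed point)."""
    model, p = linear_toy
    ss = find_steady_state(model)
    sm = log_sensitivities(model, ss)
    assert sm.entries.loc["M", "cons.K.M"] == pytest.approx(1.0, abs=1e-4)
    expected_v = -p["V"] / (p["V"] - p["c"])
    assert sm.entries.loc["M", "cons.V"] == pytest.approx(expected_v, rel=1e-3)
    # production scale: d log M* / d log c = V/(V-c)
    assert sm.entries.loc["M", "prod.V"] == pytest.approx(-expected_v, rel=1e-3)


def test_step_size_halving_changes_little(chain_toy):
    """Richardson-style check: halving the perturbation moves entries < 1e-4."""
    ss = find_steady_state(chain_toy)
    a = log_sensitivities(chain_toy, ss, delta=0.01).entries
    b = log_sensitivities(chain_toy, ss, delta=0.005).entries
    diff = (a - b).abs().to_numpy()
    scale = np.maximum(np.abs(a.to_numpy()), 1.0)
    assert np.max(diff / scale) < 1e-4


def test_matrix_dimensions_match_parameter_count(wt_model):
    ss = find_steady_state(wt_model)
    sm = log_sensitivities(wt_model, ss)
    assert sm.n == 14
    assert sm.m == len(parameter_labels(wt_model))
    # aggregates recomputable from the entries
    col, row = aggregate_sensitivities(sm.entries)
    pd.testing.assert_series_equal(col, sm.per_parameter_index)
    pd.testing.assert_series_equal(row, sm.per_metabolite_index)


def test_aggregate_indices_formula():
    entries = pd.DataFrame({"p1": [3.0, 4.0], "p2": [0.0, 0.0]},
                           index=["m1", "m2"])
    col, row = aggregate_sensitivities(entries)
    assert col["p1"] == pytest.approx(5.0 / 2.0)  # ||(3,4)|| / n
    assert col["p2"] == 0.0
    assert row["m1"] == pytest.approx(3.0 / 2.0)
    # independent recomputation on a random matrix
    rng = np.random.default_rng(0)
    m = pd.DataFrame(rng.normal(size=(3, 4)),
                     columns=[f"p{i}" for i in range(4)])
    col2, row2 = aggregate_sensitivities(m)
    for j, c in enumerate(m.columns):
        assert col2[c] == pytest.approx(np.linalg.norm(m[c]) / 3)
    for i in m.index:
        assert row2[i] == pytest.approx(np.linalg.norm(m.loc[i]) / 4)


def test_aggregates_invariant_to_permutation(chain_toy):
    ss = find_steady_state(chain_toy)
    sm = log_sensitivities(chain_toy, ss)
    shuffled = sm.entries.sample(frac=1.0, axis=0, random_state=1) \
                         .sample(frac=1.0, axis=1, random_state=2)
    col, row = aggregate_sensitivities(shuffled)
    assert sorted(col) == pytest.approx(sorted(sm.per_parameter_index))
    assert sorted(row) == pytest.approx(sorted(sm.per_metabolite_index))


def test_sensitivities_require_stable_state(linear_toy):
    model, _ = linear_toy
    ss = find_steady_state(model)
    ss.stable = False
    with pytest.raises(ValueError):
        log_sensitivities(model, ss)


def test_eigenvalue_sensitivity_of_linear_decay(linear_toy):
    """Toy relaxation rate ~ V/(K+M): |eigenvalue| rises ~1:1 with V's
    first-order part; perturbation oracle at two deltas agrees to 1e-3."""
    model, p = linear_toy
    ss = find_steady_state(model)
    a = eigenvalue_sensitivities(model, ss, delta=0.01)
    b = eigenvalue_sensitivities(model, ss, delta=0.002)
    # two-step-size agreement
    assert np.nanmax(np.abs(a.to_numpy() - b.to_numpy())) < 1e-3
    # single eigenvalue: |lambda| = V K/(K+M*)^2 with M* = cK/(V-c), so both
    # K and M* scale linearly in K and |lambda| ~ V/K: exact log-slope is -1
    assert a.loc["eig1", "cons.K.M"] == pytest.approx(-1.0, abs=1e-3)
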