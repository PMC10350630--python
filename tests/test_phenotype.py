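"""Stepwise phenotype regression, shipped reference models, leaf area."""

import numpy as np
import pandas as pd
import pytest

from mvamep.phenotype import (
    PhenotypeModel,
    evaluate_phenotype,
    forward_stepwise,
    leaf_area,
    predictor_type,
    reference_phenotype_models,
)
from mvamep.synthetic import make_regression_dataset


@pytest.mark.parametrize("l, w, expected", [(1.0, 1.0, 0.75),
                                            (0.0, 5.0, 0.0),
                                            (10.0, 1.0, 7.5)])
def test_leaf_area_correction_factor(l, w, expected):
    assert leaf_area(l, w) == pytest.approx(expected)


def test_leaf_area_rejects_negative_dimensions():
    with pytest.raises(ValueError):
        leaf_area(-1.0, 2.0)


def test_planted_two_predictor_model_recovered():
    data, truth = make_regression_dataset(seed=11, n=30)
    model, trace = forward_stepwise(data, "y")
    assert model is not None
    assert set(truth) <= set(model.predictors)
    # coefficient SE at n=30 and R2 ~ 0.7 is ~0.3; allow ~3 SE
    assert model.coefficients["x1"] == pytest.approx(2.0, abs=0.9)
    assert model.coefficients["x2"] == pytest.approx(-1.5, abs=0.9)
    assert trace.steps  # the trace records every candidate evaluation


def test_pure_noise_returns_no_model():
    rng = np.random.default_rng(4)
    data = pd.DataFrame({f"x{i}": rng.normal(size=25) for i in range(5)})
    data["y"] = rng.normal(size=25)
    model, trace = forward_stepwise(data, "y")
    assert model is None
    assert trace.steps


def test_stepwise_gates_hold_on_returned_model():
    """Every kept predictor is significant, the fit clears the adjusted-R2
    gate, and no kept pair is collinear."""
    data, _ = make_regression_dataset(seed=21, n=30)
    # add a near-duplicate of x1 to exercise the collinearity gate
    data["x1_dup"] = data["x1"] + 1e-3 * np.random.default_rng(0).normal(size=len(data))
    model, _ = forward_stepwise(data, "y")
    assert model is not None
    assert model.r2_adj > 0.2
    assert not ({"x1", "x1_dup"} <= set(model.predictors))
    import statsmodels.api as sm

    X = sm.add_constant(data[model.predictors])
    fit = sm.OLS(data["y"], X).fit()
    assert all(fit.pvalues[p] < 0.05 for p in model.predictors)
    corr = data[model.predictors].corr().abs()
    off_diag = corr.to_numpy()[~np.eye(len(model.predictors), dtype=bool)]
    assert np.all(off_diag < 0.7)


def test_too_few_lines_rejected():
    data, _ = make_regression_dataset(seed=1, n=5)
    with pytest.raises(ValueError, match="6"):
        forward_stepwise(data, "y")


def test_evaluation_is_affine_apart_from_rounding():
    model = PhenotypeModel(
        response="height", predictors=["a", "b"],
        coefficients={"intercept": 10.0, "a": 2.0, "b": -1.0},
    )
    base = model.evaluate({"a": 0.0, "b": 0.0})
    assert base == 10.0
    assert model.evaluate({"a": 1.0, "b": 0.0}) - base == pytest.approx(2.0)
    assert model.evaluate({"a": 2.0, "b": 3.0}) == pytest.approx(10.0 + 4.0 - 3.0)
    with pytest.raises(KeyError):
        model.evaluate({"a": 1.0})


def test_leaf_count_models_round_to_integer():
    ref = reference_phenotype_models()
    leaves = ref["I"]["leaves"]
    assert leaves.rounded
    assert evaluate_phenotype(leaves, {"DXP": 0.0, "MEcPP": 0.0}) == 5.0


def test_reference_models_expected_structure():
    ref = reference_phenotype_models()
    assert set(ref) == {"I", "II", "III"}
    # responses predicted per type follow the study's coverage
    assert set(ref["I"]) == {"height", "leaves", "leaf_length", "chlorophyll"}
    assert set(ref["II"]) == {"leaves", "leaf_length", "leaf_width", "chlorophyll"}
    assert set(ref["III"]) == {"height", "leaf_length", "leaf_width", "chlorophyll"}
    # typed predictors: genes, hormones and metabolites all appear
    types = {predictor_type(p) for ms in ref.values() for m in ms.values()
             for p in m.predictors}
    assert types == {"gene", "hormone", "metabolite"}
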