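"""Hormone-link fitting, formalism choice and model coupling."""

import numpy as np
import pandas as pd
import pytest

from mvamep.hormones import (
    DetectionLimit,
    HormoneLink,
    HormoneLinkError,
    attach_hormone_modifiers,
    choose_formalism,
    fit_hormone_correlations,
    remove_hormone_modifiers,
    validate_correlation_recovery,
)
from mvamep.io import model_to_dict
from mvamep.lines import HormoneMeasurement, LineProfile
from mvamep.network import ENDOGENOUS_GENES, EXOGENOUS_GENES
from mvamep.odes import assemble_odes
from mvamep.synthetic import make_link_dataset


def _lines_with(hormone_levels, below=None):
    below = below or [False] * len(hormone_levels)
    lines = []
    for i, (h, b) in enumerate(zip(hormone_levels, below)):
        ratios = {g: 1.0 for g in ENDOGENOUS_GENES}
        ratios.update({g: 0.0 for g in EXOGENOUS_GENES})
        lines.append(LineProfile(
            line_id=f"L{i}", variant="WT", expression_ratio=ratios,
            hormone={"iP": HormoneMeasurement(h, b)},
        ))
    return lines


def test_planted_exponent_recovered_at_n30():
    H, M = make_link_dataset(seed=5, n=30, alpha=2.0, g=0.8, noise_cv=0.2)
    lines = _lines_with(list(H))
    responses = pd.DataFrame({"DXP": M}, index=[f"L{i}" for i in range(30)])
    links = fit_hormone_correlations(lines, responses, "metabolite")
    assert len(links) == 1
    assert links[0].g == pytest.approx(0.8, abs=0.15)
    assert links[0].pvalue < 0.05


def test_constant_hormone_yields_no_link():
    lines = _lines_with([5.0] * 10)
    responses = pd.DataFrame({"DXP": np.linspace(1, 2, 10)},
                             index=[f"L{i}" for i in range(10)])
    assert fit_hormone_correlations(lines, responses, "metabolite") == []


def test_all_censored_hormone_skipped_with_notice():
    lines = _lines_with([5.0] * 6, below=[True] * 6)
    responses = pd.DataFrame({"DXP": np.linspace(1, 2, 6)},
                             index=[f"L{i}" for i in range(6)])
    with pytest.warns(UserWarning, match="censored"):
        links = fit_hormone_correlations(lines, responses, "metabolite")
    assert links == []


@pytest.mark.parametrize(
    "g, r2, expected",
    [(1.0, 0.8, "power_law"),     # ratio 0.8 > 0.5
     (2.0, 0.2, "saturating"),    # ratio 0.1
     (1.0, 0.5, "saturating")],   # boundary exactly 0.5 -> saturating side
)
def test_formalism_selection_rule(g, r2, expected):
    assert choose_formalism(g, r2) == expected


def test_zero_exponent_has_no_formalism():
    with pytest.raises(HormoneLinkError):
        choose_formalism(0.0, 0.5)


def _link(formalism="power_law", g=0.8, ref=10.0, K=None):
    return HormoneLink(
        hormone="iP", response="OsDXS", response_kind="gene",
        formalism=formalism, g=g, K=K, reference_level=ref,
        r2_adj=0.7, pvalue=0.01,
    )


def test_multiplier_is_one_at_reference_level():
    for link in (_link(), _link("saturating", K=10.0)):
        assert link.factor(link.reference_level) == pytest.approx(1.0)


def test_multiplier_monotone_and_continuous():
    grid = np.geomspace(0.1, 1000.0, 50)
    for link in (_link(g=0.8), _link("saturating", g=0.8, K=10.0),
                 _link(g=-0.5), _link("saturating", g=-0.5, K=10.0)):
        f = [link.factor(h) for h in grid]
        d = np.diff(f)
        assert np.all(d > 0) if link.g > 0 else np.all(d < 0)


def test_saturating_multiplier_limit_is_alpha():
    link = _link("saturating", g=0.8, K=10.0)
    assert link.factor(1e12) == pytest.approx(link.alpha_scale, rel=1e-6)


def test_below_detection_reverts_to_basal(wt_model):
    link = _link(g=0.8)
    coupled = attach_hormone_modifiers(wt_model, [link],
                                       {"iP": (50.0, True)})
    # factor 1 everywhere: rates identical to the basal model
    sys_a, sys_b = assemble_odes(wt_model), assemble_odes(coupled)
    y = sys_a.basal_vector()
    assert sys_a.rates(y) == pytest.approx(sys_b.rates(y))


def test_attach_then_remove_restores_basal_exactly(wt_model):
    link = _link(g=0.8)
    coupled = attach_hormone_modifiers(wt_model, [link], {"iP": (50.0, False)})
    sys_a, sys_b = assemble_odes(wt_model), assemble_odes(coupled)
    y = sys_a.basal_vector()
    assert sys_b.rates(y)["r10"] != pytest.approx(sys_a.rates(y)["r10"])
    restored = remove_hormone_modifiers(coupled)
    assert model_to_dict(restored) == model_to_dict(wt_model)


def test_link_to_absent_target_is_configuration_error(wt_model):
    bad = HormoneLink(hormone="iP", response="NotAPool",
                      response_kind="metabolite", formalism="power_law",
                      g=1.0, K=None, reference_level=1.0, r2_adj=0.5,
                      pvalue=0.01)
    with pytest.raises(HormoneLinkError):
        attach_hormone_modifiers(wt_model, [bad], {"iP": (1.0, False)})


def test_insignificant_link_rejected_on_construction():
    with pytest.raises(HormoneLinkError):
        _l = HormoneLink(hormone="iP", response="OsDXS", response_kind="gene",
                         formalism="power_law", g=1.0, K=None,
                         reference_level=1.0, r2_adj=0.5, pvalue=0.2)


def test_detection_limit_validation():
    assert DetectionLimit("iP", 0.0).limit == 0.0
    with pytest.raises(ValueError):
        DetectionLimit("iP", -1.0)


def test_planted_link_sign_recovered_by_coupled_model(wt_model):
    """A positive hormone->DXS link must produce a positive simulated
    hormone-DXP correlation in the coupled model."""
    gene_link = _link(g=0.4)  # modest exponent keeps the sweep stable
    met_link = HormoneLink(
        hormone="iP", response="DXP", response_kind="metabolite",
        formalism="power_law", g=0.9, K=None, reference_level=10.0,
        r2_adj=0.6, pvalue=0.01,
    )
    matched, assessed, ambiguous = validate_correlation_recovery(
        wt_model, [gene_link], [met_link], {"iP": (5.0, 20.0)})
    assert (matched, assessed, ambiguous) == (1, 1, 0)


def test_no_links_assesses_nothing(wt_model):
    assert validate_correlation_recovery(wt_model, [], [], {}) == (0, 0, 0)


def test_sign_recovery_rate_at_n30():
    """>= 95% of planted links (CV 20% noise, n = 30) recover the right sign."""
    hits = trials = 0
    for rep in range(100):
        g_true = 0.6 if rep % 2 == 0 else -0.6
        H, M = make_link_dataset(seed=1000 + rep, n=30, g=g_true, noise_cv=0.2)
        lines = _lines_with(list(H))
        responses = pd.DataFrame({"DXP": M},
                                 index=[f"L{i}" for i in range(30)])
        links = fit_hormone_correlations(lines, responses, "metabolite")
        trials += 1
        if links and np.sign(links[0].g) == np.sign(g_true):
            hits += 1
    assert hits / trials >= 0.95
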