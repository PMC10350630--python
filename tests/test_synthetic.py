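"""Synthetic cohort generator: determinism, invariants, planted structure."""

import numpy as np
import pytest

from mvamep.lines import profiles_to_frame
from mvamep.network import EXOGENOUS_BY_VARIANT, EXOGENOUS_GENES
from mvamep.odes import find_steady_state
from mvamep.network import build_variant_model
from mvamep.synthetic import (
    DEFAULT_COHORT,
    GeneratorConfig,
    generate_lines,
    generate_parameter_set,
    make_ground_truth_bundle,
)


def test_same_seed_reproduces_parameters_exactly():
    a = generate_parameter_set(GeneratorConfig(seed=9))
    b = generate_parameter_set(GeneratorConfig(seed=9))
    assert a.sets["III"].values == b.sets["III"].values
    assert a.attempts == b.attempts


def test_same_seed_reproduces_lines_byte_identically(tmp_path, library):
    cfg = GeneratorConfig(seed=4, variant="III")
    fa = profiles_to_frame(generate_lines(cfg, library))
    fb = profiles_to_frame(generate_lines(cfg, library))
    pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
    fa.to_csv(pa, sep="\t", index=False)
    fb.to_csv(pb, sep="\t", index=False)
    assert pa.read_bytes() == pb.read_bytes()


def test_calibrated_models_are_stable(library):
    for variant in ("WT", "I", "II", "III"):
        model = build_variant_model(variant, library.for_variant(variant))
        ss = find_steady_state(model)
        assert ss.converged and ss.stable


def test_wild_type_cohort_has_no_transgene_expression(library):
    lines = generate_lines(GeneratorConfig(seed=2, variant="WT"), library)
    assert len(lines) == DEFAULT_COHORT["WT"]
    for p in lines:
        assert all(p.expression_ratio[g] == 0.0 for g in EXOGENOUS_GENES)


@pytest.mark.parametrize("variant", ["I", "II", "III"])
def test_exogenous_genes_match_variant(library, variant):
    lines = generate_lines(GeneratorConfig(seed=2, variant=variant), library)
    allowed = set(EXOGENOUS_BY_VARIANT[variant])
    for p in lines:
        for g in EXOGENOUS_GENES:
            if g in allowed:
                assert p.expression_ratio[g] > 0
            else:
                assert p.expression_ratio[g] == 0.0


def test_generated_profiles_satisfy_invariants(library):
    # LineProfile.__post_init__ enforces the invariants; construction of a
    # full bundle across variants must never raise
    for variant in ("WT", "I", "II", "III"):
        generate_lines(GeneratorConfig(seed=6, variant=variant), library)


def test_empirical_log_sd_matches_config(library):
    """Expression log-SDs within 3 standard errors at n >= 100 (genes with
    neither planted deficit nor hormone modulation)."""
    cfg = GeneratorConfig(seed=8, variant="I", n_lines=150)
    lines = generate_lines(cfg, library)
    for gene in ("OsPMK", "OsMVD", "OsCMK"):
        logs = np.log([p.expression_ratio[gene] for p in lines])
        sd = np.std(logs, ddof=1)
        se = cfg.endogenous_log_sd / np.sqrt(2 * (len(lines) - 1))
        assert abs(sd - cfg.endogenous_log_sd) < 3 * se


def test_hormone_censoring_respects_detection_limits(library):
    cfg = GeneratorConfig(seed=8, variant="II", n_lines=200)
    lines = generate_lines(cfg, library)
    censored = [p.hormone["jasmonic_acid"].below_detection for p in lines]
    # the jasmonic acid limit sits half an SD below the mean: ~31% censored
    frac = np.mean(censored)
    assert 0.15 < frac < 0.5
    for p in lines:
        for h, m in p.hormone.items():
            assert m.below_detection == (m.level < cfg.detection_limits[h])


def test_ground_truth_bundle_carries_recoverable_truths():
    bundle = make_ground_truth_bundle(GeneratorConfig(seed=3, variant="II"))
    assert len(bundle.lines) == DEFAULT_COHORT["II"]
    assert {l.gene for l in bundle.true_links} == {"OsDXS", "OsMCT"}
    assert set(bundle.true_multipliers) == {"r11", "r14"}
    assert all(m > 1 for m in bundle.true_multipliers.values())
    assert set(bundle.true_phenotypes) == {
        "height", "leaves", "leaf_length", "leaf_width", "chlorophyll"}


def test_bundle_without_planted_links_assesses_nothing(library):
    from mvamep.hormones import validate_correlation_recovery

    cfg = GeneratorConfig(seed=3, variant="I", planted_links=())
    bundle = make_ground_truth_bundle(cfg)
    assert bundle.true_links == ()
    model = build_variant_model("I", bundle.params.for_variant("I"))
    assert validate_correlation_recovery(model, [], [], {}) == (0, 0, 0)


def test_fully_censored_hormone_leaves_model_basal(library):
    """Detection limits above every observed level censor the hormone, so
    the coupling stage must leave the kinetic model untouched."""
    from mvamep.hormones import HormoneLink, attach_hormone_modifiers
    from mvamep.io import model_to_dict
    from mvamep.odes import assemble_odes

    cfg = GeneratorConfig(seed=5, variant="I")
    cfg.detection_limits = {h: 1e9 for h in cfg.detection_limits}
    lines = generate_lines(cfg, library)
    assert all(m.below_detection for p in lines for m in p.hormone.values())
    model = build_variant_model("I", library.for_variant("I"))
    link = HormoneLink(hormone="iP", response="OsDXS", response_kind="gene",
                       formalism="power_law", g=0.8, K=None,
                       reference_level=5.0, r2_adj=0.7, pvalue=0.01)
    med = lines[0].hormone["iP"]
    coupled = attach_hormone_modifiers(model, [link],
                                       {"iP": (med.level, med.below_detection)})
    sys_a, sys_b = assemble_odes(model), assemble_odes(coupled)
    y = sys_a.basal_vector()
    assert sys_a.rates(y) == pytest.approx(sys_b.rates(y))
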