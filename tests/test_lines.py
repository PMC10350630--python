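"""Line profiles: scaling, medians and TSV round-trips."""

import pytest

from mvamep.lines import (
    HormoneMeasurement,
    LineProfile,
    LineProfileError,
    median_line,
    read_profiles_tsv,
    scale_line,
    wild_type_profile,
    write_profiles_tsv,
)
from mvamep.network import ENDOGENOUS_GENES, EXOGENOUS_GENES, build_variant_model
from mvamep.synthetic import GeneratorConfig, generate_lines


def _profile(variant="I", **ratios):
    base = {g: 1.0 for g in ENDOGENOUS_GENES}
    base.update({g: 0.0 for g in EXOGENOUS_GENES})
    for g in ("tHMGR",) if variant == "I" else ():
        base[g] = 1.0
    base.update(ratios)
    return LineProfile(line_id="L", variant=variant, expression_ratio=base)


def test_identity_ratios_leave_model_unchanged(library):
    model = build_variant_model("I", library.for_variant("I"))
    scaled = scale_line(model, _profile())
    for rid, r in model.reactions.items():
        assert scaled.reactions[rid].law.V == r.law.V


def test_single_gene_ratio_scales_only_its_reaction(library):
    model = build_variant_model("I", library.for_variant("I"))
    scaled = scale_line(model, _profile(tHMGR=2.0))
    for rid, r in model.reactions.items():
        expected = 2.0 * r.law.V if rid == "e_HMGR_pl" else r.law.V
        assert scaled.reactions[rid].law.V == expected


def test_zero_exogenous_ratio_silences_ectopic_reaction(library):
    model = build_variant_model("I", library.for_variant("I"))
    scaled = scale_line(model, _profile(tHMGR=0.0))
    law = scaled.reactions["e_HMGR_pl"].law
    assert law.V == 0.0
    assert law.rate({"HMGCoA_pl": 1.0}) == 0.0


def test_reciprocal_scaling_restores_parameters_exactly(library):
    model = build_variant_model("I", library.for_variant("I"))
    ratios = {g: 1.7 for g in ENDOGENOUS_GENES}
    ratios.update({g: 0.0 for g in EXOGENOUS_GENES})
    ratios["tHMGR"] = 4.0
    fwd = _profile(**ratios)
    inv_ratios = {g: (1.0 / r if r else 0.0) for g, r in ratios.items()}
    # exogenous zero cannot be inverted; keep the ectopic reaction untouched
    fwd.expression_ratio["tHMGR"] = 4.0
    inv = _profile(**dict(inv_ratios, tHMGR=0.25))
    back = scale_line(scale_line(model, fwd), inv)
    for rid, r in model.reactions.items():
        assert back.reactions[rid].law.V == pytest.approx(r.law.V, rel=1e-15)


def test_variant_mismatch_and_missing_ratio_errors(library):
    model = build_variant_model("II", library.for_variant("II"))
    with pytest.raises(LineProfileError, match="variant"):
        scale_line(model, _profile(variant="I"))
    p = _profile(variant="I")
    del p.expression_ratio["OsDXR"]
    model_i = build_variant_model("I", library.for_variant("I"))
    with pytest.raises(LineProfileError, match="OsDXR"):
        scale_line(model_i, p)


def test_wild_type_profile_invariants():
    p = wild_type_profile()
    assert all(p.expression_ratio[g] == 1.0 for g in ENDOGENOUS_GENES)
    assert all(p.expression_ratio[g] == 0.0 for g in EXOGENOUS_GENES)


def test_exogenous_gene_in_wrong_variant_rejected():
    with pytest.raises(LineProfileError, match="CrMVD"):
        _profile(variant="I", CrMVD=1.0)


def test_median_line_odd_even_and_detection_rule():
    def prof(i, dxr, ipp_level, below):
        p = _profile()
        p.line_id = f"L{i}"
        p.expression_ratio["OsDXR"] = dxr
        p.hormone = {"iP": HormoneMeasurement(ipp_level, below)}
        p.phenotype = {"height": 50.0 + i}
        return p

    odd = [prof(0, 1.0, 5.0, True), prof(1, 2.0, 7.0, True), prof(2, 4.0, 9.0, False)]
    med = median_line(odd, "I")
    assert med.expression_ratio["OsDXR"] == 2.0
    assert med.hormone["iP"].level == 7.0
    assert med.hormone["iP"].below_detection  # 2 of 3 censored
    assert med.phenotype["height"] == 51.0

    even = [prof(0, 1.0, 5.0, False), prof(1, 3.0, 7.0, True)]
    med2 = median_line(even, "I")
    assert med2.expression_ratio["OsDXR"] == 2.0  # midpoint convention
    assert not med2.hormone["iP"].below_detection  # half is not a majority


def test_median_line_rejects_empty_and_mixed_variants():
    with pytest.raises(LineProfileError):
        median_line([], "I")
    with pytest.raises(LineProfileError, match="variant"):
        median_line([_profile(), _profile(variant="I")], "II")


def test_identical_profiles_median_is_any_input():
    ps = [_profile() for _ in range(3)]
    for i, p in enumerate(ps):
        p.line_id = f"L{i}"
    med = median_line(ps, "I")
    assert med.expression_ratio == ps[0].expression_ratio


def test_tsv_round_trip_is_lossless(tmp_path, library):
    lines = generate_lines(GeneratorConfig(seed=3, variant="II"), library)
    path = tmp_path / "lines.tsv"
    write_profiles_tsv(lines, path)
    back = read_profiles_tsv(path)
    assert len(back) == len(lines)
    for a, b in zip(lines, back):
        assert a.line_id == b.line_id and a.variant == b.variant
        assert a.expression_ratio == pytest.approx(b.expression_ratio)
        for h in a.hormone:
            assert a.hormone[h].level == pytest.approx(b.hormone[h].level)
            assert a.hormone[h].below_detection == b.hormone[h].below_detection
        assert a.phenotype == pytest.approx(b.phenotype)
    # a second write of the re-read profiles is byte-identical
    path2 = tmp_path / "lines2.tsv"
    write_profiles_tsv(back, path2)
    assert path.read_bytes() == path2.read_bytes()
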