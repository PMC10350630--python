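"""Line profiles: per-line expression ratios, hormones and phenotypes.

A "line" is one independent transformant with its own molecular profile; a
"type" (variant) is the transgene-combination class.  Expression ratios are
measured relative to the wild type, and — under the proportionality
assumption between transcript change and enzyme-activity change — scale the
apparent saturation rate constant of the reactions catalysed by the gene:

    V_line = V_basal * (expression_line / expression_WT)

Exogenous transgenes are absent from non-matching variants (ratio 0); WT
lines carry ratio 1 for every endogenous gene and 0 for every transgene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .network import (
    ENDOGENOUS_GENES,
    EXOGENOUS_BY_VARIANT,
    EXOGENOUS_GENES,
    PathwayModel,
    VARIANTS,
)

HORMONES = (
    "trans_zeatin", "zeatin_riboside", "iP", "GA1", "GA3", "GA4",
    "IAA", "ABA", "salicylic_acid", "jasmonic_acid", "ACC",
)

PHENOTYPES = ("height", "leaves", "leaf_length", "leaf_width", "chlorophyll")


class LineProfileError(ValueError):
    pass


@dataclass
class HormoneMeasurement:
    level: float  # as measured (relative units); >= 0
    below_detection: bool = False


@dataclass
class LineProfile:
    """One rice line's molecular and macroscopic measurements."""

    line_id: str
    variant: str
    expression_ratio: dict[str, float]
    hormone: dict[str, HormoneMeasurement] = field(default_factory=dict)
    phenotype: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise LineProfileError(f"unknown variant {self.variant!r}")
        allowed = set(EXOGENOUS_BY_VARIANT[self.variant])
        for gene, ratio in self.expression_ratio.items():
            if ratio < 0:
                raise LineProfileError(
                    f"{self.line_id}: negative expression ratio for {gene}"
                )
            if gene in EXOGENOUS_GENES and gene not in allowed and ratio != 0:
                raise LineProfileError(
                    f"{self.line_id}: exogenous gene {gene} absent from variant "
                    f"{self.variant} must have ratio 0, got {ratio}"
                )
        for h, m in self.hormone.items():
            if m.level < 0:
                raise LineProfileError(f"{self.line_id}: negative level for {h}")


def wild_type_profile(line_id: str = "WT") -> LineProfile:
    """The reference profile: endogenous ratios 1, transgenes 0."""
    ratios = {g: 1.0 for g in ENDOGENOUS_GENES}
    ratios.update({g: 0.0 for g in EXOGENOUS_GENES})
    return LineProfile(line_id=line_id, variant="WT", expression_ratio=ratios)


def scale_line(model: PathwayModel, line: LineProfile) -> PathwayModel:
    """Personalize a variant model by the line's expression ratios.

    Each gene-tagged reaction's V is multiplied by the line's expression
    ratio for that gene; untagged reactions (exchanges, sinks) are unchanged.
    """
    if line.variant != model.variant:
        raise LineProfileError(
            f"line {line.line_id} is variant {line.variant}, "
            f"model is {model.variant}"
        )
    scaled = model.copy()
    for r in scaled.reactions.values():
        if r.gene is None:
            continue
        if r.gene not in line.expression_ratio:
            raise LineProfileError(
                f"line {line.line_id}: no expression ratio for gene {r.gene!r} "
                f"(reaction {r.id})"
            )
        r.law = r.law.with_V(r.law.V * line.expression_ratio[r.gene])
    return scaled


def _median(values: list[float]) -> float:
    """Median with even counts resolved as the mean of the middle pair."""
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else 0.5 * (s[mid - 1] + s[mid])


def median_line(profiles: list[LineProfile], variant: str) -> LineProfile:
    """Element-wise median profile over the lines of one variant.

    A hormone is flagged below detection in the median iff more than half of
    the lines are below detection for it.
    """
    if not profiles:
        raise LineProfileError("empty profile list")
    for p in profiles:
        if p.variant != variant:
            raise LineProfileError(
                f"line {p.line_id} is variant {p.variant}, expected {variant}"
            )
    genes = sorted({g for p in profiles for g in p.expression_ratio})
    ratios = {
        g: _median([p.expression_ratio[g] for p in profiles
                    if g in p.expression_ratio])
        for g in genes
    }
    hormones: dict[str, HormoneMeasurement] = {}
    for h in sorted({h for p in profiles for h in p.hormone}):
        ms = [p.hormone[h] for p in profiles if h in p.hormone]
        n_bd = sum(m.below_detection for m in ms)
        hormones[h] = HormoneMeasurement(
            level=_median([m.level for m in ms]),
            below_detection=n_bd > len(ms) / 2,
        )
    phenos: dict[str, float] = {}
    for ph in sorted({k for p in profiles for k in p.phenotype}):
        phenos[ph] = _median([p.phenotype[ph] for p in profiles
                              if ph in p.phenotype])
    return LineProfile(
        line_id=f"median_{variant}", variant=variant,
        expression_ratio=ratios, hormone=hormones, phenotype=phenos,
    )


# -- TSV round-trip ---------------------------------------------------------

def profiles_to_frame(profiles: list[LineProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row: dict[str, object] = {"line_id": p.line_id, "variant": p.variant}
        for g, r in p.expression_ratio.items():
            row[f"expr_{g}"] = r
        for h, m in p.hormone.items():
            row[f"hormone_{h}"] = m.level
            row[f"hormone_{h}_bd"] = int(m.below_detection)
        for ph, v in p.phenotype.items():
            row[f"pheno_{ph}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_profiles_tsv(profiles: list[LineProfile], path) -> None:
    profiles_to_frame(profiles).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_profiles_tsv(path) -> list[LineProfile]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], float_precision="round_trip")
    profiles = []
    for _, row in df.iterrows():
        ratios, hormones, phenos = {}, {}, {}
        for col, val in row.items():
            if col in ("line_id", "variant") or (isinstance(val, float) and math.isnan(val)):
                continue
            if col.startswith("expr_"):
                ratios[col[5:]] = float(val)
            elif col.startswith("hormone_") and col.endswith("_bd"):
                continue
            elif col.startswith("hormone_"):
                h = col[8:]
                bd_col = f"hormone_{h}_bd"
                bd = bool(int(row[bd_col])) if bd_col in row else False
                hormones[h] = HormoneMeasurement(level=float(val), below_detection=bd)
            elif col.startswith("pheno_"):
                phenos[col[6:]] = float(val)
        profiles.append(LineProfile(
            line_id=str(row["line_id"]), variant=str(row["variant"]),
            expression_ratio=ratios, hormone=hormones, phenotype=phenos,
        ))
    return profiles
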