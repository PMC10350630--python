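"""Pathway data model and the four variant topologies.

The wild-type (WT) network couples the cytosolic mevalonate (MVA) pathway
(Ac-CoA -> HMG-CoA -> MVA -> MVP -> MVPP -> IPP, plus IDI isomerisation to
DMAPP) with the plastidic methylerythritol-phosphate (MEP) pathway
(G3P + pyruvate -> DXP -> MEP -> CDP-ME -> CDP-MEP -> MEcPP -> HMBPP ->
IPP/DMAPP, plus a plastidic IDI), IPP/DMAPP exchange across the plastid
envelope, and simple sink reactions draining the IPP/DMAPP pools in both
compartments.  Engineered variants add a plastid-targeted ectopic MVA
pathway on top of the WT network:

* Type I   — plastidic HMGR (HMG-CoA_pl -> MVA_pl) plus slow HMG-CoA and MVA
  exchange; adds 2 dynamic pools (16 total).
* Type II  — Type I plus plastidic HMGS and MVK and MVP exchange; adds MVP_pl
  (17 total).
* Type III — Type II plus plastidic PMK and MVD and MVPP exchange; adds
  MVPP_pl (18 total).

Ac-CoA, acetoacetyl-CoA, G3P and pyruvate are treated as homeostatically
fixed pools: they enter rate laws but acquire no differential equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ratelaw import SaturatingRateLaw

VARIANTS = ("WT", "I", "II", "III")
#: free-form variant tag for hand-built test/toy systems; exempt from the
#: per-variant dynamic-pool-count invariant
TOY_VARIANT = "toy"

# Reference steady-state concentrations of the 14 WT dynamic pools (mM).
REFERENCE_CONCENTRATIONS: dict[str, float] = {
    "HMGCoA_cyt": 0.983,
    "MVA_cyt": 3.5e-5,
    "MVP_cyt": 3.98e-4,
    "MVPP_cyt": 3.36e-5,
    "IPP_cyt": 0.109,
    "IPP_pl": 0.0801,
    "DMAPP_cyt": 0.136,
    "DMAPP_pl": 0.124,
    "DXP": 0.0133,
    "MEP": 1.15e-3,
    "CDPME": 1.11e-4,
    "CDPMEP": 0.0920,
    "MECPP": 0.657,
    "HMBPP": 3.52e-4,
}

# Fixed (homeostatic) pool concentrations, mM.  Values are physiological-range
# choices; they act as constants in the rate laws.
FIXED_CONCENTRATIONS: dict[str, float] = {
    "AcCoA_cyt": 0.5,
    "AcAcCoA_cyt": 0.01,
    "G3P": 0.12,
    "Pyr": 0.5,
    "AcCoA_pl": 0.3,
    "AcAcCoA_pl": 0.01,
}

# Initial concentrations for the ectopic-pathway pools the variants add (mM).
ECTOPIC_INITIAL_CONCENTRATIONS: dict[str, float] = {
    "HMGCoA_pl": 0.05,
    "MVA_pl": 3.5e-5,
    "MVP_pl": 3.98e-4,
    "MVPP_pl": 3.36e-5,
}

POOL_COMPARTMENT: dict[str, str] = {
    "HMGCoA_cyt": "cytosol", "MVA_cyt": "cytosol", "MVP_cyt": "cytosol",
    "MVPP_cyt": "cytosol", "IPP_cyt": "cytosol", "DMAPP_cyt": "cytosol",
    "AcCoA_cyt": "cytosol", "AcAcCoA_cyt": "cytosol",
    "DXP": "plastid", "MEP": "plastid", "CDPME": "plastid",
    "CDPMEP": "plastid", "MECPP": "plastid", "HMBPP": "plastid",
    "IPP_pl": "plastid", "DMAPP_pl": "plastid",
    "G3P": "plastid", "Pyr": "plastid",
    "AcCoA_pl": "plastid", "AcAcCoA_pl": "plastid",
    "HMGCoA_pl": "plastid", "MVA_pl": "plastid", "MVP_pl": "plastid",
    "MVPP_pl": "plastid",
}

ENDOGENOUS_GENES = (
    "OsHMGS", "OsHMGR", "OsMK", "OsPMK", "OsMVD", "OsIPPI",
    "OsDXS", "OsDXR", "OsMCT", "OsCMK", "OsMDS", "OsHDS", "OsHDR",
    "OsWR1",
)
EXOGENOUS_GENES = ("BjHMGS", "tHMGR", "CrMK", "CrPMK", "CrMVD")

EXOGENOUS_BY_VARIANT: dict[str, tuple[str, ...]] = {
    "WT": (),
    "I": ("tHMGR",),
    "II": ("tHMGR", "BjHMGS", "CrMK"),
    "III": ("tHMGR", "BjHMGS", "CrMK", "CrPMK", "CrMVD"),
}

# (id, substrates, products, gene) — stoichiometries all 1.
_WT_REACTIONS: list[tuple[str, list[str], list[str], str | None]] = [
    ("r1", ["AcCoA_cyt", "AcAcCoA_cyt"], ["HMGCoA_cyt"], "OsHMGS"),
    ("r2", ["HMGCoA_cyt"], ["MVA_cyt"], "OsHMGR"),
    ("r3", ["MVA_cyt"], ["MVP_cyt"], "OsMK"),
    ("r4", ["MVP_cyt"], ["MVPP_cyt"], "OsPMK"),
    ("r5", ["MVPP_cyt"], ["IPP_cyt"], "OsMVD"),
    ("r6", ["IPP_cyt"], ["DMAPP_cyt"], "OsIPPI"),
    ("s_IPP_cyt", ["IPP_cyt"], [], None),
    ("s_DMAPP_cyt", ["DMAPP_cyt"], [], None),
    ("r10", ["G3P", "Pyr"], ["DXP"], "OsDXS"),
    ("r11", ["DXP"], ["MEP"], "OsDXR"),
    ("r12", ["MEP"], ["CDPME"], "OsMCT"),
    ("r13", ["CDPME"], ["CDPMEP"], "OsCMK"),
    ("r14", ["CDPMEP"], ["MECPP"], "OsMDS"),
    ("r15", ["MECPP"], ["HMBPP"], "OsHDS"),
    ("r16", ["HMBPP"], ["IPP_pl"], "OsHDR"),
    ("r17", ["HMBPP"], ["DMAPP_pl"], "OsHDR"),
    ("r18", ["IPP_pl"], ["DMAPP_pl"], "OsIPPI"),
    ("s_IPP_pl", ["IPP_pl"], [], None),
    ("s_DMAPP_pl", ["DMAPP_pl"], [], None),
    ("x_IPP_exp", ["IPP_pl"], ["IPP_cyt"], None),
    ("x_IPP_imp", ["IPP_cyt"], ["IPP_pl"], None),
    ("x_DMAPP_exp", ["DMAPP_pl"], ["DMAPP_cyt"], None),
    ("x_DMAPP_imp", ["DMAPP_cyt"], ["DMAPP_pl"], None),
]

_VARIANT_I_EXTRA = [
    ("e_HMGR_pl", ["HMGCoA_pl"], ["MVA_pl"], "tHMGR"),
    ("x_HMGCoA_in", ["HMGCoA_cyt"], ["HMGCoA_pl"], None),
    ("x_HMGCoA_out", ["HMGCoA_pl"], ["HMGCoA_cyt"], None),
    ("x_MVA_in", ["MVA_cyt"], ["MVA_pl"], None),
    ("x_MVA_out", ["MVA_pl"], ["MVA_cyt"], None),
]

_VARIANT_II_EXTRA = [
    ("e_HMGS_pl", ["AcCoA_pl", "AcAcCoA_pl"], ["HMGCoA_pl"], "BjHMGS"),
    ("e_MVK_pl", ["MVA_pl"], ["MVP_pl"], "CrMK"),
    ("x_MVP_in", ["MVP_cyt"], ["MVP_pl"], None),
    ("x_MVP_out", ["MVP_pl"], ["MVP_cyt"], None),
]

_VARIANT_III_EXTRA = [
    ("e_PMK_pl", ["MVP_pl"], ["MVPP_pl"], "CrPMK"),
    ("e_MVD_pl", ["MVPP_pl"], ["IPP_pl"], "CrMVD"),
    ("x_MVPP_in", ["MVPP_cyt"], ["MVPP_pl"], None),
    ("x_MVPP_out", ["MVPP_pl"], ["MVPP_cyt"], None),
]

_VARIANT_DYNAMIC_EXTRA: dict[str, list[str]] = {
    "WT": [],
    "I": ["HMGCoA_pl", "MVA_pl"],
    "II": ["HMGCoA_pl", "MVA_pl", "MVP_pl"],
    "III": ["HMGCoA_pl", "MVA_pl", "MVP_pl", "MVPP_pl"],
}

_VARIANT_FIXED_EXTRA: dict[str, list[str]] = {
    "WT": [],
    "I": [],
    "II": ["AcCoA_pl", "AcAcCoA_pl"],
    "III": ["AcCoA_pl", "AcAcCoA_pl"],
}

EXPECTED_DYNAMIC_COUNT = {"WT": 14, "I": 16, "II": 17, "III": 18}


def variant_reaction_table(variant: str) -> list[tuple[str, list[str], list[str], str | None]]:
    """The (id, substrates, products, gene) table of the given variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    table = list(_WT_REACTIONS)
    if variant in ("I", "II", "III"):
        table += _VARIANT_I_EXTRA
    if variant in ("II", "III"):
        table += _VARIANT_II_EXTRA
    if variant == "III":
        table += _VARIANT_III_EXTRA
    return table


class ModelConstructionError(ValueError):
    """The pathway definition or its parameters violate a model invariant."""


@dataclass(frozen=True)
class MetabolitePool:
    name: str
    compartment: str  # {"cytosol", "plastid"}
    role: str  # {"dynamic", "fixed"}
    basal_concentration: float  # mM; initial value (dynamic) or constant (fixed)

    def __post_init__(self) -> None:
        if self.compartment not in ("cytosol", "plastid"):
            raise ValueError(f"bad compartment {self.compartment!r}")
        if self.role not in ("dynamic", "fixed"):
            raise ValueError(f"bad role {self.role!r}")
        if not self.basal_concentration > 0:
            raise ValueError(
                f"basal concentration of {self.name!r} must be > 0, "
                f"got {self.basal_concentration}"
            )


@dataclass
class ReactionSpec:
    """One pathway process with saturating kinetics.

    ``hormone_multipliers`` holds (hormone, factor) pairs attached by the
    hormone-coupling stage; the effective saturation constant is
    ``V * prod(factors)``.
    """

    id: str
    substrates: list[tuple[str, int]]
    products: list[tuple[str, int]]
    law: SaturatingRateLaw
    gene: str | None = None
    hormone_multipliers: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        sub_names = {p for p, _ in self.substrates}
        missing = set(self.law.substrate_K) - sub_names
        if missing:
            raise ModelConstructionError(
                f"reaction {self.id!r}: law substrates {sorted(missing)} "
                f"not among reaction substrates"
            )
        for pool, st in self.substrates + self.products:
            if not (isinstance(st, int) and st > 0):
                raise ModelConstructionError(
                    f"reaction {self.id!r}: stoichiometry of {pool!r} must be a "
                    f"positive integer, got {st!r}"
                )

    @property
    def hormone_factor(self) -> float:
        f = 1.0
        for _, factor in self.hormone_multipliers:
            f *= factor
        return f

    def effective_law(self) -> SaturatingRateLaw:
        f = self.hormone_factor
        return self.law if f == 1.0 else self.law.with_V(self.law.V * f)


@dataclass
class ParameterSet:
    """Kinetic constants per reaction: V plus one K per law substrate.

    ``provenance`` records where the constants came from: "measured"
    (experimental tables), "calibrated" (fitted so the WT reference state is
    a stable steady state) or "synthetic".
    """

    values: dict[str, dict]  # id -> {"V": float, "K": {pool: float}}
    provenance: str = "calibrated"

    def require(self, reaction_id: str, substrates: list[str]) -> tuple[float, dict[str, float]]:
        entry = self.values.get(reaction_id)
        if entry is None:
            raise KeyError(reaction_id)
        V = entry["V"]
        K = {s: entry["K"][s] for s in substrates}
        return V, K


@dataclass
class PathwayModel:
    """Variant-specific reaction network that compiles to an ODE system."""

    variant: str
    pools: dict[str, MetabolitePool]
    reactions: dict[str, ReactionSpec]
    provenance: str = "calibrated"

    def __post_init__(self) -> None:
        self.validate()

    # -- views --------------------------------------------------------------

    @property
    def dynamic_pools(self) -> list[str]:
        return [n for n, p in self.pools.items() if p.role == "dynamic"]

    @property
    def fixed_pools(self) -> list[str]:
        return [n for n, p in self.pools.items() if p.role == "fixed"]

    def basal_state(self) -> dict[str, float]:
        """Basal concentrations of the dynamic pools (mM)."""
        return {n: self.pools[n].basal_concentration for n in self.dynamic_pools}

    def fixed_state(self) -> dict[str, float]:
        return {n: self.pools[n].basal_concentration for n in self.fixed_pools}

    def reactions_by_gene(self, gene: str) -> list[ReactionSpec]:
        return [r for r in self.reactions.values() if r.gene == gene]

    def producers(self, pool: str) -> list[ReactionSpec]:
        return [r for r in self.reactions.values()
                if any(p == pool for p, _ in r.products)]

    def consumers(self, pool: str) -> list[ReactionSpec]:
        return [r for r in self.reactions.values()
                if any(p == pool for p, _ in r.substrates)]

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        if self.variant not in VARIANTS and self.variant != TOY_VARIANT:
            raise ModelConstructionError(f"unknown variant {self.variant!r}")
        if self.variant in EXPECTED_DYNAMIC_COUNT:
            n_dyn = len(self.dynamic_pools)
            expected = EXPECTED_DYNAMIC_COUNT[self.variant]
            if n_dyn != expected:
                raise ModelConstructionError(
                    f"variant {self.variant}: {n_dyn} dynamic pools, "
                    f"expected {expected}"
                )
        for name in self.dynamic_pools:
            if not self.producers(name):
                raise ModelConstructionError(f"dynamic pool {name!r} has no producer")
            if not self.consumers(name):
                raise ModelConstructionError(f"dynamic pool {name!r} has no consumer")
        for r in self.reactions.values():
            for pool, _ in r.substrates + r.products:
                if pool not in self.pools:
                    raise ModelConstructionError(
                        f"reaction {r.id!r} references unknown pool {pool!r}"
                    )

    def copy(self) -> "PathwayModel":
        return PathwayModel(
            variant=self.variant,
            pools=dict(self.pools),
            reactions={
                rid: ReactionSpec(
                    id=r.id,
                    substrates=list(r.substrates),
                    products=list(r.products),
                    law=r.law,
                    gene=r.gene,
                    hormone_multipliers=list(r.hormone_multipliers),
                )
                for rid, r in self.reactions.items()
            },
            provenance=self.provenance,
        )


def build_variant_model(variant: str, params: ParameterSet) -> PathwayModel:
    """Assemble the pathway model of one rice genotype from kinetic constants.

    Raises :class:`ModelConstructionError` listing every missing parameter
    exhaustively if ``params`` does not cover the variant's reaction set.
    """
    table = variant_reaction_table(variant)

    pools: dict[str, MetabolitePool] = {}
    for name, conc in REFERENCE_CONCENTRATIONS.items():
        pools[name] = MetabolitePool(name, POOL_COMPARTMENT[name], "dynamic", conc)
    for name in _VARIANT_DYNAMIC_EXTRA[variant]:
        pools[name] = MetabolitePool(
            name, POOL_COMPARTMENT[name], "dynamic",
            ECTOPIC_INITIAL_CONCENTRATIONS[name],
        )
    base_fixed = ["AcCoA_cyt", "AcAcCoA_cyt", "G3P", "Pyr"]
    for name in base_fixed + _VARIANT_FIXED_EXTRA[variant]:
        pools[name] = MetabolitePool(
            name, POOL_COMPARTMENT[name], "fixed", FIXED_CONCENTRATIONS[name]
        )

    gaps: list[str] = []
    reactions: dict[str, ReactionSpec] = {}
    for rid, subs, prods, gene in table:
        try:
            V, K = params.require(rid, subs)
        except KeyError:
            gaps.append(rid)
            continue
        law = SaturatingRateLaw(V=V, substrate_K=K)
        reactions[rid] = ReactionSpec(
            id=rid,
            substrates=[(s, 1) for s in subs],
            products=[(p, 1) for p in prods],
            law=law,
            gene=gene,
        )
    if gaps:
        raise ModelConstructionError(
            f"parameter set ({params.provenance}) missing reactions for variant "
            f"{variant}: {sorted(gaps)}"
        )

    return PathwayModel(variant=variant, pools=pools, reactions=reactions,
                        provenance=params.provenance)
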