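"""Calibration of kinetic constants against the reference steady state.

Measured basal kinetic constants are not available to the package, so the
default parameter source is a calibration that

1. samples every binding constant K log-uniformly within half a decade of
   the basal concentration of its pool (so each reaction operates neither
   fully saturated nor fully first-order),
2. assigns a self-consistent steady-state flux to every reaction of the WT
   network (MVA chain flux, MEP chain flux, an HDR split between IPP and
   DMAPP, IDI fluxes, plastid-to-cytosol exchange with the export rate
   constant fixed at exactly ten times the import rate constant, and sink
   fluxes taken as the mass-balance residuals), and
3. solves V = flux / prod_i(x_i / (K_i + x_i)) at the reference
   concentrations, which makes the reference state an exact fixed point of
   the WT model by construction.

Ectopic-pathway constants are then derated so that each engineered variant's
basal model (all expression ratios 1) is also stable: the slow
MVA-intermediate exchanges run at ~1% of the corresponding cytosolic chain
V (import at a quarter of the export rate so the plastid pools drain
outward), and the plastidic HMGS entry flux is capped well below the
narrowest downstream exit capacity of that variant's ectopic chain, with a
doubled-transgene stress margin enforced at acceptance.

Candidate K draws that leave any of the four variant basal models unstable
are rejected and redrawn; the accepted draw is deterministic in the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import (
    EXOGENOUS_GENES,
    ECTOPIC_INITIAL_CONCENTRATIONS,
    FIXED_CONCENTRATIONS,
    REFERENCE_CONCENTRATIONS,
    ParameterSet,
    build_variant_model,
    variant_reaction_table,
    VARIANTS,
)
from .odes import find_steady_state

#: basal steady-state flux through the cytosolic MVA chain (mM / model-time)
MVA_CHAIN_FLUX = 1.0
#: basal steady-state flux through the plastidic MEP chain
MEP_CHAIN_FLUX = 2.0
#: HDR product split, IPP : DMAPP
HDR_IPP_FRACTION = 5.0 / 6.0
#: fraction of plastidic IPP made by HDR that the plastid IDI isomerises
PLASTID_IDI_FRACTION = 0.5
#: fraction of the post-IDI plastid surplus exported to the cytosol
NET_EXPORT_FRACTION = 0.4
#: cytosolic IDI share of the cytosolic IPP supply
CYTOSOL_IDI_FRACTION = 0.5
#: plastid-export V over import V for IPP and DMAPP
EXPORT_IMPORT_RATIO = 10.0
#: slow MVA-intermediate exchange: export V as a fraction of the chain V
SLOW_EXCHANGE_FRACTION = 0.01
#: ectopic HMGS entry flux as a fraction of its variant's bottleneck capacity
ECTOPIC_ENTRY_MARGIN = 0.15
#: half-decade log10 spread of the K draw around the pool scale
K_LOG10_SPREAD = 0.5


class CalibrationError(RuntimeError):
    pass


@dataclass
class ParameterLibrary:
    """Per-variant parameter sets sharing one calibrated endogenous core."""

    sets: dict[str, ParameterSet]
    seed: int
    attempts: int = 1
    provenance: str = "calibrated"

    def for_variant(self, variant: str) -> ParameterSet:
        return self.sets[variant]


def _pool_scale(pool: str) -> float:
    for table in (REFERENCE_CONCENTRATIONS, FIXED_CONCENTRATIONS,
                  ECTOPIC_INITIAL_CONCENTRATIONS):
        if pool in table:
            return table[pool]
    raise KeyError(pool)


def _draw_K(rng: np.random.Generator, pool: str) -> float:
    return _pool_scale(pool) * 10.0 ** rng.uniform(-K_LOG10_SPREAD, K_LOG10_SPREAD)


def _q(pool: str, K: float) -> float:
    """Saturation fraction x/(K+x) of a pool at its basal concentration."""
    x = _pool_scale(pool)
    return x / (K + x)


def _calibrate_once(rng: np.random.Generator) -> dict[str, dict]:
    """One K draw plus the flux-consistent V assignment, for all reactions."""
    # K for every reaction substrate of the largest variant (III covers all)
    K: dict[str, dict[str, float]] = {}
    for rid, subs, _, _ in variant_reaction_table("III"):
        K[rid] = {s: _draw_K(rng, s) for s in subs}

    def qprod(rid: str) -> float:
        return float(np.prod([_q(s, k) for s, k in K[rid].items()]))

    F_mva = MVA_CHAIN_FLUX
    F_mep = MEP_CHAIN_FLUX
    h_ipp = HDR_IPP_FRACTION * F_mep
    h_dmapp = (1.0 - HDR_IPP_FRACTION) * F_mep
    f_idi_pl = PLASTID_IDI_FRACTION * h_ipp

    flux: dict[str, float] = {
        "r1": F_mva, "r2": F_mva, "r3": F_mva, "r4": F_mva, "r5": F_mva,
        "r10": F_mep, "r11": F_mep, "r12": F_mep, "r13": F_mep,
        "r14": F_mep, "r15": F_mep,
        "r16": h_ipp, "r17": h_dmapp, "r18": f_idi_pl,
    }

    V: dict[str, float] = {rid: f / qprod(rid) for rid, f in flux.items()}

    # IPP exchange: V_exp = 10 * V_imp exactly; choose the import flux so the
    # net export drains NET_EXPORT_FRACTION of the plastid IPP surplus.
    def exchange(pool_pl: str, pool_cyt: str, exp_id: str, imp_id: str,
                 surplus: float) -> tuple[float, float]:
        q_exp = _q(pool_pl, K[exp_id][pool_pl])
        q_imp = _q(pool_cyt, K[imp_id][pool_cyt])
        rho = EXPORT_IMPORT_RATIO * q_exp / q_imp  # export/import flux ratio
        f_imp = NET_EXPORT_FRACTION * surplus / (rho - 1.0)
        V[imp_id] = f_imp / q_imp
        V[exp_id] = EXPORT_IMPORT_RATIO * V[imp_id]
        f_exp = V[exp_id] * q_exp
        flux[imp_id] = f_imp
        flux[exp_id] = f_exp
        return f_imp, f_exp

    ipp_surplus = h_ipp - f_idi_pl
    f_imp_i, f_exp_i = exchange("IPP_pl", "IPP_cyt", "x_IPP_exp", "x_IPP_imp",
                                ipp_surplus)
    flux["s_IPP_pl"] = ipp_surplus - (f_exp_i - f_imp_i)

    dmapp_surplus = h_dmapp + f_idi_pl
    f_imp_d, f_exp_d = exchange("DMAPP_pl", "DMAPP_cyt", "x_DMAPP_exp",
                                "x_DMAPP_imp", dmapp_surplus)
    flux["s_DMAPP_pl"] = dmapp_surplus - (f_exp_d - f_imp_d)

    f_idi_cyt = CYTOSOL_IDI_FRACTION * (F_mva + f_exp_i - f_imp_i)
    flux["r6"] = f_idi_cyt
    flux["s_IPP_cyt"] = F_mva + f_exp_i - f_imp_i - f_idi_cyt
    flux["s_DMAPP_cyt"] = f_idi_cyt + f_exp_d - f_imp_d

    for rid in ("r6", "s_IPP_cyt", "s_DMAPP_cyt", "s_IPP_pl", "s_DMAPP_pl"):
        if flux[rid] <= 0:
            raise CalibrationError(f"non-positive flux assigned to {rid}")
        V[rid] = flux[rid] / qprod(rid)

    # --- ectopic pathway (variants I-III) ---------------------------------
    # slow MVA-intermediate exchanges: export ~1% of the cytosolic chain V,
    # import at half that, so the plastid pools always drain outward.
    chain_V = {"HMGCoA": V["r2"], "MVA": V["r3"], "MVP": V["r4"], "MVPP": V["r5"]}
    for met, vc in chain_V.items():
        V[f"x_{met}_out"] = SLOW_EXCHANGE_FRACTION * vc
        V[f"x_{met}_in"] = 0.25 * SLOW_EXCHANGE_FRACTION * vc

    V["e_HMGR_pl"] = V["r2"]
    V["e_MVK_pl"] = V["r3"]
    V["e_PMK_pl"] = V["r4"]
    V["e_MVD_pl"] = V["r5"]

    return {"K": K, "V": V, "flux": flux}


def _entry_V(draw: dict, variant: str) -> float:
    """Plastidic HMGS V capped at a margin of the ectopic chain's exit capacity."""
    K, V = draw["K"], draw["V"]
    q_entry = _q("AcCoA_pl", K["e_HMGS_pl"]["AcCoA_pl"]) * \
        _q("AcAcCoA_pl", K["e_HMGS_pl"]["AcAcCoA_pl"])
    if variant == "II":
        # MVP_pl exits only through the slow exchange
        bottleneck = V["x_MVP_out"]
    else:  # III: full chain to IPP_pl, generous capacity
        bottleneck = MVA_CHAIN_FLUX / ECTOPIC_ENTRY_MARGIN * 0.15
    return ECTOPIC_ENTRY_MARGIN * bottleneck / q_entry


def _build_sets(draw: dict) -> dict[str, ParameterSet]:
    sets = {}
    for variant in VARIANTS:
        values: dict[str, dict] = {}
        for rid, subs, _, _ in variant_reaction_table(variant):
            if rid == "e_HMGS_pl":
                v = _entry_V(draw, variant)
            else:
                v = draw["V"][rid]
            values[rid] = {"V": v, "K": {s: draw["K"][rid][s] for s in subs}}
        sets[variant] = ParameterSet(values=values, provenance="calibrated")
    return sets


def calibrate_parameters(seed: int, max_attempts: int = 50) -> ParameterLibrary:
    """Draw calibrated kinetic constants, deterministic in the seed.

    Rejects draws for which any of the four variant basal models fails to
    reach a stable steady state from its basal concentrations.
    """
    rng = np.random.default_rng(seed)
    failures: list[str] = []
    for attempt in range(1, max_attempts + 1):
        try:
            draw = _calibrate_once(rng)
            sets = _build_sets(draw)
        except CalibrationError as exc:
            failures.append(f"attempt {attempt}: {exc}")
            continue
        ok = True
        for variant in VARIANTS:
            model = build_variant_model(variant, sets[variant])
            ss = find_steady_state(model)
            if not (ss.converged and ss.stable):
                failures.append(f"attempt {attempt}: variant {variant} basal "
                                f"model not stable")
                ok = False
                break
            # stress margin: doubled transgene dosage must not break the
            # ectopic chain, so only deliberately planted endogenous deficits
            # can destabilize line-personalized models
            stressed = model.copy()
            for r in stressed.reactions.values():
                if r.gene in EXOGENOUS_GENES:
                    r.law = r.law.with_V(r.law.V * 2.0)
            ss2 = find_steady_state(stressed)
            if not (ss2.converged and ss2.stable):
                failures.append(f"attempt {attempt}: variant {variant} fails "
                                f"the doubled-transgene stress margin")
                ok = False
                break
        if ok:
            return ParameterLibrary(sets=sets, seed=seed, attempts=attempt)
    raise CalibrationError(
        "calibration failed after "
        f"{max_attempts} attempts; diagnostics: {failures[-5:]}"
    )
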