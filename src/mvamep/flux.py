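"""Steady-state flux decomposition of IPP/DMAPP monomer production.

Dissects where the C5 monomers are made at a converged steady state:
production by HDR (plastid, both products), by IDI (each compartment), by
MVD (endogenous cytosolic and, where the variant carries one, ectopic
plastidic), the plastid-to-cytosol export, and the entry fluxes into the
endogenous MVA, MEP and ectopic pathways.  Per-compartment totals are sums
of their components and the overall total is the sum over compartments, so
the report conserves by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .network import PathwayModel
from .odes import SteadyState, assemble_odes


@dataclass
class FluxReport:
    """Named steady-state fluxes (mM / model-time)."""

    variant: str
    ipp_by_hdr: float
    dmapp_by_hdr: float
    idi_plastid: float
    idi_cytosol: float
    mvd_cytosol: float
    mvd_ectopic: float
    export_to_cytosol: float
    entry_mva: float
    entry_mep: float
    entry_ectopic: float
    absent: set[str] = field(default_factory=set)

    @property
    def plastid_total(self) -> float:
        return (self.ipp_by_hdr + self.dmapp_by_hdr + self.idi_plastid
                + self.mvd_ectopic)

    @property
    def cytosol_total(self) -> float:
        return self.mvd_cytosol + self.idi_cytosol

    @property
    def overall_total(self) -> float:
        return self.plastid_total + self.cytosol_total

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "ipp_by_hdr": self.ipp_by_hdr,
            "dmapp_by_hdr": self.dmapp_by_hdr,
            "idi_plastid": self.idi_plastid,
            "idi_cytosol": self.idi_cytosol,
            "mvd_cytosol": self.mvd_cytosol,
            "mvd_ectopic": self.mvd_ectopic,
            "export_to_cytosol": self.export_to_cytosol,
            "entry_mva": self.entry_mva,
            "entry_mep": self.entry_mep,
            "entry_ectopic": self.entry_ectopic,
            "plastid_total": self.plastid_total,
            "cytosol_total": self.cytosol_total,
            "overall_total": self.overall_total,
            "absent": sorted(self.absent),
        }


def flux_decomposition(model: PathwayModel, ss: SteadyState) -> FluxReport:
    """Evaluate the named fluxes of the model at a converged steady state."""
    if not ss.converged:
        raise ValueError("flux decomposition requires a converged steady state")
    system = assemble_odes(model)
    rates = system.rates(system.state_vector(ss.concentrations))
    absent: set[str] = set()

    def get(rid: str, category: str) -> float:
        if rid in rates:
            return rates[rid]
        absent.add(category)
        return 0.0

    # ectopic entry: plastidic HMGS where present (II/III); for Type I the
    # ectopic chain is fed by HMG-CoA import, so its HMGR flux is the entry
    if "e_HMGS_pl" in rates:
        entry_ectopic = rates["e_HMGS_pl"]
    elif "e_HMGR_pl" in rates:
        entry_ectopic = rates["e_HMGR_pl"]
    else:
        absent.add("entry_ectopic")
        entry_ectopic = 0.0

    return FluxReport(
        variant=model.variant,
        ipp_by_hdr=rates["r16"],
        dmapp_by_hdr=rates["r17"],
        idi_plastid=rates["r18"],
        idi_cytosol=rates["r6"],
        mvd_cytosol=rates["r5"],
        mvd_ectopic=get("e_MVD_pl", "mvd_ectopic"),
        export_to_cytosol=rates["x_IPP_exp"] + rates["x_DMAPP_exp"],
        entry_mva=rates["r1"],
        entry_mep=rates["r10"],
        entry_ectopic=entry_ectopic,
        absent=absent,
    )
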