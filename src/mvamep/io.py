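"""Model-document round-tripping (JSON) and report serialization.

A model document lists pools, reactions (with gene tags and kinetic
constants) and provenance; read -> write -> read is lossless, with parameter
values bit-equal (JSON floats use Python's shortest round-trip repr).
"""

from __future__ import annotations

import json
from pathlib import Path

from .calibrate import ParameterLibrary
from .network import (
    MetabolitePool,
    ParameterSet,
    PathwayModel,
    ReactionSpec,
)
from .ratelaw import SaturatingRateLaw


class SchemaError(ValueError):
    """A model document is malformed; the message names the offending field."""


def model_to_dict(model: PathwayModel) -> dict:
    return {
        "variant": model.variant,
        "provenance": model.provenance,
        "pools": [
            {
                "name": p.name, "compartment": p.compartment, "role": p.role,
                "basal_concentration": p.basal_concentration,
            }
            for p in model.pools.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "substrates": [[p, s] for p, s in r.substrates],
                "products": [[p, s] for p, s in r.products],
                "gene": r.gene,
                "V": r.law.V,
                "substrate_K": dict(r.law.substrate_K),
                "inhibitor_K": dict(r.law.inhibitor_K),
                "hormone_multipliers": [[h, f] for h, f in r.hormone_multipliers],
            }
            for r in model.reactions.values()
        ],
    }


def _require(obj: dict, key: str, where: str):
    if key not in obj:
        raise SchemaError(f"{where}: missing field {key!r}")
    return obj[key]


def model_from_dict(doc: dict) -> PathwayModel:
    variant = _require(doc, "variant", "document")
    pools: dict[str, MetabolitePool] = {}
    for i, p in enumerate(_require(doc, "pools", "document")):
        where = f"pools[{i}]"
        pools[_require(p, "name", where)] = MetabolitePool(
            name=p["name"],
            compartment=_require(p, "compartment", where),
            role=_require(p, "role", where),
            basal_concentration=_require(p, "basal_concentration", where),
        )
    reactions: dict[str, ReactionSpec] = {}
    for i, r in enumerate(_require(doc, "reactions", "document")):
        where = f"reactions[{i}]"
        rid = _require(r, "id", where)
        law = SaturatingRateLaw(
            V=_require(r, "V", where),
            substrate_K=dict(_require(r, "substrate_K", where)),
            inhibitor_K=dict(r.get("inhibitor_K", {})),
        )
        reactions[rid] = ReactionSpec(
            id=rid,
            substrates=[(p, int(s)) for p, s in _require(r, "substrates", where)],
            products=[(p, int(s)) for p, s in _require(r, "products", where)],
            law=law,
            gene=r.get("gene"),
            hormone_multipliers=[(h, float(f))
                                 for h, f in r.get("hormone_multipliers", [])],
        )
    return PathwayModel(
        variant=variant, pools=pools, reactions=reactions,
        provenance=doc.get("provenance", "unknown"),
    )


def save_model(model: PathwayModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def load_model(path) -> PathwayModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"document is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError("document root must be an object")
    return model_from_dict(doc)


def roundtrip_model(path_in, path_out) -> PathwayModel:
    """Read, re-write and re-read a model document; returns the final model."""
    model = load_model(path_in)
    save_model(model, path_out)
    return load_model(path_out)


# -- parameter libraries ----------------------------------------------------

def library_to_dict(lib: ParameterLibrary) -> dict:
    return {
        "seed": lib.seed,
        "attempts": lib.attempts,
        "provenance": lib.provenance,
        "sets": {
            variant: {"provenance": ps.provenance, "values": ps.values}
            for variant, ps in lib.sets.items()
        },
    }


def library_from_dict(doc: dict) -> ParameterLibrary:
    sets = {
        variant: ParameterSet(values=entry["values"],
                              provenance=entry.get("provenance", "unknown"))
        for variant, entry in _require(doc, "sets", "library").items()
    }
    return ParameterLibrary(
        sets=sets, seed=_require(doc, "seed", "library"),
        attempts=doc.get("attempts", 1),
        provenance=doc.get("provenance", "unknown"),
    )


def save_library(lib: ParameterLibrary, path) -> None:
    Path(path).write_text(json.dumps(library_to_dict(lib), indent=1))


def load_library(path) -> ParameterLibrary:
    return library_from_dict(json.loads(Path(path).read_text()))
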