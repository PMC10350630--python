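"""Shared fixtures: calibrated parameters, variant models and toy systems."""

from __future__ import annotations

import warnings

import pytest

from mvamep.calibrate import calibrate_parameters
from mvamep.network import (
    MetabolitePool,
    PathwayModel,
    ReactionSpec,
    build_variant_model,
)
from mvamep.ratelaw import SaturatingRateLaw

warnings.filterwarnings("ignore", category=RuntimeWarning)

SEED = 1


@pytest.fixture(scope="session")
def library():
    return calibrate_parameters(seed=SEED)


@pytest.fixture(scope="session")
def wt_model(library):
    return build_variant_model("WT", library.for_variant("WT"))


@pytest.fixture(scope="session")
def variant_models(library):
    return {v: build_variant_model(v, library.for_variant(v))
            for v in ("WT", "I", "II", "III")}


def toy_pool(name, conc, role="dynamic", compartment="cytosol"):
    return MetabolitePool(name, compartment, role, conc)


def toy_reaction(rid, subs, prods, V, K, gene=None):
    return ReactionSpec(
        id=rid,
        substrates=[(s, 1) for s in subs],
        products=[(p, 1) for p in prods],
        law=SaturatingRateLaw(V=V, substrate_K={s: K[s] for s in subs}),
        gene=gene,
    )


@pytest.fixture()
def linear_toy():
    """Single pool: constant production c, near-first-order consumption.

    Producer runs on a saturated fixed substrate (flux ~ c); consumer has
    K >> M so flux ~ (V/K) M.  Steady state M* ~ c K / V.
    """
    c, V, K = 0.5, 2.0, 100.0
    pools = {
        "S": toy_pool("S", 1.0, role="fixed"),
        "M": toy_pool("M", 1.0),
    }
    reactions = {
        "prod": toy_reaction("prod", ["S"], ["M"], V=c, K={"S": 1e-9}),
        "cons": toy_reaction("cons", ["M"], [], V=V, K={"M": K}),
    }
    model = PathwayModel(variant="toy", pools=pools, reactions=reactions,
                         provenance="synthetic")
    return model, {"c": c, "V": V, "K": K}


@pytest.fixture()
def chain_toy():
    """Three-pool chain A -> B -> C -> (sink) with saturating steps."""
    pools = {
        "S": toy_pool("S", 2.0, role="fixed"),
        "A": toy_pool("A", 0.5),
        "B": toy_pool("B", 0.2),
        "C": toy_pool("C", 0.1),
    }
    reactions = {
        "in": toy_reaction("in", ["S"], ["A"], V=1.0, K={"S": 1.0}),
        "ab": toy_reaction("ab", ["A"], ["B"], V=2.0, K={"A": 0.4}),
        "bc": toy_reaction("bc", ["B"], ["C"], V=1.5, K={"B": 0.3}),
        "out": toy_reaction("out", ["C"], [], V=1.2, K={"C": 0.2}),
    }
    return PathwayModel(variant="toy", pools=pools, reactions=reactions,
                        provenance="synthetic")
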