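"""Saturating-formalism rate law.

The rate of every process in the pathway models is approximated by a rational
expression in the participating concentrations,

    v = V * prod_i(x_i) / ( prod_i(K_i + x_i) + prod_b(x_b + K_b) )

where ``V`` is an apparent saturation rate constant, the ``K_i`` are apparent
binding constants of the substrates ``x_i``, and the ``K_b`` are binding
constants of inhibitors ``x_b``.  The parameters have the familiar
enzyme-kinetic reading: with a single substrate and no inhibitors the
expression reduces to the Michaelis-Menten form, and ``v -> V`` as all
substrates saturate.

Convention for the inhibitor-free case: the denominator is the substrate
product alone (no constant extra term), so the classical-kinetics reduction
holds exactly.  The inhibitor product is added only when inhibitors are
declared.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class RateLawConfigError(ValueError):
    """A rate law referenced a concentration that was not supplied."""


@dataclass(frozen=True)
class SaturatingRateLaw:
    """Rational rate expression with saturable substrate and inhibitor terms.

    Parameters
    ----------
    V : float
        Apparent saturation rate constant (mM / model-time).  Must be >= 0.
    substrate_K : dict[str, float]
        Apparent binding constant per substrate pool (mM, > 0).  Non-empty.
    inhibitor_K : dict[str, float]
        Apparent binding constant per inhibitor pool (mM, > 0).  May be empty.
    """

    V: float
    substrate_K: dict[str, float]
    inhibitor_K: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.V < 0:
            raise ValueError(f"V must be non-negative, got {self.V}")
        if not self.substrate_K:
            raise ValueError("substrate_K must name at least one substrate")
        for name, k in {**self.substrate_K, **self.inhibitor_K}.items():
            if not k > 0:
                raise ValueError(f"binding constant for {name!r} must be > 0, got {k}")

    # -- evaluation ---------------------------------------------------------

    def _terms(self, conc: dict[str, float]) -> tuple[float, float, float]:
        """Return (numerator product, substrate denom product, inhibitor product)."""
        num = 1.0
        denom_s = 1.0
        for name, k in self.substrate_K.items():
            try:
                x = conc[name]
            except KeyError:
                raise RateLawConfigError(
                    f"no concentration supplied for substrate {name!r}"
                ) from None
            num *= x
            denom_s *= k + x
        denom_i = 0.0
        if self.inhibitor_K:
            denom_i = 1.0
            for name, k in self.inhibitor_K.items():
                try:
                    x = conc[name]
                except KeyError:
                    raise RateLawConfigError(
                        f"no concentration supplied for inhibitor {name!r}"
                    ) from None
                denom_i *= x + k
        return num, denom_s, denom_i

    def rate(self, conc: dict[str, float]) -> float:
        """Flux (mM / model-time) at the given concentrations (all >= 0)."""
        num, denom_s, denom_i = self._terms(conc)
        return self.V * num / (denom_s + denom_i)

    def rate_and_gradient(self, conc: dict[str, float]) -> tuple[float, dict[str, float]]:
        """Flux plus its partial derivative with respect to each referenced pool.

        The partials are analytic: for substrate s,
        dv/dx_s = V * [ (N/x_s) * D - N * A/(K_s+x_s) ] / D**2 with N the
        substrate numerator product, A the substrate denominator product and
        D = A + B (B the inhibitor product); for inhibitor b,
        dv/dx_b = -V * N * B / (x_b + K_b) / D**2.  The N/x_s factor is formed
        as the leave-one-out product so x_s = 0 is handled exactly.
        """
        num, denom_s, denom_i = self._terms(conc)
        D = denom_s + denom_i
        v = self.V * num / D
        grad: dict[str, float] = {}
        for name, k in self.substrate_K.items():
            x = conc[name]
            # leave-one-out numerator product
            loo = 1.0
            for other in self.substrate_K:
                if other != name:
                    loo *= conc[other]
            dnum = loo
            ddenom = denom_s / (k + x)
            grad[name] = self.V * (dnum * D - num * ddenom) / (D * D)
        if self.inhibitor_K:
            for name, k in self.inhibitor_K.items():
                x = conc[name]
                dB = denom_i / (x + k)
                grad[name] = grad.get(name, 0.0) - self.V * num * dB / (D * D)
        return v, grad

    def with_V(self, V: float) -> "SaturatingRateLaw":
        """Copy of this law with a different saturation rate constant."""
        return SaturatingRateLaw(V=V, substrate_K=dict(self.substrate_K),
                                 inhibitor_K=dict(self.inhibitor_K))


def evaluate_rate(law: SaturatingRateLaw, conc: dict[str, float]) -> float:
    """Evaluate a saturating rate law at the given pool concentrations."""
    return law.rate(conc)
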