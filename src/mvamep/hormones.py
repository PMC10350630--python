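"""Phenomenological hormone coupling of the kinetic models.

Hormone levels measured at twelve weeks are screened for correlation with
molecular responses (gene-expression ratios or model metabolite
concentrations) by ordinary least squares on log10-log10 axes.  A
significant pair (slope g, adjusted R^2, p < 0.05) is encoded as a
multiplicative modifier of the affected rate terms using one of two
formalisms:

    power law     factor(H) = (H / H_ref)^g
    saturating    factor(H) = [ (H/(K+H)) / (H_ref/(K+H_ref)) ]^g

The saturating form is selected when |R^2_adj / g| <= 0.5 — a high exponent
explaining little variance suggests the response saturates over the observed
hormone range — and the power law otherwise (strict inequality).  K is the
median observed hormone level; both forms are anchored to factor 1 at the
reference (wild-type) hormone level so the basal model is preserved by
construction.  Hormone values below the experimental detection limit revert
the affected terms to the basal model (piecewise handling), and censored
lines are excluded from the fits.  No multiple-testing correction is applied
(alpha = 0.05 per pair); this is recorded in the link table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .lines import LineProfile
from .network import PathwayModel

ALPHA = 0.05
MIN_DETECTED = 4
FORMALISM_RATIO_THRESHOLD = 0.5


class HormoneLinkError(ValueError):
    pass


@dataclass(frozen=True)
class DetectionLimit:
    hormone: str
    limit: float  # hormone units, >= 0

    def __post_init__(self) -> None:
        if self.limit < 0:
            raise ValueError("detection limit must be >= 0")


@dataclass
class HormoneLink:
    """A significant hormone -> response correlation and its rate modifier."""

    hormone: str
    response: str
    response_kind: str  # {"gene", "metabolite"}
    formalism: str  # {"power_law", "saturating"}
    g: float  # fitted log-log slope (exponent)
    K: float | None  # half-saturation (saturating only)
    reference_level: float  # hormone level at which the factor is 1
    r2_adj: float
    pvalue: float

    def __post_init__(self) -> None:
        if self.pvalue >= ALPHA:
            raise HormoneLinkError(
                f"link {self.hormone}->{self.response}: p={self.pvalue:.3g} "
                f"not significant at alpha={ALPHA}"
            )
        if self.formalism == "saturating" and not (self.K and self.K > 0):
            raise HormoneLinkError("saturating formalism requires K > 0")

    @property
    def alpha_scale(self) -> float:
        """Scale constant that anchors the modifier to 1 at the reference level."""
        if self.formalism == "power_law":
            return self.reference_level ** (-self.g)
        h = self.reference_level
        return (h / (self.K + h)) ** (-self.g)

    def factor(self, level: float, below_detection: bool = False) -> float:
        """Multiplier applied to the affected V at the given hormone level."""
        if below_detection:
            return 1.0  # piecewise reversion to the basal model
        if level <= 0:
            raise ValueError("hormone level must be > 0 above the detection limit")
        if self.formalism == "power_law":
            return self.alpha_scale * level ** self.g
        return self.alpha_scale * (level / (self.K + level)) ** self.g


def choose_formalism(g: float, r2_adj: float) -> str:
    """Power law iff |R^2_adj / g| > 0.5, else saturating (boundary included)."""
    if g == 0:
        raise HormoneLinkError("no formalism for a zero exponent")
    if not np.isfinite(r2_adj):
        raise HormoneLinkError("formalism choice requires a finite adjusted R^2")
    return ("power_law" if abs(r2_adj / g) > FORMALISM_RATIO_THRESHOLD
            else "saturating")


def fit_hormone_correlations(
    lines: list[LineProfile],
    responses: pd.DataFrame,
    response_kind: str = "gene",
    alpha: float = ALPHA,
    reference_levels: dict[str, float] | None = None,
) -> list[HormoneLink]:
    """Log-log OLS of every (hormone, response) pair; keep significant fits.

    ``responses`` is indexed by line_id with one column per response variable
    (gene-expression ratios or steady-state metabolite concentrations).
    Censored (below-detection) hormone values are excluded; pairs with fewer
    than ``MIN_DETECTED`` usable lines, or with an all-censored hormone, are
    skipped with a notice.  ``reference_levels`` anchors each link's modifier
    (default: median detected level of the hormone).
    """
    by_id = {p.line_id: p for p in lines}
    hormones = sorted({h for p in lines for h in p.hormone})
    links: list[HormoneLink] = []
    for hormone in hormones:
        levels, ok_ids = [], []
        for lid in responses.index:
            p = by_id.get(str(lid))
            if p is None or hormone not in p.hormone:
                continue
            m = p.hormone[hormone]
            if m.below_detection or m.level <= 0:
                continue
            levels.append(m.level)
            ok_ids.append(lid)
        if not levels:
            warnings.warn(f"hormone {hormone}: all lines censored; skipped")
            continue
        if len(levels) < MIN_DETECTED:
            warnings.warn(f"hormone {hormone}: <{MIN_DETECTED} detected lines; skipped")
            continue
        x = np.log10(levels)
        if np.ptp(x) == 0:
            continue  # constant hormone cannot correlate
        ref = (reference_levels or {}).get(hormone, float(np.median(levels)))
        for col in responses.columns:
            y_raw = responses.loc[ok_ids, col].to_numpy(dtype=float)
            mask = np.isfinite(y_raw) & (y_raw > 0)
            if mask.sum() < MIN_DETECTED:
                continue
            y = np.log10(y_raw[mask])
            if np.ptp(y) == 0:
                continue
            fit = sm.OLS(y, sm.add_constant(x[mask])).fit()
            g = float(fit.params[1])
            p = float(fit.pvalues[1])
            if p >= alpha or g == 0:
                continue
            r2a = float(fit.rsquared_adj)
            formalism = choose_formalism(g, r2a)
            links.append(HormoneLink(
                hormone=hormone, response=str(col), response_kind=response_kind,
                formalism=formalism, g=g,
                K=ref if formalism == "saturating" else None,
                reference_level=ref, r2_adj=r2a, pvalue=p,
            ))
    return links


def links_to_frame(links: list[HormoneLink]) -> pd.DataFrame:
    return pd.DataFrame([{
        "hormone": l.hormone, "response": l.response, "kind": l.response_kind,
        "formalism": l.formalism, "alpha_scale": l.alpha_scale, "g": l.g,
        "K": l.K if l.K is not None else float("nan"),
        "r2_adj": l.r2_adj, "pvalue": l.pvalue,
        "multiple_testing_correction": "none",
    } for l in links])


def attach_hormone_modifiers(
    model: PathwayModel,
    links: list[HormoneLink],
    hormone_levels: dict[str, tuple[float, bool]],
) -> PathwayModel:
    """Multiply the affected rate terms by each link's hormone factor.

    Gene links modify the reactions tagged with the gene; metabolite links
    modify the producers and consumers of the pool.  Below-detection hormones
    contribute a factor of exactly 1 (the model reverts to basal there).
    """
    out = model.copy()
    for link in links:
        if link.hormone not in hormone_levels:
            raise HormoneLinkError(f"no level supplied for hormone {link.hormone}")
        level, below = hormone_levels[link.hormone]
        f = link.factor(level, below)
        if link.response_kind == "gene":
            targets = out.reactions_by_gene(link.response)
        elif link.response_kind == "metabolite":
            if link.response not in out.pools:
                raise HormoneLinkError(
                    f"link targets unknown pool {link.response!r}"
                )
            targets = out.producers(link.response) + out.consumers(link.response)
        else:
            raise HormoneLinkError(f"bad response kind {link.response_kind!r}")
        if not targets:
            raise HormoneLinkError(
                f"link {link.hormone}->{link.response}: no matching reaction"
            )
        for r in targets:
            r.hormone_multipliers.append((link.hormone, f))
    return out


def remove_hormone_modifiers(model: PathwayModel) -> PathwayModel:
    """Strip all attached hormone multipliers, restoring the basal model."""
    out = model.copy()
    for r in out.reactions.values():
        r.hormone_multipliers.clear()
    return out


def validate_correlation_recovery(
    model: PathwayModel,
    gene_links: list[HormoneLink],
    metabolite_links: list[HormoneLink],
    hormone_ranges: dict[str, tuple[float, float]],
    n_grid: int = 5,
    escalate_axes: tuple[str, ...] = (),
) -> tuple[int, int, int]:
    """Check the coupled model reproduces each hormone-metabolite sign.

    For every metabolite link, the hormone is swept over its observed range
    (others held at reference), the coupled model (gene links attached) is
    re-solved, and the simulated metabolite-vs-hormone trend sign is compared
    with the experimental sign (the link's fitted slope).  Returns
    (matched, assessed, ambiguous).  A hormone level at which the model loses
    stability makes the pair ambiguous, unless ``escalate_axes`` names
    stabilization targets whose capacity may be doubled until stability
    returns (the hormone dose raises the pathway input flux, so the same
    post-transcriptional upregulation must deepen with it).
    """
    from .odes import find_steady_state

    matched = assessed = ambiguous = 0
    for link in metabolite_links:
        if link.response not in model.pools:
            continue
        lo, hi = hormone_ranges.get(link.hormone, (None, None))
        if lo is None or not (0 < lo < hi):
            continue
        assessed += 1
        grid = np.geomspace(lo, hi, n_grid)

        def sweep(base) -> list[float] | None:
            concs = []
            for h in grid:
                levels = {l.hormone: (l.reference_level, False)
                          for l in gene_links}
                levels[link.hormone] = (float(h), False)
                coupled = attach_hormone_modifiers(base, gene_links, levels)
                ss = find_steady_state(coupled)
                if not (ss.converged and ss.stable):
                    return None
                concs.append(ss.concentrations[link.response])
            return concs

        # the whole sweep must share one capacity level, otherwise the trend
        # would mix models with different consumer capacities
        concs = sweep(model)
        if concs is None and escalate_axes:
            from .stabilize import apply_multipliers

            base = model
            for _ in range(4):
                base = apply_multipliers(base, {a: 2.0 for a in escalate_axes})
                concs = sweep(base)
                if concs is not None:
                    break
        if concs is None:
            ambiguous += 1
            continue
        d = np.diff(np.asarray(concs))
        if np.all(np.abs(d) < 1e-14):
            ambiguous += 1
            continue
        sim_sign = np.sign(np.sum(np.sign(d)))
        if sim_sign == 0:
            ambiguous += 1
        elif sim_sign == np.sign(link.g):
            matched += 1
    return matched, assessed, ambiguous
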