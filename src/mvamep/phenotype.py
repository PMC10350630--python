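"""Forward stepwise phenotype regression and multilevel prediction.

Macroscopic traits (height, number of leaves, leaf length, leaf width,
chlorophyll) are modelled per mutant type as multivariate linear functions

    y_hat = b0 + b1*x1 + ... + bn*xn

of typed predictors: gene-expression ratios, hormone levels and model
steady-state metabolite concentrations.  Selection is forward stepwise:
single-predictor fits are gated on coefficient significance (alpha = 0.05)
and adjusted R^2 > 0.2; the winner is the highest adjusted R^2, with AICc
(the small-sample-corrected information criterion, lower = less overfitting
risk) breaking near-ties; the model is then extended one predictor at a
time, excluding collinear pairs (|Pearson r| >= 0.7), and stops when no
addition improves adjusted R^2 by at least 0.02 with a significant new
coefficient.

Leaf-count predictions are rounded to the nearest integer.  Leaf area is
estimated from length and maximum width with the standard 0.75 shape
correction factor for rice leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .lines import HORMONES, LineProfile
from .network import ENDOGENOUS_GENES, EXOGENOUS_GENES

ALPHA = 0.05
R2_GATE = 0.2
R2_TIE = 0.02
AICC_TIE = 2.0
COLLINEAR_R = 0.7
MIN_GAIN = 0.02

_METABOLITE_ALIASES = {
    "MEcPP": "MECPP",
    "DMAPP": "DMAPP_pl",
}
_GENE_ALIASES = {
    "HMGS": "OsHMGS", "HMGR": "OsHMGR", "MVK": "OsMK", "PMK": "OsPMK",
    "MVD": "OsMVD", "DXS": "OsDXS", "DXR": "OsDXR", "MCT": "OsMCT",
    "CMK": "OsCMK", "MDS": "OsMDS", "HDS": "OsHDS", "HDR": "OsHDR",
    "IPPI": "OsIPPI", "WR1": "OsWR1",
}


def predictor_type(name: str) -> str:
    """Classify a predictor as gene expression, hormone or metabolite."""
    if name in _GENE_ALIASES or name in ENDOGENOUS_GENES or name in EXOGENOUS_GENES:
        return "gene"
    if name in HORMONES:
        return "hormone"
    return "metabolite"


def leaf_area(length: float, width: float) -> float:
    """Leaf area (cm^2) from length and maximum width, 0.75 shape factor."""
    if length < 0 or width < 0:
        raise ValueError("leaf dimensions must be non-negative")
    return 0.75 * length * width


def aicc(fit) -> float:
    """Small-sample corrected AIC of a statsmodels OLS fit."""
    k = int(fit.df_model) + 1  # slope terms + intercept
    n = int(fit.nobs)
    if n - k - 1 <= 0:
        return float("inf")
    return float(fit.aic + 2.0 * k * (k + 1) / (n - k - 1))


@dataclass
class PhenotypeModel:
    """Affine phenotype predictor of typed molecular inputs."""

    response: str
    predictors: list[str]
    coefficients: dict[str, float]  # includes "intercept"
    r2_adj: float | None = None
    aicc: float | None = None
    rounded: bool = False
    predictor_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.predictor_types:
            self.predictor_types = {p: predictor_type(p) for p in self.predictors}

    def evaluate(self, inputs: dict[str, float]) -> float:
        y = self.coefficients["intercept"]
        for p in self.predictors:
            if p not in inputs:
                raise KeyError(f"missing value for predictor {p!r}")
            y += self.coefficients[p] * inputs[p]
        return float(round(y)) if self.rounded else float(y)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "predictors": self.predictors,
            "predictor_types": self.predictor_types,
            "coefficients": self.coefficients,
            "r2_adj": self.r2_adj,
            "aicc": self.aicc,
            "rounded": self.rounded,
        }


def evaluate_phenotype(model: PhenotypeModel, inputs: dict[str, float]) -> float:
    """Predicted phenotype; leaf counts are rounded to the nearest integer."""
    return model.evaluate(inputs)


@dataclass
class StepRecord:
    predictor: str
    pvalue: float
    r2_adj: float
    aicc: float
    accepted: bool
    reason: str


@dataclass
class StepwiseTrace:
    steps: list[list[StepRecord]] = field(default_factory=list)


def _fit(data: pd.DataFrame, response: str, predictors: list[str]):
    X = sm.add_constant(data[predictors].to_numpy(dtype=float))
    y = data[response].to_numpy(dtype=float)
    return sm.OLS(y, X).fit()


def _pick_best(records: list[tuple[StepRecord, object]]):
    """Selection among admissible candidates: highest adjusted R^2; if within
    R2_TIE, lowest AICc; if AICc within AICC_TIE, highest adjusted R^2."""
    admissible = [(r, f) for r, f in records if r.accepted]
    if not admissible:
        return None
    best = max(admissible, key=lambda rf: rf[0].r2_adj)
    near = [rf for rf in admissible if best[0].r2_adj - rf[0].r2_adj <= R2_TIE]
    if len(near) > 1:
        by_aicc = min(near, key=lambda rf: rf[0].aicc)
        near_aicc = [rf for rf in near if rf[0].aicc - by_aicc[0].aicc <= AICC_TIE]
        best = max(near_aicc, key=lambda rf: rf[0].r2_adj)
    return best


def forward_stepwise(data: pd.DataFrame, response: str,
                     alpha: float = ALPHA) -> tuple[PhenotypeModel | None,
                                                    StepwiseTrace]:
    """Build the per-type phenotype model by forward selection.

    ``data`` holds one row per line with predictor columns and the response
    column.  Returns (None, trace) when no candidate passes the gates.
    """
    predictors = [c for c in data.columns if c != response]
    data = data.dropna(subset=[response])
    n = len(data)
    if n < 6:
        raise ValueError(f"need >= 6 lines, got {n}")
    usable = [p for p in predictors
              if data[p].notna().all() and data[p].nunique() > 1]
    corr = data[usable].corr().abs()

    trace = StepwiseTrace()
    included: list[str] = []
    best_fit = None
    best_r2 = -np.inf

    while True:
        records: list[tuple[StepRecord, object]] = []
        for p in usable:
            if p in included:
                continue
            if any(corr.loc[p, q] >= COLLINEAR_R for q in included):
                records.append((StepRecord(p, np.nan, np.nan, np.nan, False,
                                           "collinear with included predictor"),
                                None))
                continue
            cols = included + [p]
            if len(cols) + 1 >= n:
                records.append((StepRecord(p, np.nan, np.nan, np.nan, False,
                                           "predictor count would reach n"), None))
                continue
            fit = _fit(data, response, cols)
            pval = float(fit.pvalues[-1])
            r2a = float(fit.rsquared_adj)
            a = aicc(fit)
            if pval >= alpha:
                rec = StepRecord(p, pval, r2a, a, False, "not significant")
            elif not included and r2a <= R2_GATE:
                rec = StepRecord(p, pval, r2a, a, False,
                                 f"adjusted R2 <= {R2_GATE}")
            elif included and r2a - best_r2 < MIN_GAIN:
                rec = StepRecord(p, pval, r2a, a, False,
                                 f"adjusted R2 gain < {MIN_GAIN}")
            else:
                rec = StepRecord(p, pval, r2a, a, True, "candidate")
            records.append((rec, fit))
        trace.steps.append([r for r, _ in records])
        best = _pick_best(records)
        if best is None:
            break
        rec, fit = best
        included.append(rec.predictor)
        best_fit, best_r2 = fit, rec.r2_adj

    if best_fit is None:
        return None, trace

    coeffs = {"intercept": float(best_fit.params[0])}
    for i, p in enumerate(included):
        coeffs[p] = float(best_fit.params[i + 1])
    model = PhenotypeModel(
        response=response, predictors=list(included), coefficients=coeffs,
        r2_adj=float(best_fit.rsquared_adj), aicc=aicc(best_fit),
        rounded=(response == "leaves"),
    )
    return model, trace


# -- shipped type-specific reference models ---------------------------------

def _ref(response, terms, r2, rounded=False):
    coeffs = {"intercept": terms[0]}
    preds = []
    for name, beta in terms[1]:
        coeffs[name] = beta
        preds.append(name)
    return PhenotypeModel(response=response, predictors=preds,
                          coefficients=coeffs, r2_adj=r2, rounded=rounded)


def reference_phenotype_models() -> dict[str, dict[str, PhenotypeModel]]:
    """The fitted type-specific phenotype models of the rice study.

    Keyed by variant then response.  Metabolite predictors are in mM (model
    steady-state values), gene predictors are WT-normalized expression
    ratios, hormone predictors are measured levels; height and leaf
    dimensions in cm, chlorophyll in SPAD-derived mg/g, leaves as a rounded
    count.
    """
    return {
        "I": {
            "height": _ref("height", (56.028, [("MDS", -22.688), ("DXP", 1.590)]), 0.53),
            "leaves": _ref("leaves", (4.738, [("DXP", 0.318), ("MEcPP", -0.245)]), 0.72, rounded=True),
            "leaf_length": _ref("leaf_length", (31.045, [("HMGS", -3.135), ("HMBPP", 1549.320)]), 0.69),
            "chlorophyll": _ref("chlorophyll", (32.218, [("IAA", 0.154), ("HMGS", -1.571)]), 0.74),
        },
        "II": {
            "leaves": _ref("leaves", (3.325, [("ACC", -0.00312), ("HMGCoA_cyt", 0.0557)]), 0.70, rounded=True),
            "leaf_length": _ref("leaf_length", (41.621, [("HMGS", 6.048), ("MEP", -116.641)]), 0.77),
            "leaf_width": _ref("leaf_width", (0.596, [("HMGS", 0.124), ("MVD", 0.0464)]), 0.61),
            "chlorophyll": _ref("chlorophyll", (39.29, [("iP", 1.620), ("HDR", -1.446)]), 0.75),
        },
        "III": {
            "height": _ref("height", (76.626, [("GA4", 25.445), ("HMGS", 0.432)]), 0.60),
            "leaf_length": _ref("leaf_length", (50.826, [("WR1", 0.197), ("MVPP_cyt", 9071.25)]), 0.43),
            "leaf_width": _ref("leaf_width", (0.881, [("HMGS", 0.005), ("HMGCoA_cyt", 0.007)]), 0.40),
            "chlorophyll": _ref("chlorophyll", (33.218, [("HDR", 10.968), ("DMAPP", 75003.0)]), 0.46),
        },
    }


def gather_predictor_inputs(line: LineProfile,
                            steady_concentrations: dict[str, float] | None,
                            predictors: list[str]) -> dict[str, float]:
    """Resolve predictor values for a line: gene ratio, hormone level or
    model steady-state metabolite concentration (aliases resolved)."""
    inputs: dict[str, float] = {}
    for p in predictors:
        kind = predictor_type(p)
        if kind == "gene":
            gene = _GENE_ALIASES.get(p, p)
            inputs[p] = line.expression_ratio[gene]
        elif kind == "hormone":
            inputs[p] = line.hormone[p].level
        else:
            if steady_concentrations is None:
                raise KeyError(p)
            pool = _METABOLITE_ALIASES.get(p, p)
            inputs[p] = steady_concentrations[pool]
    return inputs


def predict_line_phenotype(
    line: LineProfile,
    steady_concentrations: dict[str, float] | None,
    models: dict[str, PhenotypeModel],
) -> dict[str, float | None]:
    """Chain molecular state to macroscopic phenotype for one line.

    ``steady_concentrations`` is the line's (stabilized) model steady state;
    pass None for an unstable line, in which case metabolite-dependent
    responses are reported as None (unpredictable).
    """
    out: dict[str, float | None] = {}
    for response, model in models.items():
        try:
            inputs = gather_predictor_inputs(line, steady_concentrations,
                                             model.predictors)
        except KeyError:
            out[response] = None
            continue
        out[response] = model.evaluate(inputs)
    return out
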