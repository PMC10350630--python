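"""Synthetic cohort generator with the statistical structure of the study.

Emulates, per engineered line: gene-expression fold-changes versus WT
(log-normal; exogenous transgenes present only in the matching variant),
hormone panels (log-normal on a log10 scale with below-detection censoring),
and macroscopic phenotypes generated from planted affine models plus
Gaussian noise (leaf counts rounded).

Two features tie the cohorts to the modelling pipeline:

* **Planted consumer deficits.**  Mutant lines under-express the consumers
  of the early MEP intermediates (DXR for DXP; additionally MDS for CDP-MEP
  in Type II; additionally HDS for MEcPP in Type III).  The planted center
  is ``gamma * q`` where ``q = x/(K+x)`` is the calibrated saturation
  fraction of the consumer — the exact capacity threshold below which the
  consuming flux can no longer carry the incoming flux — so the
  line-personalized models lose their steady state with the matching pools
  accumulating, and stabilization needs a Vmax multiplier of about
  ``1/gamma``.  Deficits deepen from Type I to Type III, so the
  stabilization magnitude ranks (II, III) > I.
* **Planted hormone links.**  A hormone modulates a gene's expression ratio
  multiplicatively as ``(H / H_median)^g``, creating recoverable log-log
  correlations between hormone levels and both gene activities and the
  downstream model metabolite concentrations.

All draws are deterministic in the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibrate import ParameterLibrary, calibrate_parameters
from .lines import HORMONES, HormoneMeasurement, LineProfile
from .network import (
    ENDOGENOUS_GENES,
    EXOGENOUS_BY_VARIANT,
    EXOGENOUS_GENES,
    ParameterSet,
)
from .phenotype import PhenotypeModel

#: cohort sizes of the study (independent transformants per type)
DEFAULT_COHORT = {"WT": 6, "I": 12, "II": 10, "III": 12}

#: planted consumer-deficit depth gamma per variant (fraction of the
#: calibrated capacity threshold)
DEFICIT_GAMMA: dict[str, dict[str, float]] = {
    "WT": {},
    "I": {"OsDXR": 0.7},
    "II": {"OsDXR": 0.3, "OsMDS": 0.3},
    "III": {"OsDXR": 0.2, "OsMDS": 0.2, "OsHDS": 0.2},
}

#: gene -> (consumed pool, reaction id) for the deficit capacity computation
_DEFICIT_REACTION = {"OsDXR": ("DXP", "r11"), "OsMDS": ("CDPMEP", "r14"),
                     "OsHDS": ("MECPP", "r15")}

#: hormone panel log10 means (levels in relative measurement units)
DEFAULT_HORMONE_LOG10_MEAN = {
    "trans_zeatin": 0.5, "zeatin_riboside": 0.3, "iP": 0.7,
    "GA1": 0.0, "GA3": 0.2, "GA4": -0.3, "IAA": 1.5, "ABA": 1.8,
    "salicylic_acid": 2.5, "jasmonic_acid": 1.2, "ACC": 2.0,
}
DEFAULT_HORMONE_LOG10_SD = {h: 0.3 for h in HORMONES}
#: detection limits; jasmonic acid is set high enough to censor ~30% of
#: lines so the piecewise detection-limit handling is exercised
DEFAULT_DETECTION_LIMITS = {
    h: 10.0 ** (DEFAULT_HORMONE_LOG10_MEAN[h] - 2.5 * DEFAULT_HORMONE_LOG10_SD[h])
    for h in HORMONES
}
DEFAULT_DETECTION_LIMITS["jasmonic_acid"] = 10.0 ** (
    DEFAULT_HORMONE_LOG10_MEAN["jasmonic_acid"]
    - 0.5 * DEFAULT_HORMONE_LOG10_SD["jasmonic_acid"]
)


@dataclass(frozen=True)
class PlantedLink:
    hormone: str
    gene: str
    g: float  # log-log exponent of the modulation


DEFAULT_PLANTED_LINKS = (
    PlantedLink("iP", "OsDXS", 0.8),
    PlantedLink("ABA", "OsMCT", -0.5),
)


@dataclass(frozen=True)
class PlantedPhenotype:
    response: str
    intercept: float
    terms: tuple[tuple[str, float], ...]  # (predictor, beta); gene or hormone
    target_r2: float = 0.7


DEFAULT_PLANTED_PHENOTYPES = (
    PlantedPhenotype("height", 50.0, (("OsDXR", 12.0), ("iP", 0.8))),
    PlantedPhenotype("leaves", 5.0, (("OsDXS", 1.5), ("ABA", -0.02))),
    PlantedPhenotype("leaf_length", 30.0, (("OsHMGS", 5.0), ("ACC", 0.05))),
    PlantedPhenotype("leaf_width", 0.8, (("OsMDS", 0.3),)),
    PlantedPhenotype("chlorophyll", 35.0, (("OsHDR", 2.0), ("iP", 0.1))),
)


@dataclass
class GeneratorConfig:
    """Study-condition knobs of the synthetic cohort generator."""

    seed: int = 0
    variant: str = "I"
    n_lines: int | None = None  # default: the study cohort size
    endogenous_log_sd: float = 0.3  # natural-log SD of expression ratios
    exogenous_log_sd: float = 0.6  # non-targeted integration varies more
    hormone_log10_mean: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HORMONE_LOG10_MEAN))
    hormone_log10_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HORMONE_LOG10_SD))
    detection_limits: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DETECTION_LIMITS))
    planted_links: tuple[PlantedLink, ...] = DEFAULT_PLANTED_LINKS
    planted_phenotypes: tuple[PlantedPhenotype, ...] = DEFAULT_PLANTED_PHENOTYPES
    deficit_gamma: dict[str, float] | None = None  # default: DEFICIT_GAMMA[variant]

    def __post_init__(self) -> None:
        if self.n_lines is None:
            self.n_lines = DEFAULT_COHORT[self.variant]
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        for sd in (self.endogenous_log_sd, self.exogenous_log_sd):
            if sd < 0:
                raise ValueError("log-SDs must be >= 0")
        if self.deficit_gamma is None:
            self.deficit_gamma = dict(DEFICIT_GAMMA[self.variant])


def generate_parameter_set(config: GeneratorConfig) -> ParameterLibrary:
    """Calibrated kinetic constants (see :mod:`mvamep.calibrate`);
    deterministic in the config seed."""
    return calibrate_parameters(seed=config.seed)


def _capacity_threshold(params: ParameterSet, gene: str) -> float:
    """Saturation fraction q of the deficit consumer at its basal substrate."""
    from .calibrate import _q  # shares the basal-scale convention

    pool, rid = _DEFICIT_REACTION[gene]
    K = params.values[rid]["K"][pool]
    return _q(pool, K)


def _expression_centers(config: GeneratorConfig, params: ParameterSet
                        ) -> dict[str, float]:
    centers = {g: 1.0 for g in ENDOGENOUS_GENES}
    for gene, gamma in config.deficit_gamma.items():
        centers[gene] = gamma * _capacity_threshold(params, gene)
    for g in EXOGENOUS_BY_VARIANT[config.variant]:
        centers[g] = 1.0
    return centers


def generate_lines(config: GeneratorConfig,
                   params: ParameterLibrary | None = None) -> list[LineProfile]:
    """A cohort of line profiles for the config's variant."""
    if params is None:
        params = generate_parameter_set(config)
    pset = params.for_variant(config.variant)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    centers = _expression_centers(config, pset)
    exo = set(EXOGENOUS_BY_VARIANT[config.variant])
    wild_type = config.variant == "WT"

    profiles: list[LineProfile] = []
    rows_signal: dict[str, list[float]] = {
        p.response: [] for p in config.planted_phenotypes}
    raw: list[dict] = []
    for i in range(config.n_lines):
        ratios: dict[str, float] = {}
        for g in ENDOGENOUS_GENES:
            if wild_type:
                ratios[g] = 1.0
            else:
                ratios[g] = centers[g] * float(
                    np.exp(rng.normal(0.0, config.endogenous_log_sd)))
        for g in EXOGENOUS_GENES:
            if g in exo:
                ratios[g] = float(np.exp(rng.normal(0.0, config.exogenous_log_sd)))
            else:
                ratios[g] = 0.0

        hormones: dict[str, HormoneMeasurement] = {}
        for h in HORMONES:
            level = 10.0 ** rng.normal(config.hormone_log10_mean[h],
                                       config.hormone_log10_sd[h])
            below = level < config.detection_limits[h]
            hormones[h] = HormoneMeasurement(level=float(level),
                                             below_detection=bool(below))

        if not wild_type:
            for link in config.planted_links:
                h_med = 10.0 ** config.hormone_log10_mean[link.hormone]
                factor = (hormones[link.hormone].level / h_med) ** link.g
                ratios[link.gene] *= factor

        raw.append({"ratios": ratios, "hormones": hormones})
        for planted in config.planted_phenotypes:
            signal = planted.intercept
            for pred, beta in planted.terms:
                val = ratios[pred] if pred in ratios else hormones[pred].level
                signal += beta * val
            rows_signal[planted.response].append(signal)

    noise_sd: dict[str, float] = {}
    for planted in config.planted_phenotypes:
        sig = np.asarray(rows_signal[planted.response])
        var = float(np.var(sig))
        r2 = planted.target_r2
        noise_sd[planted.response] = float(np.sqrt(var * (1.0 - r2) / r2)) if var > 0 else 0.0

    for i, rec in enumerate(raw):
        phenos: dict[str, float] = {}
        for planted in config.planted_phenotypes:
            y = rows_signal[planted.response][i] + rng.normal(0.0, noise_sd[planted.response])
            phenos[planted.response] = float(round(y)) if planted.response == "leaves" else float(y)
        profiles.append(LineProfile(
            line_id=f"{config.variant}_{i+1:02d}", variant=config.variant,
            expression_ratio=rec["ratios"], hormone=rec["hormones"],
            phenotype=phenos,
        ))
    return profiles


@dataclass
class GroundTruthBundle:
    """Cohort plus the truth objects every recovery test needs."""

    config: GeneratorConfig
    params: ParameterLibrary
    lines: list[LineProfile]
    true_links: tuple[PlantedLink, ...]
    true_phenotypes: dict[str, PhenotypeModel]
    true_multipliers: dict[str, float]  # reaction id -> expected Vmax multiplier


def make_ground_truth_bundle(config: GeneratorConfig) -> GroundTruthBundle:
    params = generate_parameter_set(config)
    lines = generate_lines(config, params)
    true_phenos = {
        p.response: PhenotypeModel(
            response=p.response,
            predictors=[t[0] for t in p.terms],
            coefficients={"intercept": p.intercept, **dict(p.terms)},
            rounded=(p.response == "leaves"),
        )
        for p in config.planted_phenotypes
    }
    multipliers = {
        _DEFICIT_REACTION[gene][1]: 1.0 / gamma
        for gene, gamma in config.deficit_gamma.items()
    }
    return GroundTruthBundle(
        config=config, params=params, lines=lines,
        true_links=config.planted_links, true_phenotypes=true_phenos,
        true_multipliers=multipliers,
    )


# -- small direct datasets for recovery tests -------------------------------

def make_link_dataset(seed: int, n: int = 30, alpha: float = 2.0,
                      g: float = 0.8, noise_cv: float = 0.2
                      ) -> tuple[np.ndarray, np.ndarray]:
    """(H, M) samples with M = alpha * H^g * lognormal noise."""
    rng = np.random.default_rng(seed)
    H = 10.0 ** rng.normal(1.0, 0.4, size=n)
    sigma = np.sqrt(np.log(1.0 + noise_cv ** 2))
    M = alpha * H ** g * np.exp(rng.normal(0.0, sigma, size=n))
    return H, M


def make_regression_dataset(seed: int, n: int = 30, n_decoys: int = 5,
                            betas: tuple[float, float] = (2.0, -1.5),
                            target_r2: float = 0.7) -> tuple[pd.DataFrame, list[str]]:
    """Planted 2-predictor response among decoys; returns (data, true names)."""
    rng = np.random.default_rng(seed)
    cols = {}
    for i in range(2 + n_decoys):
        cols[f"x{i+1}"] = rng.normal(0.0, 1.0, size=n)
    df = pd.DataFrame(cols)
    signal = 10.0 + betas[0] * df["x1"] + betas[1] * df["x2"]
    var = float(np.var(signal))
    sd = np.sqrt(var * (1.0 - target_r2) / target_r2)
    df["y"] = signal + rng.normal(0.0, sd, size=n)
    return df, ["x1", "x2"]
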