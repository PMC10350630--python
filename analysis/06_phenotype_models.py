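"""Forward-stepwise phenotype models and multilevel phenotype prediction.

Per mutant type: regress each macroscopic trait on gene-expression ratios,
hormone levels and model steady-state metabolite concentrations by forward
stepwise selection (significance + adjusted-R2 gates, AICc tie-breaks,
collinearity exclusion), then chain molecular state -> phenotype per line
and tabulate observed vs predicted.  Writes results/phenotype_models_<v>.json
and results/predictions_<v>.tsv.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from mvamep.pipeline import (
    build_cohorts,
    line_steady_states,
    median_variant_workflow,
    phenotype_stage,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    lib, cohorts = build_cohorts(args.seed)
    for variant in ("I", "II", "III"):
        res = median_variant_workflow(lib, variant, cohorts[variant])
        mult = res.stabilization.chosen.multipliers if res.stabilization else None
        states = line_steady_states(lib, variant, cohorts[variant], mult)
        stage = phenotype_stage(res, states)
        (args.out / f"phenotype_models_{variant}.json").write_text(json.dumps(
            {r: m.to_dict() for r, m in stage["models"].items()}, indent=1))
        stage["predictions"].to_csv(args.out / f"predictions_{variant}.tsv",
                                    sep="\t", index=False, na_rep="NA")
        print(f"Type {variant}:")
        for response, model in stage["models"].items():
            terms = " + ".join(f"{model.coefficients[p]:.3g}*{p}"
                               for p in model.predictors)
            print(f"  {response} = {model.coefficients['intercept']:.3g} + "
                  f"{terms}  (adj R2 {model.r2_adj:.2f})")
        preds = stage["predictions"].dropna()
        if len(preds):
            err = np.sqrt(np.mean((preds.observed - preds.predicted) ** 2))
            print(f"  overall observed-vs-predicted RMSE: {err:.3g}")


if __name__ == "__main__":
    main()
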