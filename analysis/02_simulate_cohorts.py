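"""Generate the synthetic line cohorts for all four genotypes.

Emulates the study's cohort structure (WT plus 12/10/12 independent
transformant lines of Types I/II/III) with per-gene expression fold-changes,
censored hormone panels and phenotypes from planted models.  Writes one TSV
per variant under results/.
"""

import argparse
from pathlib import Path

from mvamep.calibrate import calibrate_parameters
from mvamep.lines import write_profiles_tsv
from mvamep.synthetic import GeneratorConfig, generate_lines


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    lib = calibrate_parameters(seed=args.seed)
    for variant in ("WT", "I", "II", "III"):
        lines = generate_lines(GeneratorConfig(seed=args.seed, variant=variant), lib)
        path = args.out / f"lines_{variant}.tsv"
        write_profiles_tsv(lines, path)
        n_censored = sum(m.below_detection for p in lines
                         for m in p.hormone.values())
        print(f"variant {variant}: {len(lines)} lines -> {path} "
              f"({n_censored} censored hormone values)")


if __name__ == "__main__":
    main()
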