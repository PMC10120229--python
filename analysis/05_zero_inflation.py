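"""Is zero-inflation driven by population-restricted expression?

On a two-population synthetic dataset, rank genes by the two-proportion
detection-rate z-statistic into the top differentially detected ("DE")
and most stably detected ("stable") sets, fit Poisson/NB/ZIP/ZINB to each
gene's pooled counts, select by BIC, and test whether zero-inflated
models are enriched among the DE genes with an exact 2x2 analysis.
"""

import argparse
from pathlib import Path

from scbinary.pipelines import PipelineConfig, run_zi_enrichment


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--top-n", type=int, default=100)
    ap.add_argument("--out", type=Path, default=Path("results/zero_inflation"))
    args = ap.parse_args()

    cfg = PipelineConfig(out_dir=args.out, seed=args.seed, top_n=args.top_n)
    r = run_zi_enrichment(cfg)
    (de_zi, de_not), (st_zi, st_not) = r.table
    print("model selection among ranked genes (zero-inflated / not):")
    print(f"  differentially detected: {de_zi} / {de_not}")
    print(f"  stably detected:         {st_zi} / {st_not}")
    print(f"Fisher exact: p = {r.p_two_sided:.3g}, logOR = {r.log_or_cmle:.3f}, "
          f"95% CI ({r.ci95_log[0]:.3f}, {r.ci95_log[1]:.3f})")
    print(f"per-gene fits written to {args.out / 'model_fits.tsv'}")


if __name__ == "__main__":
    main()
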